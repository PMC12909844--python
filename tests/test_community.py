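import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from latentniche import (
    ConsistencyError,
    DetectionMatrix,
    FormatError,
    SiteTable,
    filter_sites,
    filter_species,
    jaccard_distances,
    rarefy_counts,
    read_detection_table,
    site_richness,
)


def _counts_matrix(values, **kw):
    values = np.asarray(values)
    sp = [f"sp{i}" for i in range(values.shape[0])]
    si = [f"s{i}" for i in range(values.shape[1])]
    return DetectionMatrix.from_arrays(values, sp, si, mode="counts", **kw)


class TestIO:
    def test_round_trip(self, tmp_path):
        m = _counts_matrix([[3, 0, 1, 2], [0, 5, 0, 0], [1, 1, 1, 1]])
        path = tmp_path / "det.tsv"
        m.to_tsv(path)
        m2 = read_detection_table(path)
        pd.testing.assert_frame_equal(m.data, m2.data)
        assert m2.mode == "counts"

    def test_duplicate_species_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("species\ts1\ts2\nspA\t1\t0\nspA\t0\t1\n")
        with pytest.raises(FormatError):
            read_detection_table(path)

    def test_binary_table_inferred_presence(self, tmp_path):
        path = tmp_path / "bin.tsv"
        path.write_text("species\ts1\ts2\nspA\t1\t0\nspB\t0\t1\n")
        assert read_detection_table(path).mode == "presence"

    def test_negative_cells_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("species\ts1\nspA\t-2\n")
        with pytest.raises(FormatError):
            read_detection_table(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "txt.tsv"
        path.write_text("species\ts1\nspA\tmany\n")
        with pytest.raises(FormatError):
            read_detection_table(path)


class TestRarefaction:
    def test_site_at_depth_unchanged(self):
        m = _counts_matrix([[7], [3]])
        out, short = rarefy_counts(m, depth=10, seed=0)
        np.testing.assert_array_equal(out.data.to_numpy(), [[7], [3]])
        assert short == []

    def test_single_species_forced_outcome(self):
        m = _counts_matrix([[100]])
        out, _ = rarefy_counts(m, depth=10, seed=1)
        assert out.data.iloc[0, 0] == 10

    def test_hypergeometric_expectation(self):
        # counts (90, 10), depth 10: retained reads of the rare species have
        # mean 1.0 and variance 10*(1/10)*(9/10)*(90/99) under sampling
        # without replacement
        m = _counts_matrix([[90], [10]])
        n_rep = 2000
        rare = np.array([rarefy_counts(m, 10, seed=s)[0].data.iloc[1, 0]
                         for s in range(n_rep)], dtype=float)
        var = 10 * 0.1 * 0.9 * (90.0 / 99.0)
        se = np.sqrt(var / n_rep)
        assert abs(rare.mean() - 1.0) <= 3.0 * se

    def test_never_increases_and_totals_hit_depth(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(5.0, size=(6, 8))
        vals[:, 0] = [1, 0, 2, 0, 1, 0]  # total 4 < depth: kept unrarefied
        m = _counts_matrix(vals)
        with pytest.warns(UserWarning):
            out, short = rarefy_counts(m, depth=20, seed=3)
        assert np.all(out.data.to_numpy() <= vals)
        totals = out.data.sum(axis=0)
        for site in m.site_ids:
            if site in short:
                assert totals[site] == vals[:, m.site_ids.index(site)].sum()
            else:
                assert totals[site] == 20

    def test_presence_mode_rejected(self):
        m = DetectionMatrix.from_arrays([[1, 0]], ["a"], ["s1", "s2"], mode="presence")
        with pytest.raises(ValueError):
            rarefy_counts(m, 5)

    def test_seed_determinism(self):
        m = _counts_matrix(np.arange(12).reshape(3, 4) + 1)
        a, _ = rarefy_counts(m, 4, seed=7)
        b, _ = rarefy_counts(m, 4, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestFilterSpecies:
    def test_occupancy_threshold_boundary(self):
        # 8 sites; spA at 5 sites (removed), spB at 6 sites (retained)
        vals = np.zeros((2, 8), dtype=int)
        vals[0, :5] = 1
        vals[1, :6] = 1
        m = _counts_matrix(vals)
        out, report = filter_species(m, min_sites=6)
        assert out.species_ids == ["sp1"]
        assert report == {"sp0": "occupancy<6"}

    def test_species_complex_removed_despite_high_occupancy(self):
        vals = np.ones((2, 10), dtype=int)
        m = _counts_matrix(vals, is_species_complex=[True, False])
        out, report = filter_species(m, min_sites=6)
        assert out.species_ids == ["sp1"]
        assert report["sp0"] == "species_complex"

    def test_toy_occupancies(self):
        # occupancies (1, 5, 6, 7, 0) -> 2 retained at min_sites=6
        vals = np.zeros((5, 7), dtype=int)
        for i, occ in enumerate([1, 5, 6, 7, 0]):
            vals[i, :occ] = 1
        out, _ = filter_species(_counts_matrix(vals), min_sites=6)
        assert out.n_species == 2

    def test_single_pass_idempotence(self):
        rng = np.random.default_rng(1)
        m = _counts_matrix(rng.integers(0, 2, size=(10, 12)))
        once, _ = filter_species(m, min_sites=3)
        twice, report = filter_species(once, min_sites=3)
        assert report == {}
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_invalid_min_sites(self):
        with pytest.raises(ValueError):
            filter_species(_counts_matrix([[1]]), min_sites=0)


class TestFilterSites:
    def _pair(self, n=10, missing_temp=(), missing_sal=()):
        vals = np.ones((3, n), dtype=int)
        m = _counts_matrix(vals)
        temp = np.linspace(10, 25, n)
        sal = np.full(n, 34.0)
        temp[list(missing_temp)] = np.nan
        sal[list(missing_sal)] = np.nan
        sites = SiteTable.from_arrays(m.site_ids, np.column_stack([np.arange(n), np.arange(n)]),
                                      covariates={"temperature": temp, "salinity": sal})
        return m, sites

    def test_missing_temperature_drops_site(self):
        m, sites = self._pair(10, missing_temp=[4])
        m2, s2, report = filter_sites(m, sites, ["temperature", "salinity"])
        assert m2.n_sites == 9 and len(s2.site_ids) == 9
        assert report == {"s4": "missing_covariate"}

    def test_no_missingness_identity(self):
        m, sites = self._pair(6)
        m2, s2, report = filter_sites(m, sites, ["temperature", "salinity"])
        assert report == {}
        pd.testing.assert_frame_equal(m2.data, m.data)

    def test_only_required_covariates_considered(self):
        m, sites = self._pair(8, missing_sal=[1, 2, 3])
        m2, _, report = filter_sites(m, sites, ["temperature"])
        assert m2.n_sites == 8 and report == {}

    def test_id_mismatch_rejected(self):
        m, sites = self._pair(5)
        m_bad = DetectionMatrix.from_arrays(m.data.to_numpy(), m.species_ids,
                                            [f"x{i}" for i in range(5)], mode="counts")
        with pytest.raises(ConsistencyError):
            filter_sites(m_bad, sites, ["temperature"])


class TestRichnessAndJaccard:
    def test_richness_examples(self):
        m = _counts_matrix([[3, 0, 0], [0, 0, 1], [1, 0, 1]])
        r = site_richness(m)
        assert list(r) == [2, 0, 2]

    def test_all_ones_column(self):
        m = _counts_matrix(np.ones((7, 1), dtype=int))
        assert site_richness(m).iloc[0] == 7

    def test_jaccard_examples(self):
        # site A={sp0,sp1}, B={sp1,sp2}, C=A, D disjoint from A, E/F empty
        vals = np.array([[1, 0, 1, 0, 0, 0],
                         [1, 1, 1, 0, 0, 0],
                         [0, 1, 0, 1, 0, 0]])
        d = jaccard_distances(_counts_matrix(vals)).to_numpy()
        assert d[0, 2] == 0.0                      # identical sites
        np.testing.assert_allclose(d[0, 1], 1 - 1 / 3)
        assert d[0, 3] == 1.0                      # disjoint non-empty
        assert d[4, 5] == 0.0                      # both empty, by convention

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.int8, (4, 5), elements=st.integers(0, 1)))
    def test_jaccard_metric_axioms(self, vals):
        d = jaccard_distances(_counts_matrix(vals.astype(int))).to_numpy()
        n = d.shape[0]
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12
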