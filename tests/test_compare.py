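"""Agreement statistics: tau-b, kappa, Bray-Curtis, overlap, medians."""

import numpy as np
import pandas as pd
import pytest

from conftest import tau_b_bruteforce
from ednacnn.compare import (
    bray_curtis,
    bray_curtis_matrix,
    cohen_kappa,
    kendall_tau_b,
    median_agreement,
    overlap_counts,
    richness_correlation,
)
from ednacnn.pipeline import SampleTable


def _table(data, hierarchy=None):
    rows = [(s, sp, n) for (s, sp), n in data.items()]
    df = pd.DataFrame(rows, columns=["sample_id", "species", "reads"])
    if hierarchy is None:
        hierarchy = {s: (f"F_{s}", "R1") for s in df["sample_id"].unique()}
    return SampleTable(df, hierarchy)


class TestKendallTauB:
    def test_perfect_and_reversed(self):
        x = np.array([5.0, 3.0, 1.0, 4.0])
        assert kendall_tau_b(x, x) == pytest.approx(1.0)
        assert kendall_tau_b(x, -x) == pytest.approx(-1.0)

    def test_frozen_tied_example(self):
        x = [12, 2, 1, 12, 2]
        y = [1, 4, 7, 1, 0]
        assert kendall_tau_b(x, y) == pytest.approx(-0.4714045, abs=1e-6)
        assert tau_b_bruteforce(x, y) == pytest.approx(-0.4714045, abs=1e-6)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(3, 30)
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            expect = tau_b_bruteforce(x, y)
            got = kendall_tau_b(x, y)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_undefined_cases(self):
        assert np.isnan(kendall_tau_b([1.0], [2.0]))
        assert np.isnan(kendall_tau_b([3, 3, 3], [1, 2, 3]))

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(20), rng.random(20)
        assert kendall_tau_b(x, y) == pytest.approx(kendall_tau_b(y, x))
        assert kendall_tau_b(np.exp(x), y) == pytest.approx(kendall_tau_b(x, y))


class TestCohenKappa:
    def test_perfect_agreement(self):
        a = np.array([1, 1, 0, 0, 1], bool)
        assert cohen_kappa(a, a) == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # a=20 both present, b=5 only A, c=10 only B, d=15 both absent
        x = [True] * 20 + [True] * 5 + [False] * 10 + [False] * 15
        y = [True] * 20 + [False] * 5 + [True] * 10 + [False] * 15
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        assert cohen_kappa(x, y) == pytest.approx(0.4)

    def test_chance_level_fixture(self):
        # marginals 0.5/0.5 with observed agreement exactly 0.5 -> kappa 0
        x = [True, True, False, False]
        y = [True, False, True, False]
        assert cohen_kappa(x, y) == pytest.approx(0.0)

    def test_undefined_when_chance_agreement_is_one(self):
        assert np.isnan(cohen_kappa([True, True], [True, True]))

    def test_symmetry_and_empty(self):
        x = np.array([1, 0, 1, 1], bool)
        y = np.array([0, 0, 1, 1], bool)
        assert cohen_kappa(x, y) == pytest.approx(cohen_kappa(y, x))
        with pytest.raises(ValueError):
            cohen_kappa([], [])


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((4, 1, 5), (4, 1, 5), 0.0),
            ((3, 0, 0), (0, 2, 5), 1.0),
            ((6, 2, 0), (2, 2, 4), 0.5),
        ],
    )
    def test_hand_fixtures(self, a, b, expected):
        assert bray_curtis(a, b) == pytest.approx(expected)

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = rng.integers(0, 50, 8), rng.integers(0, 50, 8)
            if a.sum() == 0 and b.sum() == 0:
                continue
            assert 0.0 <= bray_curtis(a, b) <= 1.0

    def test_both_zero_undefined(self):
        assert np.isnan(bray_curtis([0, 0], [0, 0]))

    def test_matrix_zero_diagonal(self):
        t = _table({("S1", "a"): 10, ("S1", "b"): 2, ("S2", "a"): 1})
        m = bray_curtis_matrix(t, level="replicate")
        assert np.allclose(np.diag(m.to_numpy()), 0.0)
        assert m.shape == (2, 2)


class TestOverlapCounts:
    def test_identical_sets_center_only(self):
        s = {"a", "b", "c"}
        out = overlap_counts(s, s, s)
        assert out["abc"] == 3
        assert sum(v for k, v in out.items() if k != "abc") == 0

    def test_disjoint_sets_exclusive_regions(self):
        out = overlap_counts({"a"}, {"b", "c"}, {"d"})
        assert (out["a_only"], out["b_only"], out["c_only"]) == (1, 2, 1)
        assert out["ab"] == out["ac"] == out["bc"] == out["abc"] == 0

    def test_inclusion_exclusion_on_random_sets(self):
        rng = np.random.default_rng(11)
        universe = [f"sp{i}" for i in range(40)]
        for _ in range(30):
            a, b, c = (
                {sp for sp in universe if rng.random() < p} for p in (0.3, 0.5, 0.4)
            )
            o = overlap_counts(a, b, c)
            assert len(a) == o["a_only"] + o["ab"] + o["ac"] + o["abc"]
            assert len(b) == o["b_only"] + o["ab"] + o["bc"] + o["abc"]
            assert len(c) == o["c_only"] + o["ac"] + o["bc"] + o["abc"]


class TestMedianAgreement:
    def test_identical_tables_all_medians_one(self):
        t = _table(
            {("S1", "a"): 100, ("S1", "b"): 10, ("S2", "b"): 50, ("S2", "c"): 5}
        )
        report = median_agreement(t, t, level="replicate", min_reads_grid=[0, 5])
        assert len(report) == 2
        assert (report["tau_median"] == 1.0).all()
        assert (report["kappa_median"] == 1.0).all()

    def test_report_rows_match_grid(self):
        t = _table({("S1", "a"): 100, ("S1", "b"): 10})
        report = median_agreement(t, t, level="replicate", min_reads_grid=[0, 5, 50])
        assert list(report["min_reads"]) == [0, 5, 50]

    def test_median_matches_direct_median(self):
        # three samples with hand-set agreement levels
        ta = _table(
            {("S1", "a"): 10, ("S1", "b"): 5, ("S1", "c"): 1,
             ("S2", "a"): 10, ("S2", "b"): 5, ("S2", "c"): 1,
             ("S3", "a"): 10, ("S3", "b"): 5, ("S3", "c"): 1}
        )
        tb = _table(
            {("S1", "a"): 20, ("S1", "b"): 7, ("S1", "c"): 2,   # tau 1
             ("S2", "a"): 1, ("S2", "b"): 5, ("S2", "c"): 10,   # tau -1
             ("S3", "a"): 10, ("S3", "b"): 1, ("S3", "c"): 5}   # tau 1/3
        )
        report = median_agreement(ta, tb, level="replicate", min_reads_grid=[0])
        taus = sorted([1.0, -1.0, 1 / 3])
        assert report["tau_median"].iloc[0] == pytest.approx(taus[1])

    def test_no_shared_samples_rejected(self):
        ta = _table({("S1", "a"): 1})
        tb = _table({("S2", "a"): 1})
        with pytest.raises(ValueError, match="share no samples"):
            median_agreement(ta, tb, level="replicate", min_reads_grid=[0])


class TestRichnessCorrelation:
    def test_identical_tables_correlate_perfectly(self):
        t = _table(
            {("S1", "a"): 5, ("S2", "a"): 5, ("S2", "b"): 5,
             ("S3", "a"): 5, ("S3", "b"): 5, ("S3", "c"): 5}
        )
        assert richness_correlation(t, t) == pytest.approx(1.0)
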