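"""Nonparametric statistics: exact/approximate branches against oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from adrenotelo.stats import (
    kruskal_wallis_dunn,
    mann_whitney,
    mann_whitney_u,
    mw_approx_p,
    mw_exact_p,
    mw_exact_p_enumerate,
    spearman,
    wilcoxon_signed_rank,
)

# printed per-patient values of the cohort tables, used as fixed inputs
ZR_MEN_CONTROL = [1.27, 1.28, 1.01, 0.96, 1.17, 0.92, 1.11]
ZR_MEN_PCI = [0.56, 0.64, 0.57, 0.49, 0.65, 0.66, 0.84, 0.54, 0.63, 0.48]


def brute_force_exact_p(x, y) -> float:
    """Independent oracle: enumerate every group assignment directly."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    u_obs, _ = mann_whitney_u(x, y)
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(n) if i not in idx]
        u = sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)
        total += 1
        lo += u <= u_obs
        hi += u >= u_obs
    return min(1.0, 2 * min(lo, hi) / total)


class TestMannWhitneyU:
    @pytest.mark.parametrize(
        ("x", "y", "u", "tie"),
        [
            ([3, 4], [1, 2], 4.0, False),
            ([1], [1], 0.5, True),
            (ZR_MEN_CONTROL, ZR_MEN_PCI, 70.0, False),  # complete separation
        ],
    )
    def test_examples(self, x, y, u, tie):
        assert mann_whitney_u(x, y) == (u, tie)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=8),
        st.lists(st.integers(0, 100), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, x, y):
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == len(x) * len(y)


class TestExactBranch:
    def test_two_by_two_tail(self):
        # C(4,2)=6 assignments; U=0 occurs once -> p = 2 * 1/6
        assert mw_exact_p(0, 2, 2) == pytest.approx(2 / 6)

    def test_non_integral_u_directed_to_approx(self):
        with pytest.raises(ValueError, match="approx"):
            mw_exact_p(3.5, 3, 3)

    def test_recurrence_equals_enumeration_spot_checks(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (4, 4), (5, 3), (6, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u, tie = mann_whitney_u(x, y)
            assert not tie
            assert mw_exact_p(u, n1, n2) == brute_force_exact_p(x, y)

    def test_enumeration_handles_ties(self):
        x = [1.0, 2.0, 2.0]
        y = [2.0, 3.0, 4.0]
        assert mw_exact_p_enumerate(x, y) == brute_force_exact_p(x, y)


class TestApproxBranch:
    def test_matches_reference_asymptotic_implementation(self):
        """Tie/continuity-corrected Gaussian branch == scipy's asymptotic MW."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(4, 12, 2)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            u, _ = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(
                x, y, use_continuity=True, method="asymptotic", alternative="two-sided"
            ).pvalue
            assert mw_approx_p(u, x, y) == pytest.approx(float(ref), abs=1e-12)

    def test_all_identical_values_give_p_one(self):
        assert mw_approx_p(4.5, [2.0] * 3, [2.0] * 3) == 1.0


class TestMannWhitneyAuto:
    def test_tie_free_input_selects_exact(self):
        res = mann_whitney(ZR_MEN_CONTROL, ZR_MEN_PCI)
        assert res.method == "exact"
        assert res.u_raw == 70.0
        assert round(res.p_two_sided, 4) == 0.0001

    def test_tied_input_selects_corrected_gaussian(self):
        res = mann_whitney([1.0, 2.0, 2.0, 5.0], [3.0, 2.0, 6.0, 7.0])
        assert res.method == "approx_cc" and res.tie_present

    def test_forced_exact_with_ties_enumerates(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [3.0, 2.0, 6.0, 7.0]
        res = mann_whitney(x, y, method="exact")
        assert res.method == "exact"
        assert res.p_two_sided == brute_force_exact_p(x, y)

    def test_identical_multisets_are_maximally_nonsignificant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        for method in ("auto", "exact", "approx"):
            assert mann_whitney(x, list(x), method=method).p_two_sided == 1.0

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=9)
            assert (
                mann_whitney(x, y).p_two_sided == mann_whitney(y, x).p_two_sided
            )

    def test_monotone_shift_decreases_p(self):
        """Shifting one group away strictly lowers p until separation."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        last = None
        for c in (0.0, 1.0, 2.0, 4.0, 8.0):
            p = mann_whitney(x + c, y).p_two_sided
            if last is not None:
                assert p <= last
            last = p
        assert mann_whitney(x + 100.0, y).u_raw == 64.0  # complete separation


class TestWilcoxon:
    def test_small_exact_case(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.w_plus == 6.0 and res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.25)

    def test_symmetric_pair_is_nonsignificant(self):
        assert wilcoxon_signed_rank([-1.0, 1.0]).p_two_sided == 1.0

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.method == "degenerate" and res.p_two_sided == 1.0
        assert res.n_zero == 2

    def test_exact_matches_reference_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = rng.normal(size=int(rng.integers(4, 12)))
            ours = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert ours.method == "exact"
            assert ours.p_two_sided == pytest.approx(float(ref), abs=1e-12)


class TestKruskalDunn:
    def test_hand_computed_h(self):
        # ranks 1..6 in groups of 2: rank sums 3, 7, 11
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        res = kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6]])
        assert res.h == pytest.approx(32 / 7)

    def test_matches_reference_h_and_p(self):
        rng = np.random.default_rng(5)
        groups = [rng.integers(0, 8, 6).astype(float) for _ in range(4)]
        res = kruskal_wallis_dunn(groups)
        ref_h, ref_p = sps.kruskal(*groups)
        assert res.h == pytest.approx(float(ref_h))
        assert res.p_two_sided == pytest.approx(float(ref_p))

    def test_group_permutation_invariance(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        a = kruskal_wallis_dunn(groups)
        b = kruskal_wallis_dunn(groups[::-1])
        assert a.h == pytest.approx(b.h)
        assert sorted(a.dunn_p_adjusted.values()) == pytest.approx(
            sorted(b.dunn_p_adjusted.values())
        )

    def test_dunn_hand_check(self):
        # mean ranks 1.5/3.5/5.5, pooled variance term 6*7/12 = 3.5
        res = kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6]])
        z_expected = 4.0 / np.sqrt(3.5 * (0.5 + 0.5))
        assert res.dunn_z[(0, 2)] == pytest.approx(z_expected)
        assert res.dunn_p_adjusted[(0, 2)] == pytest.approx(
            min(1.0, 2 * sps.norm.sf(z_expected) * 3)
        )

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis_dunn([[1.0], [2.0]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0

    def test_zero_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.rho) and res.p_two_sided is None

    def test_duration_vs_zr_rtl_in_pci_men(self, cohort):
        """Moderate negative, non-significant correlation in the cohort."""
        ids = cohort.patient_ids("PCI", "M")
        rtl = {r.patient_id: r.rtl_zr for r in cohort.rtl}
        hours = [p.duration_hours() for p in cohort.patients if p.patient_id in ids]
        vals = [rtl[i] for i in ids]
        res = spearman(hours, vals)
        assert res.rho == pytest.approx(-0.52, abs=0.05)
        assert res.p_two_sided > 0.05
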