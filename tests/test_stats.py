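from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranovol.stats import (
    DegenerateStratificationError,
    cox_binary,
    dunn_bonferroni,
    km_curve,
    kruskal_wallis,
    landmark_analysis,
    mann_whitney,
    spearman_pfs_os,
)

from oracles import (
    cox_grid_argmax,
    dunn_oracle,
    kruskal_oracle,
    mannwhitney_u_oracle,
    spearman_oracle,
)

# interleaved six-patient landmark set: 3 progressors with residual
# survivals 2/5/9 months, 3 non-progressors with 4/8/10, all deaths observed
SIX = dict(times=[2.0, 5.0, 9.0, 4.0, 8.0, 10.0],
           events=[True] * 6,
           flags=[1, 1, 1, 0, 0, 0])


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_pfs_os([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        r = spearman_pfs_os([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        r = spearman_pfs_os(x, y)
        rho_o, p_o = spearman_oracle(x, y)
        assert r.rho == pytest.approx(0.8)
        assert r.rho == pytest.approx(rho_o)
        assert r.p_value == pytest.approx(p_o, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_pfs_os([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.floats(0.1, 50, allow_nan=False), min_size=4, max_size=10,
                    unique=True))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_monotone_transform(self, xs):
        ys = [x * 2 + 1 for x in xs]
        base = spearman_pfs_os(xs, ys).rho
        trans = spearman_pfs_os([math.log(x) for x in xs], [y ** 3 for y in ys]).rho
        assert trans == pytest.approx(base)


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_rank_example(self):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        r = kruskal_wallis(groups)
        h_o, p_o = kruskal_oracle(groups)
        assert r.statistic == pytest.approx(7.2)
        assert r.statistic == pytest.approx(h_o)
        assert r.p_value == pytest.approx(p_o, rel=1e-9)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=6),
           st.lists(st.floats(0.1, 50), min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=40)
    def test_rank_invariance_under_monotone_transform(self, a, b):
        base = kruskal_wallis([a, b]).statistic
        trans = kruskal_wallis([[x ** 3 for x in a], [x ** 3 for x in b]]).statistic
        assert trans == pytest.approx(base, abs=1e-9)


class TestDunn:
    def test_identical_groups_give_p_one(self):
        pairs = dunn_bonferroni([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert all(p.p_adjusted == pytest.approx(1.0) for p in pairs)

    def test_matches_rank_oracle(self):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        pairs = dunn_bonferroni(groups)
        oracle = dunn_oracle(groups)
        for idx, p in enumerate(pairs):
            i, j = int(p.pair[0]), int(p.pair[1])
            z_o, padj_o = oracle[(i, j)]
            assert p.z == pytest.approx(z_o)
            assert p.p_adjusted == pytest.approx(padj_o)

    def test_two_groups_adjustment_factor_one(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        (pair,) = dunn_bonferroni(groups)
        z_o, padj_o = dunn_oracle(groups)[(0, 1)]
        assert pair.p_adjusted == pytest.approx(padj_o)
        # single pair: no multiplicity inflation
        from scipy.stats import norm
        assert pair.p_adjusted == pytest.approx(2 * norm.sf(abs(pair.z)))

    def test_bonferroni_cap_at_one(self):
        pairs = dunn_bonferroni([[1, 2], [1.5, 2.5], [2, 3], [1, 3]])
        assert all(p.p_adjusted <= 1.0 for p in pairs)


class TestMannWhitney:
    def test_identical_multisets_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_complete_separation_u_zero(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == mannwhitney_u_oracle([1, 2, 3], [4, 5, 6]) == 0.0

    def test_u_matches_enumeration_with_ties(self):
        a, b = [1, 2, 2, 5, 7], [2, 3, 3, 6]
        u, _ = mann_whitney(a, b)
        assert u == pytest.approx(mannwhitney_u_oracle(a, b))

    def test_singletons(self):
        u, _ = mann_whitney([1], [2])
        assert u in (0.0, 1.0)


class TestCox:
    def test_beta_matches_grid_oracle(self):
        res = cox_binary(**{"times": SIX["times"], "events": SIX["events"],
                            "group_flags": SIX["flags"]})
        beta_grid = cox_grid_argmax(SIX["times"], SIX["events"], SIX["flags"],
                                    lo=-4, hi=4, num=80001)
        assert res.beta == pytest.approx(beta_grid, abs=1e-3)
        assert not res.monotone

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"t": SIX["times"], "e": SIX["events"], "x": SIX["flags"]})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        res = cox_binary(SIX["times"], SIX["events"], SIX["flags"])
        assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)

    def test_breslow_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        times = [2, 2, 3, 5, 5, 8, 9, 9]
        events = [True, True, False, True, True, True, False, True]
        flags = [1, 0, 1, 1, 0, 0, 1, 0]
        df = pd.DataFrame({"t": times, "e": events, "x": flags})
        for ties in ("efron", "breslow"):
            cph = CoxPHFitter()
            cph.fit(df, duration_col="t", event_col="e")
            res = cox_binary(times, events, flags, ties=ties)
            grid = cox_grid_argmax(times, events, flags, lo=-4, hi=4, num=80001,
                                   ties=ties)
            assert res.beta == pytest.approx(grid, abs=1e-3)
            if ties == "efron":
                assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)

    def test_duplication_invariance(self):
        # duplicating every row leaves the score equation unchanged under
        # Breslow ties; Efron's within-tie fractions treat the duplicated
        # deaths sequentially, so its estimate only approximately agrees
        res1 = cox_binary(SIX["times"], SIX["events"], SIX["flags"], ties="breslow")
        res2 = cox_binary(SIX["times"] * 2, SIX["events"] * 2, SIX["flags"] * 2,
                          ties="breslow")
        assert res2.beta == pytest.approx(res1.beta, abs=1e-9)
        e1 = cox_binary(SIX["times"], SIX["events"], SIX["flags"])
        e2 = cox_binary(SIX["times"] * 2, SIX["events"] * 2, SIX["flags"] * 2)
        assert e2.beta == pytest.approx(e1.beta, abs=0.1)

    def test_reciprocal_hr_on_group_relabel(self):
        res = cox_binary(SIX["times"], SIX["events"], SIX["flags"])
        flipped = cox_binary(SIX["times"], SIX["events"],
                             [1 - f for f in SIX["flags"]])
        assert flipped.hr == pytest.approx(1.0 / res.hr, rel=1e-6)
        assert flipped.beta == pytest.approx(-res.beta, abs=1e-8)

    def test_constant_flag_rejected(self):
        with pytest.raises(ValueError):
            cox_binary([1, 2, 3], [True, True, False], [1, 1, 1])

    def test_all_events_in_one_group_flags_monotone_likelihood(self):
        res = cox_binary([2.0, 5.0], [True, False], [1, 0])
        assert res.monotone and math.isinf(res.hr)

    def test_fully_separated_six_patients_flagged(self):
        # every progressor event precedes every non-progressor event: the
        # partial likelihood is monotone in beta
        res = cox_binary([2, 3, 4, 8, 9, 10], [True] * 6, [1, 1, 1, 0, 0, 0])
        assert res.monotone and math.isinf(res.hr)


def _endpoint_frame():
    # six evaluable patients at the 8-month landmark
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(6)],
        "criterion": ["x"] * 6,
        "pfs_months": [4.0, 5.0, 6.0, 9.5, 10.0, 11.0],
        "pfs_event": [True, True, True, True, True, True],
        "pps_months": [6.0, 8.0, 11.0, 6.5, 6.0, 7.0],
        "pps_event": [True] * 6,
        "os_months": [10.0, 13.0, 17.0, 12.0, 16.0, 18.0],
        "os_event": [True] * 6,
    })


class TestLandmark:
    def test_groups_medians_and_hr(self):
        res = landmark_analysis(_endpoint_frame(), 8.0, "x")
        assert (res.n_included, res.n_pd, res.n_sd) == (6, 3, 3)
        assert res.median_os_pd == pytest.approx(13.0)
        assert res.median_os_sd == pytest.approx(16.0)
        grid = cox_grid_argmax([2, 5, 9, 4, 8, 10], [True] * 6, [1, 1, 1, 0, 0, 0],
                               lo=-4, hi=4, num=80001)
        assert math.log(res.hr) == pytest.approx(grid, abs=1e-3)

    def test_all_sd_is_degenerate(self):
        df = _endpoint_frame()
        df["pfs_months"] = 9.5  # nobody progressed by 8 months
        with pytest.raises(DegenerateStratificationError):
            landmark_analysis(df, 8.0, "x")

    def test_patients_not_beyond_landmark_excluded(self):
        df = _endpoint_frame()
        df.loc[0, "os_months"] = 7.0  # died before the landmark
        res = landmark_analysis(df, 8.0, "x")
        assert res.n_included == 5

    def test_positive_landmark_required(self):
        with pytest.raises(ValueError):
            landmark_analysis(_endpoint_frame(), 0.0, "x")


class TestKMCurve:
    def test_monotone_and_bounded(self):
        df = km_curve([2, 3, 5, 7, 11], [True, True, False, True, True])
        surv = df["survival"].to_numpy()
        assert np.all(np.diff(surv) <= 1e-12)
        assert surv[0] == pytest.approx(1.0)
        assert np.all((surv >= 0) & (surv <= 1))
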