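import math

import numpy as np
import pandas as pd
import pytest

from audcog.scoring import (CAT_Z_COMPONENTS, EXECUTIVE_COMPONENTS,
                            SPEED_COMPONENTS, assign_groups, build_norms,
                            combination_cat_score, global_scores, zscore,
                            zscore_frame)


def tiny_cohort(rng, n_neg=20, n_pos=40, n_visits=3):
    rows = []
    for i in range(n_neg + n_pos):
        status = "negative" if i < n_neg else "positive"
        for v in range(n_visits):
            rows.append({
                "subject_id": f"S{i:03d}", "hiv_status": status,
                "visit_time": v * 182.0,
                "gap_ms": rng.normal(6, 1.5), "hint_srt": rng.normal(-3, 1),
                "tdt_srt": rng.normal(-9, 1.5), "moca": rng.normal(27, 2),
                "tova_rt": rng.normal(420, 45),
                "tova_exg_mu": rng.normal(350, 40),
                "tova_acs": rng.normal(0, 1.5),
                "cs_groton_mps": rng.normal(0.55, 0.15),
                "cs_groton_err": rng.normal(55, 12),
                "cs_ocl_acc": rng.normal(0.85, 0.08),
                "cs_oneback_rt": rng.normal(750, 60),
                "cs_cpal_acc": rng.normal(0.8, 0.1),
            })
    return pd.DataFrame(rows)


class TestNorms:
    def test_reference_self_standardizes_to_mean0_sd1(self, rng):
        cohort = tiny_cohort(rng)
        norms = build_norms(cohort)
        ref = cohort[cohort["hiv_status"] == "negative"]
        last = ref.loc[ref.groupby("subject_id")["visit_time"].idxmax()]
        z = zscore_frame(last, norms)
        for var in norms.variables():
            vals = z[f"z_{var}"]
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_variable_flagged_unnormable(self, rng):
        cohort = tiny_cohort(rng)
        cohort["moca"] = 27.0
        norms = build_norms(cohort)
        assert "moca" in norms.unnormable
        with pytest.raises(ValueError):
            zscore(27.0, norms, "moca")

    def test_hand_computed_norms_on_small_fixture(self, rng):
        cohort = tiny_cohort(rng, n_neg=5, n_pos=12, n_visits=1)
        norms = build_norms(cohort, ["gap_ms"])
        vals = cohort[cohort["hiv_status"] == "negative"]["gap_ms"]
        assert norms.mean["gap_ms"] == pytest.approx(vals.mean())
        assert norms.sd["gap_ms"] == pytest.approx(vals.std(ddof=1))

    def test_baseline_reference_rule(self, rng):
        cohort = tiny_cohort(rng)
        norms = build_norms(cohort, ["moca"], reference_visit_rule="baseline")
        ref = cohort[(cohort["hiv_status"] == "negative")
                     & (cohort["visit_time"] == 0.0)]
        assert norms.mean["moca"] == pytest.approx(ref["moca"].mean())

    def test_too_few_reference_subjects_rejected(self, rng):
        cohort = tiny_cohort(rng, n_neg=1, n_pos=30, n_visits=1)
        with pytest.raises(ValueError, match="HIV-negative"):
            build_norms(cohort)


class TestZscore:
    def test_value_at_mean_is_zero_and_arithmetic(self, rng):
        norms = build_norms(tiny_cohort(rng), ["moca"])
        assert zscore(norms.mean["moca"], norms, "moca") == pytest.approx(0.0)
        z = zscore(norms.mean["moca"] + 2 * norms.sd["moca"], norms, "moca")
        assert z == pytest.approx(2.0)

    def test_lower_better_direction_flip(self, rng):
        # a gap threshold one SD above the reference mean is one SD worse
        norms = build_norms(tiny_cohort(rng), ["gap_ms"])
        z = zscore(norms.mean["gap_ms"] + norms.sd["gap_ms"], norms, "gap_ms")
        assert z == pytest.approx(-1.0)


class TestCombination:
    @pytest.mark.parametrize("zs,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, -1.0, 0.0), 0.0),
        ((0.4, -0.9, 0.2), -0.1),
    ])
    def test_unweighted_mean(self, zs, expected):
        assert combination_cat_score(*zs) == pytest.approx(expected)

    def test_missing_component_propagates(self):
        assert math.isnan(combination_cat_score(0.5, math.nan, 0.2))


def brute_force_groups(scores, statuses, q_low=0.20, q_high=0.80):
    """Sort-and-cut oracle: explicit order-statistic interpolation."""
    xs = sorted(scores)
    n = len(xs)

    def quantile(q):
        h = (n - 1) * q
        lo, frac = int(math.floor(h)), h - math.floor(h)
        return xs[lo] + frac * (xs[min(lo + 1, n - 1)] - xs[lo])

    lo, hi = quantile(q_low), quantile(q_high)
    out = []
    for s, st in zip(scores, statuses):
        if st == "negative":
            out.append("HIV-negative")
        elif s <= lo:
            out.append("BottomCATs")
        elif s >= hi:
            out.append("TopCATs")
        else:
            out.append("HIV-positive")
    return out


class TestAssignGroups:
    def make_last_visit(self, scores, statuses):
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(len(scores))],
            "hiv_status": statuses,
            "combo_cat_score": scores,
            "visit_time": 1000.0,
        })

    def test_matches_sort_and_cut_oracle(self, rng):
        scores = list(rng.uniform(-3, 3, 100))
        statuses = ["positive" if i % 2 else "negative" for i in range(100)]
        got = assign_groups(self.make_last_visit(scores, statuses))
        expect = brute_force_groups(scores, statuses)
        assert list(got["group"]) == expect

    def test_matches_oracle_with_heavy_ties(self, rng):
        scores = list(rng.integers(-2, 3, 80).astype(float))  # many ties
        statuses = ["positive"] * 60 + ["negative"] * 20
        got = assign_groups(self.make_last_visit(scores, statuses))
        expect = brute_force_groups(scores, statuses)
        assert list(got["group"]) == expect

    def test_groups_disjoint_and_exhaustive(self, rng):
        scores = list(rng.normal(0, 1, 120))
        statuses = ["positive" if i % 3 else "negative" for i in range(120)]
        got = assign_groups(self.make_last_visit(scores, statuses))
        pos = got[got["hiv_status"] == "positive"]
        assert set(pos["group"]) <= {"HIV-positive", "TopCATs", "BottomCATs"}
        assert (got[got["hiv_status"] == "negative"]["group"]
                == "HIV-negative").all()
        assert len(pos) == sum(
            (pos["group"] == g).sum()
            for g in ("HIV-positive", "TopCATs", "BottomCATs"))

    def test_row_order_invariance(self, rng):
        scores = list(rng.normal(0, 1, 50))
        statuses = ["positive"] * 40 + ["negative"] * 10
        df = self.make_last_visit(scores, statuses)
        a = assign_groups(df).set_index("subject_id")["group"]
        b = assign_groups(df.sample(frac=1, random_state=1)) \
            .set_index("subject_id")["group"]
        assert a.sort_index().equals(b.sort_index())

    def test_identical_scores_warn_and_fall_to_one_side(self):
        df = self.make_last_visit([1.0] * 30, ["positive"] * 30)
        with pytest.warns(UserWarning, match="degenerate"):
            got = assign_groups(df)
        assert set(got["group"]) == {"BottomCATs"}  # <= cut wins at ties

    def test_refuses_tiny_cohorts(self):
        df = self.make_last_visit([0.1 * i for i in range(9)],
                                  ["positive"] * 9)
        with pytest.raises(ValueError, match="10"):
            assign_groups(df)

    def test_missing_scores_stay_ungrouped(self, rng):
        scores = list(rng.normal(0, 1, 30)) + [math.nan]
        statuses = ["positive"] * 31
        got = assign_groups(self.make_last_visit(scores, statuses))
        assert got.iloc[-1]["group"] == "ungrouped"

    def test_worsening_a_cat_never_improves_group(self, rng):
        scores = np.array(rng.normal(0, 1, 60))
        statuses = ["positive"] * 45 + ["negative"] * 15
        base = assign_groups(self.make_last_visit(list(scores), statuses))
        order = {"BottomCATs": 0, "HIV-positive": 1, "TopCATs": 2}
        for idx in (0, 7, 23, 44):
            worse = scores.copy()
            worse[idx] -= 1.0  # one CAT worsened lowers the combo mean
            new = assign_groups(self.make_last_visit(list(worse), statuses))
            g0, g1 = base.iloc[idx]["group"], new.iloc[idx]["group"]
            assert order[g1] <= order[g0]


class TestGlobalScores:
    def test_all_zero_components_give_zero_globals(self):
        row = {f"z_{c}": 0.0 for c in
               EXECUTIVE_COMPONENTS + SPEED_COMPONENTS + CAT_Z_COMPONENTS}
        out = global_scores(pd.DataFrame([row]))
        assert out.loc[0, ["global_executive", "global_speed",
                           "global_cat"]].tolist() == [0.0, 0.0, 0.0]

    def test_executive_mean_and_component_sets(self):
        row = {f"z_{c}": 0.0 for c in SPEED_COMPONENTS + CAT_Z_COMPONENTS}
        row.update({f"z_{c}": 1.0 for c in EXECUTIVE_COMPONENTS})
        out = global_scores(pd.DataFrame([row]))
        assert out.loc[0, "global_executive"] == 1.0
        # One Back is a speed component, never an executive one
        assert "cs_oneback_rt" in SPEED_COMPONENTS
        assert "cs_oneback_rt" not in EXECUTIVE_COMPONENTS
        # the attention comparison score enters no composite
        for comps in (EXECUTIVE_COMPONENTS, SPEED_COMPONENTS,
                      CAT_Z_COMPONENTS):
            assert "tova_acs" not in comps

    def test_hand_computed_means_on_three_visit_fixture(self, rng):
        rows = []
        for v in range(3):
            rows.append({f"z_{c}": rng.normal() for c in
                         EXECUTIVE_COMPONENTS + SPEED_COMPONENTS
                         + CAT_Z_COMPONENTS})
        df = pd.DataFrame(rows)
        out = global_scores(df)
        for i in range(3):
            expect = np.mean([df.loc[i, f"z_{c}"] for c in CAT_Z_COMPONENTS])
            assert out.loc[i, "global_cat"] == pytest.approx(expect)

    def test_majority_missing_composite_is_missing(self):
        row = {f"z_{c}": math.nan for c in
               EXECUTIVE_COMPONENTS + SPEED_COMPONENTS + CAT_Z_COMPONENTS}
        row["z_cs_groton_mps"] = 1.0  # 1 of 4 executive components present
        out = global_scores(pd.DataFrame([row]))
        assert math.isnan(out.loc[0, "global_executive"])
        assert math.isnan(out.loc[0, "global_cat"])
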