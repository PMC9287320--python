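"""Reliability/validity statistics against independent oracles.

The ICC implementation is checked against a from-scratch ANOVA mean-squares
computation written here (and against pingouin); Mann-Whitney exact p-values
against full enumeration of group assignments; Spearman against the rank
formula with averaged ties.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdsense.session_model import ClinicalRecord
from pdsense.config import MDS_UPDRS_ITEMS
from pdsense.validation_stats import (build_cohort_table, icc_test_retest,
                                      mannwhitney_groups, mdsupdrs_scores,
                                      spearman_assoc, validity_report)


def icc2_oracle(x):
    """ICC(2,1) from explicitly computed ANOVA mean squares (independent path)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    subj_means = x.mean(axis=1)
    sess_means = x.mean(axis=0)
    grand = x.mean()
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((sess_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - subj_means[:, None] - sess_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_windows_give_one(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        icc, lo, hi = icc_test_retest(x)
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle_on_toy_table(self, rng):
        x = rng.normal(0, 1, (6, 2))
        icc, _, _ = icc_test_retest(x)
        assert icc == pytest.approx(icc2_oracle(x), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(5, 2, (12, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": x.ravel()})
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        # ICC(A,1): two-way random, absolute agreement, single measure
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        icc, lo, hi = icc_test_retest(x)
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=0.01)

    def test_variance_ratio_recovery(self):
        """sigma_b^2=9, sigma_w^2=1 -> ICC ~ 0.9 at n=500."""
        r = np.random.default_rng(77)
        subj = r.normal(0, 3.0, 500)
        x = subj[:, None] + r.normal(0, 1.0, (500, 2))
        icc, _, _ = icc_test_retest(x)
        assert icc == pytest.approx(0.9, abs=0.03)

    def test_listwise_deletion_and_minimum_pairs(self):
        x = np.array([[1.0, np.nan], [2.0, 2.1], [3.0, 2.9], [1.5, 1.4]])
        icc, _, _ = icc_test_retest(x)         # 3 complete pairs remain
        assert np.isfinite(icc)
        assert np.isnan(icc_test_retest(x[:3])[0])   # only 2 complete pairs


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_assoc([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_tied_ranks_match_hand_formula(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 1.0, 2.0, 2.0, 3.0]
        rho, _ = spearman_assoc(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)     # averaged ties
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_antisymmetry(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = spearman_assoc(x, y)
        r2, _ = spearman_assoc(y, x)
        r3, _ = spearman_assoc(x, -y)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r3 == pytest.approx(-r1, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman_assoc([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho)

    def test_exact_p_matches_enumeration(self):
        x = [0.3, 1.2, 0.7, 2.2, 1.9, 0.1]
        y = [1.0, 3.0, 2.0, 6.0, 4.0, 5.0]
        rho, p = spearman_assoc(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        out = mannwhitney_groups([1, 2], [3, 4])
        assert out["u_a"] == 0.0
        assert out["u_b"] == 4.0

    def test_exact_p_one_third(self):
        """Full enumeration over C(4,2)=6 rank splits gives p = 1/3."""
        out = mannwhitney_groups([1, 2], [3, 4])
        assert out["p"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_percent_median_difference(self):
        out = mannwhitney_groups([9, 10, 11], [11, 12, 13])
        assert out["pct_median_diff"] == pytest.approx(20.0)

    def test_zero_reference_median_guarded(self):
        out = mannwhitney_groups([-1, 0, 1], [2, 3, 4])
        assert out["pct_median_diff"] is None

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mannwhitney_groups([], [1.0])


class TestMdsUpdrsScores:
    def _record(self, items):
        base = {i: 0 for i in MDS_UPDRS_ITEMS}
        base.update(items)
        return ClinicalRecord(participant_id="P", mds_updrs_items=base,
                              hoehn_yahr=1)

    def test_all_zero_items_give_zero_bulbar(self):
        assert mdsupdrs_scores(self._record({}))["bulbar"] == 0.0

    def test_bulbar_composite_sum(self):
        scores = mdsupdrs_scores(self._record(
            {"2.1": 2, "2.2": 1, "2.3": 0, "3.1": 3, "3.2": 1}))
        assert scores["bulbar"] == 7.0

    def test_bulbar_bounded_by_20(self):
        scores = mdsupdrs_scores(self._record(
            {"2.1": 4, "2.2": 4, "2.3": 4, "3.1": 4, "3.2": 4}))
        assert scores["bulbar"] == 20.0

    def test_missing_item_gives_missing_subscore(self):
        rec = ClinicalRecord(participant_id="P",
                             mds_updrs_items={"2.1": 1, "3.12": 2},
                             hoehn_yahr=1)
        scores = mdsupdrs_scores(rec)
        assert scores["bulbar"] is None
        assert scores["pigd"] == 2.0


class TestValidityReport:
    @staticmethod
    def _cohort(n=24, seed=5):
        """Noisy monotone features of a latent severity, plus clinical items."""
        r = np.random.default_rng(seed)
        sev = r.uniform(0, 1, n)
        agg_rows = []
        clinicals = []
        from pdsense.config import FEATURE_DEFS, FEATURE_EXPECTED_SIGN
        for i in range(n):
            pid = f"P{i:02d}"
            items = {item: 0 for item in MDS_UPDRS_ITEMS}
            for item in MDS_UPDRS_ITEMS:
                eff = sev[i] + r.normal(0, 0.1)
                items[item] = int(np.clip(np.floor(eff * 4), 0, 4))
            items["3.4L"] = min(items["3.4L"] + 1, 4)      # left more affected
            clinicals.append(ClinicalRecord(participant_id=pid,
                                            mds_updrs_items=items,
                                            hoehn_yahr=1 + (sev[i] > 0.3)))
            for feat, d in FEATURE_DEFS.items():
                sides = ("more", "less") if d["lateralized"] else ("none",)
                for side in sides:
                    for w in (1, 2):
                        value = FEATURE_EXPECTED_SIGN[feat] * sev[i] + \
                            r.normal(0, 0.15)
                        agg_rows.append({"participant_id": pid,
                                         "feature_name": feat, "side": side,
                                         "window": w, "value": value, "n": 5})
        return pd.DataFrame(agg_rows), clinicals

    def test_report_has_17_prespecified_rows(self):
        agg, clin = self._cohort()
        cohort = build_cohort_table(agg, clin)
        rows, matrix = validity_report(cohort)
        assert len(rows) == 17

    def test_expected_directions_on_coupled_cohort(self):
        agg, clin = self._cohort()
        cohort = build_cohort_table(agg, clin)
        rows, _ = validity_report(cohort)
        assert all(r.direction_expected for r in rows
                   if r.direction_expected is not None)

    def test_degenerate_cohort_does_not_crash(self):
        agg, clin = self._cohort(n=12)
        agg["value"] = 1.0                     # identical participants
        cohort = build_cohort_table(agg, clin)
        rows, _ = validity_report(cohort)
        assert all(np.isnan(r.rho) for r in rows)

    def test_unmapped_feature_is_error(self):
        agg, clin = self._cohort(n=12)
        cohort = build_cohort_table(agg, clin)
        with pytest.raises(ValueError, match="unmapped"):
            validity_report(cohort, feature_item_map={"voice_jitter": "3.1"})

    def test_matrix_reports_absolute_correlations(self):
        agg, clin = self._cohort()
        cohort = build_cohort_table(agg, clin)
        _, matrix = validity_report(cohort)
        vals = matrix.to_numpy(dtype=float)
        assert np.nanmin(vals) >= 0.0
        assert np.nanmax(vals) <= 1.0
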