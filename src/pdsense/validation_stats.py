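"""Reliability and validity statistics.

The validation layer mirrors the structure of a feature-validation table:
for every pre-specified sensor feature (and side) it reports

* test-retest reliability: ICC(2,1) — two-way random effects, absolute
  agreement, single measure — between the fortnight-1 and fortnight-2
  aggregated values, with a 95% CI from the F-distribution method;
* clinical validity: Spearman's rank correlation between the fortnight-1
  value and the mapped MDS-UPDRS comparator item at baseline;
* sensitivity to subtle signs: Mann-Whitney U between participants scoring
  0 vs 1 on the comparator item, with the percent difference of group
  medians;
* known-groups validity: the same comparison for Hoehn & Yahr stage I vs II;
* whether the association direction matches the expected direction.

A cross-correlation matrix of |rho| between every feature and the MDS-UPDRS
total/subscale scores accompanies the table.  Raw p-values are reported;
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (BULBAR_ITEMS, FEATURE_EXPECTED_SIGN, FEATURE_ITEM_MAP,
                     FEATURE_DEFS, SUBSCALE_ITEMS, prespecified_feature_keys)
from .session_model import ClinicalRecord

__all__ = ["icc_test_retest", "spearman_assoc", "mannwhitney_groups",
           "mdsupdrs_scores", "validity_report", "ValidationRow",
           "build_cohort_table"]


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def icc_test_retest(pairs: np.ndarray, alpha: float = 0.05):
    """ICC(2,1) with a 95% CI for an (n_subjects, 2) table of repeated values.

    Two-way random effects, absolute agreement, single measure, computed from
    the ANOVA mean squares; the CI follows the F-distribution method.  Rows
    with a missing value are excluded listwise.  Returns
    ``(icc, ci_low, ci_high)``; all NaN when fewer than 3 complete pairs, and
    (1.0, NaN, NaN) for a zero-total-variance table (degenerate CI).
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    x = x[np.isfinite(x).all(axis=1)]
    n, k = x.shape
    if n < 3:
        return np.nan, np.nan, np.nan
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0, np.nan, np.nan

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)             # between-subjects
    msc = ss_cols / (k - 1)             # between-sessions
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse <= 0:
        return float(icc), np.nan, np.nan
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + \
        (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f3u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f3l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f3u * mse) / (f3u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f3l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f3l * msr)
    return float(icc), float(lower), float(upper)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! pairings (average ranks for ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    n = len(rx)
    count = 0
    total = 0
    abs_obs = abs(rho_obs) - 1e-12
    perms = itertools.permutations(range(n))
    chunk_size = 100_000
    while True:
        flat = np.fromiter(itertools.chain.from_iterable(
            itertools.islice(perms, chunk_size)), dtype=np.intp)
        if not len(flat):
            break
        idx = flat.reshape(-1, n)
        rhos = (ry[idx] @ rx) / denom
        count += int((np.abs(rhos) >= abs_obs).sum())
        total += len(idx)
    return count / total


def spearman_assoc(feature_values, clinical_scores, exact_max_n: int = 10):
    """Spearman rho and two-sided p (exact permutation for small samples).

    Average ranks for ties; incomplete pairs dropped; a constant vector
    yields (nan, nan).  For n <= ``exact_max_n`` the p-value enumerates all
    pairings; beyond that the t-approximation is used.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(clinical_scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 5:
        return np.nan, np.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mannwhitney_groups(group_a, group_b):
    """Mann-Whitney U comparison of two groups.

    Returns a dict with both U statistics (U_a references group a), the
    two-sided p (exact for min(n) <= 8 without ties, tie-corrected normal
    approximation otherwise), group sizes, and the percent difference of
    group medians ``100*(median_b - median_a)/|median_a|`` (None when the
    reference median is 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pct = None if med_a == 0 else 100.0 * (med_b - med_a) / abs(med_a)
    return {"u_a": u_a, "u_b": float(len(a) * len(b) - u_a),
            "p": float(res.pvalue), "n_a": int(len(a)), "n_b": int(len(b)),
            "pct_median_diff": pct, "method": method}


# ---------------------------------------------------------------------------
# MDS-UPDRS composite scores
# ---------------------------------------------------------------------------

def mdsupdrs_scores(clinical: ClinicalRecord) -> dict:
    """Bulbar composite and subscale sums over the collected item subset.

    The bulbar score sums items 2.1, 2.2, 2.3, 3.1 and 3.2 (range 0-20).
    A subscore with any missing constituent item is None, never imputed.
    ``total`` sums all collected items.
    """
    items = clinical.mds_updrs_items
    scores: dict[str, float | None] = {}
    for name, needed in SUBSCALE_ITEMS.items():
        if all(i in items for i in needed):
            scores[name] = float(sum(items[i] for i in needed))
        else:
            scores[name] = None
    assert tuple(SUBSCALE_ITEMS["bulbar"]) == tuple(BULBAR_ITEMS)
    scores["total"] = float(sum(items.values())) if items else None
    return scores


# ---------------------------------------------------------------------------
# Validity report
# ---------------------------------------------------------------------------

@dataclass
class ValidationRow:
    feature_name: str
    side: str
    comparator_item: str
    n_retest: int
    icc: float
    icc_ci: tuple
    n_validity: int
    rho: float
    p_rho: float
    mwu_01: dict | None
    mwu_hy: dict | None
    direction_expected: bool | None
    flag: str | None = None


def _comparator_column(feature: str, side: str) -> str:
    item = FEATURE_ITEM_MAP[feature]
    if item.endswith("L") or item.endswith("R"):
        return "item_" + item            # literal left/right item (pinned quirk)
    if FEATURE_DEFS[feature]["lateralized"]:
        return f"item_{item}_{side}"     # same-side comparator (more/less)
    return "item_" + item


def build_cohort_table(aggregated: pd.DataFrame,
                       clinical_records: list[ClinicalRecord]) -> pd.DataFrame:
    """Join window-1/2 aggregated features with clinical scores.

    One row per participant.  Feature columns are named
    ``<feature>__<side>__w<window>``; clinical item columns ``item_<id>``
    with lateralized items also mapped to more/less (``item_3.4_more`` etc.);
    subscale columns ``sub_<name>``.
    """
    from .aggregation import more_affected_side

    wide = {}
    for row in aggregated.itertuples(index=False):
        col = f"{row.feature_name}__{row.side}__w{row.window}"
        wide.setdefault(row.participant_id, {})[col] = row.value
    records = []
    for c in clinical_records:
        entry = wide.setdefault(c.participant_id, {})
        entry["hoehn_yahr"] = c.hoehn_yahr
        more, _ = more_affected_side(c)
        less = "left" if more == "right" else "right"
        for item, score in c.mds_updrs_items.items():
            entry[f"item_{item}"] = score
            if item.endswith(("L", "R")):
                base, lr = item[:-1], item[-1]
                side_label = "more" if (lr == "L") == (more == "left") else "less"
                entry[f"item_{base}_{side_label}"] = score
        for name, score in mdsupdrs_scores(c).items():
            entry[f"sub_{name}"] = score
    for pid, entry in wide.items():
        entry["participant_id"] = pid
        records.append(entry)
    return pd.DataFrame(records).set_index("participant_id").sort_index()


def validity_report(cohort: pd.DataFrame,
                    feature_item_map: dict | None = None,
                    benjamini_hochberg: bool = False):
    """One ValidationRow per pre-specified feature/side + |rho| matrix.

    ``cohort`` is the wide table from :func:`build_cohort_table`.  Raises if
    a pre-specified feature has no comparator mapping.
    """
    if feature_item_map is None:
        feature_item_map = FEATURE_ITEM_MAP
    keys = prespecified_feature_keys()
    missing = [f for f, _ in keys if f not in feature_item_map]
    if missing:
        raise ValueError(f"unmapped features: {sorted(set(missing))}")

    rows: list[ValidationRow] = []
    for feature, side in keys:
        w1 = cohort.get(f"{feature}__{side}__w1")
        w2 = cohort.get(f"{feature}__{side}__w2")
        item_col = _comparator_column(feature, side)
        item = cohort.get(item_col)
        flag = None
        if "item_" + feature_item_map[feature] != item_col and \
                feature_item_map[feature].endswith(("L", "R")):
            flag = "comparator pinned to a literal body side"

        if w1 is None:
            rows.append(ValidationRow(feature, side, item_col, 0, np.nan,
                                      (np.nan, np.nan), 0, np.nan, np.nan,
                                      None, None, None, flag="no data"))
            continue

        if w2 is not None:
            pairs = np.column_stack([w1.to_numpy(dtype=float),
                                     w2.to_numpy(dtype=float)])
            n_retest = int(np.isfinite(pairs).all(axis=1).sum())
            icc, lo, hi = icc_test_retest(pairs)
        else:
            n_retest, icc, lo, hi = 0, np.nan, np.nan, np.nan

        if item is not None:
            x = w1.to_numpy(dtype=float)
            y = item.to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n_validity = int(ok.sum())
            rho, p = spearman_assoc(x[ok], y[ok])
            mwu01 = None
            g0, g1 = x[ok & (y == 0)], x[ok & (y == 1)]
            if len(g0) and len(g1):
                mwu01 = mannwhitney_groups(g0, g1)
        else:
            n_validity, rho, p, mwu01 = 0, np.nan, np.nan, None

        mwu_hy = None
        hy = cohort.get("hoehn_yahr")
        if hy is not None:
            xv = w1.to_numpy(dtype=float)
            hyv = hy.to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(hyv)
            g1, g2 = xv[ok & (hyv == 1)], xv[ok & (hyv == 2)]
            if len(g1) and len(g2):
                mwu_hy = mannwhitney_groups(g1, g2)

        expected = FEATURE_EXPECTED_SIGN.get(feature)
        direction = None
        if expected is not None and np.isfinite(rho) and rho != 0:
            direction = bool(np.sign(rho) == expected)
        rows.append(ValidationRow(feature, side, item_col, n_retest, icc,
                                  (lo, hi), n_validity, rho, p, mwu01, mwu_hy,
                                  direction, flag=flag))

    if benjamini_hochberg:
        ps = np.array([r.p_rho for r in rows])
        ok = np.isfinite(ps)
        if ok.sum():
            adj = stats.false_discovery_control(ps[ok], method="bh")
            j = 0
            for r, keep in zip(rows, ok):
                if keep:
                    r.p_bh = float(adj[j])  # type: ignore[attr-defined]
                    j += 1

    matrix = _cross_correlation_matrix(cohort)
    return rows, matrix


def _cross_correlation_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """|rho| between every pre-specified feature (window 1) and each subscale."""
    sub_cols = [c for c in cohort.columns if c.startswith("sub_")]
    out = {}
    for feature, side in prespecified_feature_keys():
        col = f"{feature}__{side}__w1"
        if col not in cohort.columns:
            continue
        label = feature if side == "none" else f"{feature} ({side[0].upper()})"
        vals = {}
        for sc in sub_cols:
            rho, _ = spearman_assoc(cohort[col].to_numpy(dtype=float),
                                    cohort[sc].to_numpy(dtype=float))
            vals[sc.removeprefix("sub_")] = abs(rho) if np.isfinite(rho) else np.nan
        out[label] = vals
    return pd.DataFrame(out).T


def report_frame(rows: list[ValidationRow]) -> pd.DataFrame:
    """Flatten ValidationRows into a tidy table (one row per feature/side)."""
    recs = []
    for r in rows:
        rec = {"feature": r.feature_name, "side": r.side,
               "comparator": r.comparator_item, "n_retest": r.n_retest,
               "icc": r.icc, "icc_lo": r.icc_ci[0], "icc_hi": r.icc_ci[1],
               "n": r.n_validity, "rho": r.rho, "p": r.p_rho,
               "direction_expected": r.direction_expected}
        if r.mwu_01:
            rec.update({"u01_a": r.mwu_01["u_a"], "p01": r.mwu_01["p"],
                        "n0": r.mwu_01["n_a"], "n1": r.mwu_01["n_b"],
                        "pct_diff_01": r.mwu_01["pct_median_diff"]})
        if r.mwu_hy:
            rec.update({"uhy_a": r.mwu_hy["u_a"], "phy": r.mwu_hy["p"],
                        "pct_diff_hy": r.mwu_hy["pct_median_diff"]})
        recs.append(rec)
    return pd.DataFrame(recs)
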