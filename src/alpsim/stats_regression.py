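"""Statistical layer: per-ROI linear age trends with BH-FDR, and the
asymmetry-vs-ALPS correlation.

Each (ROI, metric) pair gets an ordinary least-squares fit of
``metric ~ age`` with a two-sided slope test; p-values are corrected by
step-up Benjamini-Hochberg across the whole ROI x metric family (the family
definition is configurable).  Effect sizes are reported as the
unstandardised slope beta (units of the metric per year).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "fit_age_trends",
    "bh_fdr",
    "asymmetry_alps_correlation",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced).

    NaN entries are excluded from the family size m and propagated as NaN.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if np.any((flat[ok] < 0) | (flat[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        _, adj, _, _ = multipletests(flat[ok], method="fdr_bh")
        tmp = np.full(flat.shape, np.nan)
        tmp[ok] = adj
        out = tmp.reshape(p.shape)
    return out


def fit_age_trends(
    cohort: pd.DataFrame,
    metrics: list[str] | None = None,
    roi_col: str = "roi",
    age_col: str = "age",
    alpha: float = 0.05,
    family: str = "global",
    include_global: bool = True,
) -> pd.DataFrame:
    """OLS age trends per (ROI, metric) with FDR-corrected significance.

    ``cohort`` has one row per subject (or per subject x ROI when
    ``roi_col`` is present) with an age column and metric columns.  A
    whole-mask "global" test per metric (subject-wise mean across ROIs) is
    appended when ROIs are present.  ``family`` is "global" (BH across all
    tests, the default) or "per-metric".
    """
    import statsmodels.api as sm

    if age_col not in cohort.columns:
        raise ValueError(f"no {age_col!r} column in cohort table")
    if metrics is None:
        skip = {age_col, roi_col, "subject", "subject_id"}
        metrics = [
            c
            for c in cohort.columns
            if c not in skip and np.issubdtype(cohort[c].dtype, np.number)
        ]
    if not metrics:
        raise ValueError("no metric columns to test")

    groups: list[tuple[str, pd.DataFrame]] = []
    if roi_col in cohort.columns:
        for roi, sub in cohort.groupby(roi_col, sort=True):
            groups.append((str(roi), sub))
        if include_global:
            keep = [age_col] + metrics
            sub_cols = [c for c in ("subject", "subject_id") if c in cohort.columns]
            if sub_cols:
                glob = cohort.groupby(sub_cols[0], as_index=False)[keep].mean()
            else:
                glob = cohort[keep]
            groups.append(("global", glob))
    else:
        groups.append(("global", cohort))

    rows = []
    for roi, sub in groups:
        age = sub[age_col].to_numpy(dtype=float)
        if len(age) < 3:
            raise ValueError(f"ROI {roi!r}: need at least 3 subjects")
        if np.ptp(age) == 0:
            raise ValueError(f"ROI {roi!r}: age is constant")
        X = sm.add_constant(age)
        for metric in metrics:
            y = sub[metric].to_numpy(dtype=float)
            fin = np.isfinite(y) & np.isfinite(age)
            if fin.sum() < 3:
                rows.append(
                    dict(roi=roi, metric=metric, beta=np.nan, intercept=np.nan,
                         r=np.nan, p=np.nan, n=int(fin.sum()))
                )
                continue
            fit = sm.OLS(y[fin], X[fin]).fit()
            r = float(np.sign(fit.params[1]) * np.sqrt(max(fit.rsquared, 0.0)))
            rows.append(
                dict(
                    roi=roi,
                    metric=metric,
                    beta=float(fit.params[1]),
                    intercept=float(fit.params[0]),
                    r=r,
                    p=float(fit.pvalues[1]),
                    n=int(fin.sum()),
                )
            )
    table = pd.DataFrame(rows)
    if family == "global":
        table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    elif family == "per-metric":
        table["p_fdr"] = np.nan
        for metric in metrics:
            m = table["metric"] == metric
            table.loc[m, "p_fdr"] = bh_fdr(table.loc[m, "p"].to_numpy())
    else:
        raise ValueError("family must be 'global' or 'per-metric'")
    table["significant"] = table["p_fdr"] < alpha
    return table


def asymmetry_alps_correlation(asymmetry, alps) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired per-ROI values."""
    from scipy.stats import pearsonr

    x = np.asarray(asymmetry, dtype=float)
    y = np.asarray(alps, dtype=float)
    fin = np.isfinite(x) & np.isfinite(y)
    x, y = x[fin], y[fin]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = pearsonr(x, y)
    return float(r), float(p)
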