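"""Small-area ecological regression of LBW rates on IQR-scaled exposures.

For each chemical the model is ordinary least squares of the small-area low
birth weight rate (percent of births) on the chemical's multi-year-average
exposure divided by its interquartile range across areas, optionally adjusted
for demographic covariates (female percentage, less-than-high-school
percentage, unmarried percentage, and K-1 race/ethnicity shares).  The
reported effect is therefore the percentage-point change in LBW rate per IQR
increase in exposure, with a symmetric 95% Wald interval from the t
distribution on the residual degrees of freedom.

Multiple comparisons across chemicals are controlled with the
Benjamini-Hochberg (BH) false discovery rate procedure.  ``bh_adjust``
implements the standard step-up rule; because some published small-area
analyses instead compare each ordered p-value only to its own rank threshold
(no step-up propagation, strict inequality), that variant is available
explicitly via ``step_up=False`` and is never silently substituted.

Two-pollutant sensitivity models refit the primary chemical's effect with a
second, weakly correlated (|Pearson r| below 0.5) exposure in the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import ADJUSTMENT_COLUMNS

__all__ = [
    "AssociationResult",
    "TwoPollutantResult",
    "compute_iqr",
    "fit_single_pollutant",
    "bh_adjust",
    "pearson_screen",
    "fit_two_pollutant",
    "run_associations",
    "report",
]


def compute_iqr(values) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles.

    This is the common 'linear' (type 7) quantile definition; it is recorded
    here so exposures can be re-scored identically elsewhere.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return float(q3 - q1)


@dataclass
class AssociationResult:
    """Per-IQR effect of one chemical on the LBW rate."""

    chemical: str
    effect: float          # % LBW-rate change per IQR increase
    ci_low: float
    ci_high: float
    p_value: float
    iqr: float
    n: int
    adjusted: bool
    bh_critical_value: float | None = None
    significant_after_bh: bool | None = None

    def as_row(self) -> dict:
        return {
            "chemical": self.chemical,
            "effect_pct_per_iqr": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "bh_critical": self.bh_critical_value,
            "significant": self.significant_after_bh,
            "iqr": self.iqr,
            "n": self.n,
            "adjusted": self.adjusted,
        }


@dataclass
class TwoPollutantResult:
    """Primary chemical's effect with a co-pollutant in the design."""

    chemical: str
    co_pollutant: str
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    pearson_r: float


def _design(columns: list[np.ndarray], names: list[str], covariate_df: pd.DataFrame | None):
    mats = [np.ones(len(columns[0]))] + columns
    labels = ["const"] + names
    if covariate_df is not None:
        for c in ADJUSTMENT_COLUMNS:
            if c not in covariate_df.columns:
                raise ValueError(f"covariate table missing column {c!r}")
            mats.append(covariate_df[c].to_numpy(dtype=float))
            labels.append(c)
    X = np.column_stack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            nr = np.linalg.matrix_rank(X[:, :j + 1])
            if nr == r:
                bad.append(labels[j])
            r = nr
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, labels


def _ols_effect(y, X, labels, target: str, alpha: float = 0.05):
    model = sm.OLS(y, X)
    res = model.fit()
    j = labels.index(target)
    ci = res.conf_int(alpha=alpha)
    return (float(res.params[j]), float(ci[j][0]), float(ci[j][1]),
            float(res.pvalues[j]), res)


def fit_single_pollutant(exposure, lbw_rates, covariate_df: pd.DataFrame | None = None,
                         chemical: str = "", alpha: float = 0.05) -> AssociationResult:
    """OLS of LBW rate on IQR-scaled exposure, optionally covariate-adjusted.

    ``covariate_df=None`` gives the univariable model.  The IQR is computed
    from the exposure column itself; a zero IQR (constant exposure) is an
    error because the per-IQR effect is then undefined.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(lbw_rates, dtype=float)
    if len(x) != len(y):
        raise ValueError("exposure and outcome lengths differ")
    iqr = compute_iqr(x)
    if iqr == 0:
        raise ValueError(f"IQR of exposure {chemical or ''!r} is zero; "
                         "cannot report a per-IQR effect")
    n_cov = len(ADJUSTMENT_COLUMNS) if covariate_df is not None else 0
    if len(y) <= n_cov + 2:
        raise ValueError(f"need more areas ({len(y)}) than covariates + 2 ({n_cov + 2})")
    X, labels = _design([x / iqr], ["exposure"], covariate_df)
    eff, lo, hi, p, _ = _ols_effect(y, X, labels, "exposure", alpha)
    return AssociationResult(chemical=chemical, effect=eff, ci_low=lo, ci_high=hi,
                             p_value=p, iqr=iqr, n=len(y),
                             adjusted=covariate_df is not None)


def bh_adjust(p_values, fdr: float = 0.05, step_up: bool = True,
              strict: bool = False) -> pd.DataFrame:
    """Benjamini-Hochberg multiple-comparison control.

    With ``step_up=True`` (the standard procedure) the largest rank r with
    ``p_(r) <= r/m * fdr`` is found and every test ranked at or below r is
    significant.  With ``step_up=False`` each ordered p-value is compared
    only to its own rank threshold (``<`` if ``strict``), with no
    propagation — a variant seen in some published analyses, provided for
    reproducing them, not as a default.

    Returns a DataFrame aligned with the input order: columns ``p``,
    ``rank`` (1-based, ties broken by input order), ``bh_critical``
    (rank/m*fdr) and ``significant``.  Also includes ``p_bh`` — the monotone
    step-up adjusted p-values min_{j>=i}(m*p_(j)/j) — so critical thresholds
    and adjusted p-values are never conflated.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    crit = ranks / m * fdr
    p_sorted = p[order]
    crit_sorted = np.arange(1, m + 1) / m * fdr
    if step_up:
        ok = p_sorted <= crit_sorted
        r_max = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
        sig_sorted = np.arange(1, m + 1) <= r_max
    else:
        sig_sorted = (p_sorted < crit_sorted) if strict else (p_sorted <= crit_sorted)
    sig = np.empty(m, dtype=bool)
    sig[order] = sig_sorted
    adj_sorted = np.minimum.accumulate((m * p_sorted / np.arange(1, m + 1))[::-1])[::-1]
    p_bh = np.empty(m)
    p_bh[order] = np.minimum(adj_sorted, 1.0)
    return pd.DataFrame({"p": p, "rank": ranks, "bh_critical": crit,
                         "significant": sig, "p_bh": p_bh})


def pearson_screen(exposure_df: pd.DataFrame, threshold: float = 0.5) -> list[tuple[str, str, float]]:
    """Chemical pairs whose exposures are weakly correlated: |r| < threshold.

    ``exposure_df`` is areas x chemicals (multi-year means).  Strong negative
    correlation confounds a two-pollutant fit as much as strong positive, so
    the screen uses the absolute value.
    """
    cols = list(exposure_df.columns)
    X = exposure_df.to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(R[i, j])
            if abs(r) < threshold:
                out.append((cols[i], cols[j], r))
    return out


def fit_two_pollutant(primary, co_pollutant, lbw_rates,
                      covariate_df: pd.DataFrame | None = None,
                      primary_name: str = "primary", co_name: str = "co",
                      alpha: float = 0.05) -> TwoPollutantResult:
    """OLS with two IQR-scaled exposures; reports the primary coefficient."""
    x1 = np.asarray(primary, dtype=float)
    x2 = np.asarray(co_pollutant, dtype=float)
    y = np.asarray(lbw_rates, dtype=float)
    iqr1, iqr2 = compute_iqr(x1), compute_iqr(x2)
    if iqr1 == 0 or iqr2 == 0:
        raise ValueError("constant exposure column in two-pollutant model")
    r = float(np.corrcoef(x1, x2)[0, 1])
    X, labels = _design([x1 / iqr1, x2 / iqr2], ["primary", "co"], covariate_df)
    eff, lo, hi, p, _ = _ols_effect(y, X, labels, "primary", alpha)
    return TwoPollutantResult(chemical=primary_name, co_pollutant=co_name,
                              effect=eff, ci_low=lo, ci_high=hi, p_value=p,
                              pearson_r=r)


def run_associations(mean_exposures: pd.DataFrame, outcomes: pd.DataFrame,
                     covariate_df: pd.DataFrame | None = None,
                     fdr: float = 0.05) -> list[AssociationResult]:
    """Adjusted per-chemical associations with BH flags attached.

    ``mean_exposures`` is areas x chemicals indexed like ``outcomes``
    (which needs ``lbw_rate``); rows must be aligned by area.
    """
    y = outcomes["lbw_rate"].to_numpy(dtype=float)
    results = [fit_single_pollutant(mean_exposures[c], y, covariate_df, chemical=c)
               for c in mean_exposures.columns]
    adj = bh_adjust([r.p_value for r in results], fdr=fdr)
    for res, (_, row) in zip(results, adj.iterrows()):
        res.bh_critical_value = float(row["bh_critical"])
        res.significant_after_bh = bool(row["significant"])
    return results


def report(results: list[AssociationResult], csv_path=None, json_path=None) -> pd.DataFrame:
    """Ranked results table (ascending p; ties broken by chemical name).

    Optionally writes the table as CSV and machine-readable JSON.
    """
    df = pd.DataFrame([r.as_row() for r in results])
    df = df.sort_values(["p", "chemical"], ignore_index=True)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    return df


def forest_plot(results: list[AssociationResult], path) -> None:
    """Forest-style summary of per-IQR effects with 95% CIs (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report(results)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    ypos = np.arange(len(df))[::-1]
    ax.errorbar(df["effect_pct_per_iqr"], ypos,
                xerr=[df["effect_pct_per_iqr"] - df["ci_low"],
                      df["ci_high"] - df["effect_pct_per_iqr"]],
                fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["chemical"])
    ax.set_xlabel("LBW rate change (%) per IQR increase in exposure")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
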