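"""Two-group comparison of residualized measures.

One machinery serves every measure type in the study — cognitive scores,
tract FA means, single edges, block means, density-averaged graph
metrics: a GLM test of the group coefficient (reducing to the pooled
two-sample t when no extra covariates are given), pooled-SD Cohen's d,
Benjamini-Hochberg FDR within explicit test families, and plain
correlations for post-hoc analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import GROUP_CASE, GROUP_CONTROL


def cohens_d(
    mean_case: float,
    sd_case: float,
    n_case: int,
    mean_control: float,
    sd_control: float,
    n_control: int,
) -> float:
    """Pooled-SD standardized mean difference, case minus control.

    s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2). Negative d
    means the measure is lower in the case group.
    """
    if min(n_case, n_control) < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    if sd_case < 0 or sd_control < 0:
        raise ValueError("standard deviations must be nonnegative")
    sp2 = ((n_case - 1) * sd_case**2 + (n_control - 1) * sd_control**2) / (
        n_case + n_control - 2
    )
    if sp2 <= 0:
        raise ValueError("zero pooled SD")
    return (mean_case - mean_control) / np.sqrt(sp2)


@dataclass
class ComparisonResult:
    """Group comparison of one measure."""

    measure: str
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    cohens_d: float
    statistic: float  # t of the group coefficient
    f_statistic: float
    df: float
    p: float
    q: float | None = None
    family: str | None = None

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "mean_case": self.mean_case,
            "mean_control": self.mean_control,
            "sd_case": self.sd_case,
            "sd_control": self.sd_control,
            "cohens_d": self.cohens_d,
            "t": self.statistic,
            "F": self.f_statistic,
            "df": self.df,
            "p": self.p,
            "q": self.q,
            "family": self.family,
        }

    def summary(self) -> str:
        return (
            f"{self.measure}: case {self.mean_case:.3f} ({self.sd_case:.3f}, "
            f"n={self.n_case}) vs control {self.mean_control:.3f} "
            f"({self.sd_control:.3f}, n={self.n_control}); d={self.cohens_d:.3f}, "
            f"t({self.df:.0f})={self.statistic:.3f}, p={self.p:.4g}"
        )


class GroupComparison:
    """GLM test of a group difference on one measure.

    Parameters
    ----------
    values : pd.Series
        Measure per subject (typically standardized residuals).
    groups : pd.Series
        ``"case"``/``"control"`` labels aligned to ``values``.
    covariates : pd.DataFrame, optional
        Extra confounders entered alongside the group indicator (the
        shared covariates are assumed already removed upstream).
    """

    def __init__(self, values, groups, covariates=None, name=None):
        values = pd.Series(values).astype(float)
        groups = pd.Series(groups).reindex(values.index)
        ok = values.notna() & groups.notna()
        if covariates is not None:
            covariates = pd.DataFrame(covariates).reindex(values.index).astype(float)
            ok &= covariates.notna().all(axis=1)
        self.values = values[ok]
        self.groups = groups[ok]
        self.covariates = covariates.loc[ok] if covariates is not None else None
        self.name = name or str(values.name or "measure")
        n1 = int((self.groups == GROUP_CASE).sum())
        n2 = int((self.groups == GROUP_CONTROL).sum())
        if min(n1, n2) < 2:
            raise ValueError(
                f"{self.name}: need >= 2 retained subjects per group "
                f"(case={n1}, control={n2})"
            )

    def fit(self, family: str | None = None) -> ComparisonResult:
        y = self.values.to_numpy()
        g = (self.groups == GROUP_CASE).to_numpy(float)
        cols = {"intercept": np.ones_like(y), "group": g}
        if self.covariates is not None:
            for c in self.covariates.columns:
                cols[c] = self.covariates[c].to_numpy()
        X = np.column_stack(list(cols.values()))
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify which covariate collapses the design
            names = list(cols)
            for k in range(2, X.shape[1]):
                sub = np.delete(X, k, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    raise ValueError(
                        f"{self.name}: covariate {names[k]!r} is collinear "
                        "with the design (group indicator or other columns)"
                    )
            raise ValueError(f"{self.name}: design matrix is rank deficient")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        tval = beta[1] / se
        p = 2 * stats.t.sf(abs(tval), df)

        case = y[g == 1]
        ctrl = y[g == 0]
        d = cohens_d(
            case.mean(), case.std(ddof=1), len(case),
            ctrl.mean(), ctrl.std(ddof=1), len(ctrl),
        )
        return ComparisonResult(
            measure=self.name,
            n_case=len(case),
            n_control=len(ctrl),
            mean_case=float(case.mean()),
            mean_control=float(ctrl.mean()),
            sd_case=float(case.std(ddof=1)),
            sd_control=float(ctrl.std(ddof=1)),
            cohens_d=float(d),
            statistic=float(tval),
            f_statistic=float(tval**2),
            df=float(df),
            p=float(p),
            family=family,
        )


def bh_fdr(p_values, family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, stable under ties)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def adjust_family(results: list[ComparisonResult], family: str) -> list[ComparisonResult]:
    """Attach BH q-values to a family of comparison results, in place."""
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.family = family
    return results


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("correlate requires >= 4 paired non-missing values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
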