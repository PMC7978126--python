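"""Measure preparation shared by every comparison: monotone transforms,
covariate residualization, Fisher r-to-z, edge-outlier screening, and the
PCA-derived general cognitive score.

Residualization regresses each measure on age, age^2, sex and their
interactions (plus optional confounders) and z-scores the residuals over
the retained sample, both groups pooled — the group label never enters
the design at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import sym_to_vec

TRANSFORMS = ("none", "exp", "reciprocal", "log")

# Published subject-exclusion cut: 1,000 outlier-edges on a 382-parcel
# (72,771-edge) matrix.  The default rescales that ratio to other sizes.
_SUBJECT_CUT_FRACTION = 1000.0 / 72771.0


class DegenerateMeasureError(ValueError):
    """Raised when a measure has (near-)zero residual variance."""


def apply_transform(values, tag: str):
    """Elementwise monotone transform used to normalise skewed scores.

    ``exp`` is the power map x**e, ``reciprocal`` is 1/x (order
    reversing), ``log`` the natural log. Domain violations raise; values
    are never silently clipped.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if tag == "none":
        return values.copy()
    if tag == "exp":
        if (finite < 0).any():
            raise ValueError("power-e transform requires nonnegative values")
        return values**np.e
    if tag == "reciprocal":
        if (finite <= 0).any():
            raise ValueError("reciprocal transform requires strictly positive values")
        return 1.0 / values
    if tag == "log":
        if (finite <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    raise ValueError(f"unknown transform {tag!r}; expected one of {TRANSFORMS}")


def fisher_z(r):
    """Fisher r-to-z (atanh); odd, variance-stabilising. Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def build_design(
    table: pd.DataFrame,
    confounders: tuple[str, ...] = (),
    center_age: bool = True,
) -> pd.DataFrame:
    """Covariate design matrix: intercept, age, age^2, sex, and the full
    crossing of the age terms with sex, plus any named confounders.

    Age is centered before squaring for conditioning; this leaves the
    column space (hence residuals) unchanged.
    """
    for col in ("age", "sex") + tuple(confounders):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from phenotype table")
    age = table["age"].astype(float)
    if center_age:
        age = age - age.mean()
    sex = table["sex"].astype(float)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": age,
            "age2": age**2,
            "sex": sex,
            "age_x_sex": age * sex,
            "age2_x_sex": age**2 * sex,
        },
        index=table.index,
    )
    for col in confounders:
        design[col] = table[col].astype(float)
    _check_rank(design)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    keep = ~np.isnan(X).any(axis=1)
    X = X[keep]
    # constant columns other than the intercept carry no information
    nonconst = [
        c
        for c in design.columns
        if c == "intercept" or design[c][keep].nunique() > 1
    ]
    Xr = design.loc[keep, nonconst].to_numpy(float)
    rank = np.linalg.matrix_rank(Xr)
    if rank < Xr.shape[1]:
        # name every column lying in the span of the others
        bad = []
        for k, name in enumerate(nonconst):
            others = np.delete(Xr, k, axis=1)
            fit, *_ = np.linalg.lstsq(others, Xr[:, k], rcond=None)
            resid = Xr[:, k] - others @ fit
            scale = max(1.0, np.abs(Xr[:, k]).max())
            if np.abs(resid).max() < 1e-8 * scale:
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; redundant columns: {bad}")


@dataclass
class ResidualizedMeasure:
    """Standardized residuals of one measure after covariate removal."""

    name: str
    values: pd.Series  # indexed by retained subject ids; mean 0, SD 1
    transform_tag: str = "none"
    excluded_subjects: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        v = self.values.to_numpy(float)
        if v.size and (abs(v.mean()) > 1e-8 or abs(v.std(ddof=1) - 1) > 1e-8):
            raise ValueError("residualized values must be standardized")


def residualize(
    measure: pd.Series,
    design: pd.DataFrame,
    transform: str = "none",
    name: str | None = None,
) -> ResidualizedMeasure:
    """Least-squares residuals of ``measure`` on ``design``, z-scored over
    the retained (non-missing) subjects.

    Missing rows (in the measure or any design column) are dropped and
    reported in ``excluded_subjects``. A measure lying in the design's
    column space raises :class:`DegenerateMeasureError` rather than
    dividing by a near-zero SD.
    """
    name = name or str(measure.name or "measure")
    measure = measure.astype(float).reindex(design.index)
    y = apply_transform(measure.to_numpy(), transform)
    X = design.to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    excluded = {
        str(s): "missing value" for s in design.index[~ok]
    }
    if ok.sum() <= X.shape[1]:
        raise ValueError(
            f"{name}: only {int(ok.sum())} complete rows for "
            f"{X.shape[1]} design columns"
        )
    Xo, yo = X[ok], y[ok]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    sd = resid.std(ddof=1)
    scale = max(np.abs(yo).max(), 1.0)
    if sd <= 1e-10 * scale:
        raise DegenerateMeasureError(
            f"{name}: near-zero residual variance (SD={sd:.3g}); "
            "measure is explained by the covariates"
        )
    z = (resid - resid.mean()) / sd
    return ResidualizedMeasure(
        name=name,
        values=pd.Series(z, index=design.index[ok], name=name),
        transform_tag=transform,
        excluded_subjects=excluded,
    )


@dataclass
class OutlierReport:
    """Edge-wise >k·SD outlier flags and the resulting subject exclusions."""

    subject_ids: list[str]
    edge_flags: np.ndarray  # (n_subjects, n_edges) bool
    per_subject_count: pd.Series
    excluded_subject_ids: list[str]
    sd_cut: float
    subject_cut: int
    zero_sd_edges: np.ndarray  # indices of edges with zero SD (never flagged)


def default_subject_cut(n_edges: int) -> int:
    """Outlier-edge exclusion threshold scaled to the edge count
    (1,000 edges at a 382-parcel matrix)."""
    return int(round(_SUBJECT_CUT_FRACTION * n_edges))


def detect_edge_outliers(
    matrices: dict[str, np.ndarray],
    sd_cut: float = 4.0,
    subject_cut: int | None = None,
) -> OutlierReport:
    """Flag subject-edges deviating more than ``sd_cut`` SD from the
    cross-subject edge mean; list subjects with more than ``subject_cut``
    flagged edges for exclusion.

    Single pass: edge means/SDs are estimated once over all subjects and
    not re-estimated after exclusion. Edges with zero SD are reported and
    never flagged.
    """
    ids = list(matrices)
    if len(ids) < 3:
        raise ValueError("outlier detection requires at least 3 subjects")
    E = np.stack([sym_to_vec(matrices[s]) for s in ids])
    if subject_cut is None:
        subject_cut = default_subject_cut(E.shape[1])
    mean = E.mean(axis=0)
    sd = E.std(axis=0, ddof=1)
    zero_sd = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        flags = np.abs(E - mean) > sd_cut * sd
    flags[:, zero_sd] = False
    counts = flags.sum(axis=1)
    excluded = [ids[k] for k in range(len(ids)) if counts[k] > subject_cut]
    return OutlierReport(
        subject_ids=ids,
        edge_flags=flags,
        per_subject_count=pd.Series(counts, index=ids, name="n_outlier_edges"),
        excluded_subject_ids=excluded,
        sd_cut=sd_cut,
        subject_cut=int(subject_cut),
        zero_sd_edges=zero_sd,
    )


@dataclass
class GeneralFactor:
    """First principal component of the z-scored test battery."""

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    imputed: pd.DataFrame  # boolean mask of imputed cells


def general_factor(
    score_table: pd.DataFrame,
    anchor: str | None = None,
    impute: str = "median",
) -> GeneralFactor:
    """General cognitive score g: first PCA component of the z-scored
    tests, sign-oriented so the anchor test's loading is positive.

    Missing cells are median-imputed per test (the configured default)
    before the decomposition and flagged in the output.
    """
    if score_table.shape[1] < 2:
        raise ValueError("need at least 2 tests for a general factor")
    X = score_table.astype(float).copy()
    const = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if const:
        raise ValueError(f"constant test columns: {const}")
    mask = X.isna()
    if mask.to_numpy().any():
        if impute != "median":
            raise ValueError(f"unknown imputation {impute!r}")
        X = X.fillna(X.median())
    Z = (X - X.mean()) / X.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = pd.Series(Vt[0], index=X.columns, name="loading")
    anchor = anchor or X.columns[0]
    if anchor not in loadings.index:
        raise KeyError(f"anchor test {anchor!r} not in score table")
    if loadings[anchor] < 0:
        loadings = -loadings
        U = U.copy()
        U[:, 0] = -U[:, 0]
    g = pd.Series(U[:, 0] * s[0], index=X.index, name="g")
    ve = float(s[0] ** 2 / (s**2).sum())
    return GeneralFactor(scores=g, loadings=loadings, variance_explained=ve, imputed=mask)
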