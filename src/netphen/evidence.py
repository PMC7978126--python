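"""Interval-null JZS Bayes factors and posterior probabilities of
association (PPA).

The Bayes factor contrasts two hypotheses about the standardized group
difference delta of a two-sample design, both derived from a zero-centred
Cauchy prior (the JZS prior): the *alternative* truncates the prior to
the complement of a null interval (default (-0.1, 0.1), effects too small
to matter), the *null region* truncates it to the interval itself. Each
marginal likelihood integrates the noncentral-t density of the observed
t statistic over the truncated prior::

    m(R) = (1/P(R)) * int_R  nct(t; df, delta*sqrt(n_eff)) dCauchy(delta)

with n_eff = n1*n2/(n1+n2) and df = n1+n2-2, evaluated by adaptive
quadrature. BF = m(complement) / m(interval). As the interval width goes
to zero this converges to the standard point-null JZS Bayes factor, which
is exposed separately.

PPA converts a BF into a posterior probability given a prior probability
of association, the device used to grade evidence under multiplicity:
posterior odds = BF * pi/(1-pi), PPA = odds/(1+odds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

DEFAULT_NULL_INTERVAL = (-0.1, 0.1)
MEDIUM_CAUCHY_SCALE = float(np.sqrt(2) / 2)

EVIDENCE_LABELS = (
    "null_substantial",
    "inconclusive",
    "alt_substantial",
    "alt_strong",
)


def _effective_n(n_case: int, n_control: int) -> float:
    return n_case * n_control / (n_case + n_control)


def _restricted_marginal(t, df, sqrt_neff, lo, hi, scale, rtol=1e-9):
    """Marginal likelihood of t under Cauchy(0, scale) truncated to [lo, hi]."""
    prior = stats.cauchy(0.0, scale)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_neff) * prior.pdf(delta)

    pieces = []
    # split at 0 and at the likelihood peak for quadrature robustness
    peak = t / sqrt_neff
    cuts = sorted({c for c in (0.0, peak) if (lo < c < hi)})
    bounds = [lo, *cuts, hi]
    for a, b in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(integrand, a, b, epsrel=rtol, epsabs=0, limit=400)
        pieces.append(val)
    mass = prior.cdf(hi) - prior.cdf(lo)
    if mass <= 0:
        raise ValueError("prior mass of the region is zero")
    return sum(pieces) / mass


def interval_bayes_factor(
    t_statistic: float,
    n_case: int,
    n_control: int,
    null_interval: tuple[float, float] = DEFAULT_NULL_INTERVAL,
    cauchy_scale: float = MEDIUM_CAUCHY_SCALE,
) -> float:
    """JZS Bayes factor of the interval complement versus the null interval.

    BF > 1 favours a standardized effect outside ``null_interval``; BF < 1
    favours a negligible effect inside it.
    """
    if not np.isfinite(t_statistic):
        raise ValueError("t statistic must be finite")
    lo, hi = null_interval
    if not lo < hi:
        raise ValueError("null interval must have positive width")
    df = n_case + n_control - 2
    if df < 1:
        raise ValueError("need n1 + n2 - 2 >= 1 degrees of freedom")
    sn = np.sqrt(_effective_n(n_case, n_control))
    m_null = _restricted_marginal(t_statistic, df, sn, lo, hi, cauchy_scale)
    prior = stats.cauchy(0.0, cauchy_scale)
    # complement = two unbounded tails, integrated separately
    tail_lo = integrate.quad(
        lambda d: stats.nct.pdf(t_statistic, df, d * sn) * prior.pdf(d),
        -np.inf, lo, epsrel=1e-9, epsabs=0, limit=400,
    )[0]
    tail_hi = integrate.quad(
        lambda d: stats.nct.pdf(t_statistic, df, d * sn) * prior.pdf(d),
        hi, np.inf, epsrel=1e-9, epsabs=0, limit=400,
    )[0]
    mass_c = prior.cdf(lo) + prior.sf(hi)
    m_alt = (tail_lo + tail_hi) / mass_c
    return float(m_alt / m_null)


def point_null_bayes_factor(
    t_statistic: float,
    n_case: int,
    n_control: int,
    cauchy_scale: float = MEDIUM_CAUCHY_SCALE,
) -> float:
    """Standard two-sample JZS Bayes factor against the point null delta=0."""
    if not np.isfinite(t_statistic):
        raise ValueError("t statistic must be finite")
    df = n_case + n_control - 2
    if df < 1:
        raise ValueError("need n1 + n2 - 2 >= 1 degrees of freedom")
    sn = np.sqrt(_effective_n(n_case, n_control))
    m_alt = _restricted_marginal(t_statistic, df, sn, -np.inf, np.inf, cauchy_scale)
    m_null = stats.t.pdf(t_statistic, df)
    return float(m_alt / m_null)


def ppa(bf: float, prior_pi: float) -> float:
    """Posterior probability of association from a BF and prior probability."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if not 0 < prior_pi < 1:
        raise ValueError("prior probability must lie in (0, 1)")
    odds = bf * prior_pi / (1.0 - prior_pi)
    return odds / (1.0 + odds)


def grade_evidence(bf: float) -> str:
    """Conventional evidence grade: BF < 0.3 substantial for the null
    region, BF > 3 substantial and BF > 10 strong for the alternative;
    everything between (boundaries included at 0.3 and 3) is inconclusive.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf < 0.3:
        return "null_substantial"
    if bf <= 3:
        return "inconclusive"
    if bf <= 10:
        return "alt_substantial"
    return "alt_strong"


@dataclass
class EvidenceResult:
    """Interval-null evidence summary for one comparison."""

    measure: str
    t: float
    n_case: int
    n_control: int
    bf: float
    null_interval: tuple[float, float]
    cauchy_scale: float
    prior_pi: float
    ppa: float
    grade: str

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "t": self.t,
            "df": self.n_case + self.n_control - 2,
            "bf": self.bf,
            "null_lo": self.null_interval[0],
            "null_hi": self.null_interval[1],
            "cauchy_scale": self.cauchy_scale,
            "prior_pi": self.prior_pi,
            "ppa": self.ppa,
            "grade": self.grade,
        }


def evaluate_evidence(
    measure: str,
    t_statistic: float,
    n_case: int,
    n_control: int,
    prior_pi: float,
    null_interval: tuple[float, float] = DEFAULT_NULL_INTERVAL,
    cauchy_scale: float = MEDIUM_CAUCHY_SCALE,
) -> EvidenceResult:
    """BF, PPA and grade for one two-group comparison.

    ``prior_pi`` is an explicit input: use a hypothesis-driven prior
    (e.g. 0.1) for small confirmatory families and 1/m for an m-test
    exploratory family.
    """
    bf = interval_bayes_factor(
        t_statistic, n_case, n_control, null_interval, cauchy_scale
    )
    return EvidenceResult(
        measure=measure,
        t=float(t_statistic),
        n_case=n_case,
        n_control=n_control,
        bf=bf,
        null_interval=tuple(null_interval),
        cauchy_scale=cauchy_scale,
        prior_pi=prior_pi,
        ppa=ppa(bf, prior_pi),
        grade=grade_evidence(bf),
    )
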