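"""Multi-locus odds model of dichotomous disease.

A disease is generated by an additive model on the log-odds scale: an
individual carrying ``g`` risk alleles (out of ``m`` effect-allele positions,
i.e. ``m/2`` diploid risk SNPs) is affected with probability

    P(Y=1 | G=g) = logistic(beta0 + beta * g).

Under Hardy-Weinberg and linkage equilibrium with a shared risk-allele
frequency ``p_a``, the population count G is Binomial(m, p_a).  The intercept
``beta0`` is not a free parameter: it is calibrated so that the model-implied
disease probability equals a target prevalence K.

Two architectures are supported: :class:`FixedEffectModel` (every SNP shares
one effect size and allele frequency; the intercept calibrates exactly against
the binomial pmf) and :class:`HeterogeneousModel` (per-SNP effect sizes and
frequencies; the score distribution is not enumerable, so the intercept is
calibrated by Monte Carlo with common random numbers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, log_expit, logit
from scipy.stats import binom

__all__ = [
    "FixedEffectModel",
    "HeterogeneousModel",
    "penetrance",
    "allele_count_pmf",
    "joint_pmf",
    "solve_intercept",
    "solve_intercept_mc",
    "CalibrationError",
]

#: base half-width of the intercept root bracket; widened by the score range
#: |beta| * m of the model, since the intercept scales like -beta * E[G]
INTERCEPT_MARGIN = 60.0


def _intercept_bracket(score_range: float) -> tuple[float, float]:
    half = INTERCEPT_MARGIN + abs(score_range)
    return (-half, half)


class CalibrationError(RuntimeError):
    """Raised when the intercept root is not bracketed within ±60."""


def _log_binom_pmf(n: int, p: float) -> np.ndarray:
    """log Binomial(n, p) pmf over 0..n (log-space; safe for large n)."""
    return binom.logpmf(np.arange(n + 1), n, p)


def _implied_log_prevalence(beta0: float, beta: float, log_pmf: np.ndarray) -> float:
    """log P(Y=1) = log sum_g expit(beta0 + beta*g) * P(G=g), in log-space."""
    g = np.arange(log_pmf.size)
    terms = log_expit(beta0 + beta * g) + log_pmf
    m = terms.max()
    return float(m + np.log(np.exp(terms - m).sum()))


def solve_intercept(
    prevalence: float,
    beta: float,
    risk_allele_freq: float,
    n_effect_alleles: int,
) -> float:
    """Calibrate the intercept beta0 so the model prevalence equals the target.

    The implied prevalence sum_g logistic(beta0 + beta*g) Binom(g; m, p_a) is
    strictly increasing in beta0, so the root is unique; it is found by
    Brent's method on the bracket ``INTERCEPT_BRACKET`` and reproduces the
    target prevalence to better than 1e-10.

    Raises
    ------
    CalibrationError
        If the root is not bracketed within [-60, 60].
    ValueError
        If ``prevalence`` is not in (0, 1).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    if beta == 0.0:
        return float(logit(prevalence))
    log_pmf = _log_binom_pmf(n_effect_alleles, risk_allele_freq)
    log_k = np.log(prevalence)

    def f(b0: float) -> float:
        return _implied_log_prevalence(b0, beta, log_pmf) - log_k

    lo, hi = _intercept_bracket(beta * n_effect_alleles)
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"intercept root not bracketed in [{lo}, {hi}] "
            f"(K={prevalence}, beta={beta}, p={risk_allele_freq}, m={n_effect_alleles})"
        )
    return float(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))


@dataclass
class FixedEffectModel:
    """Four-parameter disease model with a shared effect size.

    Parameters
    ----------
    prevalence : float
        Population disease probability K, in (0, 1).
    beta : float
        Log odds ratio per risk allele; the true conditional OR is exp(beta).
    risk_allele_freq : float
        Risk allele frequency p_a at every effect SNP, in (0, 1).
    n_effect_alleles : int
        Total effect-allele positions m (= 2 x number of risk SNPs); even, >= 2.
    intercept : float, optional
        Background log odds beta0.  Derived by calibration when omitted.
    """

    prevalence: float
    beta: float
    risk_allele_freq: float
    n_effect_alleles: int
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError("risk_allele_freq must be in (0,1)")
        m = self.n_effect_alleles
        if m < 2 or m % 2 != 0:
            raise ValueError("n_effect_alleles must be an even integer >= 2")
        if self.intercept is None:
            self.intercept = solve_intercept(
                self.prevalence, self.beta, self.risk_allele_freq, m
            )

    @classmethod
    def from_or(
        cls,
        prevalence: float,
        or_true: float,
        risk_allele_freq: float,
        n_snps: int,
    ) -> "FixedEffectModel":
        """Build from the odds-scale effect size and the number of risk SNPs."""
        return cls(prevalence, float(np.log(or_true)), risk_allele_freq, 2 * n_snps)

    @property
    def or_true(self) -> float:
        """True conditional odds ratio exp(beta)."""
        return float(np.exp(self.beta))

    @property
    def n_snps(self) -> int:
        return self.n_effect_alleles // 2

    def to_json(self) -> str:
        return json.dumps(
            {
                "prevalence": self.prevalence,
                "beta": self.beta,
                "risk_allele_freq": self.risk_allele_freq,
                "n_effect_alleles": self.n_effect_alleles,
                "intercept": self.intercept,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FixedEffectModel":
        d = json.loads(s)
        if "or_true" in d and "beta" not in d:
            d["beta"] = float(np.log(d.pop("or_true")))
        return cls(**d)


def penetrance(model: FixedEffectModel, g) -> np.ndarray | float:
    """Disease probability given a total risk-allele count.

    ``logistic(beta0 + beta*g)``; strictly increasing in g when beta > 0.
    Accepts a scalar or array of counts in [0, m].
    """
    g_arr = np.asarray(g)
    if np.any(g_arr < 0) or np.any(g_arr > model.n_effect_alleles):
        raise ValueError(f"risk-allele count out of range 0..{model.n_effect_alleles}")
    out = expit(model.intercept + model.beta * g_arr)
    return float(out) if np.isscalar(g) else out


def allele_count_pmf(model: FixedEffectModel) -> np.ndarray:
    """Population pmf of the total risk-allele count: Binomial(m, p_a)."""
    return np.exp(_log_binom_pmf(model.n_effect_alleles, model.risk_allele_freq))


def joint_pmf(model: FixedEffectModel) -> np.ndarray:
    """Joint pmf P(Y=y, G=g), shape (2, m+1); rows y=0 (healthy), y=1 (affected).

    Entries are penetrance (or its complement) times the binomial count pmf.
    Row y=1 sums to the calibrated prevalence.
    """
    log_pmf = _log_binom_pmf(model.n_effect_alleles, model.risk_allele_freq)
    g = np.arange(model.n_effect_alleles + 1)
    eta = model.intercept + model.beta * g
    log_joint = np.vstack([log_expit(-eta) + log_pmf, log_expit(eta) + log_pmf])
    return np.exp(log_joint)


def implied_prevalence(model: FixedEffectModel) -> float:
    """Model-implied P(Y=1) (should equal the target prevalence after calibration)."""
    log_pmf = _log_binom_pmf(model.n_effect_alleles, model.risk_allele_freq)
    return float(np.exp(_implied_log_prevalence(model.intercept, model.beta, log_pmf)))


# ---------------------------------------------------------------------------
# heterogeneous architecture


@dataclass
class HeterogeneousModel:
    """Disease model with per-SNP effect sizes and allele frequencies.

    The log-odds score of a subject is sum_j beta_j * g_j with
    g_j ~ Binomial(2, p_j) independent across SNPs.  The intercept is
    calibrated to the target prevalence by Monte Carlo (see
    :func:`solve_intercept_mc`); pass ``calibration_draws``/``calibration_seed``
    to control that step.
    """

    prevalence: float
    betas: np.ndarray
    freqs: np.ndarray
    intercept: float | None = None
    calibration_draws: int = 1_000_000
    calibration_seed: int = 0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.betas.shape != self.freqs.shape or self.betas.ndim != 1:
            raise ValueError("betas and freqs must be 1-D and of equal length")
        if self.betas.size < 1:
            raise ValueError("at least one SNP required")
        if np.any(self.freqs <= 0) or np.any(self.freqs >= 1):
            raise ValueError("freqs must lie in (0,1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.intercept is None:
            self.intercept = solve_intercept_mc(
                self.betas,
                self.freqs,
                self.prevalence,
                n_draws=self.calibration_draws,
                seed=self.calibration_seed,
            )

    @property
    def n_snps(self) -> int:
        return self.betas.size

    @property
    def ors_true(self) -> np.ndarray:
        return np.exp(self.betas)

    def to_json(self) -> str:
        return json.dumps(
            {
                "prevalence": self.prevalence,
                "betas": self.betas.tolist(),
                "freqs": self.freqs.tolist(),
                "intercept": self.intercept,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HeterogeneousModel":
        return cls(**json.loads(s))


def _score_sample(
    betas: np.ndarray, freqs: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_draws genetic scores sum_j beta_j * Binomial(2, p_j)."""
    score = np.zeros(n_draws)
    for b, p in zip(betas, freqs):
        score += b * rng.binomial(2, p, size=n_draws)
    return score


def solve_intercept_mc(
    betas: Sequence[float],
    freqs: Sequence[float],
    target_prevalence: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo intercept calibration for a heterogeneous architecture.

    Draws a fixed population of ``n_draws`` genetic scores once, then solves
    mean(logistic(beta0 + score)) = target on those same draws (common random
    numbers make the objective smooth, monotone and deterministic given the
    seed).  The returned intercept reproduces the target on the calibration
    sample to < 1e-6; its accuracy as a population value is limited by the
    Monte-Carlo error of ``n_draws``.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0,1)")
    betas = np.asarray(betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.all(betas == 0.0):
        return float(logit(target_prevalence))
    rng = np.random.default_rng(seed)
    score = _score_sample(betas, freqs, n_draws, rng)

    def f(b0: float) -> float:
        return float(expit(b0 + score).mean() - target_prevalence)

    lo, hi = _intercept_bracket(2.0 * float(np.abs(betas).sum()))
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(f"intercept root not bracketed in [{lo}, {hi}]")
    return float(brentq(f, lo, hi, xtol=1e-10))
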