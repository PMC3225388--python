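"""Exact genotype distribution of a focal SNP given disease status.

Pick one of the m/2 risk SNPs and call its risk-allele count X in {0,1,2};
the remaining background count Z = G - X is Binomial(m-2, p_a), independent
of X under linkage equilibrium.  Bayes' rule then gives the genotype
distribution among cases and among controls in closed form, and a weighted
logistic fit on that exact three-point design yields the asymptotic marginal
odds ratio that single-SNP analysis estimates — the analytic oracle the
simulated medians converge to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_expit, logsumexp
from scipy.stats import binom

from ._logistic import fit_logit_slope
from .odds_model import FixedEffectModel

__all__ = [
    "FocalGenotypeDistribution",
    "focal_genotype_pmf",
    "asymptotic_marginal_or",
]


def focal_genotype_pmf(model: FixedEffectModel, y: int) -> np.ndarray:
    """P(X = x | Y = y) for focal genotype x in {0, 1, 2}.

    Computed in log-space as
    ``Binom(x; 2, p_a) * sum_z P(Y=y | G=x+z) Binom(z; m-2, p_a)``,
    normalized over x.  Requires m >= 2.
    """
    if y not in (0, 1):
        raise ValueError("disease status y must be 0 or 1")
    m = model.n_effect_alleles
    if m < 2:
        raise ValueError("focal-SNP distribution requires m >= 2")
    p = model.risk_allele_freq
    x = np.arange(3)
    log_px = binom.logpmf(x, 2, p)
    z = np.arange(m - 1)
    log_pz = binom.logpmf(z, m - 2, p)
    eta = model.intercept + model.beta * (x[:, None] + z[None, :])
    log_pen = log_expit(eta) if y == 1 else log_expit(-eta)
    log_w = log_px + logsumexp(log_pz[None, :] + log_pen, axis=1)
    return np.exp(log_w - logsumexp(log_w))


@dataclass(frozen=True)
class FocalGenotypeDistribution:
    """Focal-SNP genotype probabilities conditional on case/control status."""

    probs_case: np.ndarray
    probs_control: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.probs_case, self.probs_control):
            if v.shape != (3,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
                raise ValueError("genotype probabilities must be a 3-vector summing to 1")

    @classmethod
    def from_model(cls, model: FixedEffectModel) -> "FocalGenotypeDistribution":
        return cls(focal_genotype_pmf(model, 1), focal_genotype_pmf(model, 0))


def asymptotic_marginal_or(
    model: FixedEffectModel, case_fraction: float = 0.5
) -> float:
    """Large-sample marginal odds ratio of single-SNP logistic analysis.

    Fits the per-allele logistic model to the exact three-point genotype
    design weighted by ``case_fraction * P(x|Y=1)`` and
    ``(1-case_fraction) * P(x|Y=0)`` — the infinite-sample limit of a
    case-control study with that case fraction — and returns exp(slope).
    Because the marginal odds ratio is non-collapsible, the result lies at or
    below exp(beta) for beta > 0 and m > 2.
    """
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must be in (0,1)")
    if model.beta == 0.0:
        return 1.0
    dist = FocalGenotypeDistribution.from_model(model)
    w_case = case_fraction * dist.probs_case
    w_ctrl = (1.0 - case_fraction) * dist.probs_control
    # guard against numerically vanished design points at extreme p_a
    tiny = (w_case + w_ctrl) < 1e-300
    if tiny.any():
        warnings.warn(
            "degenerate focal design: dropping genotype value(s) with zero mass",
            RuntimeWarning,
        )
        w_case = np.where(tiny, 0.0, w_case)
        w_ctrl = np.where(tiny, 0.0, w_ctrl)
    slope, converged = fit_logit_slope(w_case, w_ctrl)
    if not converged:
        raise RuntimeError("asymptotic marginal OR fit did not converge")
    return float(np.exp(slope))
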