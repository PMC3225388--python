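"""Case-control cohort simulation and single-SNP odds-ratio estimation.

Two sampling paths mirror the two disease architectures:

* fixed effects — every replicate draws focal-SNP genotypes i.i.d. from the
  exact case/control genotype distributions (the genetic background is
  marginalized analytically, which is mathematically identical to simulating
  all SNPs and orders of magnitude faster);
* heterogeneous — full genotype vectors are drawn per subject and subjects
  are rejection-sampled on simulated disease status until the case and
  control strata are filled, because per-SNP conditional distributions are
  not closed-form when effect sizes differ.

Odds ratios are estimated per SNP either by additive logistic regression on
genotype count (the standard GWAS test) or from the 2x2 allele table.
Replicates with separation or zero cells fall back to the Haldane-Anscombe
corrected allele-table OR and are counted, never dropped (dropping would bias
the median at low allele frequencies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._logistic import allele_table_or, fit_logit_slope
from .focal_snp import FocalGenotypeDistribution
from .odds_model import FixedEffectModel, HeterogeneousModel

__all__ = [
    "CaseControlSample",
    "MedianORResult",
    "sample_fixed_effect_cohort",
    "estimate_or",
    "median_or_experiment",
    "draw_architecture",
    "rejection_sample_cohort",
    "heterogeneous_experiment",
]


@dataclass
class CaseControlSample:
    """Genotype counts of a case-control study.

    ``case_genotype_counts``/``control_genotype_counts`` have shape (3,) for a
    single focal SNP or (S, 3) for S SNPs; entry [..., x] counts subjects with
    genotype x in {0,1,2}.
    """

    case_genotype_counts: np.ndarray
    control_genotype_counts: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        self.case_genotype_counts = np.asarray(self.case_genotype_counts)
        self.control_genotype_counts = np.asarray(self.control_genotype_counts)
        if np.any(self.case_genotype_counts.sum(axis=-1) != self.n_cases):
            raise ValueError("case genotype counts must sum to n_cases")
        if np.any(self.control_genotype_counts.sum(axis=-1) != self.n_controls):
            raise ValueError("control genotype counts must sum to n_controls")

    @classmethod
    def from_genotype_matrices(
        cls, case_genotypes: np.ndarray, control_genotypes: np.ndarray
    ) -> "CaseControlSample":
        """Build from (subjects x SNPs) genotype matrices with values in {0,1,2}."""
        return cls(
            _genotype_counts(case_genotypes),
            _genotype_counts(control_genotypes),
            case_genotypes.shape[0],
            control_genotypes.shape[0],
        )


def _genotype_counts(genotypes: np.ndarray) -> np.ndarray:
    """Collapse a (subjects, S) genotype matrix to per-SNP counts (S, 3)."""
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    n_snps = g.shape[1]
    idx = (3 * np.arange(n_snps)[None, :] + g).ravel()
    return np.bincount(idx, minlength=3 * n_snps).reshape(n_snps, 3)


@dataclass
class MedianORResult:
    """Median estimated odds ratio over simulation replicates for one SNP."""

    or_true: float
    or_median: float
    n_replicates: int
    n_fallback: int = 0
    replicate_ors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.or_median <= 0 or self.n_replicates < 1:
            raise ValueError("or_median must be positive and n_replicates >= 1")

    @property
    def fallback_fraction(self) -> float:
        return self.n_fallback / self.n_replicates


def sample_fixed_effect_cohort(
    model: FixedEffectModel,
    n_cases: int,
    n_controls: int,
    rng_seed: int | np.random.Generator = 0,
) -> CaseControlSample:
    """Draw one case-control sample of the focal SNP under fixed effects.

    Case genotypes are i.i.d. from P(X|Y=1) and control genotypes from
    P(X|Y=0); only the genotype counts are returned (sufficient for any
    single-SNP estimator).
    """
    rng = np.random.default_rng(rng_seed)
    dist = FocalGenotypeDistribution.from_model(model)
    return CaseControlSample(
        rng.multinomial(n_cases, dist.probs_case),
        rng.multinomial(n_controls, dist.probs_control),
        n_cases,
        n_controls,
    )


def _estimate_or_batch(
    case_counts: np.ndarray, control_counts: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """ORs for a batch of (..., 3) count tables; returns (ors, fallback_mask)."""
    if method == "allele_table":
        ors = allele_table_or(case_counts, control_counts)
        return np.atleast_1d(ors), np.zeros(np.atleast_1d(ors).shape, dtype=bool)
    if method != "logistic":
        raise ValueError(f"unknown estimator {method!r}")
    slopes, converged = fit_logit_slope(case_counts, control_counts)
    slopes = np.atleast_1d(slopes)
    converged = np.atleast_1d(converged)
    ors = np.exp(slopes)
    if not converged.all():
        fallback = allele_table_or(case_counts, control_counts)
        ors = np.where(converged, ors, np.atleast_1d(fallback))
    return ors, ~converged


def estimate_or(sample: CaseControlSample, method: str = "logistic"):
    """Single-SNP odds ratio(s) from a sample.

    ``logistic``: exp(slope) of case status on genotype count; falls back to
    the corrected allele-table OR on separation.  ``allele_table``: 2x2
    allele-table OR with Haldane-Anscombe correction of zero cells.
    Returns a scalar for a single-SNP sample, an array of length S otherwise.
    """
    ors, _ = _estimate_or_batch(
        sample.case_genotype_counts, sample.control_genotype_counts, method
    )
    return float(ors[0]) if sample.case_genotype_counts.ndim == 1 else ors


def median_or_experiment(
    model: FixedEffectModel,
    n_replicates: int = 10_000,
    n_cases: int = 1750,
    n_controls: int = 1750,
    method: str = "logistic",
    rng_seed: int = 0,
    keep_replicates: bool = False,
) -> MedianORResult:
    """Median single-SNP OR over replicated fixed-effect case-control samples.

    All replicates are drawn from one seeded generator, so the result is a
    pure function of (model, sizes, method, rng_seed).  With many replicates
    the median approximates the analytic asymptotic marginal OR.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    dist = FocalGenotypeDistribution.from_model(model)
    case_counts = rng.multinomial(n_cases, dist.probs_case, size=n_replicates)
    control_counts = rng.multinomial(n_controls, dist.probs_control, size=n_replicates)
    ors, fallback = _estimate_or_batch(case_counts, control_counts, method)
    return MedianORResult(
        or_true=model.or_true,
        or_median=float(np.median(ors)),
        n_replicates=n_replicates,
        n_fallback=int(fallback.sum()),
        replicate_ors=ors if keep_replicates else None,
    )


def draw_architecture(
    n_snps: int,
    exp_rate: float = 5.0,
    maf_low: float = 0.05,
    maf_high: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a polygenic architecture: exponential effects, uniform frequencies.

    Effect sizes (log odds ratios) are i.i.d. Exponential(rate); with the
    default rate 5 the mean log OR is 0.2 and the expected allelic OR is
    rate/(rate-1) = 1.25.  Risk allele frequencies are i.i.d.
    Uniform(maf_low, maf_high); the defaults avoid rare variants.
    The architecture is meant to be drawn once and held fixed across
    simulation replicates.
    """
    if not 0.0 < maf_low < maf_high < 1.0:
        raise ValueError("require 0 < maf_low < maf_high < 1")
    if exp_rate <= 1.0:
        warnings.warn(
            "exp_rate <= 1 implies an infinite expected odds ratio", RuntimeWarning
        )
    rng = np.random.default_rng(rng_seed)
    betas = rng.exponential(scale=1.0 / exp_rate, size=n_snps)
    freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    return betas, freqs


def rejection_sample_cohort(
    model: HeterogeneousModel,
    n_cases: int = 2500,
    n_controls: int = 2500,
    rng_seed: int | np.random.Generator = 0,
    max_draws: int = 1_000_000_000,
) -> CaseControlSample:
    """Sample a cohort by drawing subjects until both strata are full.

    Each drawn subject gets genotypes g_j ~ Binomial(2, p_j), a score
    sum_j beta_j g_j, and disease status Y ~ Bernoulli(logistic(b0 + score));
    the first n_cases cases and n_controls controls in draw order are kept.
    Expected draws are about n_cases / prevalence; ``max_draws`` guards
    against a miscalibrated intercept.
    """
    rng = np.random.default_rng(rng_seed)
    p = model.freqs
    betas = model.betas
    b0 = model.intercept
    n_snps = model.n_snps
    need_case, need_ctrl = n_cases, n_controls
    case_counts = np.zeros((n_snps, 3), dtype=np.int64)
    ctrl_counts = np.zeros((n_snps, 3), dtype=np.int64)
    drawn = 0
    from scipy.special import expit  # local import keeps module load light

    while need_case > 0 or need_ctrl > 0:
        expected = need_case / model.prevalence + need_ctrl / (1 - model.prevalence)
        batch = int(np.clip(1.1 * expected + 1000, 2000, 120_000))
        if drawn + batch > max_draws:
            raise RuntimeError(
                f"rejection sampler exceeded max_draws={max_draws}; "
                "check intercept calibration"
            )
        # Binomial(2, p) as a sum of two Bernoulli draws; float32 uniforms are
        # exact to ~6e-8 in p, negligible against Monte-Carlo noise
        h1 = rng.random((batch, n_snps), dtype=np.float32) < p
        h2 = rng.random((batch, n_snps), dtype=np.float32) < p
        score = h1 @ betas + h2 @ betas
        y = rng.random(batch) < expit(b0 + score)
        drawn += batch
        keep_case = np.flatnonzero(y)[:need_case]
        keep_ctrl = np.flatnonzero(~y)[:need_ctrl]
        if keep_case.size:
            g = h1[keep_case].astype(np.int8) + h2[keep_case]
            case_counts += _genotype_counts(g)
            need_case -= keep_case.size
        if keep_ctrl.size:
            g = h1[keep_ctrl].astype(np.int8) + h2[keep_ctrl]
            ctrl_counts += _genotype_counts(g)
            need_ctrl -= keep_ctrl.size
    return CaseControlSample(case_counts, ctrl_counts, n_cases, n_controls)


def heterogeneous_experiment(
    model: HeterogeneousModel,
    n_replicates: int = 10_000,
    n_cases: int = 2500,
    n_controls: int = 2500,
    rng_seed: int = 0,
    method: str = "logistic",
    keep_replicates: bool = False,
) -> list[MedianORResult]:
    """Per-SNP median single-SNP OR over replicated rejection-sampled cohorts.

    Replicate r uses an independent child stream of the master seed
    (``SeedSequence(rng_seed).spawn``), so results are reproducible and
    order-independent.  Returns one :class:`MedianORResult` per SNP, paired
    with its true conditional OR exp(beta_j).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(n_replicates)
    all_ors = np.empty((n_replicates, model.n_snps))
    fallback_counts = np.zeros(model.n_snps, dtype=int)
    for r, child in enumerate(children):
        sample = rejection_sample_cohort(
            model, n_cases, n_controls, np.random.default_rng(child)
        )
        ors, fallback = _estimate_or_batch(
            sample.case_genotype_counts, sample.control_genotype_counts, method
        )
        all_ors[r] = ors
        fallback_counts += fallback
    medians = np.median(all_ors, axis=0)
    return [
        MedianORResult(
            or_true=float(np.exp(model.betas[j])),
            or_median=float(medians[j]),
            n_replicates=n_replicates,
            n_fallback=int(fallback_counts[j]),
            replicate_ors=all_ors[:, j] if keep_replicates else None,
        )
        for j in range(model.n_snps)
    ]
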