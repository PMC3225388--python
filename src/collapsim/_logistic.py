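"""Vectorized logistic fits on the 3-point genotype design.

A single-SNP additive association test is a logistic regression of case status
on the genotype count x in {0, 1, 2}.  Its sufficient statistics are the six
(possibly fractional) weights w_y(x), so many fits — one per simulation
replicate or per SNP — reduce to batched 2-parameter Newton iterations on
tiny tables.  This is the workhorse behind both the simulated odds-ratio
estimates and the analytic asymptotic marginal odds ratio.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_X = np.array([0.0, 1.0, 2.0])

#: |slope| above which a fit is treated as separated/divergent (OR > e^15)
SLOPE_DIVERGENCE = 15.0


def fit_logit_slope(
    case_weights: np.ndarray,
    control_weights: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood slope of logistic(case | genotype) per table.

    Parameters
    ----------
    case_weights, control_weights : arrays of shape (..., 3)
        Counts (or fractional weights) of genotypes {0,1,2} among cases and
        controls.  Any leading batch shape is allowed.

    Returns
    -------
    slope : array of batch shape
        Fitted log odds ratio per allele.  NaN where the fit diverged.
    converged : boolean array of batch shape
        False where the likelihood has no finite maximizer (separation /
        empty design) or Newton failed to converge.
    """
    scalar_input = np.asarray(case_weights).ndim == 1
    w1 = np.atleast_2d(np.asarray(case_weights, dtype=float))
    w0 = np.atleast_2d(np.asarray(control_weights, dtype=float))
    batch_shape = w1.shape[:-1]
    w1 = w1.reshape(-1, 3)
    w0 = w0.reshape(-1, 3)
    n = w0 + w1  # total weight per design point, (R, 3)
    total = n.sum(axis=1)
    n_case = w1.sum(axis=1)

    # start at the marginal intercept, zero slope
    frac = np.divide(n_case, total, out=np.full_like(total, 0.5), where=total > 0)
    frac = np.clip(frac, 1e-12, 1 - 1e-12)
    a = np.log(frac / (1 - frac))
    b = np.zeros_like(a)
    active = np.ones(a.size, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        eta = a[:, None] + b[:, None] * _X
        mu = expit(eta)
        # score of (a, b)
        resid = w1 - n * mu
        ga = resid.sum(axis=1)
        gb = (resid * _X).sum(axis=1)
        # negative Hessian entries
        v = n * mu * (1 - mu)
        haa = v.sum(axis=1)
        hab = (v * _X).sum(axis=1)
        hbb = (v * _X**2).sum(axis=1)
        det = haa * hbb - hab**2
        ok = active & (det > 1e-30)
        da = np.where(ok, (hbb * ga - hab * gb) / np.where(det > 0, det, 1.0), 0.0)
        db = np.where(ok, (haa * gb - hab * ga) / np.where(det > 0, det, 1.0), 0.0)
        # damp huge steps to keep Newton stable on near-separated tables
        step = np.maximum(np.abs(da), np.abs(db))
        damp = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-30), 1.0)
        a = a + da * damp
        b = b + db * damp
        active = ok & ((np.abs(ga) > tol * np.maximum(total, 1.0))
                       | (np.abs(gb) > tol * np.maximum(total, 1.0)))

    converged = (~active) & np.isfinite(b) & (np.abs(b) < SLOPE_DIVERGENCE)
    slope = np.where(converged, b, np.nan)
    slope = slope.reshape(batch_shape)
    converged = converged.reshape(batch_shape)
    if scalar_input:
        return float(slope[0]), bool(converged[0])
    return slope, converged


def allele_table_or(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    correct_zero_cells: bool = True,
) -> np.ndarray:
    """Allele-based 2x2 table odds ratio, optionally Haldane-Anscombe corrected.

    Genotype counts over {0,1,2} are collapsed to allele counts (each subject
    contributes two alleles).  When ``correct_zero_cells`` and any cell of a
    table is zero, 0.5 is added to all four cells of that table.
    """
    scalar_input = np.asarray(case_counts).ndim == 1
    c1 = np.atleast_2d(np.asarray(case_counts, dtype=float))
    c0 = np.atleast_2d(np.asarray(control_counts, dtype=float))
    batch_shape = c1.shape[:-1]
    c1 = c1.reshape(-1, 3)
    c0 = c0.reshape(-1, 3)
    risk1 = c1 @ _X
    risk0 = c0 @ _X
    non1 = c1 @ (2 - _X)
    non0 = c0 @ (2 - _X)
    table = np.stack([risk1, non1, risk0, non0], axis=1)
    if correct_zero_cells:
        zero = (table == 0).any(axis=1)
        table[zero] += 0.5
    or_ = (table[:, 0] * table[:, 3]) / (table[:, 1] * table[:, 2])
    or_ = or_.reshape(batch_shape)
    return float(or_[0]) if scalar_input else or_
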