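"""Label-dilution birth-dating of cells from nuclear 15N measurements.

During a 14N chase, each cell division halves the nuclear 15N excess laid
down during labeling: a cell that divided k times retains e0 * 0.5**k.
Post-mitotic reference cells (cortical neurons) never divide, so their
measured ratios define the retention level of a zero-division cell; beta
cells at or above that reference level are called long-lived cells (LLCs),
cells below it have divided and are called young.

The module provides the forward dilution law, the inverse division-count
estimator, neuron-referenced LLC classification, cohort LLC fractions with
bootstrap uncertainty, and an EM deconvolution of the division-count
mixture from noisy log2-excess values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .mims import NucleusMeasurement

#: Sentinel for noise-dominated nuclei whose excess is <= 0: the division
#: count is indeterminate (label fully diluted into background).
INDETERMINATE = float("nan")


@dataclass(frozen=True)
class ReferenceThresholds:
    """Reference 15N/14N levels from post-mitotic cells.

    Both the mean and the minimum over reference cells are carried: the
    minimum is the most permissive bound consistent with zero divisions,
    the mean is a stricter alternative.
    """

    ref_mean_ratio: float
    ref_min_ratio: float

    def __post_init__(self):
        if not 0 < self.ref_min_ratio <= self.ref_mean_ratio:
            raise ValueError(
                f"require 0 < min <= mean, got min={self.ref_min_ratio}, "
                f"mean={self.ref_mean_ratio}"
            )


@dataclass(frozen=True)
class CellAgeCall:
    """Per-cell age call: LLC/young label plus estimated division count."""

    cell_id: str
    ratio: float
    excess: float
    k_est: float  # continuous; NaN when indeterminate
    k_int: int | None  # rounded; None when indeterminate
    is_llc: bool


@dataclass(frozen=True)
class CohortSummary:
    """LLC fraction for one diet group with a percentile-bootstrap CI."""

    group: str
    n_cells: int
    llc_fraction: float
    ci_low: float
    ci_high: float
    mean_k_est: float


@dataclass(frozen=True)
class DivisionMixtureFit:
    """EM fit of the division-count mixture on log2-excess values."""

    weights: np.ndarray  # w_k for k = 0..K_max
    sigma: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray


def label_after_divisions(e0: float, k) -> float:
    """Nuclear label excess after k divisions: e0 * 0.5**k.

    Each division splits the nuclear DNA between daughters, removing 50% of
    the 15N excess.  k may be real-valued for model curves.
    """
    if e0 <= 0:
        raise ValueError(f"e0 must be > 0, got {e0}")
    if np.any(np.asarray(k) < 0):
        raise ValueError("division count k must be >= 0")
    return e0 * 0.5**k


def estimate_divisions(excess: float, e_ref: float) -> float:
    """Invert the dilution law: k = log2(e_ref / excess), clipped at 0.

    excess <= 0 (a noise-dominated nucleus) returns NaN with a warning:
    such a nucleus has diluted its label below natural abundance and its
    division count cannot be estimated.
    """
    if e_ref <= 0:
        raise ValueError(f"reference excess must be > 0, got {e_ref}")
    if excess <= 0:
        warnings.warn(
            "excess <= 0: noise-dominated nucleus, division count indeterminate",
            stacklevel=2,
        )
        return INDETERMINATE
    return max(0.0, math.log2(e_ref / excess))


def reference_thresholds(reference_measurements) -> ReferenceThresholds:
    """Mean and minimum 15N/14N ratio over post-mitotic reference cells."""
    ratios = [m.ratio for m in reference_measurements]
    if len(ratios) < 2:
        raise ValueError("need at least 2 reference cells")
    return ReferenceThresholds(
        ref_mean_ratio=float(np.mean(ratios)), ref_min_ratio=float(np.min(ratios))
    )


def classify_cell(
    measurement,
    thresholds: ReferenceThresholds,
    e_ref: float,
    rule: str = "min",
    cell_id: str | None = None,
) -> CellAgeCall:
    """Classify one cell as LLC or young against the neuron reference.

    Under the default "min" rule a cell is an LLC iff its ratio is at or
    above the lowest reference-neuron ratio (inclusive); the "mean" rule
    uses the reference mean instead.  The division count is estimated from
    excess relative to ``e_ref``; a non-positive excess is indeterminate
    and the cell is counted as young (maximally diluted).
    """
    if rule not in ("min", "mean"):
        raise ValueError(f"rule must be 'min' or 'mean', got {rule!r}")
    cutoff = thresholds.ref_min_ratio if rule == "min" else thresholds.ref_mean_ratio
    if measurement.excess <= 0:
        k_est, k_int = INDETERMINATE, None
        is_llc = False  # noise-dominated: counted as young
    else:
        k_est = estimate_divisions(measurement.excess, e_ref)
        k_int = int(round(k_est))
        is_llc = measurement.ratio >= cutoff
    return CellAgeCall(
        cell_id=cell_id if cell_id is not None else str(measurement.label_id),
        ratio=measurement.ratio,
        excess=measurement.excess,
        k_est=k_est,
        k_int=k_int,
        is_llc=is_llc,
    )


def cohort_llc_fraction(
    calls: list[CellAgeCall],
    group: str = "",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> CohortSummary:
    """LLC fraction of a cohort with a cell-level percentile bootstrap CI."""
    if not calls:
        raise ValueError("need at least one call")
    flags = np.array([c.is_llc for c in calls], dtype=float)
    frac = float(flags.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    boot = flags[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    k_vals = np.array([c.k_est for c in calls])
    k_vals = k_vals[np.isfinite(k_vals)]
    return CohortSummary(
        group=group,
        n_cells=len(calls),
        llc_fraction=frac,
        ci_low=float(lo),
        ci_high=float(hi),
        mean_k_est=float(k_vals.mean()) if k_vals.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# Division-count mixture deconvolution
# ---------------------------------------------------------------------------


def _mixture_loglik(x, mu_k, w, sigma):
    # log sum_k w_k N(x | mu_k, sigma^2), stable via logsumexp
    from scipy.special import logsumexp

    z = (x[:, None] - mu_k[None, :]) / sigma
    log_comp = (
        np.log(np.maximum(w, 1e-300))[None, :]
        - 0.5 * z**2
        - math.log(sigma)
        - 0.5 * math.log(2 * math.pi)
    )
    return logsumexp(log_comp, axis=1)


def fit_division_mixture(
    excess_values,
    e_ref: float,
    k_max: int = 6,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init_weights=None,
    init_sigma: float | None = None,
) -> DivisionMixtureFit:
    """EM deconvolution of division counts from noisy excess measurements.

    Model: log2(e_i) ~ Normal(log2(e_ref) - k, sigma^2) mixed over
    k = 0..k_max with weights w.  Component means are fixed by the dilution
    law (one unit of log2-excess per division); EM estimates the weights and
    the shared measurement noise sigma.  Log-likelihood is non-decreasing
    across iterations; convergence when the gain drops below ``tol``.

    Indeterminate cells (excess <= 0) must be excluded upstream.
    """
    x = np.asarray(excess_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(x <= 0):
        raise ValueError("all excess values must be > 0 (exclude indeterminates)")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if e_ref <= 0:
        raise ValueError("e_ref must be > 0")

    x = np.log2(x)
    mu_k = math.log2(e_ref) - np.arange(k_max + 1, dtype=float)
    w = (
        np.full(k_max + 1, 1.0 / (k_max + 1))
        if init_weights is None
        else np.asarray(init_weights, dtype=float) / np.sum(init_weights)
    )
    sigma = float(np.std(x)) if init_sigma is None else float(init_sigma)
    sigma = max(sigma, 1e-3)

    path = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities
        z = (x[:, None] - mu_k[None, :]) / sigma
        log_comp = (
            np.log(np.maximum(w, 1e-300))[None, :]
            - 0.5 * z**2
            - math.log(sigma)
            - 0.5 * math.log(2 * math.pi)
        )
        m = log_comp.max(axis=1, keepdims=True)
        p = np.exp(log_comp - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float(np.sum(np.log(norm[:, 0]) + m[:, 0]))
        path.append(ll)
        if ll - prev_ll < tol and n_iter > 1:
            converged = True
            break
        prev_ll = ll
        # M-step
        w = resp.mean(axis=0)
        var = float(np.sum(resp * (x[:, None] - mu_k[None, :]) ** 2) / x.size)
        sigma = max(math.sqrt(var), 1e-6)

    return DivisionMixtureFit(
        weights=w,
        sigma=sigma,
        loglik=path[-1],
        n_iter=n_iter,
        converged=converged,
        loglik_path=np.asarray(path),
    )


def mixture_loglik(excess_values, e_ref: float, weights, sigma: float) -> float:
    """Log-likelihood of the division-count mixture at given parameters.

    Shared by the EM fitter and any external maximizer used to cross-check it.
    """
    x = np.log2(np.asarray(excess_values, dtype=float))
    mu_k = math.log2(e_ref) - np.arange(len(weights), dtype=float)
    return float(np.sum(_mixture_loglik(x, mu_k, np.asarray(weights, float), sigma)))
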