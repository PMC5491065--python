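"""Three-stage single-channel preprocessing.

The pipeline applied to each raw linear-scale matrix is

1. background correction (default: a normal+exponential convolution model
   fitted per array by the method of moments),
2. quantile normalization across arrays,
3. negative-control brightness filtering: per array the 95th percentile of
   the negative-control probes defines a background ceiling, and a regular
   probe is kept only if it is at least 10% brighter than that ceiling on
   at least three arrays,

followed by a log2 transformation for the downstream statistics.

Numerical conventions that matter and are fixed here:

* the 95th percentile interpolates linearly between order statistics at
  position 1 + (n-1)p (numpy's default, R type 7);
* "at least 10% brighter" is multiplicative, value >= 1.10 x Q95, with >=
  at the boundary;
* quantile-normalization ties within a column receive the mean of the
  reference distribution over their tied ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import StageError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

BACKGROUND_METHODS = ("normexp_moments", "subtract_floor")

#: floor used by subtract_floor before the offset is added
_SUBTRACT_EPS = 0.5


@dataclass
class FilterDecision:
    """Per-probe outcome of the negative-control brightness filter."""

    probe_id: str
    per_array_bright: np.ndarray       # bool, one entry per array
    kept: bool
    threshold_per_array: np.ndarray    # linear-scale thresholds

    @property
    def n_bright_arrays(self) -> int:
        return int(self.per_array_bright.sum())


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def _normexp_moment_fit(x: np.ndarray) -> tuple[float, float, float] | None:
    """Method-of-moments fit of observed = Exp(alpha) + N(mu, sigma^2).

    Moment identities: mean = mu + alpha, var = sigma^2 + alpha^2, third
    central moment = 2 alpha^3.  Returns (alpha, mu, sigma) or None when
    the estimate is infeasible (non-positive alpha or sigma^2).
    """
    m1 = x.mean()
    c = x - m1
    m2 = np.mean(c ** 2)
    m3 = np.mean(c ** 3)
    if m3 <= 0:
        return None
    alpha = (m3 / 2.0) ** (1.0 / 3.0)
    sigma2 = m2 - alpha ** 2
    if alpha <= 0 or sigma2 <= 0:
        return None
    return alpha, m1 - alpha, float(np.sqrt(sigma2))


def _normexp_signal(x: np.ndarray, alpha: float, mu: float, sigma: float) -> np.ndarray:
    """E[signal | observed] under the convolution model (computed in log
    space for numerical stability in the deep-background tail)."""
    mu_sf = x - mu - sigma ** 2 / alpha
    log_ratio = stats.norm.logpdf(0.0, loc=mu_sf, scale=sigma) - stats.norm.logsf(
        0.0, loc=mu_sf, scale=sigma
    )
    signal = mu_sf + sigma ** 2 * np.exp(log_ratio)
    # conditional expectation of a positive variable; clip numeric dust
    return np.maximum(signal, 1e-12)


def _background_means(
    matrix: ExpressionMatrix, control_types: np.ndarray | None
) -> np.ndarray:
    """Per-array background level: negative-control mean when flags are
    available, otherwise the 5th percentile of the array."""
    if control_types is not None:
        control_types = np.asarray(control_types)
        neg = control_types == -1
        if neg.any():
            return matrix.values[neg].mean(axis=0)
    return np.percentile(matrix.values, 5, axis=0)


def background_correct(
    matrix: ExpressionMatrix,
    method: str = "normexp_moments",
    offset: float = 16.0,
    control_types: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Background-correct a raw linear matrix, per array.

    ``normexp_moments`` fits, independently per array, the convolution
    model observed = exponential signal + normal background by the method
    of moments and replaces each value by the conditional expectation of
    the signal given the observation; arrays whose moment estimates are
    infeasible (sigma^2 <= 0) fall back to ``subtract_floor`` with a logged
    warning.  ``subtract_floor`` computes max(x - background_mean, 0.5)
    where the background mean comes from that array's negative controls
    (or its 5th percentile when no control flags are supplied).  ``offset``
    is added afterwards in both cases, so every output value is strictly
    positive.
    """
    matrix.require(stage="raw", scale="linear")
    if method not in BACKGROUND_METHODS:
        raise ValidationError(f"unknown background method {method!r}")
    if offset < 0:
        raise ValidationError("offset must be non-negative")

    values = matrix.values
    out = np.empty_like(values)
    floors = _background_means(matrix, control_types)
    for j in range(values.shape[1]):
        col = values[:, j]
        corrected = None
        if method == "normexp_moments":
            fit = _normexp_moment_fit(col)
            if fit is None:
                logger.warning(
                    "array %s: normexp moment fit infeasible, "
                    "falling back to subtract_floor",
                    matrix.sample_ids[j],
                )
            else:
                alpha, mu, sigma = fit
                corrected = _normexp_signal(col, alpha, mu, sigma)
        if corrected is None:
            corrected = np.maximum(col - floors[j], _SUBTRACT_EPS)
        out[:, j] = corrected + offset
    if not (out > 0).all():
        raise ValidationError("background correction produced non-positive values")
    return matrix.with_values(out, stage="background_corrected")


def fit_normexp(values: np.ndarray) -> tuple[float, float, float]:
    """Public moment fit for one array; raises when infeasible."""
    fit = _normexp_moment_fit(np.asarray(values, dtype=float))
    if fit is None:
        raise ValidationError("normexp moment estimate infeasible (sigma^2 <= 0)")
    return fit


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common mean empirical distribution.

    The reference distribution is the across-array mean of the sorted
    columns; each value is replaced by the reference value at its
    within-column rank, tied values sharing the mean of the reference
    values at their tied ranks.  Within-column rank order is preserved.
    """
    matrix.require(stage="background_corrected")
    values = matrix.values
    n, p = values.shape
    if p < 2:
        logger.warning("quantile_normalize: single-sample matrix, no-op")
        return matrix.with_values(values.copy(), stage="normalized")
    if n == 0:
        return matrix.with_values(values.copy(), stage="normalized")

    reference = np.sort(values, axis=0).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(values)
    for j in range(p):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ordered = col[order]
        # tie-block boundaries in sorted order
        starts = np.flatnonzero(np.concatenate(([True], ordered[1:] != ordered[:-1])))
        ends = np.concatenate((starts[1:], [n]))
        block_means = (csum[ends] - csum[starts]) / (ends - starts)
        sorted_out = np.repeat(block_means, ends - starts)
        out[order, j] = sorted_out
    return matrix.with_values(out, stage="normalized")


# ---------------------------------------------------------------------------
# log2 transform
# ---------------------------------------------------------------------------

def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform a linear-scale matrix (any stage); all values must be
    strictly positive."""
    matrix.require(scale="linear")
    bad = ~(matrix.values > 0)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValidationError(
            f"non-positive value for probe {matrix.probe_ids[i]!r}; "
            "cannot log2-transform"
        )
    return matrix.with_values(np.log2(matrix.values), scale="log2")


# ---------------------------------------------------------------------------
# negative-control filtering
# ---------------------------------------------------------------------------

def negctrl_filter(
    matrix: ExpressionMatrix,
    control_types: np.ndarray,
    percentile: float = 95.0,
    brightness_factor: float = 1.10,
    min_arrays: int = 3,
) -> tuple[ExpressionMatrix, list[FilterDecision]]:
    """Drop control probes and dim probes from a normalized linear matrix.

    Per array ``a`` the threshold is ``brightness_factor x Q(percentile)``
    of that array's negative-control values, the quantile interpolating
    linearly between order statistics.  A regular probe is kept iff its
    value meets the threshold (>=) on at least ``min_arrays`` arrays.
    Control probes (control_type != 0) are removed from the output
    unconditionally; decisions are reported for every regular probe.
    """
    matrix.require(scale="linear")
    if matrix.stage not in ("normalized", "background_corrected", "raw"):
        raise StageError(f"cannot filter a matrix at stage {matrix.stage!r}")
    control_types = np.asarray(control_types)
    if control_types.shape[0] != matrix.n_probes:
        raise ValidationError("control_types length != number of probes")

    neg = control_types == -1
    if not neg.any():
        raise ValidationError("no negative-control probes in matrix")
    neg_values = matrix.values[neg]
    thresholds = brightness_factor * np.percentile(neg_values, percentile, axis=0)
    if not (thresholds > 0).all():
        j = int(np.argmax(~(thresholds > 0)))
        raise ValidationError(
            f"non-positive negative-control threshold on array "
            f"{matrix.sample_ids[j]!r}"
        )

    regular = control_types == 0
    reg_idx = np.flatnonzero(regular)
    bright = matrix.values[regular] >= thresholds[np.newaxis, :]
    n_bright = bright.sum(axis=1)
    kept = n_bright >= min_arrays

    decisions = [
        FilterDecision(
            probe_id=matrix.probe_ids[i],
            per_array_bright=bright[k],
            kept=bool(kept[k]),
            threshold_per_array=thresholds,
        )
        for k, i in enumerate(reg_idx)
    ]
    keep_idx = reg_idx[kept]
    filtered = matrix.with_values(
        matrix.values[keep_idx],
        stage="filtered",
        probe_ids=[matrix.probe_ids[i] for i in keep_idx],
    )
    logger.info(
        "negctrl_filter: kept %d/%d regular probes (thresholds %.3g..%.3g)",
        len(keep_idx), regular.sum(), thresholds.min(), thresholds.max(),
    )
    return filtered, decisions


def preprocess_pipeline(
    matrix: ExpressionMatrix,
    control_types: np.ndarray,
    background_method: str = "normexp_moments",
    offset: float = 16.0,
    percentile: float = 95.0,
    brightness_factor: float = 1.10,
    min_arrays: int = 3,
) -> tuple[ExpressionMatrix, list[FilterDecision]]:
    """Background-correct, quantile-normalize, filter, then log2.

    Returns the filtered log2 matrix ready for the pattern statistics plus
    the per-probe filter decisions.
    """
    corrected = background_correct(
        matrix, method=background_method, offset=offset,
        control_types=control_types,
    )
    normalized = quantile_normalize(corrected)
    filtered, decisions = negctrl_filter(
        normalized, control_types,
        percentile=percentile,
        brightness_factor=brightness_factor,
        min_arrays=min_arrays,
    )
    return log2_transform(filtered), decisions
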