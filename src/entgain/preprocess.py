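"""Expression preprocessing: standardization, ternary quantization, QC.

Each gene's time series g(t) is first standardized with the normal
transformation

    eta[g(t)] = (g(t) - E[g(t)]) / sigma[g(t)],

where the expectation and the standard deviation are population moments
over the observed (non-missing) time points. The standardized signal
alpha is then quantized into three regulation levels through a threshold
mapping with upper threshold h and lower threshold l:

    +1 (up)    if alpha >= h
    -1 (down)  if alpha <= l
     0 (basal) otherwise.

The extreme branches take precedence at the boundaries, making the
mapping total; the set {alpha = h} u {alpha = l} has negligible measure
so the choice does not affect results in practice. Missing time points
carry the explicit not-observed code through both steps unchanged.

A quality-control filter drops genes observed at fewer than
``min_observed`` time points (default 25, matching a 48-sample series
where at least half the cycle must be seen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, ThresholdError
from .io import ExpressionMatrix

__all__ = [
    "QuantizationThresholds",
    "normal_transform",
    "quantize",
    "qc_filter",
    "preprocess",
]


@dataclass(frozen=True)
class QuantizationThresholds:
    """Upper (h) and lower (l) cutoffs on the standardized signal."""

    h: float = 0.5
    l: float = -0.5

    def __post_init__(self) -> None:
        if self.l > self.h:
            raise ThresholdError(f"lower threshold {self.l} exceeds upper {self.h}")


def normal_transform(
    series, missing_mask=None, ddof: int = 0
) -> np.ndarray:
    """Standardize one series to mean 0, standard deviation 1.

    Moments are computed over non-missing positions only (population
    moments by default; set ``ddof=1`` for the sample estimator).
    Missing positions are preserved untouched.

    Raises
    ------
    DegenerateSeriesError
        If the observed values have zero standard deviation.
    """
    series = np.asarray(series, dtype=float)
    if missing_mask is None:
        missing_mask = np.isnan(series)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    obs = series[~missing_mask]
    if obs.size < 2:
        raise DegenerateSeriesError("need >=2 observed values to standardize")
    sigma = obs.std(ddof=ddof)
    if sigma == 0:
        raise DegenerateSeriesError("constant series cannot be standardized")
    out = series.copy()
    out[~missing_mask] = (obs - obs.mean()) / sigma
    return out


def quantize(
    matrix: ExpressionMatrix,
    thr: QuantizationThresholds = QuantizationThresholds(),
    standardize: bool = True,
    ddof: int = 0,
) -> ExpressionMatrix:
    """Quantize a real-valued matrix into ternary regulation levels.

    Applies :func:`normal_transform` per gene (unless ``standardize`` is
    off, for data already standardized upstream) and then the threshold
    mapping. Genes whose observed values are constant cannot be
    standardized and are dropped with a warning — a flat profile carries
    no regulation signal.
    """
    import logging

    logger = logging.getLogger(__name__)
    if matrix.quantized:
        raise ValueError("matrix is already quantized")
    miss = ~matrix.observed_mask()
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i, gene in enumerate(matrix.gene_ids):
        row = matrix.values[i].astype(float)
        m = miss[i]
        if standardize:
            try:
                row = normal_transform(row, m, ddof=ddof)
            except DegenerateSeriesError:
                logger.warning("dropping gene %s: degenerate (constant) series", gene)
                continue
        q = np.zeros(row.shape, dtype=int)
        q[row >= thr.h] = 1
        q[row <= thr.l] = -1
        q[m] = matrix.missing_code
        kept_ids.append(gene)
        rows.append(q)
    out = np.asarray(rows, dtype=int).reshape(len(rows), matrix.n_timepoints)
    return ExpressionMatrix(
        kept_ids, out, quantized=True, missing_code=matrix.missing_code
    )


def qc_filter(matrix: ExpressionMatrix, min_observed: int = 25) -> ExpressionMatrix:
    """Keep genes observed at >= ``min_observed`` time points, in order."""
    counts = matrix.n_observed()
    keep = [g for g, c in zip(matrix.gene_ids, counts) if c >= min_observed]
    return matrix.subset(keep)


def preprocess(
    matrix: ExpressionMatrix,
    thr: QuantizationThresholds = QuantizationThresholds(),
    min_observed: int = 25,
) -> ExpressionMatrix:
    """QC-filter, standardize and quantize in one step."""
    filtered = qc_filter(matrix, min_observed)
    if filtered.quantized:
        return filtered
    return quantize(filtered, thr)
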