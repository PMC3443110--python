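"""Per-array global scaling and the log-transform floor.

Arrays are normalized multiplicatively so that a tail-trimmed mean of each
array's signals hits a common target intensity (default 150, the GCOS/MAS5
convention with a 2% trimmed mean). Before any log2 statistic, signals are
floored at a small positive intensity (default 10) so that undetected
transcripts contribute log2(10) = 3.32 rather than -inf; 3.32 is therefore
the smallest possible mean log intensity in downstream tables.

Trimming is symmetric and count-based: of k values, the floor(k * trim)
smallest and floor(k * trim) largest are removed before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingConfig", "trimmed_mean", "scale_array", "scale_matrix", "floor_and_log2"]


@dataclass(frozen=True)
class ScalingConfig:
    """Global-scaling parameters.

    target
        Intensity the trimmed mean of every array is scaled to (> 0).
    trim_fraction
        Fraction removed from each tail before averaging, in [0, 0.5).
    floor
        Positive intensity applied before log2; log2(floor) bounds every
        log-scale statistic from below.
    """

    target: float = 150.0
    trim_fraction: float = 0.02
    floor: float = 10.0

    def __post_init__(self) -> None:
        if not self.target > 0:
            raise ValueError("target must be > 0")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if not self.floor > 0:
            raise ValueError("floor must be > 0")


def trimmed_mean(values, trim_fraction: float = 0.02) -> float:
    """Mean after dropping floor(k*trim_fraction) values from each tail."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = values.size
    cut = int(np.floor(k * trim_fraction))
    if k - 2 * cut <= 0:
        raise ValueError("no values survive trimming")
    ordered = np.sort(values)
    return float(ordered[cut : k - cut].mean())


def scale_array(signals, config: ScalingConfig = ScalingConfig()):
    """Scale one array so its trimmed mean equals ``config.target``.

    Returns ``(scaled_signals, scale_factor)`` with
    ``scale_factor = target / trimmed_mean(signals)``.
    """
    signals = np.asarray(signals, dtype=float)
    tm = trimmed_mean(signals, config.trim_fraction)
    if tm <= 0:
        raise ValueError("trimmed mean of signals must be > 0 (all-zero array?)")
    factor = config.target / tm
    return signals * factor, factor


def scale_matrix(matrix, config: ScalingConfig = ScalingConfig()):
    """Scale every sample of an :class:`~rankde.io.ExpressionMatrix` independently.

    Returns ``(scaled_matrix, factors)`` where *factors* maps sample id to
    the multiplicative factor applied to that array.
    """
    from .io import ExpressionMatrix

    scaled = matrix.signals.copy()
    factors: dict[str, float] = {}
    for sid in matrix.sample_ids:
        scaled[sid], factors[sid] = scale_array(scaled[sid].to_numpy(), config)
    return ExpressionMatrix(scaled, matrix.calls), factors


def floor_and_log2(signal, config: ScalingConfig = ScalingConfig()):
    """log2 of the signal floored at ``config.floor``; monotone, never -inf.

    Accepts scalars or arrays. With the default floor of 10 the minimum
    output is log2(10) = 3.3219 (printed as 3.32 in result tables).
    """
    arr = np.log2(np.maximum(np.asarray(signal, dtype=float), config.floor))
    if np.ndim(signal) == 0:
        return float(arr)
    return arr
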