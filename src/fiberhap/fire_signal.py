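"""Aggregate FIRE accessibility signal and genome-wide peak calling.

The per-base aggregate signal at genomic position ``g`` is the phred-scaled
sum over the MSPs of all fibers covering ``g``::

    S_g = -10 * sum_k log10(1 - p_k)

where ``p_k`` is the precision of the k-th overlapping MSP.  Fibers covering
``g`` without an MSP there contribute a ``p = 0`` term, i.e. nothing.  Under
the reading that ``prod_k (1 - p_k)`` is the probability that no overlapping
patch is a true regulatory element, ``S_g`` is a phred-scaled per-base
p-value, and peaks are called where it exceeds the Bonferroni-corrected
threshold ``S* = -10 * log10(alpha / genome_size)``.

By default every MSP contributes with its precision; restricting the sum to
high-precision patches (the fiber-level FIRE definition) is available via
``min_precision`` and changes the signal only negligibly, since low-p terms
are near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import Fiber, GenomicInterval, Peak

#: floor applied to (1 - p) before the log, keeping S finite at p = 1
CLAMP = 1e-10


@dataclass(frozen=True)
class SignalTrack:
    """Per-base aggregate FIRE score over ``[start, start + len(values))``."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or v.min() < 0):
            raise ValueError("signal values must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + len(self.values))


def msp_weight(precision: float) -> float:
    """Phred contribution of a single MSP: ``-10 * log10(1 - p)`` (clamped)."""
    return -10.0 * math.log10(max(1.0 - precision, CLAMP))


def aggregate_fire_signal(
    fibers: Sequence[Fiber],
    region: GenomicInterval,
    min_precision: float = 0.0,
) -> SignalTrack:
    """Aggregate the FIRE signal of ``fibers`` across ``region``.

    MSPs with precision below ``min_precision`` are ignored (default 0:
    every patch contributes).
    """
    values = np.zeros(len(region), dtype=float)
    for fiber in fibers:
        if fiber.chrom != region.chrom:
            continue
        for msp in fiber.msps:
            if msp.precision < min_precision:
                continue
            lo = max(msp.interval.start, region.start) - region.start
            hi = min(msp.interval.end, region.end) - region.start
            if lo < hi:
                values[lo:hi] += msp_weight(msp.precision)
    return SignalTrack(region.chrom, region.start, values)


def peak_score_threshold(alpha: float, genome_size: int) -> float:
    """Bonferroni-corrected score threshold ``S* = -10*log10(alpha/G)``.

    A base is significant iff ``S_g >= S*``, i.e. its combined null
    probability is at most ``alpha / genome_size``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if genome_size < 1:
        raise ValueError("genome_size must be >= 1")
    return -10.0 * math.log10(alpha / genome_size)


def call_fire_peaks(
    track: SignalTrack,
    threshold: float,
    merge_gap: int = 0,
    peak_prefix: str = "peak",
) -> list[Peak]:
    """Maximal runs of consecutive bases with ``S_g >= threshold``.

    Runs separated by sub-threshold gaps of at most ``merge_gap`` bases are
    merged.  Each peak records the maximum signal within its span.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    above = track.values >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    # merge runs whose gap <= merge_gap
    merged: list[list[int]] = [[int(run_starts[0]), int(run_ends[0])]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if int(s) - merged[-1][1] <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    peaks = []
    for i, (s, e) in enumerate(merged, start=1):
        peaks.append(
            Peak(
                GenomicInterval(track.chrom, track.start + s, track.start + e),
                f"{peak_prefix}_{i}",
                float(track.values[s:e].max()),
            )
        )
    return peaks
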