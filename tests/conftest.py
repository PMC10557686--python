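"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from fiberhap import Fiber, GenomicInterval, MspCall, Peak


def make_fiber(
    start: int,
    end: int,
    msps: list[tuple[int, int, float]] = (),
    hap: str = "H1",
    fid: str = "f1",
    chrom: str = "chrA",
) -> Fiber:
    return Fiber(
        GenomicInterval(chrom, start, end),
        fid,
        hap,
        tuple(MspCall(GenomicInterval(chrom, s, e), p) for s, e, p in msps),
    )


def make_peak(start: int, end: int, pid: str = "p1", chrom: str = "chrA") -> Peak:
    return Peak(GenomicInterval(chrom, start, end), pid)


@pytest.fixture
def fiber_factory():
    return make_fiber


@pytest.fixture
def peak_factory():
    return make_peak
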