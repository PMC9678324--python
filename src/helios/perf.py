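"""Analytic processing-time and memory model of the optical architecture.

A modulator of aperture L x W pixels refreshing every T seconds
processes the whole comparison workload of two inputs totalling N and M
characters in

    time = (2 * N * M / (L**2 * W)) * T      seconds

(two pixels per coded character; the shift count R does not enter
because all shifts propagate in parallel), while the memory is simply
the aperture itself, S = L * W pixels.  The closed forms as published
omit the switching-time factor, but every printed estimate equals the
product above, so T is part of the contract here; the note is recorded
in the package docs.  Comparable published optical architectures differ
only in their pixels-per-character coefficient:

    OptCAM  (16*N*M / (L**2 * W)) * T
    HAWPOD  ( 4*N*M / L**2) * T
    Moire   (16*N*M / L**2) * T
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PerfSpec", "PerfEstimate", "helios_time", "helios_memory", "comparative_time"]

BYTES_PER_PIXEL = 1  # MB figures below use 1 byte/pixel, 1 MB = 2**20 bytes


@dataclass(frozen=True)
class PerfSpec:
    """Problem and hardware sizes for the analytic model.

    ``n`` and ``m`` are the *total* character counts of the two inputs
    (a genome, or the summed bases of a read set), in bases -- no unit
    guessing is performed.  ``l`` and ``w`` are the modulator aperture
    in pixels and ``switching_time`` is the refresh period in seconds
    (the reciprocal of the switching rate).
    """

    n: float
    m: float
    l: int = 1024
    w: int = 1024
    switching_time: float = 1e-8  # 100 MHz graphene modulator default

    def __post_init__(self) -> None:
        if min(self.n, self.m) <= 0 or min(self.l, self.w) <= 0:
            raise ValueError("all sizes must be positive")
        if self.switching_time <= 0:
            raise ValueError("switching time must be positive")


@dataclass(frozen=True)
class PerfEstimate:
    time_seconds: float
    memory_pixels: int
    memory_mb: float
    method: str


def helios_time(spec: PerfSpec) -> float:
    """Processing time in seconds: (2NM / (L^2 W)) * T."""
    return (2.0 * spec.n * spec.m / (spec.l**2 * spec.w)) * spec.switching_time


def helios_memory(spec: PerfSpec) -> int:
    """Required memory in pixels: the modulator aperture L x W."""
    return spec.l * spec.w


def memory_mb(spec: PerfSpec) -> float:
    return helios_memory(spec) * BYTES_PER_PIXEL / 2**20


_COEFFICIENTS = {
    # (numerator coefficient, divide by aperture width W as well?)
    "helios": (2.0, True),
    "optcam": (16.0, True),
    "hawpod": (4.0, False),
    "moire": (16.0, False),
}


def comparative_time(method: str, spec: PerfSpec) -> float:
    """Processing time of a named optical architecture on ``spec``."""
    try:
        coeff, per_width = _COEFFICIENTS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_COEFFICIENTS)}"
        ) from None
    denom = spec.l**2 * (spec.w if per_width else 1)
    return (coeff * spec.n * spec.m / denom) * spec.switching_time


def estimate(method: str, spec: PerfSpec) -> PerfEstimate:
    return PerfEstimate(
        time_seconds=comparative_time(method, spec),
        memory_pixels=helios_memory(spec),
        memory_mb=memory_mb(spec),
        method=method.lower(),
    )
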