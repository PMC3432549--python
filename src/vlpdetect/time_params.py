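"""Temporal late-potential parameters on the vector magnitude.

The three classical SAECG parameters, with the QRS duration re-anchored at
the R peak (late potentials only perturb the *end* of the complex, and the
R peak is a far more robust landmark than the QRS onset):

* QRSd  -- time from the R-wave peak to the J point, ms;
* RMS40 -- root-mean-square voltage of the terminal 40 ms of the QRS, uV;
* LAS40 -- duration of the terminal low-amplitude (< 40 uV) signal, ms.

Late potentials lengthen QRSd and LAS40 and lower RMS40. A record is called
positive when at least ``min_abnormal`` (default 2) of the three parameters
fall outside their normal range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FiducialError
from .fiducials import VectorMagnitude

LAS_LEVEL_UV = 40.0


@dataclass
class TimeParams:
    qrsd: float  # ms
    rms40: float  # uV
    las40: float  # ms
    standard_qrsd: float | None = None  # onset-to-J, when the onset was found


@dataclass
class TimeThresholds:
    """Population thresholds; the defaults are the study values for PTB-like
    acquisitions and are expected to be refit per hardware."""

    qrsd_max_ms: float = 95.0
    rms40_min_uv: float = 63.5
    las40_max_ms: float = 44.2
    min_abnormal: int = 2

    def __post_init__(self):
        if self.min_abnormal not in (1, 2, 3):
            raise ValueError("min_abnormal must be 1, 2 or 3")


def qrsd(vm: VectorMagnitude) -> float:
    """R-peak-to-J-point duration in ms."""
    if vm.r_peak is None or vm.j_point is None:
        raise FiducialError("r_peak and j_point must be set")
    if vm.j_point < vm.r_peak:
        raise FiducialError("j_point precedes r_peak")
    if vm.j_point == vm.r_peak:
        warnings.warn("degenerate QRSd: j_point equals r_peak", stacklevel=2)
    return (vm.j_point - vm.r_peak) / vm.fs * 1000.0


def rms40(vm: VectorMagnitude, span_ms: float = 40.0) -> float:
    """RMS voltage over the terminal ``span_ms`` of the QRS ([J-40 ms, J))."""
    if vm.j_point is None:
        raise FiducialError("j_point must be set")
    w = int(round(span_ms * vm.fs / 1000.0))
    if vm.j_point < w:
        raise FiducialError(f"fewer than {span_ms} ms of samples before the J point")
    seg = vm.vm[vm.j_point - w : vm.j_point]
    return float(np.sqrt(np.mean(seg**2)))


def las40(vm: VectorMagnitude, level_uv: float = LAS_LEVEL_UV) -> float:
    """Duration (ms) of the maximal contiguous sub-``level_uv`` run ending
    at the J point."""
    if vm.j_point is None:
        raise FiducialError("j_point must be set")
    n = 0
    for t in range(vm.j_point - 1, -1, -1):
        if vm.vm[t] < level_uv:
            n += 1
        else:
            break
    return n / vm.fs * 1000.0


def compute_time_params(vm: VectorMagnitude) -> TimeParams:
    std_qrsd = None
    if vm.qrs_onset is not None and vm.j_point is not None:
        std_qrsd = (vm.j_point - vm.qrs_onset) / vm.fs * 1000.0
    return TimeParams(qrsd=qrsd(vm), rms40=rms40(vm), las40=las40(vm), standard_qrsd=std_qrsd)


def classify_time(
    params: TimeParams, thr: TimeThresholds | None = None
) -> tuple[bool, dict[str, bool]]:
    """At-least-``min_abnormal``-of-three rule.

    Abnormal means QRSd above, RMS40 below, LAS40 above threshold. Returns
    (verdict, per-parameter abnormality flags).
    """
    thr = thr or TimeThresholds()
    flags = {
        "qrsd": params.qrsd > thr.qrsd_max_ms,
        "rms40": params.rms40 < thr.rms40_min_uv,
        "las40": params.las40 > thr.las40_max_ms,
    }
    return sum(flags.values()) >= thr.min_abnormal, flags
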