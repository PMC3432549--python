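"""Band-limiting and interference removal for HRECG records.

The front end is a causal (single-pass, nonlinear-phase) 4th-order
Butterworth band-pass, 25-300 Hz by default: the high-pass corner removes DC
and respiratory baseline wander, the low-pass corner bounds the noise
bandwidth while keeping the whole 40-300 Hz late-potential band. Causal
filtering is deliberate -- zero-phase (forward-backward) filtering smears
QRS energy backwards *and forwards* into the ST segment, exactly where late
potentials live. Mains interference at 50 Hz and harmonics, when present, is
removed with narrow 2nd-order Butterworth band-stop (notch) filters.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import RecordError
from .record import EcgRecord

TRANSIENT_S = 0.5  # start-up transient of the causal filters, excluded from beat extraction


def _apply_sos(record: EcgRecord, sos: np.ndarray) -> EcgRecord:
    out = record.copy()
    out.signal = sps.sosfilt(sos, record.signal, axis=0)
    out.meta["transient_samples"] = max(
        int(record.meta.get("transient_samples", 0)), int(TRANSIENT_S * record.fs)
    )
    return out


def bandpass_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    """Design the band-pass; ``order`` is the overall filter order (poles)."""
    if not (0 < low < high < fs / 2):
        raise RecordError(f"band ({low}, {high}) Hz is invalid for fs={fs} Hz")
    if order < 2 or order % 2:
        raise RecordError("band-pass order must be a positive even integer")
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    record: EcgRecord, low: float = 25.0, high: float = 300.0, order: int = 4
) -> EcgRecord:
    """Causal Butterworth band-pass applied identically to every lead."""
    sos = bandpass_sos(low, high, order, record.fs)
    out = _apply_sos(record, sos)
    out.meta.setdefault("filters", []).append(
        {"kind": "bandpass", "low_hz": low, "high_hz": high, "order": order}
    )
    return out


def notch_sos(center: float, width: float, order: int, fs: float) -> np.ndarray:
    """Band-stop design; ``width`` is the total -3 dB stop-band width."""
    lo, hi = center - width / 2.0, center + width / 2.0
    if not (0 < lo and hi < fs / 2):
        raise RecordError(f"notch band ({lo}, {hi}) Hz is invalid for fs={fs} Hz")
    if order < 2 or order % 2:
        raise RecordError("notch order must be a positive even integer")
    return sps.butter(order // 2, [lo, hi], btype="bandstop", fs=fs, output="sos")


def notch_filter(
    record: EcgRecord, center: float, width: float = 5.0, order: int = 2
) -> EcgRecord:
    """Causal Butterworth notch around ``center`` Hz (per lead)."""
    sos = notch_sos(center, width, order, record.fs)
    out = _apply_sos(record, sos)
    out.meta.setdefault("filters", []).append(
        {"kind": "notch", "center_hz": center, "width_hz": width, "order": order}
    )
    return out


def detect_mains_peaks(
    record: EcgRecord,
    base: float = 50.0,
    max_harmonics: int = 5,
    factor: float = 10.0,
) -> list[float]:
    """Mains tones actually present in the record.

    Welch periodogram of the summed leads; the power at ``h * base`` must
    exceed the local median (within +-10 Hz, the tone's +-1.5 Hz
    neighbourhood excluded) by ``factor`` to count as interference. Returns
    an empty list for a clean record.
    """
    if record.n_samples < 2 * record.fs:
        raise RecordError("need at least 2 s of signal to detect mains peaks")
    x = record.signal.sum(axis=1)
    nperseg = min(int(4 * record.fs), record.n_samples)
    f, pxx = sps.welch(x, fs=record.fs, nperseg=nperseg)
    found = []
    for h in range(1, max_harmonics + 1):
        fc = base * h
        if fc >= record.fs / 2 - 2.0:
            break
        near = (f >= fc - 1.0) & (f <= fc + 1.0)
        ring = (f >= fc - 10.0) & (f <= fc + 10.0) & ~((f >= fc - 1.5) & (f <= fc + 1.5))
        if not near.any() or not ring.any():
            continue
        if pxx[near].max() > factor * np.median(pxx[ring]):
            found.append(fc)
    return found


def preprocess_record(
    record: EcgRecord,
    low: float = 25.0,
    high: float = 300.0,
    order: int = 4,
    notch_enabled: bool = True,
    notch_base: float = 50.0,
    notch_width: float = 5.0,
    notch_order: int = 2,
    notch_max_harmonics: int = 5,
    notch_factor: float = 10.0,
) -> EcgRecord:
    """Full acquisition-stage preprocessing: band-pass, then notch any
    detected mains tones."""
    out = bandpass_filter(record, low=low, high=high, order=order)
    if notch_enabled:
        try:
            peaks = detect_mains_peaks(
                record, base=notch_base, max_harmonics=notch_max_harmonics, factor=notch_factor
            )
        except RecordError:
            peaks = []
        for fc in peaks:
            if low < fc < high:  # tones outside the passband are already gone
                out = notch_filter(out, center=fc, width=notch_width, order=notch_order)
    return out
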