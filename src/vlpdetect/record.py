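"""The multi-lead ECG record container used throughout the pipeline.

Amplitudes are carried in microvolts everywhere; sampling frequency in Hz.
High-resolution ECG (HRECG) records default to 1 kHz, the rate of the PTB
diagnostic database this package's processing chain is designed for.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .errors import RecordError

DEFAULT_FS = 1000.0


@dataclass
class EcgRecord:
    """Multi-lead sampled ECG.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_leads)
        Per-lead samples in microvolts.
    fs : float
        Sampling frequency in Hz (> 0).
    lead_names : list of str, optional
        Lead labels; autogenerated ``L0, L1, ...`` when omitted.
    meta : dict
        Free-form provenance. Synthetic records store ground truth here:
        ``r_peaks`` (sample indices), ``qrs_ends``, ``qrs_onsets``,
        ``vlp_beats`` (per-beat booleans), ``lead_gains``.
    """

    signal: np.ndarray
    fs: float = DEFAULT_FS
    lead_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.signal.ndim != 2:
            raise RecordError("signal must be a (n_samples, n_leads) matrix")
        if not self.fs > 0:
            raise RecordError(f"sampling frequency must be positive, got {self.fs}")
        if self.lead_names is None:
            self.lead_names = [f"L{i}" for i in range(self.n_leads)]
        if len(self.lead_names) != self.n_leads:
            raise RecordError("lead_names length does not match lead count")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EcgRecord":
        return EcgRecord(
            signal=self.signal.copy(),
            fs=self.fs,
            lead_names=list(self.lead_names),
            meta=_copy.deepcopy(self.meta),
        )

    def with_signal(self, signal: np.ndarray) -> "EcgRecord":
        """New record sharing fs/leads/meta with replacement samples."""
        out = self.copy()
        out.signal = np.asarray(signal, dtype=float)
        if out.signal.shape != self.signal.shape:
            raise RecordError("replacement signal must keep the same shape")
        return out
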