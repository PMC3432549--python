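"""Wigner-Ville distribution and normalized time-frequency energy indices.

Late potentials are localized jointly in time (end of QRS, early ST) and
frequency (40-300 Hz), which makes a quadratic time-frequency
representation a natural detector. The discrete Wigner-Ville distribution
(WVD) used here is, for each time sample t, the Fourier transform over the
lag k of the instantaneous autocorrelation x[t+k] x[t-k] (the standard
lag-doubling convention, so the frequency axis is calibrated to span
[0, fs/2) and a pure tone at f0 produces a ridge reading f0). For a *real*
input the lag kernel is undersampled, so a mirror (alias) image of every
component appears reflected about half the Nyquist frequency; the energy
windows below stop at 300 Hz, and both numerator and denominator windows
see the same aliasing, which cancels in the normalized indices.

Three mean-square window energies are computed on the TFR matrix over the
55-300 Hz band:

* E_VLP  : t in [J - 55 ms, J + 25 ms]   (around the J point)
* E_END  : t in [QRSoff, QRSoff + 80 ms] (independent of the J location)
* E_QRS  : t in [R peak, QRSoff]         (normalization)

each divided by its pixel count k. The indices EN = E_VLP / E_QRS and
EN_END = E_END / E_QRS are amplitude-scale invariant; late potentials lower
EN and raise EN_END, and the bivariable rule "positive iff
EN_END > EN / 10" separates the two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import FiducialError, VlpError
from .fiducials import VectorMagnitude


@dataclass
class TfrMatrix:
    """Discrete time-frequency energy matrix with calibrated axes.

    ``values`` is (n_times, n_freqs); ``t_axis`` holds absolute sample
    indices (so fiducials can be mapped straight into the matrix) and
    ``f_axis`` is in Hz up to fs/2.
    """

    values: np.ndarray
    t_axis: np.ndarray
    f_axis: np.ndarray
    fs: float
    method: str = "wvd"


@dataclass
class EnergyWindow:
    """Rectangular region of the TFR: samples [t_min, t_max] x Hz [f_min, f_max]."""

    t_min: int
    t_max: int
    f_min: float
    f_max: float

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise VlpError("t_min must precede t_max")
        if not self.f_min < self.f_max:
            raise VlpError("f_min must be below f_max")


@dataclass
class TfIndices:
    e_vlp: float
    e_end: float
    e_qrs: float
    en: float
    en_end: float


def wigner_ville(
    x: np.ndarray,
    fs: float,
    n_freq: int = 256,
    t_start: int = 0,
    t_stop: int | None = None,
    t_offset: int = 0,
    analytic: bool = False,
) -> TfrMatrix:
    """Discrete WVD of a single-lead signal.

    For each output time t the two-sided lag kernel r[k] = x[t+k] x*[t-k],
    |k| < n_freq, is Fourier-transformed; the real part is retained. Values
    are scaled so the time marginal holds exactly:
    sum_f WVD(t, f) * df = |x(t)|^2  with  df = fs / (2 n_freq).

    ``t_start``/``t_stop`` restrict the computed columns (the kernel still
    uses all samples); ``t_offset`` shifts the reported t_axis so it can
    carry absolute record coordinates. ``analytic=True`` transforms the
    analytic signal instead of the real one, suppressing the alias image.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise VlpError("empty signal")
    if analytic:
        xa = sps.hilbert(x)
    else:
        xa = x
    N = len(x)
    t_stop = N if t_stop is None else min(t_stop, N)
    times = np.arange(t_start, t_stop)
    K = n_freq
    k = np.arange(K)
    i1 = times[:, None] + k[None, :]
    i2 = times[:, None] - k[None, :]
    valid = (i1 < N) & (i2 >= 0)
    r = np.zeros((len(times), K), dtype=complex if analytic else float)
    r[valid] = xa[i1[valid]] * np.conj(xa[i2[valid]]) if analytic else xa[i1[valid]] * xa[i2[valid]]
    # two-sided even lag extension: W = 2 Re{FFT(r)} - r[0]
    W = 2.0 * np.real(np.fft.fft(r, axis=1)) - np.real(r[:, [0]])
    W *= 2.0 / fs  # calibrates the time marginal, df = fs / (2K)
    f_axis = np.arange(K) * fs / (2.0 * K)
    return TfrMatrix(values=W, t_axis=times + t_offset, f_axis=f_axis, fs=fs)


def default_vlp_window(
    vm: VectorMagnitude,
    pre_ms: float = 55.0,
    post_ms: float = 25.0,
    f_min: float = 55.0,
    f_max: float = 300.0,
) -> EnergyWindow:
    """The J-point-centred VLP search window: [J-55, J+25] ms x [55, 300] Hz."""
    if vm.j_point is None:
        raise FiducialError("j_point must be set")
    ms = vm.fs / 1000.0
    return EnergyWindow(
        t_min=int(round(vm.j_point - pre_ms * ms)),
        t_max=int(round(vm.j_point + post_ms * ms)),
        f_min=f_min,
        f_max=f_max,
    )


def window_energy(tfr: TfrMatrix, w: EnergyWindow) -> float:
    """Mean of TFR^2 over the window (sum normalized by the pixel count k).

    Windows partially outside the matrix are clipped with a warning; a
    window that clips to nothing is an error.
    """
    rows = (tfr.t_axis >= w.t_min) & (tfr.t_axis <= w.t_max)
    cols = (tfr.f_axis >= w.f_min) & (tfr.f_axis <= w.f_max)
    if rows.sum() == 0 or cols.sum() == 0:
        raise VlpError("energy window is empty after clipping")
    inside = (w.t_min >= tfr.t_axis[0]) and (w.t_max <= tfr.t_axis[-1])
    if not inside:
        warnings.warn("energy window clipped to the TFR bounds", stacklevel=2)
    block = tfr.values[np.ix_(rows, cols)]
    return float(np.mean(block**2))


def compute_en_indices(
    tfr: TfrMatrix,
    vm: VectorMagnitude,
    pre_ms: float = 55.0,
    post_ms: float = 25.0,
    f_min: float = 55.0,
    f_max: float = 300.0,
    end_span_ms: float = 80.0,
) -> TfIndices:
    """EN = E_VLP / E_QRS and EN_END = E_END / E_QRS from the three windows."""
    if vm.r_peak is None or vm.j_point is None or vm.qrs_off is None:
        raise FiducialError("r_peak, j_point and qrs_off must all be set")
    ms = vm.fs / 1000.0
    w_vlp = default_vlp_window(vm, pre_ms, post_ms, f_min, f_max)
    w_end = EnergyWindow(
        t_min=int(vm.qrs_off),
        t_max=int(round(vm.qrs_off + end_span_ms * ms)),
        f_min=f_min,
        f_max=f_max,
    )
    w_qrs = EnergyWindow(t_min=int(vm.r_peak), t_max=int(vm.qrs_off), f_min=f_min, f_max=f_max)
    e_vlp = window_energy(tfr, w_vlp)
    e_end = window_energy(tfr, w_end)
    e_qrs = window_energy(tfr, w_qrs)
    if e_qrs == 0:
        raise VlpError("E_QRS is zero; cannot normalize")
    return TfIndices(e_vlp=e_vlp, e_end=e_end, e_qrs=e_qrs, en=e_vlp / e_qrs, en_end=e_end / e_qrs)


def classify_tf(idx: TfIndices, slope: float = 0.1) -> bool:
    """Bivariable rule: positive iff the point (EN, EN_END) lies strictly
    above the separation line EN_END = slope * EN (ties are negative)."""
    return bool(idx.en_end > slope * idx.en)
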