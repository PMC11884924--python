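"""Time- and frequency-domain HRV indices for short RR segments.

Frequency-domain chain: cubic-spline resampling to a uniform 4 Hz grid,
smoothness-priors detrending, autoregressive model fit by the Burg lattice
recursion (default order 19), one-sided AR power spectral density, and
trapezoidal band powers over TP [0.04, 0.4], LF [0.04, 0.15] and
HF [0.15, 0.4] Hz.  Time-domain indices (mRRI, SDNN) come straight from the
NN intervals before any resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import spsolve

from .ecg_rr import RRISeries

__all__ = [
    "UniformSeries",
    "ARModel",
    "PSDEstimate",
    "BandDefinition",
    "HRVIndices",
    "INDEX_NAMES",
    "time_domain_indices",
    "resample_cubic_spline",
    "detrend_smoothness_priors",
    "burg_fit",
    "ar_psd",
    "band_power",
    "frequency_domain_indices",
    "compute_indices",
]

INDEX_NAMES = ("mRRI", "SDNN", "TP", "LF", "HF", "nLF", "nHF", "LF_HF")


@dataclass
class UniformSeries:
    """Uniformly resampled RR values (ms)."""

    values: np.ndarray
    sampling_rate: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sampling_rate


@dataclass
class ARModel:
    """All-pole model: x_t + a_1 x_{t-1} + ... + a_p x_{t-p} = e_t."""

    coefficients: np.ndarray  # a_1 .. a_p
    innovation_variance: float  # ms^2
    reflection_coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def order(self) -> int:
        return int(np.asarray(self.coefficients).size)


@dataclass
class PSDEstimate:
    """One-sided spectral density on a uniform grid over (0, fs/2]."""

    frequencies: np.ndarray  # Hz
    density: np.ndarray  # ms^2/Hz

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)


@dataclass(frozen=True)
class BandDefinition:
    """Analysis bands in Hz; LF and HF partition the total-power range."""

    tp: tuple[float, float] = (0.04, 0.4)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not (self.lf[0] == self.tp[0] and self.hf[1] == self.tp[1] and self.lf[1] == self.hf[0]):
            raise ValueError("LF and HF must partition the TP range")


@dataclass
class HRVIndices:
    mRRI: float  # ms
    SDNN: float  # ms
    TP: float  # ms^2
    LF: float  # ms^2
    HF: float  # ms^2
    nLF: float  # percent
    nHF: float  # percent
    LF_HF: float  # ratio; NaN when HF == 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


# ---------------------------------------------------------------------------


def time_domain_indices(rr: RRISeries) -> tuple[float, float]:
    """mRRI (arithmetic mean, ms) and SDNN (sample SD, n-1 denominator, ms)."""
    nn = rr.nn_intervals()
    if nn.size < 2:
        raise ValueError("time-domain indices need at least 2 normal intervals")
    return float(np.mean(nn)), float(np.std(nn, ddof=1))


def resample_cubic_spline(
    rr: RRISeries,
    fs: float = 4.0,
    start: float | None = None,
    end: float | None = None,
) -> UniformSeries:
    """Cubic spline through (beat time, interval) evaluated on a uniform grid.

    Interval *i* is anchored at the time of its closing beat.  The grid spans
    ``[start, end]`` (defaulting to the anchored range) clipped so that no
    extrapolation occurs; for a 180 s window at 4 Hz this yields 720 samples.
    """
    if len(rr) < 4:
        raise ValueError("resampling requires at least 4 intervals")
    x = rr.beat_times[1:]
    y = rr.intervals
    if x[-1] - x[0] < 30.0:
        raise ValueError("segment must span at least 30 s")
    t0 = x[0] if start is None else max(start, x[0])
    t1 = x[-1] if end is None else min(end, x[-1])
    n = int(np.floor((t1 - t0) * fs))
    if n < 2:
        raise ValueError("resampling grid would be empty")
    grid = t0 + np.arange(n) / fs
    spline = CubicSpline(x, y)
    return UniformSeries(values=spline(grid), sampling_rate=fs, start_time=t0)


def detrend_smoothness_priors(x: UniformSeries, lam: float = 500.0) -> UniformSeries:
    """Remove the slow trend with a smoothness-priors high-pass.

    Output is ``x - (I + lam^2 D2' D2)^{-1} x`` with D2 the second-difference
    operator; ``lam = 0`` returns an identically zero series (the smoother is
    then the identity).  At 4 Hz the default ``lam = 500`` has its cutoff
    near 0.035 Hz, below the 0.04 Hz analysis floor.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    n = len(x)
    if n < 3:
        raise ValueError("detrending requires at least 3 samples")
    if lam == 0:
        return UniformSeries(np.zeros(n), x.sampling_rate, x.start_time)
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )
    a = sparse.eye_array(n, format="csc") + (lam**2) * (d2.T @ d2)
    trend = spsolve(a, x.values)
    return UniformSeries(x.values - trend, x.sampling_rate, x.start_time)


def burg_fit(x: UniformSeries | np.ndarray, order: int = 19) -> ARModel:
    """Fit an AR model by the Burg lattice recursion.

    At each stage the reflection coefficient minimizes the summed forward
    plus backward prediction-error power; the innovation variance is the
    final prediction-error power.
    """
    data = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    n = data.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples for order {order}")
    if np.ptp(data) == 0:
        raise ValueError("degenerate (constant) input: AR model undefined")

    e = float(np.dot(data, data) / n)
    a = np.array([1.0])
    refl = np.empty(order)
    f = data[1:].astype(float)  # forward prediction errors
    b = data[:-1].astype(float)  # backward prediction errors
    for m in range(order):
        den = float(np.dot(f, f) + np.dot(b, b))
        if den <= 0:
            raise ValueError("prediction-error power vanished; reduce the order")
        k = -2.0 * float(np.dot(f, b)) / den
        refl[m] = k
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        e *= 1.0 - k * k
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return ARModel(coefficients=a[1:], innovation_variance=e, reflection_coefficients=refl)


def ar_psd(model: ARModel, fs: float, n_freqs: int = 4096) -> PSDEstimate:
    """One-sided AR spectral density on an ``n_freqs`` grid over (0, fs/2].

    P(f) = 2 sigma^2 / (fs |1 + sum_k a_k e^{-i 2 pi k f / fs}|^2); its
    integral over (0, fs/2] recovers the modelled process variance.
    """
    freqs = np.linspace(0.0, fs / 2.0, n_freqs + 1)[1:]
    a_full = np.concatenate([[1.0], np.asarray(model.coefficients, dtype=float)])
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(a_full.size)) / fs)
    denom = np.abs(z @ a_full) ** 2
    density = 2.0 * model.innovation_variance / (fs * denom)
    return PSDEstimate(frequencies=freqs, density=density)


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the density over [f_lo, f_hi].

    Band edges are linearly interpolated onto the grid, so powers over
    adjacent bands add exactly to the power over their union.
    """
    f_lo, f_hi = band
    if f_hi <= f_lo:
        raise ValueError(f"inverted band {band}")
    f = psd.frequencies
    p = psd.density
    if f_lo < f[0] or f_hi > f[-1]:
        raise ValueError(f"band {band} outside the PSD grid [{f[0]}, {f[-1]}]")
    inside = (f > f_lo) & (f < f_hi)
    fi = np.concatenate([[f_lo], f[inside], [f_hi]])
    pi = np.concatenate([[np.interp(f_lo, f, p)], p[inside], [np.interp(f_hi, f, p)]])
    return float(np.trapezoid(pi, fi))


def frequency_domain_indices(
    rr: RRISeries,
    fs: float = 4.0,
    ar_order: int = 19,
    lam: float = 500.0,
    bands: BandDefinition = BandDefinition(),
    n_freqs: int = 4096,
    start: float | None = None,
    end: float | None = None,
) -> dict[str, float]:
    """TP, LF, HF, nLF, nHF, LF/HF for one usable segment.

    Full chain: resample -> detrend -> Burg AR -> PSD -> band powers.
    ``nHF`` is computed as ``100 - nLF`` so the normalization identity is
    exact; a zero HF power yields a missing (NaN) LF/HF, never infinity.
    """
    uniform = resample_cubic_spline(rr, fs=fs, start=start, end=end)
    detrended = detrend_smoothness_priors(uniform, lam=lam)
    model = burg_fit(detrended, order=ar_order)
    psd = ar_psd(model, fs=fs, n_freqs=n_freqs)
    tp = band_power(psd, bands.tp)
    lf = band_power(psd, bands.lf)
    hf = band_power(psd, bands.hf)
    if lf + hf > 0:
        nlf = 100.0 * lf / (lf + hf)
        nhf = 100.0 - nlf
    else:
        nlf = nhf = np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return {"TP": tp, "LF": lf, "HF": hf, "nLF": nlf, "nHF": nhf, "LF_HF": lf_hf}


def compute_indices(
    rr: RRISeries,
    fs: float = 4.0,
    ar_order: int = 19,
    lam: float = 500.0,
    bands: BandDefinition = BandDefinition(),
    start: float | None = None,
    end: float | None = None,
) -> HRVIndices:
    """All eight indices for one segment."""
    mrri, sdnn = time_domain_indices(rr)
    fd = frequency_domain_indices(
        rr, fs=fs, ar_order=ar_order, lam=lam, bands=bands, start=start, end=end
    )
    return HRVIndices(mRRI=mrri, SDNN=sdnn, **fd)
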