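"""PC1 reduction and acceleration power spectra of a triaxial epoch.

A tremor oscillation at the wrist is close to uniaxial within one posture, so
the triaxial signal is reduced to its first principal component (PC1): the
unit direction of maximal acceleration variance.  The PC1 projection feeds a
Welch power spectral density, from which the tremor metrics are read:

* peak frequency — grid frequency of the PSD maximum inside the metric band;
* peak power — the PSD value there (m²/s⁴/Hz);
* total power — trapezoidal integral of the PSD over the band (m²/s⁴),
  by default 1–20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataError

#: Metric band over which tremor power is integrated, Hz.
DEFAULT_BAND = (1.0, 20.0)


@dataclass(frozen=True)
class PCAResult:
    """First principal component of a demeaned triaxial epoch."""

    component_series: np.ndarray  # (N,) projection onto the loading, m/s²
    loading: np.ndarray  # unit 3-vector
    variance_fraction: float  # lambda_1 / sum(lambda)
    eigenvalues: np.ndarray  # 3 nonnegative values, descending


@dataclass(frozen=True)
class EstimatorMeta:
    window: str
    segment_s: float
    overlap: float
    n_segments: int


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided acceleration PSD on a uniform frequency grid."""

    frequencies: np.ndarray  # Hz, ascending, uniform step
    psd: np.ndarray  # m²/s⁴/Hz, >= 0
    delta_f: float
    estimator_meta: EstimatorMeta


@dataclass(frozen=True)
class TremorMetrics:
    """Scalar tremor measures read from one spectrum."""

    peak_frequency_hz: float
    peak_power: float  # m²/s⁴/Hz
    total_power: float  # m²/s⁴ over `band`
    band: tuple[float, float] = DEFAULT_BAND
    pc1_variance_fraction: float = float("nan")


def pca_first_component(xyz: np.ndarray) -> PCAResult:
    """Project a demeaned (N, 3) epoch onto its first principal axis.

    Computed from the SVD of the demeaned data matrix; the loading is the
    eigenvector of the 3x3 sample covariance with the largest eigenvalue.
    Sign convention: the first loading entry with magnitude > 1e-12 is made
    positive, so results are deterministic.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise DataError(f"expected an (N, 3) epoch, got shape {xyz.shape}")
    n = xyz.shape[0]
    if n < 4:
        raise DataError(f"epoch too short for PCA ({n} < 4 samples)")
    centered = xyz - xyz.mean(axis=0)
    if not np.any(centered):
        raise DataError("all-zero epoch: PCA is degenerate")

    # Covariance eigendecomposition via SVD of the data matrix:
    # eigenvalues of cov (ddof=1) are s**2 / (n - 1).
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = np.zeros(3)
    eigvals[: s.size] = s**2 / (n - 1)
    loading = vt[0]
    nz = np.flatnonzero(np.abs(loading) > 1e-12)
    if nz.size and loading[nz[0]] < 0:
        loading = -loading
    total = eigvals.sum()
    return PCAResult(
        component_series=centered @ loading,
        loading=loading,
        variance_fraction=float(eigvals[0] / total),
        eigenvalues=eigvals,
    )


def power_spectrum(
    x: np.ndarray,
    sample_rate: float,
    segment_s: float = 10.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectrumEstimate:
    """Welch one-sided PSD with mean averaging.

    Density normalisation: the integral of the PSD over all frequencies
    equals the signal's sample variance (Parseval, within windowing
    tolerance).  Frequency resolution is ``1 / segment_s`` (0.1 Hz for the
    default 10 s segments, about 5 averaged segments per 28 s trimmed
    epoch at 50% overlap).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError("power_spectrum expects a 1-D signal")
    if not (0 <= overlap < 1):
        raise ConfigurationError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(segment_s * sample_rate))
    if x.size < nperseg:
        raise DataError(
            f"signal of {x.size} samples is shorter than one {nperseg}-sample "
            f"({segment_s} s) estimator segment"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        x,
        fs=sample_rate,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        average="mean",
    )
    n_segments = 1 + (x.size - nperseg) // (nperseg - noverlap)
    return SpectrumEstimate(
        frequencies=freqs,
        psd=psd,
        delta_f=float(freqs[1] - freqs[0]),
        estimator_meta=EstimatorMeta(
            window=window,
            segment_s=segment_s,
            overlap=overlap,
            n_segments=n_segments,
        ),
    )


def band_metrics(
    spectrum: SpectrumEstimate,
    band: tuple[float, float] = DEFAULT_BAND,
    pc1_fraction: float = float("nan"),
) -> TremorMetrics:
    """Peak frequency/power and total band power from a spectrum.

    The peak search is restricted to the metric band so sub-band voluntary
    movement cannot masquerade as tremor; PSD ties resolve to the lowest
    frequency.  Total power is the trapezoidal integral over the band.
    """
    lo, hi = band
    f = spectrum.frequencies
    if lo < f[0] or hi > f[-1] or lo >= hi:
        raise ConfigurationError(
            f"band {band} Hz outside the spectrum grid [{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    fb, pb = f[mask], spectrum.psd[mask]
    i_peak = int(np.argmax(pb))  # argmax returns the first (lowest-f) maximum
    total = float(np.trapezoid(pb, fb))
    return TremorMetrics(
        peak_frequency_hz=float(fb[i_peak]),
        peak_power=float(pb[i_peak]),
        total_power=total,
        band=(float(lo), float(hi)),
        pc1_variance_fraction=float(pc1_fraction),
    )


def average_spectra(spectra: list[SpectrumEstimate]) -> SpectrumEstimate:
    """Pointwise arithmetic mean of PSDs sharing one frequency grid."""
    if not spectra:
        raise DataError("cannot average an empty list of spectra")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.frequencies.shape != ref.frequencies.shape or not np.allclose(
            s.frequencies, ref.frequencies
        ):
            raise ConfigurationError(
                "mismatched frequency grids: "
                f"delta_f/ranges {s.delta_f}/[{s.frequencies[0]}, "
                f"{s.frequencies[-1]}] vs {ref.delta_f}/[{ref.frequencies[0]}, "
                f"{ref.frequencies[-1]}]"
            )
    mean_psd = np.mean([s.psd for s in spectra], axis=0)
    return replace(
        ref,
        psd=mean_psd,
        estimator_meta=replace(ref.estimator_meta, n_segments=len(spectra)),
    )
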