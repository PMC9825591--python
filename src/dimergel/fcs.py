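"""Fluorescence correlation spectroscopy: correlators, model fits, calibration.

An intensity time trace (photon counts per bin) is condensed into a normalized
autocorrelation curve G(tau) with a multi-tau lag ladder, then fitted with the
one-species 3D-Gaussian free-diffusion model

    G(tau) = G0 / [ (1 + tau/tau_D) * sqrt(1 + (w_xy/w_z)^2 * tau/tau_D) ] + c0

without triplet or photophysical terms.  The diffusion coefficient follows from the
characteristic dwell time as D = w_xy^2 / (4 tau_D), and the amplitude G0 is the
inverse mean occupancy of the effective detection volume V_eff = pi^{3/2} w_xy^2 w_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AVOGADRO",
    "IntensityTrace",
    "CorrelationCurve",
    "FcsFit",
    "DetectionVolume",
    "FcsFitError",
    "default_detection_volume",
    "multitau_autocorrelation",
    "direct_autocorrelation",
    "autocorrelation_model",
    "fit_autocorrelation",
    "measure_diffusion",
    "diffusion_from_fit",
    "calibrate_detection_volume",
    "normalize_by_G0",
]

AVOGADRO = 6.02214076e23

#: Default axial-to-lateral aspect ratio of the confocal volume (not fitted).
DEFAULT_KAPPA = 5.0
#: Measured effective detection volume, femtoliters (1 fL == 1 um^3).
DEFAULT_VEFF_FL = 0.58


class FcsFitError(RuntimeError):
    """Raised when an autocorrelation fit cannot be performed or fails to converge."""


@dataclass(frozen=True)
class IntensityTrace:
    """Photon counts per time bin."""

    bin_width: float  # seconds
    counts: np.ndarray  # non-negative integers
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D sequence of length >= 2")
        if np.any(counts < 0):
            raise ValueError("photon counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def duration(self) -> float:
        return self.bin_width * len(self.counts)

    @property
    def mean_rate(self) -> float:
        """Mean count rate, photons/s."""
        return float(self.counts.mean() / self.bin_width)


@dataclass(frozen=True)
class CorrelationCurve:
    """Normalized intensity autocorrelation on a quasi-logarithmic lag ladder."""

    lags: np.ndarray  # seconds, strictly increasing
    G: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self):
        lags = np.asarray(self.lags, float)
        G = np.asarray(self.G, float)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not (np.all(np.isfinite(lags)) and np.all(np.isfinite(G))):
            raise ValueError("correlation curve must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", G)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, float))


@dataclass(frozen=True)
class DetectionVolume:
    """Confocal detection volume: 1/e^2 radii (um) and effective volume (fL)."""

    w_xy: float
    w_z: float

    def __post_init__(self):
        if self.w_xy <= 0 or self.w_z <= self.w_xy:
            raise ValueError("need 0 < w_xy < w_z")

    @property
    def kappa(self) -> float:
        return self.w_z / self.w_xy

    @property
    def V_eff_fl(self) -> float:
        """Effective volume pi^{3/2} w_xy^2 w_z in fL (= um^3)."""
        return math.pi**1.5 * self.w_xy**2 * self.w_z

    @property
    def V_eff_liters(self) -> float:
        return self.V_eff_fl * 1e-15


def default_detection_volume(
    V_eff_fl: float = DEFAULT_VEFF_FL, kappa: float = DEFAULT_KAPPA
) -> DetectionVolume:
    """Detection volume from a calibrated V_eff (fL) and aspect ratio kappa."""
    w_xy = (V_eff_fl / (math.pi**1.5 * kappa)) ** (1.0 / 3.0)
    return DetectionVolume(w_xy=w_xy, w_z=kappa * w_xy)


@dataclass(frozen=True)
class FcsFit:
    """Fitted one-species autocorrelation model."""

    G0: float
    tau_D: float  # seconds
    c0: float
    kappa: float
    covariance: np.ndarray  # 3x3 for (G0, tau_D, c0)

    def __post_init__(self):
        if self.G0 <= 0 or self.tau_D <= 0:
            raise ValueError("G0 and tau_D must be positive")

    @property
    def stderr(self) -> tuple[float, float, float]:
        """68% (1-sigma) parameter uncertainties from the covariance."""
        return tuple(np.sqrt(np.diag(self.covariance)))


# ---------------------------------------------------------------------------
# Correlators
# ---------------------------------------------------------------------------

def _correlate_at_lag(x: np.ndarray, j: int) -> float:
    """Symmetric-normalization autocorrelation of x at integer lag j.

    Means are taken over the overlapping segments, which removes the leading-order
    bias from slow drifts and finite trace length.
    """
    a = x[:-j] if j else x
    b = x[j:] if j else x
    if len(a) == 0:
        raise ValueError("lag exceeds trace length")
    ma, mb = a.mean(), b.mean()
    if ma == 0.0 or mb == 0.0:
        raise ZeroDivisionError("trace mean is zero over a correlation segment")
    return float(np.dot(a, b) / len(a) / (ma * mb) - 1.0)


def _lag_ladder(n: int, m: int, max_lag_bins: int) -> list[tuple[int, int]]:
    """Multi-tau lag ladder as (lag_in_base_bins, bin_factor) pairs.

    Stage 0 holds ``m`` linear lags at base resolution; each subsequent stage doubles
    the bin width and contributes ``m // 2`` lags.
    """
    ladder = [(j, 1) for j in range(1, m + 1)]
    factor = 2
    while True:
        lags = [j * factor for j in range(m // 2 + 1, m + 1)]
        if lags[0] > max_lag_bins or n // factor < 2 * m:
            break
        ladder.extend((j, factor) for j in lags if j <= max_lag_bins)
        factor *= 2
    return ladder


def _bin_trace(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).sum(axis=1)


def multitau_autocorrelation(
    trace: IntensityTrace,
    m: int = 16,
    max_lag: float | None = None,
    n_segments: int = 10,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon-count trace.

    ``m`` linear lags at base resolution, then stages of ``m/2`` lags with bin width
    doubled at each stage, up to ``max_lag`` (default: a tenth of the trace).  Per-lag
    standard errors are estimated by correlating ``n_segments`` contiguous
    sub-traces independently; pass ``n_segments=0`` to skip them.
    """
    x = trace.counts.astype(float)
    if len(x) < 4 * m:
        raise ValueError(f"trace too short for m={m} (need >= {4 * m} bins)")
    if x.mean() == 0.0:
        raise ZeroDivisionError("zero-mean trace cannot be normalized")
    if max_lag is None:
        max_lag = trace.duration / 10.0
    max_lag_bins = max(1, int(max_lag / trace.bin_width))
    ladder = _lag_ladder(len(x), m, max_lag_bins)

    def correlate(xs: np.ndarray) -> np.ndarray:
        binned = {1: xs}
        out = np.empty(len(ladder))
        for i, (lag, factor) in enumerate(ladder):
            if factor not in binned:
                binned[factor] = _bin_trace(xs, factor)
            xb = binned[factor]
            j = lag // factor
            # Lags longer than half the (sub-)trace are too noisy to estimate.
            out[i] = _correlate_at_lag(xb, j) if j < len(xb) // 2 else np.nan
        return out

    G = correlate(x)
    keep = np.isfinite(G)
    lags = np.array([lag * trace.bin_width for lag, _ in ladder])

    sem = None
    if n_segments and len(x) // n_segments >= 4 * m:
        seg_len = len(x) // n_segments
        segs = []
        for k in range(n_segments):
            seg = x[k * seg_len : (k + 1) * seg_len]
            if seg.mean() > 0:
                try:
                    segs.append(correlate(seg))
                except ZeroDivisionError:
                    continue
        if len(segs) >= 3:
            segs = np.array(segs)
            import warnings

            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sem = np.nanstd(segs, axis=0, ddof=1) / np.sqrt(
                    np.sum(np.isfinite(segs), axis=0).clip(1)
                )
            # Long lags unavailable in the sub-traces inherit the largest
            # estimated uncertainty (conservative down-weighting).
            bad = ~np.isfinite(sem) | (sem <= 0)
            if np.all(bad):
                sem = None
            else:
                sem[bad] = np.nanmax(sem[~bad])
        if sem is not None:
            sem = sem[keep]
    return CorrelationCurve(lags=lags[keep], G=G[keep], sem=sem)


def direct_autocorrelation(trace: IntensityTrace, lags_s: np.ndarray) -> CorrelationCurve:
    """Reference correlator: naive evaluation at the requested lags.

    For lags that are not an integral number of base bins apart from the multi-tau
    grid this simply rounds to the nearest bin.  Intended as the independent oracle
    for :func:`multitau_autocorrelation` on short traces (cost O(N * n_lags)).
    """
    x = trace.counts.astype(float)
    G = np.empty(len(lags_s))
    for i, tau in enumerate(np.asarray(lags_s, float)):
        j = int(round(tau / trace.bin_width))
        G[i] = _correlate_at_lag(x, j)
    return CorrelationCurve(lags=np.asarray(lags_s, float), G=G)


def direct_autocorrelation_binned(
    trace: IntensityTrace, ladder: list[tuple[int, int]]
) -> np.ndarray:
    """Oracle matching the multi-tau estimator exactly: same binning, naive loops."""
    x = trace.counts.astype(float)
    out = np.empty(len(ladder))
    for i, (lag, factor) in enumerate(ladder):
        xb = _bin_trace(x, factor)
        j = lag // factor
        n = len(xb) - j
        a, b = xb[:n], xb[j:]
        s = 0.0
        for k in range(n):  # deliberately naive
            s += a[k] * b[k]
        out[i] = s / n / (a.mean() * b.mean()) - 1.0
    return out


# ---------------------------------------------------------------------------
# Model and fitting
# ---------------------------------------------------------------------------

def autocorrelation_model(tau, G0, tau_D, c0, kappa=DEFAULT_KAPPA):
    """One-species 3D-Gaussian diffusion autocorrelation."""
    tau = np.asarray(tau, float)
    return G0 / ((1.0 + tau / tau_D) * np.sqrt(1.0 + (tau / tau_D) / kappa**2)) + c0


def fit_autocorrelation(
    curve: CorrelationCurve,
    kappa: float = DEFAULT_KAPPA,
    p0: tuple[float, float, float] | None = None,
) -> FcsFit:
    """Weighted least-squares fit of the one-species model to a correlation curve.

    Weights are the per-lag standard errors when available (zero/missing sems fall
    back to unweighted).  kappa is held fixed: it is poorly constrained by a single
    curve and is a property of the instrument, not the sample.
    """
    lags, G = curve.lags, curve.G
    if len(lags) < 10 or lags[-1] / lags[0] < 100.0:
        raise FcsFitError("need >= 10 lags spanning at least two decades")
    if float(np.max(np.abs(G))) < 1e-9:
        raise FcsFitError("correlation curve is flat: no intensity fluctuations to fit")
    if p0 is None:
        G0_0 = max(float(np.max(G[:4])), 1e-3)
        half = G0_0 / 2.0
        below = np.nonzero(G < half)[0]
        tau0 = float(lags[below[0]]) if len(below) else float(np.sqrt(lags[0] * lags[-1]))
        p0 = (G0_0, tau0, 0.0)
    sigma = None
    if curve.sem is not None and np.all(curve.sem > 0):
        sigma = curve.sem
    try:
        popt, pcov = curve_fit(
            lambda t, G0, tau_D, c0: autocorrelation_model(t, G0, tau_D, c0, kappa),
            lags,
            G,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, lags[0] / 100.0, -np.inf], [np.inf, lags[-1] * 100.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise FcsFitError(f"autocorrelation fit did not converge: {err}") from err
    if not np.all(np.isfinite(popt)):
        raise FcsFitError("autocorrelation fit returned non-finite parameters")
    return FcsFit(G0=float(popt[0]), tau_D=float(popt[1]), c0=float(popt[2]),
                  kappa=kappa, covariance=pcov)


def measure_diffusion(
    trace: IntensityTrace,
    detection: DetectionVolume | None = None,
    kappa: float = DEFAULT_KAPPA,
    m: int = 16,
    window_tau_mult: float = 100.0,
    weighted: bool = False,
) -> tuple[FcsFit, float]:
    """Full single-trace pipeline: correlate, fit, convert to D (um^2/s).

    A two-pass fit is used: after an initial fit over the whole lag ladder, the fit
    is repeated restricted to lags <= ``window_tau_mult`` x tau_D, which removes the
    influence of the noise-dominated long-lag baseline on the dwell time.  The fit
    is unweighted by default: per-lag errors estimated from ten trace segments are
    too noisy to help and were found to amplify outliers (see the methods note);
    ``weighted=True`` restores segment-sem weighting.
    """
    if detection is None:
        detection = default_detection_volume(kappa=kappa)
    curve = multitau_autocorrelation(trace, m=m, n_segments=10 if weighted else 0)
    if not weighted and curve.sem is not None:
        curve = CorrelationCurve(curve.lags, curve.G, None)
    fit = fit_autocorrelation(curve, kappa=kappa)
    if window_tau_mult:
        keep = curve.lags <= window_tau_mult * fit.tau_D
        if keep.sum() >= 10 and curve.lags[keep][-1] / curve.lags[0] >= 100.0:
            windowed = CorrelationCurve(
                curve.lags[keep],
                curve.G[keep],
                None if curve.sem is None else curve.sem[keep],
            )
            fit = fit_autocorrelation(windowed, kappa=kappa)
    return fit, diffusion_from_fit(fit, detection)


def diffusion_from_fit(fit: FcsFit, dv: DetectionVolume) -> float:
    """Diffusion coefficient D = w_xy^2 / (4 tau_D), um^2/s."""
    return dv.w_xy**2 / (4.0 * fit.tau_D)


def calibrate_detection_volume(
    series: list[tuple[float, float]], kappa: float = DEFAULT_KAPPA
) -> tuple[DetectionVolume, bool]:
    """Detection volume from a dilution series of (concentration_nM, fitted G0).

    Mean occupancy N = 1/G0 scales as N = c * N_A * V_eff; V_eff is regressed
    through the origin across the series.  Returns the volume and a consistency
    flag (True when the per-point V_eff spread exceeds 25% relative).
    """
    if len(series) < 3:
        raise ValueError("calibration needs at least three concentrations")
    c = np.array([s[0] for s in series]) * 1e-9  # mol/L
    G0 = np.array([s[1] for s in series])
    if np.any(c <= 0) or np.any(G0 <= 0):
        raise ValueError("concentrations and G0 must be positive")
    N = 1.0 / G0
    V_each = N / (AVOGADRO * c)  # liters
    V_eff = float(np.dot(c, N) / np.dot(c, c) / AVOGADRO)
    inconsistent = bool((V_each.max() - V_each.min()) / V_each.mean() > 0.25)
    return default_detection_volume(V_eff * 1e15, kappa), inconsistent


def normalize_by_G0(curve: CorrelationCurve, fit: FcsFit) -> CorrelationCurve:
    """Amplitude-normalized curve G' = (G - c0)/G0, so G' -> 1 as tau -> 0."""
    sem = None if curve.sem is None else curve.sem / fit.G0
    return CorrelationCurve(lags=curve.lags, G=(curve.G - fit.c0) / fit.G0, sem=sem)
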