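"""Thermotropic analysis: bilinear spectral decomposition, sigmoid fitting,
DSC feature extraction, FTIR-style preprocessing and fluctuation mechanics.

The bilinear model factors an absorbance matrix D (wavelength x temperature)
into concentration-domain profiles C (temperature x k), spectral profiles S
(wavelength x k) and a residual E, with D = S C^T + E.  Melting profiles are
fitted with sums of Boltzmann sigmoids

    y(T) = y0 + sum_i a_i / (1 + exp((T_i - T) / w_i))

whose centers T_i are the inflection temperatures reported as transition
temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import FitError, ParseError
from .units import R_KJ_PER_MOL_K

__all__ = [
    "SpectraMatrix",
    "MeltingFit",
    "Thermogram",
    "FluctuationSeries",
    "MechanicalEstimates",
    "smooth_sg",
    "baseline_correct",
    "mca_decompose",
    "boltzmann_profile",
    "fit_boltzmann",
    "dsc_features",
    "band_maxima",
    "heat_capacity_fluct",
    "area_compressibility",
    "bending_modulus",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectraMatrix:
    """Wavelength x temperature absorbance matrix with optional factors."""

    wavelengths: np.ndarray  # nm, length n_w
    temperatures: np.ndarray  # degC, length n_t
    absorbance: np.ndarray  # (n_w, n_t)
    C: np.ndarray | None = None  # (n_t, k) temperature-domain profiles
    S: np.ndarray | None = None  # (n_w, k) wavelength-domain profiles
    E: np.ndarray | None = None  # (n_w, n_t) residual
    explained_variance: float | None = None
    truth: dict = field(default_factory=dict)  # generator ground truth, if any

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.wavelengths), len(self.temperatures)):
            raise ParseError("absorbance matrix shape does not match grids")


@dataclass
class MeltingFit:
    """Result of a single/double Boltzmann fit of a melting profile."""

    model: str  # 'single' or 'double'
    centers: np.ndarray  # degC, sorted ascending for double
    widths: np.ndarray
    amplitudes: np.ndarray
    offset: float
    center_se: np.ndarray
    r_squared: float
    chi_squared: float  # raw sum of squared residuals
    chi_squared_reduced: float
    resolved: bool = True  # False when double-fit centers are unresolved

    @property
    def t_m(self) -> float:
        return float(self.centers[0]) if self.model == "single" else float(self.centers[-1])


@dataclass
class Thermogram:
    """DSC trace: temperature (degC) vs excess heat flow."""

    temperature: np.ndarray
    heat_flow: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if len(self.temperature) != len(self.heat_flow):
            raise ParseError("temperature and heat-flow lengths differ")
        if len(self.temperature) > 1 and not np.all(np.diff(self.temperature) > 0):
            raise ParseError("temperature grid must be strictly increasing")


@dataclass
class FluctuationSeries:
    """Samples of enthalpy H (kJ/mol) or area A (nm^2) at temperature T (K)."""

    samples: np.ndarray
    temperature_k: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) < 2:
            raise ParseError("need at least 2 samples for a fluctuation estimate")
        if self.temperature_k <= 0:
            raise ParseError("temperature must be positive (K)")


@dataclass
class MechanicalEstimates:
    c_p: float  # kJ mol^-1 K^-1
    kappa_a: float  # nm^2 mol kJ^-1
    k_a: float | None  # kJ mol^-1 nm^-2 (None if kappa_a == 0)
    thickness_nm: float


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def smooth_sg(curve: np.ndarray, window_points: int, poly_order: int) -> np.ndarray:
    """Savitzky-Golay smoothing; even windows are widened to the next odd size.

    Endpoints use the polynomial fitted to the edge window (scipy 'interp'
    mode), so polynomials up to ``poly_order`` are reproduced exactly.
    """
    curve = np.asarray(curve, dtype=float)
    window = int(window_points)
    if window % 2 == 0:
        window += 1
    if window <= poly_order:
        raise ParseError("window must exceed polynomial order")
    if window > len(curve):
        raise ParseError("window longer than series")
    return signal.savgol_filter(curve, window, poly_order, mode="interp")


def baseline_correct(
    x: np.ndarray,
    y: np.ndarray,
    anchor_regions: list[tuple[float, float]],
    method: str = "linear",
) -> np.ndarray:
    """Subtract a baseline fitted through anchor regions of the abscissa.

    ``method`` is 'linear' (default) or 'poly<k>' for a degree-k polynomial.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.zeros(len(x), dtype=bool)
    for lo, hi in anchor_regions:
        mask |= (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise ParseError("anchor regions cover fewer than 2 points")
    if method == "linear":
        degree = 1
    elif method.startswith("poly"):
        degree = int(method[4:])
    else:
        raise ParseError(f"unknown baseline method '{method}'")
    coeff = np.polyfit(x[mask], y[mask], degree)
    return y - np.polyval(coeff, x)


# ---------------------------------------------------------------------------
# bilinear decomposition
# ---------------------------------------------------------------------------


def mca_decompose(spectra: SpectraMatrix, n_components: int = 1) -> SpectraMatrix:
    """Truncated SVD factorization D = S C^T + E.

    C holds temperature-domain profiles scaled by the singular values, S the
    unit-norm wavelength-domain profiles.  Signs are fixed so each C column
    correlates positively with the temperature-resolved mean absorbance.
    Returns a new SpectraMatrix carrying C, S, E and the explained-variance
    fraction sum(sigma_kept^2)/sum(sigma^2).
    """
    D = spectra.absorbance
    k = int(n_components)
    if k < 1 or k > min(D.shape):
        raise ParseError(f"n_components must be in [1, {min(D.shape)}]")
    U, sv, Vt = np.linalg.svd(D, full_matrices=False)
    S = U[:, :k]  # (n_w, k)
    C = (Vt[:k, :].T * sv[:k])  # (n_t, k)
    mean_abs = D.mean(axis=0)  # per temperature
    for j in range(k):
        c = C[:, j]
        corr = np.dot(c - c.mean(), mean_abs - mean_abs.mean())
        sign = 1.0 if corr >= 0 else -1.0
        C[:, j] *= sign
        S[:, j] *= sign
    E = D - S @ C.T
    total = float(np.sum(sv**2))
    explained = float(np.sum(sv[:k] ** 2) / total) if total > 0 else 1.0
    return SpectraMatrix(
        wavelengths=spectra.wavelengths,
        temperatures=spectra.temperatures,
        absorbance=D,
        C=C,
        S=S,
        E=E,
        explained_variance=explained,
        truth=dict(spectra.truth),
    )


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------


def boltzmann_profile(t, offset, centers, widths, amplitudes):
    """y(T) = offset + sum_i a_i / (1 + exp((T_i - T)/w_i))."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, float(offset))
    for c, w, a in zip(np.atleast_1d(centers), np.atleast_1d(widths), np.atleast_1d(amplitudes)):
        arg = np.clip((c - t) / w, -700.0, 700.0)
        y = y + a / (1.0 + np.exp(arg))
    return y


def _pack_model(n):
    def model(t, *params):
        offset = params[0]
        centers = params[1 : 1 + n]
        widths = params[1 + n : 1 + 2 * n]
        amplitudes = params[1 + 2 * n :]
        return boltzmann_profile(t, offset, centers, widths, amplitudes)

    return model


def fit_boltzmann(
    temperatures: np.ndarray,
    profile: np.ndarray,
    n_transitions: int = 1,
    n_starts: int = 8,
    seed: int = 0,
) -> MeltingFit:
    """Nonlinear least-squares fit of 1 or 2 Boltzmann sigmoids.

    Multi-start initialization: centers are seeded from quantiles of the
    temperature range (jittered across restarts), widths from a fraction of
    the span, amplitudes from the profile range.  Reports each center as an
    inflection temperature with its standard error; chi^2 is the raw sum of
    squared residuals.  Double fits whose centers are closer than
    0.4 x max(width) are flagged unresolved.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(profile, dtype=float)
    n = int(n_transitions)
    if n not in (1, 2):
        raise ParseError("n_transitions must be 1 or 2")
    n_params = 1 + 3 * n
    if len(t) < 4 * n + 2:
        raise ParseError("too few points for a stable fit")

    span = t.max() - t.min()
    amp_guess = y[-1] - y[0]
    rng = np.random.default_rng(seed)
    model = _pack_model(n)

    best = None
    for trial in range(n_starts):
        if n == 1:
            centers0 = [t.min() + span * (0.5 + 0.25 * (rng.random() - 0.5) * (trial > 0))]
        else:
            q = np.array([0.35, 0.65]) + (rng.random(2) - 0.5) * 0.2 * (trial > 0)
            centers0 = list(t.min() + span * np.sort(q))
        widths0 = [span / 10 * (1 + trial % 3)] * n
        amps0 = [amp_guess / n] * n
        p0 = [y[0]] + centers0 + widths0 + amps0
        lower = [-np.inf] + [t.min() - span] * n + [1e-6] * n + [-np.inf] * n
        upper = [np.inf] + [t.max() + span] * n + [10 * span] * n + [np.inf] * n
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        ssr = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError(
            f"Boltzmann fit did not converge after {n_starts} starts "
            f"(n_transitions={n}, {len(t)} points)"
        )
    ssr, popt, pcov = best
    offset = float(popt[0])
    centers = np.array(popt[1 : 1 + n])
    widths = np.array(popt[1 + n : 1 + 2 * n])
    amplitudes = np.array(popt[1 + 2 * n :])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    center_se = perr[1 : 1 + n]
    order = np.argsort(centers)
    centers, widths, amplitudes, center_se = (
        centers[order],
        widths[order],
        amplitudes[order],
        center_se[order],
    )
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    dof = max(len(t) - n_params, 1)
    resolved = True
    if n == 2 and abs(centers[1] - centers[0]) < 2 * widths.max() / 5:
        resolved = False
    return MeltingFit(
        model="single" if n == 1 else "double",
        centers=centers,
        widths=widths,
        amplitudes=amplitudes,
        offset=offset,
        center_se=center_se,
        r_squared=r2,
        chi_squared=ssr,
        chi_squared_reduced=ssr / dof,
        resolved=resolved,
    )


# ---------------------------------------------------------------------------
# DSC features
# ---------------------------------------------------------------------------


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic refinement of a local maximum at index i."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dx = x[i + 1] - x[i]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def dsc_features(
    thermo: Thermogram,
    baseline_fraction: float = 0.15,
    minor_prominence: float = 0.01,
) -> dict:
    """Extract T_max, T_onset and minor endothermal events from a thermogram.

    T_max: parabolic-interpolated argmax of the main peak.  T_onset:
    intersection of the pre-transition baseline (linear fit over the first
    ``baseline_fraction`` of the scan) with the tangent at the leading-edge
    inflection.  Minor events: local maxima outside the main peak whose
    prominence exceeds ``minor_prominence`` x main-peak height.
    """
    t = thermo.temperature
    y = thermo.heat_flow
    if np.ptp(y) == 0:
        raise ParseError("no peak in thermogram (flat trace)")
    i_max = int(np.argmax(y))
    t_max, peak_height = _parabolic_peak(t, y, i_max)

    n_base = max(int(len(t) * baseline_fraction), 2)
    base_coeff = np.polyfit(t[:n_base], y[:n_base], 1)
    baseline = np.polyval(base_coeff, t)
    if peak_height - np.polyval(base_coeff, t_max) <= 0:
        raise ParseError("no peak above the pre-transition baseline")

    # leading-edge inflection: max slope between baseline region and peak
    dy = np.gradient(y, t)
    lead = slice(n_base, i_max + 1)
    if i_max <= n_base:
        raise ParseError("main peak inside the baseline region")
    i_infl = n_base + int(np.argmax(dy[lead]))
    slope = dy[i_infl]
    if slope <= base_coeff[0]:
        raise ParseError("leading edge has no rising inflection")
    # tangent: y = y_i + slope (t - t_i); intersect with baseline line
    t_onset = (
        (y[i_infl] - slope * t[i_infl]) - base_coeff[1]
    ) / (base_coeff[0] - slope)

    excess = y - baseline
    peaks, props = signal.find_peaks(
        excess, prominence=minor_prominence * (peak_height - baseline[i_max])
    )
    half_width = max((t[-1] - t[0]) * 0.08, 1.0)
    minor = []
    for p in peaks:
        if abs(t[p] - t_max) <= half_width:
            continue
        tp, _ = _parabolic_peak(t, y, p)
        minor.append(float(tp))
    return {
        "t_max": float(t_max),
        "t_onset": float(t_onset),
        "peak_height": float(peak_height),
        "minor_events": minor,
    }


def band_maxima(
    x: np.ndarray,
    y: np.ndarray,
    window: tuple[float, float] | None = None,
    smooth_points: int = 0,
    poly_order: int = 3,
    min_prominence_frac: float = 0.01,
) -> list[float]:
    """Local maxima positions (sub-grid, parabolic) inside an abscissa window.

    Used for FTIR band positions (x in cm^-1) after optional smoothing.
    A flat trace yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        mask = (x >= min(window)) & (x <= max(window))
        x, y = x[mask], y[mask]
    if len(x) < 3 or np.ptp(y) == 0:
        return []
    if smooth_points:
        y = smooth_sg(y, smooth_points, poly_order)
    peaks, _ = signal.find_peaks(y, prominence=min_prominence_frac * np.ptp(y))
    return [(_parabolic_peak(x, y, p))[0] for p in peaks]


# ---------------------------------------------------------------------------
# fluctuation mechanics
# ---------------------------------------------------------------------------


def heat_capacity_fluct(series: FluctuationSeries) -> float:
    """c_p = (<H^2> - <H>^2) / (R T^2), H in kJ/mol -> c_p in kJ mol^-1 K^-1."""
    var = float(np.var(series.samples, ddof=1))
    return var / (R_KJ_PER_MOL_K * series.temperature_k**2)


def area_compressibility(series: FluctuationSeries) -> float:
    """kappa_A^T = (<A^2> - <A>^2) / (<A> R T), A in nm^2."""
    mean = float(np.mean(series.samples))
    if mean <= 0:
        raise ParseError("mean area must be positive")
    var = float(np.var(series.samples, ddof=1))
    return var / (mean * R_KJ_PER_MOL_K * series.temperature_k)


def bending_modulus(thickness_nm: float, kappa_a: float) -> float:
    """K_A = d^2 / (16 kappa_A^T)."""
    if kappa_a <= 0:
        raise ParseError("kappa_A^T must be positive (zero gives infinite modulus)")
    return thickness_nm**2 / (16.0 * kappa_a)


def mechanical_estimates(
    area_series: FluctuationSeries,
    thickness_nm: float,
    enthalpy_series: FluctuationSeries | None = None,
) -> MechanicalEstimates:
    kappa = area_compressibility(area_series)
    cp = heat_capacity_fluct(enthalpy_series) if enthalpy_series is not None else float("nan")
    ka = bending_modulus(thickness_nm, kappa) if kappa > 0 else None
    return MechanicalEstimates(c_p=cp, kappa_a=kappa, k_a=ka, thickness_nm=thickness_nm)


# ---------------------------------------------------------------------------
# CSV I/O for spectra and thermograms
# ---------------------------------------------------------------------------


def read_spectra_csv(path) -> SpectraMatrix:
    """Spectra CSV: first column wavelength (nm), header row of temperatures."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    temperatures = np.array([float(c) for c in df.columns[1:]])
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpectraMatrix(wavelengths, temperatures, absorbance)


def write_spectra_csv(path, spectra: SpectraMatrix) -> None:
    import pandas as pd

    df = pd.DataFrame(
        spectra.absorbance, columns=[f"{t:g}" for t in spectra.temperatures]
    )
    df.insert(0, "wavelength_nm", spectra.wavelengths)
    df.to_csv(path, index=False)


def read_thermogram_csv(path) -> Thermogram:
    """DSC CSV: two columns, temperature (degC) and heat flow."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return Thermogram(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_thermogram_csv(path, thermo: Thermogram) -> None:
    import pandas as pd

    pd.DataFrame(
        {"temperature_C": thermo.temperature, "heat_flow": thermo.heat_flow}
    ).to_csv(path, index=False)
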