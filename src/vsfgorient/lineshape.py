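"""Multipeak Voigt fitting of homodyne VSFG spectra.

A homodyne-detected spectrum measures intensity proportional to
``|chi|^2``, so the susceptibility magnitude of a band is the square root
of its fitted peak amplitude; its sign is lost to detection.  Spectra in
the CH-stretch window are modelled as a constant baseline plus a sum of
Voigt components added in intensity (resonance cross terms are ignored —
a deliberate simplification appropriate for a spectrum dominated by one
band).  The analysis band is the CH2 asymmetric stretch near 2910 cm-1;
companions sit near 2860, 2930 and 2960 cm-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import voigt_profile as _scipy_voigt

__all__ = [
    "DEFAULT_PEAK_CENTERS",
    "ANALYSIS_CENTER",
    "VoigtPeak",
    "Spectrum",
    "MultipeakFit",
    "voigt_profile",
    "fit_multipeak",
    "extract_chi_magnitude",
]

#: Default CH-stretch band seeds (cm-1): CH2 symmetric, CH2 asymmetric
#: (the analysis band), and the two Fermi resonances.
DEFAULT_PEAK_CENTERS = (2860.0, 2910.0, 2930.0, 2960.0)

#: The band used for orientation analysis.
ANALYSIS_CENTER = 2910.0


@dataclass(frozen=True)
class VoigtPeak:
    """One Voigt component, parameterized by peak height.

    ``gaussian_width`` is the Gaussian sigma and ``lorentzian_width`` the
    Lorentzian half-width gamma, both in cm-1.  ``amplitude`` is the peak
    height at the center, in intensity units.
    """

    center: float
    gaussian_width: float
    lorentzian_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not all(
            np.isfinite(v)
            for v in (self.center, self.gaussian_width, self.lorentzian_width, self.amplitude)
        ):
            raise ValueError("Voigt peak parameters must be finite")
        if self.gaussian_width <= 0 and self.lorentzian_width <= 0:
            raise ValueError("at least one of the Voigt widths must be positive")
        if self.gaussian_width < 0 or self.lorentzian_width < 0:
            raise ValueError("Voigt widths must be nonnegative")
        if self.amplitude < 0:
            raise ValueError("Voigt amplitude must be nonnegative")


@dataclass
class Spectrum:
    """A single spectrum: strictly increasing wavenumber axis + intensities."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    polarization: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.wavenumber, self.intensity]),
            delimiter=",",
            header="wavenumber,intensity",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, polarization: str = "") -> "Spectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(wavenumber=arr[:, 0], intensity=arr[:, 1], polarization=polarization)


def _voigt_height(x, center, sigma, gamma):
    """Unit-height Voigt profile (height 1 at the center)."""
    sigma = max(float(sigma), 1e-12)
    return _scipy_voigt(np.asarray(x, dtype=float) - center, sigma, gamma) / _scipy_voigt(
        0.0, sigma, gamma
    )


def voigt_profile(x, peak: VoigtPeak) -> np.ndarray:
    """Evaluate one amplitude-scaled Voigt component on the grid ``x``.

    The Voigt is the convolution of a Gaussian (sigma = ``gaussian_width``)
    and a Lorentzian (half-width = ``lorentzian_width``), rescaled so that
    its value at the center equals ``amplitude``.
    """
    return peak.amplitude * _voigt_height(x, peak.center, peak.gaussian_width, peak.lorentzian_width)


@dataclass
class MultipeakFit:
    """Result of a multipeak fit: peaks, uncertainties, residuals, status."""

    peaks: list
    baseline: float
    stderr: list
    baseline_stderr: float
    residual_norm: float
    success: bool
    message: str
    polarization: str = ""
    result: object = None  # underlying lmfit.ModelResult

    def model(self, x) -> np.ndarray:
        return self.baseline + sum(voigt_profile(x, p) for p in self.peaks)

    def report(self) -> dict:
        return {
            "success": self.success,
            "message": self.message,
            "baseline": self.baseline,
            "baseline_stderr": self.baseline_stderr,
            "residual_norm": self.residual_norm,
            "polarization": self.polarization,
            "peaks": [
                {
                    "center": p.center,
                    "gaussian_width": p.gaussian_width,
                    "lorentzian_width": p.lorentzian_width,
                    "amplitude": p.amplitude,
                    "stderr": se,
                }
                for p, se in zip(self.peaks, self.stderr)
            ],
        }


def fit_multipeak(
    spec: Spectrum,
    initial_peaks,
    baseline: float = 0.0,
    share_widths: bool = False,
) -> MultipeakFit:
    """Least-squares fit of baseline + sum of Voigt components.

    ``initial_peaks`` seeds the optimizer; centers must lie inside the axis
    range.  With ``share_widths`` the Gaussian and Lorentzian widths are
    tied across components.  Non-convergence is flagged in the result
    rather than raised; a flat (zero-variance) spectrum is an error.
    """
    import lmfit

    initial_peaks = list(initial_peaks)
    if len(initial_peaks) == 0:
        raise ValueError("need at least one initial peak")
    x, yv = spec.wavenumber, spec.intensity
    if x.size < 4 * len(initial_peaks):
        raise ValueError(
            f"spectrum of length {x.size} too short for {len(initial_peaks)} peaks"
        )
    if np.ptp(yv) == 0:
        raise ValueError("degenerate (flat) spectrum: nothing to fit")
    lo, hi = x[0], x[-1]
    for p in initial_peaks:
        if not (lo <= p.center <= hi):
            raise ValueError(f"initial center {p.center} outside axis range [{lo}, {hi}]")

    span = hi - lo

    def one_peak(x, center, sigma, gamma, height):
        return height * _voigt_height(x, center, sigma, gamma)

    model = lmfit.models.ConstantModel(prefix="bl_")
    params = model.make_params(c=baseline)
    for i, p in enumerate(initial_peaks):
        pref = f"p{i}_"
        comp = lmfit.Model(one_peak, prefix=pref)
        model = model + comp
        params.update(comp.make_params())
        params[f"{pref}center"].set(value=p.center, min=lo, max=hi)
        params[f"{pref}sigma"].set(value=max(p.gaussian_width, 1e-3), min=1e-3, max=span)
        params[f"{pref}gamma"].set(value=max(p.lorentzian_width, 1e-3), min=1e-3, max=span)
        params[f"{pref}height"].set(value=max(p.amplitude, np.ptp(yv) * 1e-3), min=0.0)
        if share_widths and i > 0:
            params[f"{pref}sigma"].set(expr="p0_sigma")
            params[f"{pref}gamma"].set(expr="p0_gamma")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(yv, params, x=x)

    fitted, stderr = [], []
    for i, p in enumerate(initial_peaks):
        pref = f"p{i}_"
        fitted.append(
            VoigtPeak(
                center=result.params[f"{pref}center"].value,
                gaussian_width=result.params[f"{pref}sigma"].value,
                lorentzian_width=result.params[f"{pref}gamma"].value,
                amplitude=max(result.params[f"{pref}height"].value, 0.0),
            )
        )
        stderr.append(
            {
                k: (result.params[f"{pref}{n}"].stderr)
                for k, n in (
                    ("center", "center"),
                    ("gaussian_width", "sigma"),
                    ("lorentzian_width", "gamma"),
                    ("amplitude", "height"),
                )
            }
        )
    success = bool(result.success)
    message = result.message if success else f"fit did not converge: {result.message}"
    if not success:
        warnings.warn(f"multipeak fit returned partial result: {message}")
    return MultipeakFit(
        peaks=fitted,
        baseline=result.params["bl_c"].value,
        stderr=stderr,
        baseline_stderr=result.params["bl_c"].stderr,
        residual_norm=float(np.linalg.norm(result.residual)),
        success=success,
        message=message,
        polarization=spec.polarization,
        result=result,
    )


def extract_chi_magnitude(
    fit: MultipeakFit, target_center: float = ANALYSIS_CENTER, window: float = 10.0
) -> float:
    """Susceptibility magnitude of the band nearest ``target_center``.

    Homodyne detection measures intensity proportional to ``|chi|^2``, so
    ``|chi| = sqrt(peak amplitude)``; the sign is undetermined.  Raises if
    no fitted peak lies within ``window`` cm-1 of the target.
    """
    centers = np.array([p.center for p in fit.peaks])
    dist = np.abs(centers - target_center)
    i = int(np.argmin(dist))
    if dist[i] > window:
        raise ValueError(
            f"no fitted peak within +/-{window} cm-1 of {target_center} cm-1 "
            f"(nearest at {centers[i]:.1f})"
        )
    return float(np.sqrt(max(fit.peaks[i].amplitude, 0.0)))
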