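"""Synthetic data: training/test sets for the inverse solver and synthetic
polarization-resolved hyperspectral cubes.

The training generator draws random orientations, hyperpolarizabilities
and sheet coverage ratios, pushes them through the twist-averaged forward
model for a pair of sheets rotated 60 degrees in plane, and stores the
normalized signed susceptibilities as network inputs with an 11-value
target encoding.  The cube generator emulates the measurement itself:
rhombic sheets on a dark background, a dominant CH2 asymmetric-stretch
band at 2910 cm-1 whose intensity is ``|chi|^2`` per polarization,
companion CH bands, and additive Gaussian noise at a target per-pixel
signal-to-noise ratio.

Target encoding (11 values per sample)
--------------------------------------
The twist-averaged forward map is invariant under two discrete
transformations: ``(phi + pi, -g)`` and ``(pi - theta, g with chiral
components negated)``.  Each sample is therefore stored as its canonical
representative with ``phi`` folded into [0, pi) and ``theta`` into
[0, pi/2), the grouped hyperpolarizability transformed accordingly and
normalized to unit length, and two binary indicators recording which
angle interval the originally drawn sample occupied:

    [g1..g6, phi_fold, theta_fold, n_ratio, ind_phi, ind_theta]

The indicators realize the angle-interval disambiguation of the inverse
problem: the branches they name are exactly the images of the canonical
solution under the two invariances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .cube import HyperspectralCube
from .lineshape import DEFAULT_PEAK_CENTERS, ANALYSIS_CENTER, _voigt_height
from .tensor import (
    POLARIZATIONS,
    HyperpolarizabilityC7,
    grouped_beta,
    grouped_susceptibilities,
)

__all__ = [
    "GenerationRanges",
    "TrainingSet",
    "Sheet",
    "SheetScene",
    "N_INPUTS",
    "N_OUTPUTS",
    "canonicalize",
    "encode_targets",
    "decode_targets",
    "two_sheet_susceptibilities",
    "gen_training_set",
    "gen_test_set",
    "gen_cube",
]

#: Width of a network input row: two sheets x eight polarization combinations.
N_INPUTS = 16
#: Width of a target row: 6 grouped amplitudes + phi + theta + N + 2 indicators.
N_OUTPUTS = 11

#: Grouping matrix: rows are (zzz, xxz, xzx, zxx, xzy+zxy, xyz-zxy) in the
#: canonical 7-component order.
GROUPING_MATRIX = np.array(
    [
        [1, 0, 0, 0, 0, 0, 0],
        [0, 1, 0, 0, 0, 0, 0],
        [0, 0, 1, 0, 0, 0, 0],
        [0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 1, 1, 0],
        [0, 0, 0, 0, 0, -1, 1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class GenerationRanges:
    """Sampling domains for the random training process.

    Hyperpolarizability components are drawn independently and uniformly,
    angles uniformly on their full domains, and the coverage ratio N
    uniformly on an interval log-symmetric around 1.
    """

    beta_low: float = -1.0
    beta_high: float = 1.0
    n_low: float = 0.2
    n_high: float = 5.0
    phi_low: float = 0.0
    phi_high: float = 2 * np.pi
    theta_low: float = 0.0
    theta_high: float = np.pi
    delta_phi_deg: float = 60.0
    constrain_delta_phi: bool = True

    def validate(self) -> None:
        for lo, hi, name in (
            (self.beta_low, self.beta_high, "beta"),
            (self.n_low, self.n_high, "n"),
            (self.phi_low, self.phi_high, "phi"),
            (self.theta_low, self.theta_high, "theta"),
        ):
            if not (hi > lo):
                raise ValueError(f"empty sampling domain for {name}: [{lo}, {hi}]")
        if self.n_low <= 0:
            raise ValueError("coverage ratio must be positive")


@dataclass
class TrainingSet:
    """Normalized susceptibility inputs and 11-value targets for the solver."""

    inputs: np.ndarray
    outputs: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != N_INPUTS:
            raise ValueError(f"inputs must be (n, {N_INPUTS})")
        if self.outputs.shape != (self.inputs.shape[0], N_OUTPUTS):
            raise ValueError(f"outputs must be (n, {N_OUTPUTS})")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def save(self, path) -> None:
        """Write arrays as compressed npz with a JSON sidecar of seeds/ranges."""
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        np.savez_compressed(path, inputs=self.inputs, outputs=self.outputs)
        with open(path + ".json", "w") as fh:
            json.dump({"seed": self.seed, "params": self.params}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrainingSet":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        arrs = np.load(path)
        try:
            with open(path + ".json") as fh:
                side = json.load(fh)
        except FileNotFoundError:
            side = {"seed": -1, "params": {}}
        return cls(
            inputs=arrs["inputs"], outputs=arrs["outputs"],
            seed=side["seed"], params=side["params"],
        )


def canonicalize(phi, theta, g):
    """Fold (phi, theta, g) onto the canonical branch of the forward map.

    Returns ``(phi_fold, theta_fold, g_fold, ind_phi, ind_theta)`` where
    ``phi_fold`` lies in [0, pi), ``theta_fold`` in [0, pi/2], and the
    indicators record the original intervals ([pi, 2pi) resp. [pi/2, pi)).
    The folded triple produces exactly the same eight susceptibilities as
    the input triple.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float)) % (2 * np.pi)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    g = np.atleast_2d(np.asarray(g, dtype=float)).copy()
    if np.any(theta < 0) or np.any(theta >= np.pi):
        raise ValueError("theta must lie in [0, pi)")
    ind_theta = theta >= np.pi / 2
    theta = np.where(ind_theta, np.pi - theta, theta)
    g[ind_theta, 4:6] *= -1.0  # chiral groups flip with the tilt supplement
    ind_phi = phi >= np.pi
    phi = np.where(ind_phi, phi - np.pi, phi)
    g[ind_phi, :] *= -1.0  # the whole response is odd under a half-turn
    return phi, theta, g, ind_phi.astype(float), ind_theta.astype(float)


def encode_targets(phi, theta, g, n_ratio):
    """Canonicalize and pack one or more samples into 11-value target rows.

    The stored angles are the canonical-branch representatives, so the two
    indicator slots — which name the interval the stored angles occupy —
    are zero for generated rows.  The non-canonical branches produce
    bit-identical susceptibilities (exact degeneracies of the forward
    map), so no information is lost by storing the representative; the
    solver reports the degenerate images as equivalent solutions.
    """
    phi_f, theta_f, g_f, _, _ = canonicalize(phi, theta, g)
    norms = np.linalg.norm(g_f, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("grouped hyperpolarizability must be nonzero")
    g_f = g_f / norms
    ind_p = (phi_f >= np.pi).astype(float)
    ind_t = (theta_f >= np.pi / 2).astype(float)
    n_ratio = np.broadcast_to(np.asarray(n_ratio, dtype=float), phi_f.shape)
    return np.column_stack([g_f, phi_f, theta_f, n_ratio, ind_p, ind_t])


def decode_targets(y):
    """Unpack target rows into ``(g, phi, theta, n_ratio, ind_phi, ind_theta)``.

    ``phi`` and ``theta`` are the folded (canonical-branch) angles; callers
    wanting the original branch apply the indicated transformations.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != N_OUTPUTS:
        raise ValueError(f"target rows must have {N_OUTPUTS} values")
    return y[:, :6], y[:, 6], y[:, 7], y[:, 8], y[:, 9], y[:, 10]


def two_sheet_susceptibilities(g, phi1, theta, n_ratio, delta_phi_deg=60.0, normalize=True):
    """Stacked signed susceptibilities of a sheet pair, optionally normalized.

    Sheet 2 shares the tilt and hyperpolarizability of sheet 1, is rotated
    in plane by ``delta_phi_deg`` and scaled by the coverage ratio.
    Returns an array (..., 16).
    """
    g = np.asarray(g, dtype=float)
    phi1 = np.asarray(phi1, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n_ratio = np.asarray(n_ratio, dtype=float)
    delta = np.deg2rad(delta_phi_deg)
    chi1 = grouped_susceptibilities(g, phi1, theta)
    chi2 = grouped_susceptibilities(g, phi1 + delta, theta)
    chi2 = chi2 * n_ratio[..., None]
    x = np.concatenate([chi1, chi2], axis=-1)
    if normalize:
        norms = np.linalg.norm(x, axis=-1, keepdims=True)
        x = np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)
    return x


def _generate(n, rng, ranges: GenerationRanges) -> tuple:
    beta7 = rng.uniform(ranges.beta_low, ranges.beta_high, size=(n, 7))
    phi = rng.uniform(ranges.phi_low, ranges.phi_high, size=n) % (2 * np.pi)
    theta = rng.uniform(ranges.theta_low, ranges.theta_high, size=n)
    theta = np.clip(theta, 0.0, np.pi - 1e-12)
    n_ratio = rng.uniform(ranges.n_low, ranges.n_high, size=n)
    g = beta7 @ GROUPING_MATRIX.T
    # degenerate all-zero groupings are a measure-zero event; guard anyway
    bad = np.linalg.norm(g, axis=1) == 0
    if np.any(bad):
        g[bad] = rng.uniform(ranges.beta_low, ranges.beta_high, size=(bad.sum(), 7)) @ GROUPING_MATRIX.T
    y = encode_targets(phi, theta, g, n_ratio)
    g_c, phi_c, theta_c, n_c, _, _ = decode_targets(y)
    if ranges.constrain_delta_phi:
        delta = ranges.delta_phi_deg
    else:
        delta = np.rad2deg(rng.uniform(0, 2 * np.pi, size=n))
    x = two_sheet_susceptibilities(g_c, phi_c, theta_c, n_c, delta_phi_deg=delta)
    return x, y


def gen_training_set(n: int, seed: int, ranges: GenerationRanges | None = None) -> TrainingSet:
    """Generate ``n`` forward-model-consistent training rows, reproducibly.

    Every row satisfies the round-trip invariant: decoding its 11 target
    values and pushing them through the two-sheet forward model reproduces
    the normalized 16-value input exactly (up to floating point).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    ranges = ranges or GenerationRanges()
    ranges.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    x, y = _generate(int(n), rng, ranges)
    return TrainingSet(
        inputs=x, outputs=y, seed=int(seed),
        params={"role": "train", **asdict(ranges)},
    )


def gen_test_set(n: int, seed: int, ranges: GenerationRanges | None = None) -> TrainingSet:
    """Generate an independent test set from a disjoint seed stream."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    ranges = ranges or GenerationRanges()
    ranges.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    x, y = _generate(int(n), rng, ranges)
    return TrainingSet(
        inputs=x, outputs=y, seed=int(seed),
        params={"role": "test", **asdict(ranges)},
    )


# ---------------------------------------------------------------------------
# synthetic hyperspectral cubes
# ---------------------------------------------------------------------------


@dataclass
class Sheet:
    """One rhombic sheet: polygon footprint plus orientation and response."""

    vertices: np.ndarray  # (k, 2) pixel coordinates as (x, y)
    phi_deg: float
    theta_deg: float
    beta: HyperpolarizabilityC7 = field(
        default_factory=lambda: HyperpolarizabilityC7(
            beta_zzz=1.0, beta_xxz=0.45, beta_xzx=0.35, beta_zxx=0.3,
            beta_xzy=0.25, beta_zxy=-0.15, beta_xyz=0.2,
        )
    )
    amplitude_scale: float = 1.0
    sheet_id: str = "sheet"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("sheet vertices must be (k, 2) pixel coordinates")

    def susceptibilities(self) -> np.ndarray:
        g = grouped_beta(self.beta).to_array()
        return self.amplitude_scale * grouped_susceptibilities(
            g, np.deg2rad(self.phi_deg), np.deg2rad(self.theta_deg)
        )

    def mask(self, shape) -> np.ndarray:
        from skimage.draw import polygon

        ny, nx = shape
        rr, cc = polygon(self.vertices[:, 1], self.vertices[:, 0], shape=(ny, nx))
        m = np.zeros((ny, nx), dtype=bool)
        m[rr, cc] = True
        return m


@dataclass
class SheetScene:
    """Scene description for the cube generator.

    ``target_snr`` is the per-pixel signal-to-noise ratio of the 2910 cm-1
    peak in the reference polarization, measured over the sheet footprint.
    """

    sheets: list
    shape: tuple = (64, 64)
    wavenumber: np.ndarray = field(
        default_factory=lambda: np.arange(2800.0, 3000.0 + 1e-9, 2.0)
    )
    baseline: float = 10.0
    target_snr: float = 56.0
    reference_polarization: str = "SSS"
    gaussian_width: float = 6.0
    lorentzian_width: float = 4.0
    #: relative heights of companion CH bands w.r.t. the 2910 band
    band_rel_amplitudes: dict = field(
        default_factory=lambda: {2860.0: 0.30, 2930.0: 0.25, 2960.0: 0.20}
    )

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        if self.wavenumber[0] > 2800.0 or self.wavenumber[-1] < 3000.0:
            raise ValueError("wavenumber axis must cover 2800-3000 cm-1")
        ny, nx = self.shape
        for s in self.sheets:
            v = s.vertices
            if (v[:, 0].min() < 0 or v[:, 0].max() > nx - 1
                    or v[:, 1].min() < 0 or v[:, 1].max() > ny - 1):
                raise ValueError(f"sheet {s.sheet_id!r} extends outside image bounds")


def _band_profile(scene: SheetScene) -> np.ndarray:
    """Unit-2910-amplitude spectral profile (all CH bands, height-scaled)."""
    w = scene.wavenumber
    prof = _voigt_height(w, ANALYSIS_CENTER, scene.gaussian_width, scene.lorentzian_width)
    for center, rel in scene.band_rel_amplitudes.items():
        prof = prof + rel * _voigt_height(w, center, scene.gaussian_width, scene.lorentzian_width)
    return prof


def gen_cube(scene: SheetScene, seed: int) -> HyperspectralCube:
    """Render a noisy polarization-resolved hyperspectral cube of the scene.

    Per pixel and polarization the spectrum is ``baseline + |chi|^2 *
    multiband profile + Gaussian noise``; overlapping sheets add their
    intensity contributions.  The noise variance is set so that the
    2910 cm-1 peak height over the sheet footprint in the reference
    polarization has the scene's target per-pixel SNR.  Gaussian noise may
    produce small negative counts; they are kept (not clipped).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    ny, nx = scene.shape
    w = scene.wavenumber
    profile = _band_profile(scene)
    i2910 = int(np.argmin(np.abs(w - ANALYSIS_CENTER)))
    signal = np.zeros((len(POLARIZATIONS), ny, nx, w.size))
    ref = POLARIZATIONS.index(scene.reference_polarization)
    peak_heights = []  # per-pixel 2910 peak height in the reference polarization
    for sheet in scene.sheets:
        chi = sheet.susceptibilities()
        mask = sheet.mask(scene.shape)
        amps = chi**2  # homodyne detection
        contrib = amps[:, None, None, None] * profile[None, None, None, :] * mask[None, :, :, None]
        signal += contrib
    if scene.sheets:
        total_mask = np.any([s.mask(scene.shape) for s in scene.sheets], axis=0)
        peak = signal[ref, :, :, i2910]
        mean_peak = float(peak[total_mask].mean()) if total_mask.any() else 0.0
    else:
        mean_peak = 0.0
    if mean_peak > 0:
        sigma = mean_peak / scene.target_snr
    else:
        sigma = max(scene.baseline, 1.0) / scene.target_snr
    noisy = scene.baseline + signal + rng.normal(0.0, sigma, size=signal.shape)
    meta = {
        "seed": int(seed),
        "noise_sigma": sigma,
        "baseline": scene.baseline,
        "target_snr": scene.target_snr,
        "reference_polarization": scene.reference_polarization,
        "sheets": [
            {
                "sheet_id": s.sheet_id,
                "phi_deg": s.phi_deg,
                "theta_deg": s.theta_deg,
                "amplitude_scale": s.amplitude_scale,
                "vertices": s.vertices.tolist(),
                "beta": s.beta.to_array().tolist(),
                "susceptibilities": dict(
                    zip(POLARIZATIONS, s.susceptibilities().tolist())
                ),
            }
            for s in scene.sheets
        ],
    }
    return HyperspectralCube(data=noisy, wavenumber=w, meta=meta)
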