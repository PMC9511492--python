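"""Forward model: C7-symmetric hyperpolarizability to lab-frame susceptibilities.

The supramolecular subunit (two beta-cyclodextrin rings threaded by one
surfactant chain) has C7 symmetry.  Its molecular-frame hyperpolarizability
tensor ``beta_ijk`` then has 13 nonzero entries built from 7 nondegenerate
amplitudes.  The subunit is carried into the lab frame by an intrinsic
z-y'-z'' Euler rotation (in-plane rotation ``phi``, tilt ``theta``, twist
``psi``); the twist is physically arbitrary and is averaged uniformly over
[0, 2*pi).  With the axial (Z) field component neglected, the measurable
response reduces to 8 lab-frame susceptibilities indexed by polarization
combinations of S (lab X) and P (lab Y) beams.

The twist average is carried out symbolically once; the resulting closed
forms are frozen here.  Writing ``a = sin(phi) sin(theta)``,
``b = cos(phi) sin(theta)``, ``c = cos(theta)`` and grouping the seven
amplitudes into the six combinations the averaged equations depend on,

    g1 = beta_zzz          g4 = beta_zxx
    g2 = beta_xxz          g5 = beta_xzy + beta_zxy
    g3 = beta_xzx          g6 = beta_xyz - beta_zxy

the eight susceptibilities are cubic trig polynomials in (a, b, c); see
:func:`grouped_coefficients`.  Two exact discrete degeneracies follow:
``(phi + pi, -beta)`` and ``(pi - theta, beta with chiral components
negated)`` leave all eight values unchanged, which is why the inverse
problem needs angle-interval disambiguation.

A further *continuous* invariance deserves emphasis.  The twist-averaged
response is a transversely isotropic cubic form in the unit direction
``u`` of the molecular symmetry axis: in an adapted basis,

    chi_IJK = alpha u_I u_J u_K + beta3 d_IJ u_K + beta2 d_IK u_J
              + beta1 d_JK u_I + (chiral terms ~ u_Z u)

with (alpha, beta_i, gammas) a linear bijection of the grouped
amplitudes.  Restricted to in-plane indices the three families scale as
sin^3(theta), sin(theta) and sin(theta)cos(theta), so a change of tilt
can be absorbed exactly into a rescaling of the three families (see
:func:`tilt_compensated_beta`).  Tilt is therefore not identifiable from
in-plane susceptibilities alone when the hyperpolarizability amplitudes
are completely unknown; it becomes estimable only through prior bounds
on those amplitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "POLARIZATIONS",
    "CHIRAL_COMPONENTS",
    "HyperpolarizabilityC7",
    "Orientation",
    "GroupedBeta",
    "SusceptibilitySet",
    "expand_c7",
    "euler_matrix",
    "grouped_beta",
    "grouped_coefficients",
    "grouped_susceptibilities",
    "tilt_compensated_beta",
    "lab_susceptibilities",
    "lab_susceptibilities_quadrature",
]

#: Fixed order of the eight polarization combinations (signal, upconversion,
#: IR beam polarizations).  S maps to lab X, P to lab Y.
POLARIZATIONS = ("SSS", "SSP", "SPS", "PSS", "SPP", "PSP", "PPS", "PPP")

#: Names of the chiral (antisymmetric-pair) molecular components.
CHIRAL_COMPONENTS = ("beta_xzy", "beta_zxy", "beta_xyz")

_COMPONENTS = (
    "beta_zzz", "beta_xxz", "beta_xzx", "beta_zxx",
    "beta_xzy", "beta_zxy", "beta_xyz",
)


@dataclass(frozen=True)
class HyperpolarizabilityC7:
    """The 7 nondegenerate molecular-frame hyperpolarizability amplitudes.

    Amplitudes are dimensionless (arbitrary units); only ratios matter once
    measured intensities are normalized.
    """

    beta_zzz: float = 0.0
    beta_xxz: float = 0.0
    beta_xzx: float = 0.0
    beta_zxx: float = 0.0
    beta_xzy: float = 0.0
    beta_zxy: float = 0.0
    beta_xyz: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite hyperpolarizability component {f.name}={v!r}")

    def to_array(self) -> np.ndarray:
        """The 7 amplitudes in canonical order (zzz, xxz, xzx, zxx, xzy, zxy, xyz)."""
        return np.array([getattr(self, n) for n in _COMPONENTS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "HyperpolarizabilityC7":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected 7 components, got shape {arr.shape}")
        return cls(**dict(zip(_COMPONENTS, arr)))


@dataclass(frozen=True)
class Orientation:
    """Euler angles of a sheet's subunits, radians.

    ``phi`` is the in-plane rotation in [0, 2*pi), ``theta`` the tilt from
    the surface normal in [0, pi).  The twist ``psi`` is carried for
    completeness but every measurable quantity averages uniformly over it.
    """

    phi: float
    theta: float
    psi: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.phi) and np.isfinite(self.theta)):
            raise ValueError("orientation angles must be finite")
        object.__setattr__(self, "phi", float(self.phi) % (2 * np.pi))
        th = float(self.theta) % (2 * np.pi)
        if th >= np.pi:
            # theta is a polar angle; fold the representative into [0, pi)
            th = 2 * np.pi - th if th > np.pi else 0.0
        object.__setattr__(self, "theta", th)


@dataclass(frozen=True)
class GroupedBeta:
    """The 6 independent combinations the twist-averaged equations depend on."""

    values: tuple

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class SusceptibilitySet:
    """Eight lab-frame susceptibilities keyed by polarization combination."""

    values: dict = field(default_factory=dict)
    frame: str = "lab"
    sheet_id: str = "sheet"

    def to_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in POLARIZATIONS], dtype=float)

    @classmethod
    def from_array(cls, arr, sheet_id: str = "sheet") -> "SusceptibilitySet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 susceptibilities, got shape {arr.shape}")
        return cls(values=dict(zip(POLARIZATIONS, arr.tolist())), sheet_id=sheet_id)

    def to_frame(self):
        """Tabular (pandas) form with columns sheet_id, polarization, value."""
        import pandas as pd

        return pd.DataFrame(
            {
                "sheet_id": self.sheet_id,
                "polarization": list(POLARIZATIONS),
                "value": [self.values[p] for p in POLARIZATIONS],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"sheet_id": self.sheet_id, "frame": self.frame, "values": self.values}
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_csv(cls, path, sheet_id=None):
        import pandas as pd

        df = pd.read_csv(path)
        if sheet_id is not None:
            df = df[df["sheet_id"] == sheet_id]
        vals = dict(zip(df["polarization"], df["value"].astype(float)))
        missing = set(POLARIZATIONS) - set(vals)
        if missing:
            raise ValueError(f"missing polarization combinations in {path}: {sorted(missing)}")
        sid = str(df["sheet_id"].iloc[0]) if len(df) else "sheet"
        return cls(values={p: vals[p] for p in POLARIZATIONS}, sheet_id=sid)


def expand_c7(beta: HyperpolarizabilityC7) -> np.ndarray:
    """Expand the 7 amplitudes to the full rank-3 molecular-frame tensor.

    The C7 degeneracy pattern places 13 nonzero entries: ``beta_zzz`` alone,
    three mirror pairs (xxz=yyz, xzx=yzy, zxx=zyy) and three chiral
    antisymmetric pairs (xzy=-yzx, zxy=-zyx, xyz=-yxz).
    """
    if not isinstance(beta, HyperpolarizabilityC7):
        beta = HyperpolarizabilityC7.from_array(np.asarray(beta, dtype=float))
    B = np.zeros((3, 3, 3))
    x, y, z = 0, 1, 2
    B[z, z, z] = beta.beta_zzz
    B[x, x, z] = B[y, y, z] = beta.beta_xxz
    B[x, z, x] = B[y, z, y] = beta.beta_xzx
    B[z, x, x] = B[z, y, y] = beta.beta_zxx
    B[x, z, y], B[y, z, x] = beta.beta_xzy, -beta.beta_xzy
    B[z, x, y], B[z, y, x] = beta.beta_zxy, -beta.beta_zxy
    B[x, y, z], B[y, x, z] = beta.beta_xyz, -beta.beta_xyz
    return B


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_matrix(orientation: Orientation | tuple, psi_value: float | None = None) -> np.ndarray:
    """Proper rotation matrix for the intrinsic z-y'-z'' Euler convention.

    Equivalent to the extrinsic composition ``Rz(phi) @ Ry(theta) @ Rz(psi)``.
    """
    if isinstance(orientation, Orientation):
        phi, theta = orientation.phi, orientation.theta
        psi = orientation.psi if psi_value is None else psi_value
    else:
        phi, theta = orientation
        psi = psi_value
    if psi is None:
        psi = 0.0
    return _rz(phi) @ _ry(theta) @ _rz(psi)


def grouped_beta(beta: HyperpolarizabilityC7) -> GroupedBeta:
    """Project the 7 amplitudes onto the 6 combinations that matter.

    The direction ``beta_xzy - beta_zxy - beta_xyz`` is annihilated by the
    twist average, so the forward map has rank 6 in beta.
    """
    if not isinstance(beta, HyperpolarizabilityC7):
        beta = HyperpolarizabilityC7.from_array(np.asarray(beta, dtype=float))
    return GroupedBeta(
        values=(
            beta.beta_zzz,
            beta.beta_xxz,
            beta.beta_xzx,
            beta.beta_zxx,
            beta.beta_xzy + beta.beta_zxy,
            beta.beta_xyz - beta.beta_zxy,
        )
    )


def grouped_coefficients(phi, theta) -> np.ndarray:
    """Coefficient matrix C with shape (..., 8, 6) such that chi = C @ g.

    Closed forms from the one-off symbolic twist average.  With
    ``a = sin(phi) sin(theta)``, ``b = cos(phi) sin(theta)``,
    ``c = cos(theta)``::

        chi_SSS = b^3 g1 + b(1-b^2)(g2+g3+g4)
        chi_SSP = a b^2 g1 + a(1-b^2) g2 - a b^2 (g3+g4) + b c g5
        chi_SPS = a b^2 g1 - a b^2 g2 + a(1-b^2) g3 - a b^2 g4 + b c g6
        chi_PSS = a b^2 g1 - a b^2 (g2+g3) + a(1-b^2) g4 - b c (g5+g6)
        chi_SPP = a^2 b g1 - a^2 b (g2+g3) + b(1-a^2) g4 + a c (g5+g6)
        chi_PSP = a^2 b g1 - a^2 b g2 + b(1-a^2) g3 - a^2 b g4 - a c g6
        chi_PPS = a^2 b g1 + b(1-a^2) g2 - a^2 b (g3+g4) - a c g5
        chi_PPP = a^3 g1 + a(1-a^2)(g2+g3+g4)

    Every term carries sin(theta), so all eight susceptibilities vanish
    identically at zero tilt.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    a = np.sin(phi) * np.sin(theta)
    b = np.cos(phi) * np.sin(theta)
    c = np.cos(theta)
    z = np.zeros(np.broadcast(a, b).shape)
    a2, b2 = a * a, b * b
    rows = [
        # g1,        g2,            g3,            g4,            g5,        g6
        [b * b2, b * (1 - b2), b * (1 - b2), b * (1 - b2), z, z],                     # SSS
        [a * b2, a * (1 - b2), -a * b2, -a * b2, b * c, z],                           # SSP
        [a * b2, -a * b2, a * (1 - b2), -a * b2, z, b * c],                           # SPS
        [a * b2, -a * b2, -a * b2, a * (1 - b2), -b * c, -b * c],                     # PSS
        [a2 * b, -a2 * b, -a2 * b, b * (1 - a2), a * c, a * c],                       # SPP
        [a2 * b, -a2 * b, b * (1 - a2), -a2 * b, z, -a * c],                          # PSP
        [a2 * b, b * (1 - a2), -a2 * b, -a2 * b, -a * c, z],                          # PPS
        [a * a2, a * (1 - a2), a * (1 - a2), a * (1 - a2), z, z],                     # PPP
    ]
    C = np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)
    return C


def grouped_susceptibilities(g, phi, theta) -> np.ndarray:
    """Vectorized forward map: grouped beta (..., 6) -> susceptibilities (..., 8)."""
    g = np.asarray(g, dtype=float)
    C = grouped_coefficients(phi, theta)
    return np.einsum("...ij,...j->...i", C, g)


def tilt_compensated_beta(g, theta_from, theta_to) -> np.ndarray:
    """Grouped amplitudes that reproduce the same in-plane susceptibilities
    at a different tilt.

    Demonstrates the continuous tilt degeneracy of the in-plane-restricted
    forward map: for any orientation set sharing one tilt,
    ``grouped_susceptibilities(g, phi, theta_from)`` equals
    ``grouped_susceptibilities(g', phi, theta_to)`` with the returned
    ``g'``, for every ``phi``.  Requires both tilts in (0, pi/2).
    """
    g = np.asarray(g, dtype=float)
    s1, c1 = np.sin(theta_from), np.cos(theta_from)
    s2, c2 = np.sin(theta_to), np.cos(theta_to)
    if s1 * c1 == 0 or s2 * c2 == 0:
        raise ValueError("tilts must lie strictly inside (0, pi/2)")
    alpha = g[..., 0] - (g[..., 1] + g[..., 2] + g[..., 3])
    alpha = alpha * (s1 / s2) ** 3
    betas = g[..., 1:4] * (s1 / s2)
    gammas = g[..., 4:6] * (s1 * c1) / (s2 * c2)
    g1 = alpha + betas.sum(axis=-1)
    return np.concatenate(
        [np.stack([g1], axis=-1), betas, gammas], axis=-1
    )


def lab_susceptibilities(
    beta: HyperpolarizabilityC7, phi: float, theta: float, sheet_id: str = "sheet"
) -> SusceptibilitySet:
    """Twist-averaged lab-frame susceptibilities for one sheet.

    Parameters are the molecular amplitudes and the sheet's in-plane
    rotation and tilt (radians).  Returns the 8 values in the fixed
    polarization order.
    """
    orient = Orientation(phi=phi, theta=theta)
    g = grouped_beta(beta).to_array()
    chi = grouped_susceptibilities(g, orient.phi, orient.theta)
    return SusceptibilitySet.from_array(chi, sheet_id=sheet_id)


def lab_susceptibilities_quadrature(
    beta: HyperpolarizabilityC7, phi: float, theta: float, n_psi: int = 720
) -> np.ndarray:
    """Brute-force oracle: rotate the full 27-element tensor and average over twist.

    Numerically rotates ``expand_c7(beta)`` at ``n_psi`` equally spaced twist
    angles, averages, and reads off the X/Y lab components.  Kept as an
    independent cross-check of the frozen closed forms.
    """
    B = expand_c7(beta)
    acc = np.zeros((3, 3, 3))
    for psi in np.arange(n_psi) * 2 * np.pi / n_psi:
        R = euler_matrix((phi, theta), psi)
        acc += np.einsum("Ii,Jj,Kk,ijk->IJK", R, R, R, B)
    acc /= n_psi
    lab = {"S": 0, "P": 1}
    return np.array([acc[lab[p[0]], lab[p[1]], lab[p[2]]] for p in POLARIZATIONS])
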