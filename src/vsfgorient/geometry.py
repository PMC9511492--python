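"""Independent geometric consistency checks on a recovered tilt angle.

Two cheap cross-checks complement the spectroscopic inversion: the
stacking-height trigonometry (a tilted column of subunits is shorter than
an upright one by the cosine of the tilt) and a steric-feasibility
classifier that treats subunits as parallel rigid cylinders on the known
supramolecular lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PackingModel", "tilt_from_heights", "steric_class"]


@dataclass(frozen=True)
class PackingModel:
    """Rigid-cylinder packing of supramolecular subunits on a lattice.

    Defaults describe the cyclodextrin-surfactant subunit: lattice spacing
    from small-angle X-ray scattering (1.52 nm) and an effective van der
    Waals cylinder diameter and height chosen once for that subunit.
    """

    lattice_spacing: float = 1.52  # nm
    diameter: float = 1.25  # nm, effective subunit cylinder diameter
    height: float = 1.55  # nm, subunit cylinder height
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.lattice_spacing, self.diameter, self.height) <= 0:
            raise ValueError("all packing lengths must be positive")
        if not (0.0 <= self.tilt_deg <= 90.0):
            raise ValueError("tilt must lie in [0, 90] degrees")


def tilt_from_heights(h_observed: float, h_upright: float) -> float:
    """Tilt angle (degrees) implied by a shortened stacking height.

    A stack of subunits tilted by ``theta`` from the normal has height
    ``h_upright * cos(theta)``, so ``theta = arccos(h_observed /
    h_upright)``.  Requires ``0 < h_observed <= h_upright``.
    """
    if not (h_observed > 0 and h_upright > 0):
        raise ValueError("heights must be positive")
    if h_observed > h_upright:
        raise ValueError(
            f"observed height {h_observed} exceeds upright height {h_upright}: "
            "no real tilt angle"
        )
    return float(np.rad2deg(np.arccos(h_observed / h_upright)))


def steric_class(
    model: PackingModel,
    tight_fraction: float = 0.10,
) -> tuple[str, float]:
    """Classify subunit packing at the model's tilt as clear/tight/collision.

    Subunits tilt in parallel, so the distance between adjacent cylinder
    axes shrinks from the lattice spacing ``L`` to ``L cos(theta)`` and
    the inter-cylinder gap is ``L cos(theta) - d``.  The gap is negative
    on collision and "tight" below ``tight_fraction`` of the diameter.
    Returns ``(classification, gap_nm)``.
    """
    theta = np.deg2rad(model.tilt_deg)
    gap = model.lattice_spacing * np.cos(theta) - model.diameter
    if gap < 0:
        cls = "collision"
    elif gap < tight_fraction * model.diameter:
        cls = "tight"
    else:
        cls = "clear"
    return cls, float(gap)
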