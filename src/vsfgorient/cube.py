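"""Hyperspectral cube container and HDF5 I/O.

A cube holds one intensity array per polarization combination, indexed
``(polarization, y, x, wavenumber)``, plus axis metadata.  On disk it is a
single HDF5 file with datasets ``/cube``, ``/wavenumber``,
``/polarizations`` and a JSON metadata attribute under ``/meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tensor import POLARIZATIONS

__all__ = ["HyperspectralCube", "save_cube", "load_cube"]


@dataclass
class HyperspectralCube:
    """Intensity array (n_pol, ny, nx, n_wavenumber) plus axes and provenance."""

    data: np.ndarray
    wavenumber: np.ndarray
    polarizations: tuple = POLARIZATIONS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.polarizations = tuple(self.polarizations)
        if self.data.ndim != 4:
            raise ValueError("cube data must be 4-D (polarization, y, x, wavenumber)")
        if self.data.shape[0] != len(self.polarizations):
            raise ValueError("first cube axis must match the polarization list")
        if self.data.shape[-1] != self.wavenumber.size:
            raise ValueError("last cube axis must match the wavenumber axis")

    @property
    def shape(self):
        return self.data.shape

    def pol_index(self, polarization: str) -> int:
        try:
            return self.polarizations.index(polarization)
        except ValueError:
            raise KeyError(
                f"unknown polarization {polarization!r}; have {self.polarizations}"
            ) from None

    def plane(self, polarization: str) -> np.ndarray:
        """The (ny, nx, n_wavenumber) array for one polarization combination."""
        return self.data[self.pol_index(polarization)]


def save_cube(cube: HyperspectralCube, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.data, compression="gzip", compression_opts=4)
        fh.create_dataset("wavenumber", data=cube.wavenumber)
        fh.create_dataset(
            "polarizations", data=np.array([p.encode() for p in cube.polarizations])
        )
        fh.attrs["meta"] = json.dumps(cube.meta, default=str)


def load_cube(path) -> HyperspectralCube:
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["cube"][...]
        wavenumber = fh["wavenumber"][...]
        pols = tuple(p.decode() for p in fh["polarizations"][...])
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return HyperspectralCube(data=data, wavenumber=wavenumber, polarizations=pols, meta=meta)
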