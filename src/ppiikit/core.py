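"""Shared containers and angle primitives.

Two containers travel through the whole pipeline:

``DihedralSeries``
    Per-frame, per-residue backbone torsions (phi, psi, omega) in degrees.
    Terminal torsions that need atoms from a neighbouring residue (phi of
    residue 1, psi/omega of the last residue) are undefined and stored as
    NaN; every statistic downstream skips them.

``BackboneEnsemble``
    Per-frame Cartesian coordinates (Å) of the backbone atoms N, CA, C and
    optionally O of each residue.

Residue indexing is 1-based throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DihedralSeries",
    "BackboneEnsemble",
    "wrap_angle",
    "dihedral_angle",
]


def wrap_angle(angle):
    """Wrap angles in degrees into the interval (-180, 180].

    NaN values pass through unchanged.
    """
    return 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0


def dihedral_angle(p0, p1, p2, p3):
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the IUPAC sign convention (cis = 0, trans = 180); accepts arrays
    with the point coordinates on the last axis and broadcasts over leading
    axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _validate_angles(name: str, arr: np.ndarray) -> None:
    finite = arr[np.isfinite(arr)]
    if finite.size and (np.any(finite <= -180.0) or np.any(finite > 180.0)):
        raise ValueError(f"{name} angles must lie in (-180, 180] degrees")


@dataclass
class DihedralSeries:
    """Backbone torsions for an ensemble: arrays of shape (n_frames, n_residues)."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    label: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if not (self.phi.shape == self.psi.shape == self.omega.shape):
            raise ValueError("phi, psi and omega must have identical shapes")
        for name, arr in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            _validate_angles(name, arr)
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"{self.n_residues} residues"
            )

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def frame(self, index: int) -> "DihedralSeries":
        """Single-frame view (still shaped (1, n_residues))."""
        return DihedralSeries(
            self.phi[index : index + 1],
            self.psi[index : index + 1],
            self.omega[index : index + 1],
            label=self.label,
            sequence=self.sequence,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns frame, residue, phi, psi, omega.

        Frames and residues are 1-based; undefined torsions appear as NaN.
        """
        frames, residues = np.meshgrid(
            np.arange(1, self.n_frames + 1),
            np.arange(1, self.n_residues + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "residue": residues.ravel(),
                "phi": self.phi.ravel(),
                "psi": self.psi.ravel(),
                "omega": self.omega.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DihedralSeries):
            return NotImplemented
        return (
            self.label == other.label
            and self.sequence == other.sequence
            and self.phi.shape == other.phi.shape
            and all(
                np.array_equal(a, b, equal_nan=True)
                for a, b in (
                    (self.phi, other.phi),
                    (self.psi, other.psi),
                    (self.omega, other.omega),
                )
            )
        )


@dataclass
class BackboneEnsemble:
    """Backbone coordinates in Å, shaped (n_frames, n_residues, n_atoms, 3).

    ``atom_names`` lists the atoms stored per residue, always starting with
    ("N", "CA", "C"); a trailing "O" is optional.
    """

    coords: np.ndarray
    atom_names: tuple[str, ...] = ("N", "CA", "C")
    label: str = ""
    sequence: str | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 3:
            self.coords = self.coords[np.newaxis]
        if self.coords.ndim != 4 or self.coords.shape[-1] != 3:
            raise ValueError(
                "coords must have shape (n_frames, n_residues, n_atoms, 3)"
            )
        self.atom_names = tuple(self.atom_names)
        if self.atom_names[:3] != ("N", "CA", "C"):
            raise ValueError("atom_names must start with ('N', 'CA', 'C')")
        if len(self.atom_names) != self.coords.shape[2]:
            raise ValueError("atom_names length does not match coordinate axis")
        if np.any(~np.isfinite(self.coords)):
            raise ValueError("backbone coordinates contain non-finite values")
        self._index = {name: i for i, name in enumerate(self.atom_names)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def atom(self, name: str) -> np.ndarray:
        """Coordinates of one backbone atom type, shape (n_frames, n_residues, 3)."""
        return self.coords[:, :, self._index[name], :]

    def frame(self, index: int) -> "BackboneEnsemble":
        return BackboneEnsemble(
            self.coords[index : index + 1],
            atom_names=self.atom_names,
            label=self.label,
            sequence=self.sequence,
        )
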