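"""Internal-coordinate backbone building and helix geometry.

Chains are built by sequential natural-extension (NeRF) placement from a
table of bond lengths and angles plus the requested (phi, psi, omega)
torsions, and measured back into torsions, helix parameters (rise per
residue, residues per turn, pitch, handedness), radius of gyration and
end-to-end distance.

The helix fit follows the simple axis construction that suffices for
near-ideal helices: the axis is the principal component of the centred CA
point cloud, the rise is the mean projection of successive CA
displacements on the axis, and the turn angle is the mean rotation of
successive CA positions about the axis.  Handedness is taken from the
sign of the CA pseudo-torsion (CA_i..CA_{i+3}): positive = right-handed,
negative = left-handed.  (The signed rotation about the axis is ambiguous
modulo 360 degrees for helices near three residues per turn and is not
used for handedness.)
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .core import BackboneEnsemble, DihedralSeries, dihedral_angle

__all__ = [
    "GeometryTable",
    "HelixParameters",
    "default_geometry",
    "build_backbone",
    "build_ideal_chain",
    "measure_dihedrals",
    "helix_parameters",
    "compute_rg",
    "compute_end_to_end",
]

# Atomic masses (u) for the mass-weighted radius of gyration.
ATOM_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999}

_REQUIRED_LENGTHS = ("N-CA", "CA-C", "C-N")
_REQUIRED_ANGLES = ("N-CA-C", "CA-C-N", "C-N-CA")


@dataclass(frozen=True)
class GeometryTable:
    """Bond lengths (Å) and bond angles (degrees) used for chain building."""

    bond_lengths: dict
    bond_angles: dict

    def __post_init__(self) -> None:
        for key in _REQUIRED_LENGTHS:
            if key not in self.bond_lengths:
                raise ValueError(f"geometry table is missing bond length {key!r}")
        for key in _REQUIRED_ANGLES:
            if key not in self.bond_angles:
                raise ValueError(f"geometry table is missing bond angle {key!r}")

    @classmethod
    def from_file(cls, path) -> "GeometryTable":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(dict(raw["bond_lengths"]), dict(raw["bond_angles"]))


def default_geometry() -> GeometryTable:
    """Standard peptide geometry shipped with the package."""
    resource = importlib.resources.files("ppiikit.data") / "backbone_geometry.yaml"
    raw = yaml.safe_load(resource.read_text())
    return GeometryTable(dict(raw["bond_lengths"]), dict(raw["bond_angles"]))


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d bonded to c with angle b-c-d and torsion a-b-c-d (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    dihedrals: DihedralSeries,
    geometry: GeometryTable | None = None,
    place_oxygens: bool = True,
) -> BackboneEnsemble:
    """Build Cartesian backbones from one or more frames of torsions.

    Requires phi for residues 2..n, and psi and omega for residues
    1..n-1; any NaN among those is a hard error.  Carbonyl oxygens are
    placed from psi when available (the terminal O uses the trans
    orientation of the preceding C-N unit it would have had).

    Re-measuring torsions from the output reproduces the inputs to well
    below 1e-6 degrees.
    """
    geometry = geometry or default_geometry()
    lengths, angles = geometry.bond_lengths, geometry.bond_angles
    n_frames, n_res = dihedrals.n_frames, dihedrals.n_residues
    if n_res < 2:
        raise ValueError("need at least two residues to build a backbone")

    for name, arr, sl in (
        ("phi", dihedrals.phi, np.s_[:, 1:]),
        ("psi", dihedrals.psi, np.s_[:, :-1]),
        ("omega", dihedrals.omega, np.s_[:, :-1]),
    ):
        if np.any(~np.isfinite(arr[sl])):
            frame, residue = np.argwhere(~np.isfinite(arr[sl]))[0]
            raise ValueError(
                f"{name} undefined at frame {frame + 1}, "
                f"residue {residue + 1 + (1 if name == 'phi' else 0)}"
            )

    with_o = place_oxygens and "C-O" in lengths and "CA-C-O" in angles
    atom_names = ("N", "CA", "C", "O") if with_o else ("N", "CA", "C")
    coords = np.zeros((n_frames, n_res, len(atom_names), 3))

    ang_ncac = np.deg2rad(angles["N-CA-C"])
    for f in range(n_frames):
        n_atoms = np.zeros((n_res, 3))
        ca = np.zeros((n_res, 3))
        c = np.zeros((n_res, 3))
        ca[0] = [lengths["N-CA"], 0.0, 0.0]
        c[0] = ca[0] + lengths["CA-C"] * np.array(
            [-np.cos(ang_ncac), np.sin(ang_ncac), 0.0]
        )
        for i in range(1, n_res):
            n_atoms[i] = _place_atom(
                n_atoms[i - 1], ca[i - 1], c[i - 1],
                lengths["C-N"], angles["CA-C-N"], dihedrals.psi[f, i - 1],
            )
            ca[i] = _place_atom(
                ca[i - 1], c[i - 1], n_atoms[i],
                lengths["N-CA"], angles["C-N-CA"], dihedrals.omega[f, i - 1],
            )
            c[i] = _place_atom(
                c[i - 1], n_atoms[i], ca[i],
                lengths["CA-C"], angles["N-CA-C"], dihedrals.phi[f, i],
            )
        coords[f, :, 0] = n_atoms
        coords[f, :, 1] = ca
        coords[f, :, 2] = c
        if with_o:
            for i in range(n_res):
                # O is anti to the next N across the sp2 carbonyl carbon;
                # for the C-terminal residue use the psi the chain would
                # continue with (trans orientation of the last psi known).
                psi = dihedrals.psi[f, i] if i < n_res - 1 else dihedrals.psi[f, n_res - 2]
                coords[f, i, 3] = _place_atom(
                    n_atoms[i], ca[i], c[i],
                    lengths["C-O"], angles["CA-C-O"], psi + 180.0,
                )

    ensemble = BackboneEnsemble(
        coords, atom_names=atom_names, label=dihedrals.label,
        sequence=dihedrals.sequence,
    )
    _check_peptide_bonds(ensemble)
    return ensemble


def _check_peptide_bonds(ensemble: BackboneEnsemble) -> None:
    c_atoms = ensemble.atom("C")[:, :-1]
    n_atoms = ensemble.atom("N")[:, 1:]
    dist = np.linalg.norm(c_atoms - n_atoms, axis=-1)
    if np.any((dist < 1.2) | (dist > 1.45)):
        raise ValueError("built backbone has a C-N peptide bond outside [1.2, 1.45] Å")


def build_ideal_chain(
    n_residues: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    geometry: GeometryTable | None = None,
) -> BackboneEnsemble:
    """Single-frame chain with every torsion set to the same (phi, psi, omega)."""
    series = DihedralSeries(
        np.full((1, n_residues), float(phi)),
        np.full((1, n_residues), float(psi)),
        np.full((1, n_residues), float(omega)),
    )
    return build_backbone(series, geometry=geometry)


def measure_dihedrals(ensemble: BackboneEnsemble) -> DihedralSeries:
    """Backbone torsions of every frame; terminal torsions are NaN."""
    n = ensemble.atom("N")
    ca = ensemble.atom("CA")
    c = ensemble.atom("C")
    n_frames, n_res = ensemble.n_frames, ensemble.n_residues
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    omega = np.full((n_frames, n_res), np.nan)
    if n_res >= 2:
        # phi_i = C(i-1)-N(i)-CA(i)-C(i), psi_i = N(i)-CA(i)-C(i)-N(i+1),
        # omega_i = CA(i)-C(i)-N(i+1)-CA(i+1)
        phi[:, 1:] = dihedral_angle(c[:, :-1], n[:, 1:], ca[:, 1:], c[:, 1:])
        psi[:, :-1] = dihedral_angle(n[:, :-1], ca[:, :-1], c[:, :-1], n[:, 1:])
        omega[:, :-1] = dihedral_angle(ca[:, :-1], c[:, :-1], n[:, 1:], ca[:, 1:])
    return DihedralSeries(
        phi, psi, omega, label=ensemble.label, sequence=ensemble.sequence
    )


@dataclass(frozen=True)
class HelixParameters:
    """Rise per residue (Å), residues per turn, pitch (Å/turn), handedness."""

    rise_per_residue: float
    residues_per_turn: float
    pitch: float
    handedness: str

    def __post_init__(self) -> None:
        if abs(self.pitch - self.rise_per_residue * self.residues_per_turn) > 1e-6:
            raise ValueError("pitch must equal rise_per_residue * residues_per_turn")
        if self.residues_per_turn <= 2:
            raise ValueError("residues_per_turn must exceed 2")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")


def helix_parameters(
    backbone: BackboneEnsemble,
    window: tuple[int, int] | None = None,
    frame: int = 0,
) -> HelixParameters:
    """Fit helix parameters to the CA trace of one frame.

    ``window`` is an inclusive 1-based residue range; it must span at
    least six residues.  A near-collinear CA trace (mean turn angle below
    1 degree) raises ``ValueError("degenerate helix")``.
    """
    ca = backbone.atom("CA")[frame]
    if window is not None:
        first, last = window
        ca = ca[first - 1 : last]
    if ca.shape[0] < 6:
        raise ValueError("helix window must span at least 6 residues")
    if np.any(~np.isfinite(ca)):
        raise ValueError("CA coordinates must be finite")

    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]

    # refine the direction from second differences of the CA trace: for a
    # helix the vectors (d_{i+1} - d_i) are perpendicular to the axis, so
    # their pairwise cross products are parallel to it, independent of how
    # many turns the chain covers (the plain principal axis tilts for
    # partial turns)
    second = np.diff(np.diff(ca, axis=0), axis=0)
    crosses = np.cross(second[:-1], second[1:])
    norms_c = np.linalg.norm(crosses, axis=1)
    good = norms_c > 1e-9
    if good.any():
        directions = crosses[good] / norms_c[good, None]
        directions *= np.sign(directions @ axis)[:, None]
        refined = directions.mean(axis=0)
        if np.linalg.norm(refined) > 1e-9:
            axis = refined / np.linalg.norm(refined)

    rises = (ca[1:] - ca[:-1]) @ axis
    if rises.mean() < 0:
        axis = -axis
        rises = -rises
    rise = float(rises.mean())

    # refinement: locate the axis position by a least-squares circle fit to
    # the CA positions projected on the plane perpendicular to the axis
    # (the point-cloud centroid is off-axis for partial helix turns)
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    x = centred @ e1
    y = centred @ e2
    design = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    solution, *_ = np.linalg.lstsq(design, x**2 + y**2, rcond=None)
    centre_x, centre_y = solution[0], solution[1]

    radial = np.column_stack([x - centre_x, y - centre_y])
    norms = np.linalg.norm(radial, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate helix")
    u = radial / norms[:, None]
    cos_turn = np.sum(u[:-1] * u[1:], axis=1)
    # z-component of the cross product in the right-handed (e1, e2, axis) frame
    sin_turn = u[:-1, 0] * u[1:, 1] - u[:-1, 1] * u[1:, 0]
    turn_angles = np.degrees(np.arctan2(sin_turn, cos_turn))
    turn = float(np.abs(turn_angles).mean())
    if turn < 1.0:
        raise ValueError("degenerate helix")

    residues_per_turn = 360.0 / turn
    pitch = rise * residues_per_turn

    # handedness from the CA pseudo-torsion sign
    pseudo = dihedral_angle(ca[:-3], ca[1:-2], ca[2:-1], ca[3:])
    handedness = "right" if np.nanmean(pseudo) > 0 else "left"
    return HelixParameters(rise, residues_per_turn, pitch, handedness)


def _masses(ensemble: BackboneEnsemble, mass_weighted: bool) -> np.ndarray:
    if mass_weighted:
        return np.array([ATOM_MASSES[a] for a in ensemble.atom_names])
    return np.ones(len(ensemble.atom_names))


def compute_rg(
    ensemble: BackboneEnsemble | np.ndarray,
    mass_weighted: bool = True,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Radius of gyration per frame, in nm.

    Accepts a ``BackboneEnsemble`` (weighted by backbone atomic masses by
    default, or unit masses with ``mass_weighted=False``) or a raw
    coordinate array shaped (n_frames, n_atoms, 3) in Å with optional
    explicit ``masses``.
    """
    if isinstance(ensemble, BackboneEnsemble):
        coords = ensemble.coords.reshape(ensemble.n_frames, -1, 3)
        weights = np.tile(_masses(ensemble, mass_weighted), ensemble.n_residues)
    else:
        coords = np.asarray(ensemble, dtype=float)
        if coords.ndim == 2:
            coords = coords[np.newaxis]
        if coords.ndim != 3 or coords.shape[-1] != 3:
            raise ValueError("raw coordinates must have shape (n_frames, n_atoms, 3)")
        weights = (
            np.asarray(masses, dtype=float)
            if masses is not None
            else np.ones(coords.shape[1])
        )
    if coords.shape[1] < 1:
        raise ValueError("empty frame")
    weights = weights / weights.sum()
    centroid = np.einsum("a,fax->fx", weights, coords)
    delta = coords - centroid[:, None, :]
    rg_angstrom = np.sqrt(np.einsum("a,fa->f", weights, np.sum(delta**2, axis=-1)))
    return rg_angstrom / 10.0


def compute_end_to_end(ensemble: BackboneEnsemble) -> np.ndarray:
    """Distance N(1) to C(last) per frame, in nm."""
    if ensemble.n_residues < 2:
        raise ValueError("need at least two residues for an end-to-end distance")
    start = ensemble.atom("N")[:, 0]
    end = ensemble.atom("C")[:, -1]
    return np.linalg.norm(end - start, axis=-1) / 10.0
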