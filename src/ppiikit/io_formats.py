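"""Readers and writers for the formats the pipeline touches.

Coordinate ensembles come in as multi-model PDB files (one frame per
MODEL record, backbone atoms N/CA/C and optionally O per residue, parsed
with biotite) or as a plain dihedral CSV with the fixed dialect

    frame,residue,phi,psi,omega

(1-based frame and residue indices, angles in degrees, blank cells for
undefined terminal torsions).  Experimental scalar couplings come in as
a CSV with columns residue,type,value_Hz.  Tabular pipeline products are
written as CSV, nested products as JSON; every writer has a matching
reader that round-trips to an equal object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

from .core import BackboneEnsemble, DihedralSeries, wrap_angle
from .couplings import COUPLING_TYPES, CouplingTable
from .ensemble_compare import ClusterResult, PCAProjection
from .observables_trends import RegressionResult
from .rama_ss import SSProfile

__all__ = [
    "EnsembleSource",
    "ExperimentalCouplingRecord",
    "read_ensemble",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_dihedral_csv",
    "write_dihedral_csv",
    "read_experimental_couplings",
    "write_results",
    "read_results",
    "read_ss_profile",
    "read_coupling_table",
]

_DIHEDRAL_COLUMNS = ("frame", "residue", "phi", "psi", "omega")
_FORMATS = ("pdb", "dihedral_csv")


@dataclass
class EnsembleSource:
    """Where an ensemble comes from and how to parse it."""

    path: str | Path
    format: str
    label: str
    frame_count: int | None = None

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ValueError(
                f"unknown format {self.format!r}; allowed: {', '.join(_FORMATS)}"
            )
        if not self.label:
            raise ValueError("source label must be nonempty")
        if self.frame_count is not None and self.frame_count < 1:
            raise ValueError("frame_count must be at least 1")


@dataclass(frozen=True)
class ExperimentalCouplingRecord:
    """One experimental scalar coupling: residue, type and value in Hz."""

    residue_index: int
    coupling_type: str
    value: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(
                f"unknown coupling type {self.coupling_type!r}; "
                f"allowed: {', '.join(COUPLING_TYPES)}"
            )
        if not np.isfinite(self.value):
            raise ValueError("coupling value must be finite")


def read_ensemble(source: EnsembleSource):
    """Dispatch on the declared format.

    PDB input yields a ``BackboneEnsemble``; dihedral CSV input yields a
    ``DihedralSeries``.
    """
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(path)
    if source.format == "pdb":
        ensemble = read_pdb_ensemble(path, label=source.label)
    else:
        ensemble = read_dihedral_csv(path, label=source.label)
    source.frame_count = ensemble.n_frames
    return ensemble


def read_pdb_ensemble(path, label: str = "") -> BackboneEnsemble:
    """Multi-model PDB to a BackboneEnsemble (one frame per MODEL)."""
    pdb_file = PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    frames = []
    has_oxygen = True
    n_residues_ref = None
    for model in range(1, n_models + 1):
        atoms = pdb_file.get_structure(model=model)
        atoms = atoms[struc.filter_amino_acids(atoms)]
        res_ids = pd.unique(atoms.res_id)
        if n_residues_ref is None:
            n_residues_ref = len(res_ids)
        elif len(res_ids) != n_residues_ref:
            raise ValueError(
                f"model {model} has {len(res_ids)} residues, "
                f"expected {n_residues_ref}"
            )
        frame = np.zeros((len(res_ids), 4, 3))
        frame_has_o = True
        for r, res_id in enumerate(res_ids):
            residue = atoms[atoms.res_id == res_id]
            for a, name in enumerate(("N", "CA", "C")):
                hit = residue[residue.atom_name == name]
                if len(hit) == 0:
                    raise ValueError(
                        f"model {model}, residue {res_id}: missing backbone "
                        f"atom {name}"
                    )
                frame[r, a] = hit.coord[0]
            hit = residue[residue.atom_name == "O"]
            if len(hit) == 0:
                frame_has_o = False
            else:
                frame[r, 3] = hit.coord[0]
        has_oxygen = has_oxygen and frame_has_o
        frames.append(frame)
    if n_residues_ref is None or n_residues_ref == 0:
        raise ValueError(f"{path}: no amino-acid residues found")
    coords = np.stack(frames)
    if not has_oxygen:
        coords = coords[:, :, :3]
    return BackboneEnsemble(
        coords,
        atom_names=("N", "CA", "C", "O") if has_oxygen else ("N", "CA", "C"),
        label=label,
    )


def write_pdb_ensemble(ensemble: BackboneEnsemble, path) -> Path:
    """BackboneEnsemble to a multi-model PDB file."""
    n_res = ensemble.n_residues
    n_atoms_per_res = len(ensemble.atom_names)
    if ensemble.sequence is not None:
        res_names = [
            ProteinSequence.convert_letter_1to3(letter).upper()
            for letter in ensemble.sequence
        ]
    else:
        res_names = ["ALA"] * n_res

    template = struc.AtomArray(n_res * n_atoms_per_res)
    idx = 0
    for r in range(n_res):
        for name in ensemble.atom_names:
            template.chain_id[idx] = "A"
            template.res_id[idx] = r + 1
            template.res_name[idx] = res_names[r]
            template.atom_name[idx] = name
            template.element[idx] = name[0]
            idx += 1
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = ensemble.coords.reshape(ensemble.n_frames, -1, 3)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    path = Path(path)
    pdb_file.write(str(path))
    return path


def read_dihedral_csv(path, label: str = "") -> DihedralSeries:
    """Fixed-dialect dihedral CSV to a DihedralSeries."""
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty dihedral CSV") from err
    missing = set(_DIHEDRAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for column in _DIHEDRAL_COLUMNS:
        try:
            table[column] = pd.to_numeric(table[column])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: unparseable value in column {column!r}") from err
    if len(table) == 0:
        raise ValueError(f"{path}: no data rows")

    frames = np.sort(table["frame"].unique())
    residues = np.sort(table["residue"].unique())
    if not np.array_equal(residues, np.arange(1, len(residues) + 1)):
        raise ValueError(f"{path}: residues must be contiguous starting at 1")
    counts = table.groupby("frame")["residue"].count()
    if counts.nunique() != 1:
        raise ValueError(f"{path}: inconsistent residue counts across frames")

    shape = (len(frames), len(residues))
    arrays = {}
    frame_pos = {f: i for i, f in enumerate(frames)}
    rows = table["frame"].map(frame_pos).to_numpy()
    cols = table["residue"].to_numpy() - 1
    for angle in ("phi", "psi", "omega"):
        values = table[angle].to_numpy(dtype=float)
        # wrap only out-of-range entries so in-range values stay bit-exact
        with np.errstate(invalid="ignore"):
            outside = (values <= -180.0) | (values > 180.0)
        values = np.where(outside, wrap_angle(values), values)
        grid = np.full(shape, np.nan)
        grid[rows, cols] = values
        arrays[angle] = grid
    return DihedralSeries(arrays["phi"], arrays["psi"], arrays["omega"], label=label)


def write_dihedral_csv(dihedrals: DihedralSeries, path) -> Path:
    """DihedralSeries to the fixed CSV dialect (lossless round trip)."""
    path = Path(path)
    dihedrals.to_frame().to_csv(path, index=False)
    return path


def read_experimental_couplings(path) -> list[ExperimentalCouplingRecord]:
    """CSV with columns residue,type,value_Hz (and optional note)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if len(table) == 0:
        return []
    missing = {"residue", "type", "value_Hz"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        records.append(
            ExperimentalCouplingRecord(
                residue_index=int(row["residue"]),
                coupling_type=str(row["type"]),
                value=float(row["value_Hz"]),
                source_note=str(row["note"]) if "note" in table.columns else "",
            )
        )
    return records


def write_results(result, path) -> Path:
    """Serialise a pipeline product: tabular as CSV, nested as JSON."""
    path = Path(path)
    if isinstance(result, SSProfile):
        frame = result.per_residue.copy()
        frame.insert(0, "_kind", "SSProfile")
        frame.to_csv(path, index=False)
    elif isinstance(result, CouplingTable):
        frame = result.table.copy()
        frame.insert(0, "_kind", "CouplingTable")
        frame.to_csv(path, index=False)
    elif isinstance(result, (ClusterResult, RegressionResult, PCAProjection)):
        with open(path, "w") as handle:
            json.dump(result.to_dict(), handle, indent=1)
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")
    return path


def read_ss_profile(path) -> SSProfile:
    """Read back a profile CSV written by ``write_results``."""
    frame = pd.read_csv(path)
    if "_kind" in frame.columns:
        frame = frame.drop(columns=["_kind"])
    n_frames = int(frame["n_frames"].iloc[0]) if len(frame) else 0
    class_names = [c for c in ("coil", "PPII", "helix", "beta") if c in frame.columns]
    if len(frame):
        weights = frame[class_names].to_numpy()
        counts = np.where(np.isfinite(weights).all(axis=1), n_frames, 0)
        chain_average = {}
        for name in class_names:
            values = frame[name].to_numpy()
            chain_average[name] = float(
                np.nansum(values * counts) / counts.sum()
            )
    else:
        chain_average = {name: np.nan for name in class_names}
    return SSProfile(frame, chain_average, n_frames)


def read_coupling_table(path) -> CouplingTable:
    frame = pd.read_csv(path)
    if "_kind" in frame.columns:
        frame = frame.drop(columns=["_kind"])
    return CouplingTable(frame)


_JSON_KINDS = {
    "ClusterResult": ClusterResult.from_dict,
    "RegressionResult": RegressionResult.from_dict,
    "PCAProjection": PCAProjection.from_dict,
}


def read_results(path):
    """Reload any product written by ``write_results``."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        data = json.loads(text)
        kind = data.get("kind")
        if kind not in _JSON_KINDS:
            raise ValueError(f"{path}: unknown result kind {kind!r}")
        return _JSON_KINDS[kind](data)
    header = stripped.splitlines()[0] if stripped else ""
    if header.startswith("_kind"):
        kind = stripped.splitlines()[1].split(",")[0]
    else:
        raise ValueError(f"{path}: cannot infer result kind")
    if kind == "SSProfile":
        return read_ss_profile(path)
    if kind == "CouplingTable":
        return read_coupling_table(path)
    raise ValueError(f"{path}: unknown result kind {kind!r}")
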