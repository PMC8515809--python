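"""Ramachandran-window classification and PPII secondary-structure profiles.

Four rectangular (phi, psi) windows define the structured regions:

* beta:   -180 <= phi < -104  and  104 <= psi <= 180
* PPII:   -104 <= phi <= -46  and  116 <= psi <= 174
* alphaR:  -90 <= phi <= -30  and  -90 <= psi <=   0
* alphaL:   30 <= phi <=  90  and    0 <= psi <=  90

Anything outside the four windows is random coil.  A DSSP-PPII-style
per-residue assignment then requires a residue to sit in a run of at
least ``min_run`` consecutive residues of the same class (PPII,
helix-like = alphaR or alphaL, beta-like) before it counts as structured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DihedralSeries

__all__ = [
    "RegionWindow",
    "RegionLabelMatrix",
    "SSProfile",
    "REGION_CODES",
    "REGION_NAMES",
    "ASSIGN_CODES",
    "ASSIGN_NAMES",
    "default_windows",
    "classify_region",
    "classify_matrix",
    "region_populations",
    "rama_density_map",
    "assign_ppii_runs",
    "ss_profile",
    "omega_cis_fraction",
]

MISSING = -1
REGION_CODES = {"coil": 0, "beta": 1, "PPII": 2, "alphaR": 3, "alphaL": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

ASSIGN_CODES = {"coil": 0, "PPII": 1, "helix": 2, "beta": 3}
ASSIGN_NAMES = {v: k for k, v in ASSIGN_CODES.items()}

# region code -> assignment class code (before the run-length rule)
_REGION_TO_CLASS = {0: 0, 1: 3, 2: 1, 3: 2, 4: 2}


@dataclass(frozen=True)
class RegionWindow:
    """A rectangular Ramachandran window with per-edge inclusivity."""

    name: str
    phi_min: float
    phi_max: float
    psi_min: float
    psi_max: float
    phi_min_inclusive: bool = True
    phi_max_inclusive: bool = True
    psi_min_inclusive: bool = True
    psi_max_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.phi_min < self.phi_max and self.psi_min < self.psi_max):
            raise ValueError(f"window {self.name!r}: min must be below max")

    def contains(self, phi, psi):
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        lo_phi = phi >= self.phi_min if self.phi_min_inclusive else phi > self.phi_min
        hi_phi = phi <= self.phi_max if self.phi_max_inclusive else phi < self.phi_max
        lo_psi = psi >= self.psi_min if self.psi_min_inclusive else psi > self.psi_min
        hi_psi = psi <= self.psi_max if self.psi_max_inclusive else psi < self.psi_max
        return lo_phi & hi_phi & lo_psi & hi_psi


def default_windows() -> list[RegionWindow]:
    """The four shipped windows (see module docstring)."""
    return [
        RegionWindow("beta", -180.0, -104.0, 104.0, 180.0, phi_max_inclusive=False),
        RegionWindow("PPII", -104.0, -46.0, 116.0, 174.0),
        RegionWindow("alphaR", -90.0, -30.0, -90.0, 0.0),
        RegionWindow("alphaL", 30.0, 90.0, 0.0, 90.0),
    ]


def _intervals_overlap(a_min, a_max, a_min_inc, a_max_inc,
                       b_min, b_max, b_min_inc, b_max_inc) -> bool:
    lo = max(a_min, b_min)
    hi = min(a_max, b_max)
    if lo < hi:
        return True
    if lo > hi:
        return False
    # touching edges overlap only if the shared point is inside both
    in_a = (a_min_inc if lo == a_min else True) and (a_max_inc if lo == a_max else True)
    in_b = (b_min_inc if lo == b_min else True) and (b_max_inc if lo == b_max else True)
    return in_a and in_b


def _validate_disjoint(windows: list[RegionWindow]) -> None:
    for wa, wb in itertools.combinations(windows, 2):
        phi_overlap = _intervals_overlap(
            wa.phi_min, wa.phi_max, wa.phi_min_inclusive, wa.phi_max_inclusive,
            wb.phi_min, wb.phi_max, wb.phi_min_inclusive, wb.phi_max_inclusive,
        )
        psi_overlap = _intervals_overlap(
            wa.psi_min, wa.psi_max, wa.psi_min_inclusive, wa.psi_max_inclusive,
            wb.psi_min, wb.psi_max, wb.psi_min_inclusive, wb.psi_max_inclusive,
        )
        if phi_overlap and psi_overlap:
            raise ValueError(f"windows {wa.name!r} and {wb.name!r} overlap")


@dataclass
class RegionLabelMatrix:
    """Per-frame, per-residue region codes; -1 marks undefined torsions."""

    labels: np.ndarray
    region_codes: dict = field(default_factory=lambda: dict(REGION_CODES))

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=np.int8))
        valid = set(self.region_codes.values()) | {MISSING}
        if not set(np.unique(self.labels)) <= valid:
            raise ValueError("label matrix contains unknown region codes")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


def classify_region(phi: float, psi: float,
                    windows: list[RegionWindow] | None = None) -> str:
    """Region name for one (phi, psi) pair; 'coil' outside all windows."""
    windows = windows if windows is not None else default_windows()
    _validate_disjoint(windows)
    for window in windows:
        if window.contains(phi, psi):
            return window.name
    return "coil"


def classify_matrix(dihedrals: DihedralSeries,
                    windows: list[RegionWindow] | None = None) -> RegionLabelMatrix:
    """Vectorised window classification of a whole ensemble."""
    windows = windows if windows is not None else default_windows()
    _validate_disjoint(windows)
    labels = np.zeros(dihedrals.phi.shape, dtype=np.int8)
    defined = np.isfinite(dihedrals.phi) & np.isfinite(dihedrals.psi)
    for window in windows:
        code = REGION_CODES.get(window.name)
        if code is None:
            raise ValueError(f"unknown region name {window.name!r}")
        inside = window.contains(dihedrals.phi, dihedrals.psi) & defined
        labels[inside] = code
    labels[~defined] = MISSING
    return RegionLabelMatrix(labels)


def region_populations(labels: RegionLabelMatrix) -> dict[str, float]:
    """Fraction of defined (frame, residue) cells per region; sums to 1."""
    defined = labels.labels[labels.labels != MISSING]
    if defined.size == 0:
        raise ValueError("no defined labels to compute populations from")
    return {
        name: float(np.mean(defined == code))
        for code, name in sorted(REGION_NAMES.items())
    }


def rama_density_map(dihedrals: DihedralSeries, bin_width: float = 4.0):
    """2D (phi, psi) histogram over (-180, 180]^2, normalised to max 1.

    Returns ``(grid, phi_edges, psi_edges)`` where grid[i, j] covers
    phi_edges[i:i+2] x psi_edges[j:j+2].
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 360 evenly")
    defined = np.isfinite(dihedrals.phi) & np.isfinite(dihedrals.psi)
    phi = dihedrals.phi[defined]
    psi = dihedrals.psi[defined]
    if phi.size == 0:
        raise ValueError("no defined (phi, psi) pairs to histogram")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # nudge exact -180 (excluded from the torus interval) into the first bin
    grid, phi_edges, psi_edges = np.histogram2d(
        np.clip(phi, -180.0 + 1e-12, None), np.clip(psi, -180.0 + 1e-12, None),
        bins=[edges, edges],
    )
    return grid / grid.max(), phi_edges, psi_edges


def _runs_to_classes(class_row: np.ndarray, min_run: int) -> np.ndarray:
    """Apply the run-length rule to one frame of per-residue class codes."""
    out = class_row.copy()
    n = class_row.size
    i = 0
    while i < n:
        j = i
        while j < n and class_row[j] == class_row[i]:
            j += 1
        if class_row[i] > 0 and (j - i) < min_run:
            out[i:j] = ASSIGN_CODES["coil"]
        i = j
    return out


def assign_ppii_runs(labels: RegionLabelMatrix, min_run: int = 2) -> np.ndarray:
    """DSSP-PPII-style assignment with a minimum run length.

    Returns an integer matrix with codes from ``ASSIGN_CODES`` (missing
    cells stay -1).  A residue is PPII in a frame iff it belongs to a
    maximal run of >= min_run consecutive residues in the PPII window;
    helix-like (alphaR or alphaL) and beta-like runs are treated the same
    way; everything else is coil.  Undefined residues break runs.
    """
    if min_run < 1:
        raise ValueError("min_run must be at least 1")
    classes = np.full(labels.labels.shape, MISSING, dtype=np.int8)
    defined = labels.labels != MISSING
    for region_code, class_code in _REGION_TO_CLASS.items():
        classes[defined & (labels.labels == region_code)] = class_code
    if min_run == 1:
        return classes
    out = classes.copy()
    for f in range(classes.shape[0]):
        row = classes[f]
        segments = np.where(row == MISSING)[0]
        start = 0
        for stop in list(segments) + [row.size]:
            if stop > start:
                out[f, start:stop] = _runs_to_classes(row[start:stop], min_run)
            start = stop + 1
    return out


@dataclass
class SSProfile:
    """Per-residue assignment-class fractions plus the chain average.

    ``per_residue`` has columns residue, PPII, helix, beta, coil,
    n_frames; fractions of residues whose torsions are never defined
    (chain termini) are NaN.
    """

    per_residue: pd.DataFrame
    chain_average: dict[str, float]
    n_frames: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSProfile):
            return NotImplemented
        if self.n_frames != other.n_frames:
            return False
        if set(self.chain_average) != set(other.chain_average):
            return False
        if not all(
            np.isclose(self.chain_average[k], other.chain_average[k])
            for k in self.chain_average
        ):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.per_residue.reset_index(drop=True),
                other.per_residue.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def ss_profile(assignments: np.ndarray) -> SSProfile:
    """Average the run-length assignments over frames."""
    assignments = np.atleast_2d(assignments)
    n_frames, n_res = assignments.shape
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rows = []
    class_names = [ASSIGN_NAMES[c] for c in sorted(ASSIGN_NAMES)]
    for r in range(n_res):
        col = assignments[:, r]
        col = col[col != MISSING]
        row = {"residue": r + 1}
        for name in class_names:
            row[name] = (
                float(np.mean(col == ASSIGN_CODES[name])) if col.size else np.nan
            )
        rows.append(row)
    per_residue = pd.DataFrame(rows)
    per_residue["n_frames"] = n_frames
    defined = assignments[assignments != MISSING]
    chain_average = {
        name: float(np.mean(defined == ASSIGN_CODES[name])) for name in class_names
    }
    return SSProfile(per_residue, chain_average, n_frames)


def omega_cis_fraction(dihedrals: DihedralSeries) -> np.ndarray:
    """Per-residue fraction of frames with |omega| < 90 degrees.

    Residues whose omega is never defined (the chain terminus) get NaN.
    """
    defined = np.isfinite(dihedrals.omega)
    if not defined.any():
        raise ValueError("omega undefined for every residue")
    with np.errstate(invalid="ignore"):
        cis = np.abs(dihedrals.omega) < 90.0
    counts = defined.sum(axis=0).astype(float)
    frac = np.where(counts > 0, (cis & defined).sum(axis=0) / np.maximum(counts, 1), np.nan)
    return frac
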