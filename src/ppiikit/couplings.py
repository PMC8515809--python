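"""NMR scalar-coupling back-calculation and chi-squared scoring.

A Karplus-type relation J(theta) = A cos^2(theta + delta) + B cos(theta +
delta) + C maps one backbone torsion to one coupling.  For an ensemble
the coupling is evaluated per frame on the selected torsion and then
averaged — the average of J, never J of the average angle, because the
relation is nonlinear.  Ensembles are scored against experiment with

    chi^2 = (1/N) * sum_i ((<J_i>_calc - J_i,exp) / sigma_i)^2

where sigma_i is the error of the Karplus parametrization itself and N
is the number of compared couplings (the 1/N is the default "reduced"
mode; a raw-sum mode is available).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import DihedralSeries, wrap_angle

__all__ = [
    "COUPLING_TYPES",
    "TORSION_SELECTORS",
    "KarplusParamSet",
    "CouplingTable",
    "load_karplus_registry",
    "default_karplus_registry",
    "karplus",
    "ensemble_couplings",
    "chi2_score",
    "coupling_curve",
]

logger = logging.getLogger(__name__)

COUPLING_TYPES = (
    "3JHNHa", "3JHaC'", "3JHNC'", "3JHNCb", "1JNCa", "2JNCa", "3JHNCa",
)
TORSION_SELECTORS = ("phi", "psi", "psi_prev")


@dataclass(frozen=True)
class KarplusParamSet:
    """Coefficients (Hz), angular shift (deg), parametrization error (Hz)."""

    coupling_type: str
    A: float
    B: float
    C: float
    delta: float
    sigma: float
    selector: str
    citation: str = ""

    def __post_init__(self) -> None:
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(
                f"unknown coupling type {self.coupling_type!r}; "
                f"allowed: {', '.join(COUPLING_TYPES)}"
            )
        if self.selector not in TORSION_SELECTORS:
            raise ValueError(f"unknown torsion selector {self.selector!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def load_karplus_registry(path) -> dict[str, KarplusParamSet]:
    """Read a YAML coefficient registry; returns {coupling_type: paramset}."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return _registry_from_mapping(raw)


def _registry_from_mapping(raw) -> dict[str, KarplusParamSet]:
    registry = {}
    for entry in raw["couplings"]:
        params = KarplusParamSet(
            coupling_type=entry["type"],
            A=float(entry["A"]), B=float(entry["B"]), C=float(entry["C"]),
            delta=float(entry["delta"]), sigma=float(entry["sigma"]),
            selector=entry["selector"], citation=entry.get("citation", ""),
        )
        registry[params.coupling_type] = params
    return registry


def default_karplus_registry() -> dict[str, KarplusParamSet]:
    """The literature parametrizations shipped with the package."""
    resource = importlib.resources.files("ppiikit.data") / "karplus.yaml"
    return _registry_from_mapping(yaml.safe_load(resource.read_text()))


def karplus(theta, params: KarplusParamSet):
    """Evaluate J(theta) in Hz; theta in degrees, scalar or array."""
    shifted = np.deg2rad(np.asarray(theta, dtype=float) + params.delta)
    cos = np.cos(shifted)
    return params.A * cos**2 + params.B * cos + params.C


@dataclass
class CouplingTable:
    """Calculated (and optionally experimental) couplings per residue.

    ``table`` columns: residue, coupling_type, calc_mean, exp_value,
    sigma.  Rows without an experimental value are kept but excluded
    from the chi^2 score.
    """

    table: pd.DataFrame

    _COLUMNS = ("residue", "coupling_type", "calc_mean", "exp_value", "sigma")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"coupling table is missing columns {sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CouplingTable):
            return NotImplemented
        a = self.table[list(self._COLUMNS)].reset_index(drop=True)
        b = other.table[list(self._COLUMNS)].reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


def _select_torsion(dihedrals: DihedralSeries, residue: int, selector: str):
    """Torsion series (over frames) for a 1-based residue, or None if undefined."""
    if selector == "phi":
        values = dihedrals.phi[:, residue - 1]
    elif selector == "psi":
        values = dihedrals.psi[:, residue - 1]
    else:  # psi_prev
        if residue < 2:
            return None
        values = dihedrals.psi[:, residue - 2]
    if np.any(~np.isfinite(values)):
        return None
    return values


def ensemble_couplings(
    dihedrals: DihedralSeries,
    paramsets: list[KarplusParamSet] | dict[str, KarplusParamSet] | None = None,
    experimental: list | None = None,
) -> CouplingTable:
    """Frame-averaged couplings for every residue and parametrization.

    ``experimental`` may be a list of records with attributes
    (residue_index, coupling_type, value) — typically from
    ``io_formats.read_experimental_couplings`` — whose values are merged
    into the ``exp_value`` column.  Rows whose selected torsion is
    undefined (chain termini, psi_prev at residue 1) are omitted with a
    logged warning.
    """
    if paramsets is None:
        paramsets = default_karplus_registry()
    if isinstance(paramsets, dict):
        paramsets = list(paramsets.values())

    exp_lookup = {}
    for record in experimental or []:
        exp_lookup[(record.residue_index, record.coupling_type)] = record.value

    rows = []
    for params in paramsets:
        for residue in range(1, dihedrals.n_residues + 1):
            theta = _select_torsion(dihedrals, residue, params.selector)
            if theta is None:
                logger.warning(
                    "skipping %s at residue %d: torsion %s undefined",
                    params.coupling_type, residue, params.selector,
                )
                continue
            rows.append(
                {
                    "residue": residue,
                    "coupling_type": params.coupling_type,
                    "calc_mean": float(np.mean(karplus(theta, params))),
                    "exp_value": exp_lookup.get(
                        (residue, params.coupling_type), np.nan
                    ),
                    "sigma": params.sigma,
                }
            )
    return CouplingTable(pd.DataFrame(rows, columns=list(CouplingTable._COLUMNS)))


def chi2_score(table: CouplingTable, reduced: bool = True) -> float:
    """Sum of sigma-normalised squared deviations; mean when reduced."""
    rows = table.table.dropna(subset=["exp_value"])
    if len(rows) == 0:
        raise ValueError("no rows with experimental values to score")
    terms = ((rows["calc_mean"] - rows["exp_value"]) / rows["sigma"]) ** 2
    total = float(terms.sum())
    return total / len(rows) if reduced else total


def coupling_curve(params: KarplusParamSet, step: float = 1.0) -> pd.DataFrame:
    """J(theta) sampled on a regular grid over (-180, 180]."""
    if step <= 0:
        raise ValueError("step must be positive")
    theta = wrap_angle(np.arange(-180.0 + step, 180.0 + step / 2, step))
    return pd.DataFrame({"theta": theta, "J": karplus(theta, params)})
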