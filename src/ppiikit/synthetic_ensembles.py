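"""Synthetic dihedral ensembles with known per-residue basin occupancies.

These ensembles stand in for MD trajectories: for every frame and residue
a conformational basin (PPII, alphaR, alphaL, beta or coil) is drawn from
the residue's propensity weights and (phi, psi) is then drawn from a
wrapped normal centred on the basin.  Omega is drawn near +180 degrees
(trans) or, with probability ``cis_fraction``, near 0 (cis).  Draws are
independent across frames and residues — a deliberate simplification of
real MD, adequate because every downstream statistic is a frame-weighted
average.

Terminal torsions (phi of residue 1, psi/omega of the last residue) are
emitted as NaN, matching what a coordinate-derived ensemble provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DihedralSeries, wrap_angle

__all__ = [
    "BasinDefinition",
    "PropensityProfile",
    "SyntheticSpec",
    "BASIN_NAMES",
    "default_basins",
    "uniform_profile",
    "proline_biased_profile",
    "sample_ensemble",
    "make_forcefield_family",
]

BASIN_NAMES = ("PPII", "alphaR", "alphaL", "beta", "coil")

_OMEGA_SPREAD = 5.0  # degrees, wrapped-normal spread of the omega draw


@dataclass(frozen=True)
class BasinDefinition:
    """A (phi, psi) basin: wrapped-normal centre and spread in degrees."""

    name: str
    mean_phi: float
    mean_psi: float
    spread_phi: float = 10.0
    spread_psi: float = 10.0

    def __post_init__(self) -> None:
        if self.name not in BASIN_NAMES:
            raise ValueError(f"unknown basin name {self.name!r}")
        if self.spread_phi <= 0 or self.spread_psi <= 0:
            raise ValueError("basin spreads must be positive")
        for mean in (self.mean_phi, self.mean_psi):
            if not (-180.0 < mean <= 180.0):
                raise ValueError("basin means must lie in (-180, 180]")


def default_basins(spread: float = 10.0) -> list[BasinDefinition]:
    """Five basins centred on the classification windows.

    PPII sits at the ideal PPII backbone (-75, +145); alphaR, alphaL and
    beta sit at the centres of their windows; coil sits at (+150, 0),
    outside every window.
    """
    return [
        BasinDefinition("PPII", -75.0, 145.0, spread, spread),
        BasinDefinition("alphaR", -60.0, -45.0, spread, spread),
        BasinDefinition("alphaL", 60.0, 45.0, spread, spread),
        BasinDefinition("beta", -142.0, 142.0, spread, spread),
        BasinDefinition("coil", 150.0, 0.0, spread, spread),
    ]


@dataclass
class PropensityProfile:
    """Per-residue basin weights for a peptide sequence."""

    sequence: str
    weights: list[dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.sequence):
            raise ValueError("need one weight mapping per residue")
        for r, mapping in enumerate(self.weights, start=1):
            if any(w < 0 for w in mapping.values()):
                raise ValueError(f"residue {r}: negative basin weight")
            total = sum(mapping.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"residue {r}: basin weights sum to {total!r}, expected 1"
                )
            unknown = set(mapping) - set(BASIN_NAMES)
            if unknown:
                raise ValueError(f"residue {r}: unknown basins {sorted(unknown)}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def uniform_profile(sequence: str, weights: dict[str, float]) -> PropensityProfile:
    """Same basin weights at every residue."""
    return PropensityProfile(sequence, [dict(weights) for _ in sequence])


def proline_biased_profile(
    sequence: str,
    ppii_base: float = 0.30,
    ppii_pro: float = 0.75,
    neighbour_boost: float = 0.10,
    coil_basin: str = "coil",
) -> PropensityProfile:
    """PPII weight raised at proline positions (and a little next to them).

    Emulates the observation that PPII content tracks the proline content
    and localises around the Pro residues; the remaining weight goes to
    ``coil_basin``.
    """
    sequence = sequence.upper()
    n = len(sequence)
    weights = []
    for i in range(n):
        if sequence[i] == "P":
            ppii = ppii_pro
        else:
            neighbours_pro = (i > 0 and sequence[i - 1] == "P") or (
                i + 1 < n and sequence[i + 1] == "P"
            )
            ppii = ppii_base + (neighbour_boost if neighbours_pro else 0.0)
        ppii = min(max(ppii, 0.0), 1.0)
        weights.append({"PPII": ppii, coil_basin: 1.0 - ppii})
    return PropensityProfile(sequence, weights)


@dataclass
class SyntheticSpec:
    """Everything needed to draw one labelled ensemble reproducibly."""

    profile: PropensityProfile
    n_frames: int
    seed: int
    cis_fraction: float = 0.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise ValueError("cis_fraction must lie in [0, 1]")
        if not self.label:
            raise ValueError("label must be nonempty")


def sample_ensemble(
    spec: SyntheticSpec, basins: list[BasinDefinition] | None = None
) -> DihedralSeries:
    """Draw a DihedralSeries from the spec; identical inputs give identical output."""
    basins = basins if basins is not None else default_basins()
    by_name = {b.name: b for b in basins}
    used = {name for mapping in spec.profile.weights for name in mapping}
    missing = used - set(by_name)
    if missing:
        raise ValueError(f"profile uses basins without definitions: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    n_frames, n_res = spec.n_frames, spec.profile.n_residues
    phi = np.empty((n_frames, n_res))
    psi = np.empty((n_frames, n_res))

    for r, mapping in enumerate(spec.profile.weights):
        names = sorted(mapping)
        probs = np.array([mapping[n] for n in names])
        choice = rng.choice(len(names), size=n_frames, p=probs)
        for k, name in enumerate(names):
            basin = by_name[name]
            sel = choice == k
            count = int(sel.sum())
            phi[sel, r] = rng.normal(basin.mean_phi, basin.spread_phi, count)
            psi[sel, r] = rng.normal(basin.mean_psi, basin.spread_psi, count)

    cis = rng.random((n_frames, n_res)) < spec.cis_fraction
    omega_centre = np.where(cis, 0.0, 180.0)
    omega = omega_centre + rng.normal(0.0, _OMEGA_SPREAD, (n_frames, n_res))

    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    omega = wrap_angle(omega)
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan
    omega[:, -1] = np.nan
    return DihedralSeries(
        phi, psi, omega, label=spec.label, sequence=spec.profile.sequence
    )


def make_forcefield_family(
    base: PropensityProfile,
    perturbations: list[tuple[str, dict[str, float]]],
    n_frames: int,
    seed: int,
    basins: list[BasinDefinition] | None = None,
    cis_fraction: float = 0.0,
) -> list[DihedralSeries]:
    """One ensemble per perturbation, emulating force fields that differ
    only in their basin preferences.

    Each perturbation is ``(label, {basin: weight shift})``; the shifts
    are added to every residue's weights and the result renormalised.  A
    shift driving any weight negative is a hard error.
    """
    ensembles = []
    for k, (label, shifts) in enumerate(perturbations):
        new_weights = []
        for r, mapping in enumerate(base.weights, start=1):
            shifted = dict(mapping)
            for name, delta in shifts.items():
                shifted[name] = shifted.get(name, 0.0) + delta
            if any(w < -1e-12 for w in shifted.values()):
                raise ValueError(
                    f"perturbation {label!r} drives a weight negative at residue {r}"
                )
            total = sum(shifted.values())
            new_weights.append({n: max(w, 0.0) / total for n, w in shifted.items()})
        profile = PropensityProfile(base.sequence, new_weights)
        spec = SyntheticSpec(
            profile, n_frames, seed=(seed + 1009 * k) % (2**31 - 1),
            cis_fraction=cis_fraction, label=label,
        )
        ensembles.append(sample_ensemble(spec, basins))
    return ensembles
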