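"""Cross-ensemble comparison: dihedral PCA, free-energy surfaces and
GROMOS clustering with per-source cluster populations.

Ensembles from different sources ("force fields") are concatenated and
projected onto common principal components computed from the cosine and
sine of every defined backbone dihedral, so that all sources share one
low-dimensional map.  Conformations are clustered with the greedy
neighbour-count (GROMOS / Daura et al.) algorithm, with the distance
cutoff chosen by scanning until the combined population of the top
clusters is closest to a target fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA

from .core import DihedralSeries

__all__ = [
    "PCAProjection",
    "ClusterResult",
    "dihedral_features",
    "pca_concat",
    "free_energy_surface",
    "pairwise_rmsd",
    "gromos_cluster",
    "select_cutoff",
    "weighted_cluster_populations",
]

logger = logging.getLogger(__name__)


def dihedral_features(
    dihedrals: DihedralSeries, include_omega: bool = False
) -> np.ndarray:
    """Per-frame feature matrix of (cos, sin) of every defined torsion.

    Torsion columns that are undefined in any frame (the chain termini)
    are dropped entirely, so the feature layout is identical across
    frames and across ensembles of the same peptide.
    """
    angle_sets = [dihedrals.phi, dihedrals.psi]
    if include_omega:
        angle_sets.append(dihedrals.omega)
    blocks = []
    for angles in angle_sets:
        keep = np.all(np.isfinite(angles), axis=0)
        radians = np.deg2rad(angles[:, keep])
        blocks.append(np.cos(radians))
        blocks.append(np.sin(radians))
    features = np.hstack(blocks)
    if features.shape[1] == 0:
        raise ValueError("no defined torsions to featurise")
    return features


@dataclass
class PCAProjection:
    """Scores and metadata of a PCA on concatenated labelled ensembles."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    source_labels: np.ndarray
    mean: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")
        if evr.sum() > 1.0 + 1e-9:
            raise ValueError("explained-variance fractions must sum to at most 1")

    def source_scores(self, source: str) -> np.ndarray:
        mask = self.source_labels == source
        if not mask.any():
            raise ValueError(f"no frames from source {source!r}")
        return self.scores[mask]

    def to_dict(self) -> dict:
        return {
            "kind": "PCAProjection",
            "scores": np.asarray(self.scores).tolist(),
            "loadings": np.asarray(self.loadings).tolist(),
            "explained_variance_ratio": np.asarray(
                self.explained_variance_ratio
            ).tolist(),
            "source_labels": np.asarray(self.source_labels).astype(str).tolist(),
            "mean": np.asarray(self.mean).tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PCAProjection":
        return cls(
            scores=np.array(data["scores"], dtype=float),
            loadings=np.array(data["loadings"], dtype=float),
            explained_variance_ratio=np.array(
                data["explained_variance_ratio"], dtype=float
            ),
            source_labels=np.array(data["source_labels"], dtype=str),
            mean=np.array(data["mean"], dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PCAProjection):
            return NotImplemented
        return all(
            np.array_equal(np.asarray(a), np.asarray(b))
            for a, b in (
                (self.scores, other.scores),
                (self.loadings, other.loadings),
                (self.explained_variance_ratio, other.explained_variance_ratio),
                (self.source_labels, other.source_labels),
                (self.mean, other.mean),
            )
        )


def pca_concat(
    ensembles: list[DihedralSeries],
    n_components: int = 2,
    include_omega: bool = False,
) -> PCAProjection:
    """Common-component PCA on the concatenation of labelled ensembles."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    n_res = {e.n_residues for e in ensembles}
    if len(n_res) != 1:
        raise ValueError("all ensembles must have the same residue count")
    features = np.vstack(
        [dihedral_features(e, include_omega=include_omega) for e in ensembles]
    )
    labels = np.concatenate(
        [np.repeat(e.label, e.n_frames) for e in ensembles]
    )
    if features.shape[0] < n_components:
        raise ValueError("fewer frames than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features)
    return PCAProjection(
        scores=scores,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        source_labels=labels,
        mean=pca.mean_,
    )


def free_energy_surface(
    projection: PCAProjection,
    source: str,
    bins: int = 40,
    temperature: float = 300.0,
):
    """Relative free energy -ln(p/p_max) on the (PC1, PC2) plane, in kT.

    Returns ``(surface, pc1_edges, pc2_edges, temperature)``; empty bins
    are masked.  The temperature is carried as metadata only — the
    surface itself is in units of kT.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    scores = projection.source_scores(source)
    counts, x_edges, y_edges = np.histogram2d(scores[:, 0], scores[:, 1], bins=bins)
    with np.errstate(divide="ignore"):
        surface = np.ma.masked_where(counts == 0, -np.log(counts / counts.max()))
    return surface, x_edges, y_edges, temperature


def pairwise_rmsd(coordinates: np.ndarray) -> np.ndarray:
    """All-against-all best-fit RMSD matrix (same units as the input).

    ``coordinates`` has shape (n_frames, n_atoms, 3); every pair is
    optimally superposed (Kabsch) before the RMSD is taken.
    """
    coords = np.asarray(coordinates, dtype=float)
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    centred = coords - coords.mean(axis=1, keepdims=True)
    matrix = np.zeros((n_frames, n_frames))
    for i in range(n_frames):
        for j in range(i + 1, n_frames):
            _, rssd = Rotation.align_vectors(centred[i], centred[j])
            matrix[i, j] = matrix[j, i] = rssd / np.sqrt(n_atoms)
    return matrix


@dataclass
class ClusterResult:
    """GROMOS clustering output.

    ``assignments`` holds 1-based cluster ids per frame, with id 1 the
    largest cluster; ``centers`` and ``sizes`` are indexed by cluster id
    minus one.  ``source_weights`` (optional) maps cluster id to
    {source: fraction} as filled in by ``weighted_cluster_populations``.
    """

    assignments: np.ndarray
    centers: list[int]
    sizes: list[int]
    cutoff: float
    source_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if sum(self.sizes) != self.assignments.size:
            raise ValueError("cluster sizes must sum to the frame count")
        if any(s2 > s1 for s1, s2 in zip(self.sizes, self.sizes[1:])):
            raise ValueError("cluster sizes must be non-increasing with id")
        for cid, center in enumerate(self.centers, start=1):
            if self.assignments[center] != cid:
                raise ValueError(f"center of cluster {cid} is not a member")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def top_fraction(self, k: int) -> float:
        """Combined population fraction of the k largest clusters."""
        return sum(self.sizes[:k]) / self.assignments.size

    def to_dict(self) -> dict:
        return {
            "kind": "ClusterResult",
            "assignments": self.assignments.tolist(),
            "centers": list(self.centers),
            "sizes": list(self.sizes),
            "cutoff": self.cutoff,
            "source_weights": {
                str(cid): dict(w) for cid, w in self.source_weights.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClusterResult":
        return cls(
            assignments=np.array(data["assignments"], dtype=int),
            centers=list(data["centers"]),
            sizes=list(data["sizes"]),
            cutoff=float(data["cutoff"]),
            source_weights={
                int(cid): dict(w) for cid, w in data.get("source_weights", {}).items()
            },
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterResult):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _distance_matrix(data: np.ndarray, metric: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if metric == "euclidean":
        if data.ndim != 2:
            raise ValueError("euclidean metric expects a (n_frames, d) matrix")
        matrix = squareform(pdist(data))
    elif metric == "rmsd":
        if data.ndim != 3:
            raise ValueError("rmsd metric expects (n_frames, n_atoms, 3) coordinates")
        matrix = pairwise_rmsd(data)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.any(~np.isfinite(matrix)):
        raise ValueError("non-finite pairwise distances")
    return matrix


def gromos_cluster(
    data: np.ndarray,
    cutoff: float,
    metric: str = "euclidean",
    distance_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering (GROMOS / Daura et al.).

    Repeatedly the unassigned frame with the most unassigned neighbours
    at distance < cutoff (strict; a centre counts itself) becomes a
    cluster centre; it and its neighbours form the cluster and are
    removed.  Ties go to the lowest frame index.  Cluster ids are
    re-ordered by decreasing size afterwards.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    matrix = (
        np.asarray(distance_matrix, dtype=float)
        if distance_matrix is not None
        else _distance_matrix(data, metric)
    )
    if np.any(~np.isfinite(matrix)):
        raise ValueError("non-finite pairwise distances")
    n_frames = matrix.shape[0]
    if n_frames < 1:
        raise ValueError("need at least one frame")

    neighbours = matrix < cutoff  # diagonal is True: centres count themselves
    unassigned = np.ones(n_frames, dtype=bool)
    raw_ids = np.zeros(n_frames, dtype=int)
    raw_centers: list[int] = []
    cluster = 0
    while unassigned.any():
        counts = (neighbours & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbours[center] & unassigned
        cluster += 1
        raw_ids[members] = cluster
        raw_centers.append(center)
        unassigned[members] = False

    sizes = np.array([(raw_ids == c).sum() for c in range(1, cluster + 1)])
    order = np.argsort(-sizes, kind="stable")
    remap = {int(old) + 1: rank + 1 for rank, old in enumerate(order)}
    assignments = np.array([remap[c] for c in raw_ids])
    centers = [raw_centers[int(old)] for old in order]
    return ClusterResult(
        assignments=assignments,
        centers=centers,
        sizes=sorted(sizes.tolist(), reverse=True),
        cutoff=float(cutoff),
    )


def select_cutoff(
    data: np.ndarray,
    metric: str = "euclidean",
    step: float = 0.05,
    top_k: int = 8,
    target_fraction: float = 0.5,
    distance_matrix: np.ndarray | None = None,
) -> float:
    """Scan cutoffs in increments of ``step`` for the one whose top-k
    combined cluster population is closest to ``target_fraction``.

    Ties prefer the smaller cutoff.  If the scan reaches the maximum
    pairwise distance without the population bracketing the target, the
    best cutoff found is returned with a logged warning.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    matrix = (
        np.asarray(distance_matrix, dtype=float)
        if distance_matrix is not None
        else _distance_matrix(data, metric)
    )
    max_distance = matrix.max()
    if matrix.shape[0] == 1 or max_distance == 0:
        logger.warning(
            "degenerate input for cutoff selection: every frame falls in one "
            "cluster at the first cutoff (population 1.0)"
        )
        return float(step)
    best_cutoff, best_gap = None, np.inf
    bracketed = False
    cutoff = step
    while True:
        result = gromos_cluster(None, cutoff, distance_matrix=matrix)
        fraction = result.top_fraction(top_k)
        gap = abs(fraction - target_fraction)
        if gap < best_gap - 1e-12:
            best_cutoff, best_gap = cutoff, gap
        if fraction >= target_fraction:
            bracketed = True
        if fraction >= 1.0 or cutoff > max_distance:
            break
        cutoff += step
    if not bracketed:
        logger.warning(
            "cutoff scan exhausted at %.3f without top-%d population reaching "
            "%.2f; returning best found (%.3f)",
            cutoff, top_k, target_fraction, best_cutoff,
        )
    return float(best_cutoff)


def weighted_cluster_populations(
    result: ClusterResult,
    source_labels,
    top_k: int = 8,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cluster per-source composition and per-source top-k totals.

    Returns ``(composition, topk_population)``: ``composition`` has one
    row per (cluster, source) with the fraction of the cluster's frames
    contributed by that source (summing to 1 within each cluster);
    ``topk_population`` maps each source to the fraction of its own
    frames that fall inside the top-k clusters.  The per-cluster weights
    are also stored on ``result.source_weights``.
    """
    labels = np.asarray(source_labels)
    if labels.size != result.assignments.size:
        raise ValueError("need one source label per frame")
    sources = list(dict.fromkeys(labels.tolist()))
    rows = []
    for cid in range(1, result.n_clusters + 1):
        members = result.assignments == cid
        weights = {}
        for source in sources:
            weights[source] = float(np.mean(labels[members] == source))
            rows.append(
                {"cluster": cid, "source": source, "fraction": weights[source]}
            )
        result.source_weights[cid] = weights
    topk = {}
    in_top = result.assignments <= min(top_k, result.n_clusters)
    for source in sources:
        own = labels == source
        topk[source] = float(np.mean(in_top[own]))
    return pd.DataFrame(rows), topk
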