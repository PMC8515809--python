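"""Dihedral PCA, free-energy surfaces and GROMOS clustering."""

import numpy as np
import pytest

import ppiikit as pk
from ppiikit.core import DihedralSeries
from ppiikit.ensemble_compare import ClusterResult


def brute_force_gromos(distance_matrix, cutoff):
    """Independent re-implementation: explicit loops over the matrix."""
    n = distance_matrix.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_center, best_members = None, None
        for candidate in sorted(unassigned):
            members = {
                j for j in unassigned if distance_matrix[candidate, j] < cutoff
            }
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = candidate, members
        clusters.append((best_center, sorted(best_members)))
        unassigned -= best_members
    clusters.sort(key=lambda item: -len(item[1]))
    assignments = np.empty(n, dtype=int)
    for cid, (_, members) in enumerate(clusters, start=1):
        assignments[members] = cid
    centers = [c for c, _ in clusters]
    return assignments, centers


def test_dihedral_features_shapes_and_identity():
    phi = np.array([[np.nan, 0.0, -75.0]])
    psi = np.array([[145.0, 0.0, np.nan]])
    omega = np.array([[180.0, 180.0, np.nan]])
    series = DihedralSeries(phi, psi, omega)
    features = pk.dihedral_features(series)
    # 2 defined phi columns + 2 defined psi columns -> 8 features
    assert features.shape == (1, 8)
    # every (cos, sin) pair has unit norm
    cos_cols = features[0, [0, 1, 4, 5]]
    sin_cols = features[0, [2, 3, 6, 7]]
    assert np.allclose(cos_cols**2 + sin_cols**2, 1.0)


def test_features_all_zero_angles():
    series = DihedralSeries(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((2, 3)))
    features = pk.dihedral_features(series, include_omega=True)
    n = features.shape[1] // 2
    # cos blocks are 1, sin blocks are 0, for every angle
    assert np.allclose(np.sort(features, axis=1)[:, :n], 0.0)
    assert np.allclose(np.sort(features, axis=1)[:, n:], 1.0)


def _blob_ensembles(rng, centres, n_frames=60, n_res=6, spread=3.0):
    out = []
    for k, (phi0, psi0) in enumerate(centres):
        phi = pk.wrap_angle(rng.normal(phi0, spread, (n_frames, n_res)))
        psi = pk.wrap_angle(rng.normal(psi0, spread, (n_frames, n_res)))
        omega = np.full((n_frames, n_res), 180.0)
        out.append(DihedralSeries(phi, psi, omega, label=f"src{k}"))
    return out


def test_pca_duplicated_ensemble_symmetric(rng):
    (ensemble,) = _blob_ensembles(rng, [(-75, 145)])
    twin = DihedralSeries(
        ensemble.phi.copy(), ensemble.psi.copy(), ensemble.omega.copy(), label="copy"
    )
    projection = pk.pca_concat([ensemble, twin])
    a = projection.source_scores("src0")
    b = projection.source_scores("copy")
    assert np.allclose(a, b)


def test_pca_separates_two_point_clouds(rng):
    ensembles = _blob_ensembles(rng, [(-75, 145), (60, -60)], spread=1.0)
    projection = pk.pca_concat(ensembles)
    a = projection.source_scores("src0")[:, 0]
    b = projection.source_scores("src1")[:, 0]
    assert a.max() < b.min() or b.max() < a.min()


def test_pca_explained_variance_matches_eigendecomposition(rng):
    ensembles = _blob_ensembles(rng, [(-75, 145), (-60, -45)], spread=15.0)
    features = np.vstack([pk.dihedral_features(e) for e in ensembles])
    projection = pk.pca_concat(ensembles, n_components=4)
    centred = features - features.mean(axis=0)
    eigenvalues = np.linalg.eigvalsh(np.cov(centred, rowvar=False))[::-1]
    expected = eigenvalues[:4] / eigenvalues.sum()
    assert np.allclose(projection.explained_variance_ratio, expected, atol=1e-10)


def test_pca_scores_are_centred(rng):
    ensembles = _blob_ensembles(rng, [(-75, 145), (-60, -45)])
    projection = pk.pca_concat(ensembles)
    assert np.allclose(projection.scores.mean(axis=0), 0.0, atol=1e-9)


def test_pca_rejects_too_few_frames():
    series = DihedralSeries([[0.0, 10.0]], [[20.0, 30.0]], [[180.0, 180.0]])
    with pytest.raises(ValueError, match="fewer frames"):
        pk.pca_concat([series], n_components=5)


def test_free_energy_surface_minimum_is_zero(rng):
    ensembles = _blob_ensembles(rng, [(-75, 145), (60, -60)])
    projection = pk.pca_concat(ensembles)
    surface, _, _, temperature = pk.free_energy_surface(projection, "src0", bins=12)
    assert surface.min() == 0.0
    assert temperature == 300.0


def test_free_energy_surface_masks_empty_bins(rng):
    ensembles = _blob_ensembles(rng, [(-75, 145), (60, -60)], spread=0.5)
    projection = pk.pca_concat(ensembles)
    surface, _, _, _ = pk.free_energy_surface(projection, "src0", bins=10)
    assert surface.mask.any()  # far-away bins hold no frames


def test_free_energy_surface_two_equal_modes():
    scores = np.array([[-1.0, 0.0]] * 10 + [[1.0, 0.0]] * 10)
    projection = pk.PCAProjection(
        scores=scores,
        loadings=np.zeros((2, 4)),
        explained_variance_ratio=np.array([0.6, 0.2]),
        source_labels=np.array(["x"] * 20),
    )
    surface, _, _, _ = pk.free_energy_surface(projection, "x", bins=2)
    assert np.count_nonzero(surface == 0.0) == 2


def test_gromos_all_identical_frames():
    result = pk.gromos_cluster(np.zeros((7, 3)), cutoff=0.5)
    assert result.n_clusters == 1
    assert result.sizes == [7]
    assert result.centers == [0]


def test_gromos_tiny_cutoff_gives_singletons(rng):
    data = rng.normal(size=(12, 4))
    min_dist = np.min(
        [np.linalg.norm(a - b) for i, a in enumerate(data) for b in data[i + 1:]]
    )
    result = pk.gromos_cluster(data, cutoff=min_dist * 0.5)
    assert result.n_clusters == 12
    assert result.sizes == [1] * 12


def test_gromos_two_separated_blobs(rng):
    blob_a = rng.normal(0.0, 0.3, size=(25, 5))
    blob_b = rng.normal(8.0, 0.3, size=(15, 5))
    data = np.vstack([blob_a, blob_b])
    result = pk.gromos_cluster(data, cutoff=3.0)
    assert result.n_clusters == 2
    assert result.sizes == [25, 15]
    assert np.all(result.assignments[:25] == 1)
    assert np.all(result.assignments[25:] == 2)


def test_gromos_matches_brute_force_on_random_data(rng):
    from scipy.spatial.distance import pdist, squareform

    data = rng.normal(size=(80, 6))
    matrix = squareform(pdist(data))
    for cutoff in (1.5, 2.5, 3.5):
        result = pk.gromos_cluster(data, cutoff=cutoff)
        assignments, centers = brute_force_gromos(matrix, cutoff)
        assert result.assignments.tolist() == assignments.tolist()
        assert result.centers == centers


def test_gromos_rmsd_metric_clusters_conformers():
    ppii = pk.build_ideal_chain(8, -75.0, 145.0, 180.0)
    alpha = pk.build_ideal_chain(8, -57.0, -47.0, 180.0)
    frames = np.concatenate([
        np.repeat(ppii.coords.reshape(1, -1, 3), 5, axis=0),
        np.repeat(alpha.coords.reshape(1, -1, 3), 3, axis=0),
    ])
    matrix = pk.pairwise_rmsd(frames)
    assert matrix[0, 4] == pytest.approx(0.0, abs=1e-9)
    assert matrix[0, 5] > 1.0
    result = pk.gromos_cluster(frames, cutoff=1.0, metric="rmsd")
    assert result.n_clusters == 2
    assert result.sizes == [5, 3]


def test_pairwise_rmsd_is_superposition_invariant(rng):
    from scipy.spatial.transform import Rotation

    frame = rng.normal(size=(10, 3))
    rotated = Rotation.from_euler("zyx", [0.7, -0.2, 1.1]).apply(frame) + 5.0
    matrix = pk.pairwise_rmsd(np.stack([frame, rotated]))
    assert matrix[0, 1] == pytest.approx(0.0, abs=1e-9)


def test_cluster_result_invariants_enforced():
    with pytest.raises(ValueError, match="sum"):
        ClusterResult(np.array([1, 1, 2]), centers=[0, 2], sizes=[2, 2], cutoff=1.0)
    with pytest.raises(ValueError, match="non-increasing"):
        ClusterResult(np.array([1, 2, 2]), centers=[0, 1], sizes=[1, 2], cutoff=1.0)


def test_gromos_permutation_equivariant(rng):
    data = rng.normal(size=(30, 4))
    result = pk.gromos_cluster(data, cutoff=2.0)
    perm = rng.permutation(30)
    permuted = pk.gromos_cluster(data[perm], cutoff=2.0)
    # un-permute: partitions must coincide (ids may swap among equal sizes)
    original_sets = {
        frozenset(np.where(result.assignments == c)[0])
        for c in range(1, result.n_clusters + 1)
    }
    unpermuted = np.empty(30, dtype=int)
    unpermuted[perm] = permuted.assignments
    permuted_sets = {
        frozenset(np.where(unpermuted == c)[0])
        for c in range(1, permuted.n_clusters + 1)
    }
    assert original_sets == permuted_sets


def test_select_cutoff_exact_hit(rng):
    # 16 frames: one blob of 8 at distance ~0, plus 8 isolated outliers;
    # at a small cutoff the top-8 clusters hold blob(8) + 7 singletons
    data = np.vstack([
        rng.normal(0.0, 0.001, size=(8, 2)),
        np.arange(8)[:, None] * np.array([100.0, 0.0]) + 50.0,
    ])
    cutoff = pk.select_cutoff(data, step=0.05, top_k=8, target_fraction=0.9375)
    result = pk.gromos_cluster(data, cutoff)
    assert result.top_fraction(8) == pytest.approx(15 / 16)
    assert cutoff == pytest.approx(0.05)


def test_select_cutoff_single_frame_warns(caplog):
    with caplog.at_level("WARNING"):
        cutoff = pk.select_cutoff(np.zeros((1, 2)), step=0.05)
    assert cutoff == pytest.approx(0.05)
    assert "degenerate" in caplog.text


def test_select_cutoff_matches_exhaustive_scan(rng):
    data = np.vstack([
        rng.normal(0.0, 0.4, size=(20, 3)),
        rng.normal(4.0, 0.4, size=(12, 3)),
        rng.normal(-5.0, 0.4, size=(8, 3)),
    ])
    step, top_k, target = 0.1, 2, 0.5
    chosen = pk.select_cutoff(data, step=step, top_k=top_k, target_fraction=target)
    from scipy.spatial.distance import pdist, squareform

    matrix = squareform(pdist(data))
    best, best_gap = None, np.inf
    cutoff = step
    while cutoff <= matrix.max() + step:
        frac = pk.gromos_cluster(data, cutoff).top_fraction(top_k)
        gap = abs(frac - target)
        if gap < best_gap - 1e-12:
            best, best_gap = cutoff, gap
        cutoff += step
    assert chosen == pytest.approx(best)


def test_weighted_populations_counting():
    result = ClusterResult(
        np.array([1, 1, 1, 1, 2, 2]), centers=[0, 4], sizes=[4, 2], cutoff=1.0
    )
    labels = np.array(["A", "A", "A", "B", "B", "B"])
    composition, topk = pk.weighted_cluster_populations(result, labels, top_k=1)
    first = composition[composition["cluster"] == 1].set_index("source")["fraction"]
    assert first["A"] == pytest.approx(0.75)
    assert first["B"] == pytest.approx(0.25)
    # top-1 cluster holds 3 of A's 3 frames and 1 of B's 3 frames
    assert topk["A"] == pytest.approx(1.0)
    assert topk["B"] == pytest.approx(1 / 3)


def test_weighted_populations_single_source():
    result = ClusterResult(
        np.array([1, 1, 2]), centers=[0, 2], sizes=[2, 1], cutoff=1.0
    )
    composition, _ = pk.weighted_cluster_populations(result, ["only"] * 3)
    assert np.allclose(composition["fraction"], 1.0)


def test_dominant_source_per_cluster_matches_generator(rng):
    base = pk.uniform_profile("A" * 8, {"PPII": 0.5, "alphaR": 0.5})
    family = pk.make_forcefield_family(
        base,
        [("ppii-rich", {"PPII": 0.45, "alphaR": -0.45}),
         ("alpha-rich", {"PPII": -0.45, "alphaR": 0.45})],
        n_frames=120,
        seed=13,
    )
    features = np.vstack([pk.dihedral_features(e) for e in family])
    labels = np.concatenate([np.repeat(e.label, e.n_frames) for e in family])
    result = pk.gromos_cluster(features, cutoff=2.0)
    composition, _ = pk.weighted_cluster_populations(result, labels)
    # the two largest clusters are each dominated by the source built to
    # prefer that basin combination
    top_two = composition[composition["cluster"] <= 2]
    dominant = top_two.loc[top_two.groupby("cluster")["fraction"].idxmax(), "source"]
    assert set(dominant) == {"ppii-rich", "alpha-rich"}
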