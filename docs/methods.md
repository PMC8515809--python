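# Methods

This note documents the models, conventions and numerical choices behind
`ppiikit`, in the order the pipeline runs.

## Ensemble representation

The central container is the `DihedralSeries`: per-frame, per-residue
backbone torsions (φ, ψ, ω) in degrees, always wrapped into (−180°, 180°].
Residue indexing is 1-based.  φ of residue 1 and ψ/ω of the last residue
require atoms from a neighbouring residue and are therefore undefined;
they are stored as NaN and excluded from every statistic, feature matrix
and coupling calculation.  Coordinate ensembles (`BackboneEnsemble`) hold
N/CA/C (optionally O) positions in Å.

## Synthetic ensembles

The generator draws, independently for every frame and residue, a
conformational basin from the residue's propensity weights and then
(φ, ψ) from a wrapped normal centred on that basin (sample unwrapped,
wrap into (−180°, 180°]).  The five shipped basins are PPII (−75°, +145°
— the ideal PPII backbone), α<sub>R</sub> (−60°, −45°), α<sub>L</sub>
(+60°, +45°), β (−142°, +142°) — each at the centre of its classification
window — and coil at (+150°, 0°), chosen so that it cannot leak into any
window at moderate spreads.  The default angular spread is 10° per axis:
wide enough to be a nontrivial test of the classifier, narrow enough that
a basin loses less than ~1% of its draws past its window edges.  ω is
drawn near +180° (trans) with spread 5°, or near 0° (cis) with
probability `cis_fraction` (default 0).

Deliberate simplifications relative to real MD: draws are uncorrelated
in time and across residues, there are no side-chain degrees of freedom,
and basin shapes are axis-aligned Gaussians on the torus.  Consequently,
passing parameter-recovery tests demonstrates that the analysis stack
measures what the generator put in; it does not validate force fields or
sampling convergence on real trajectories.  `make_forcefield_family`
produces ensembles differing only in basin weights (per-ensemble seeds
derived as `seed + 1009·k`, kept below 2³¹), emulating force fields with
different secondary-structure preferences.

## Backbone building and helix geometry

Chains are built by natural-extension (NeRF) placement with a
user-editable geometry table; the shipped defaults are standard peptide
values: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, angles N–CA–C 111.0°,
CA–C–N 116.2°, C–N–CA 121.7° (C=O 1.229 Å at 120.5° for the optional
oxygens).  Rebuilt-then-measured torsions agree with the inputs to below
10⁻⁶ degrees; built peptide bonds are verified to lie in [1.2, 1.45] Å.

Helix parameters are fitted to the CA trace (≥ 6 residues).  The axis
*direction* is taken from second differences of the trace: for any
circular helix the vectors d<sub>i+1</sub> − d<sub>i</sub> (with
d<sub>i</sub> = CA<sub>i+1</sub> − CA<sub>i</sub>) are perpendicular to
the axis, so their pairwise cross products are parallel to it.  This is
exact for ideal helices at any chain length, whereas the principal axis
of the raw point cloud tilts by a few percent when the chain does not
cover whole turns.  The axis *position* comes from a least-squares circle
fit to the CAs projected on the normal plane (the point-cloud centroid is
off-axis for partial turns).  Rise is the mean projection of successive
CA displacements on the axis; the turn angle is the mean rotation of
successive radial vectors about it; residues/turn = 360°/turn angle;
pitch = rise × residues/turn.  A mean turn angle below 1° (or a radial
distance collapsing to zero) raises a "degenerate helix" error.

Handedness is the sign of the mean CA pseudo-torsion
(CA<sub>i</sub>…CA<sub>i+3</sub>): positive → right-handed.  The signed
rotation about the fitted axis is *not* used, because at ~3 residues per
turn a rotation of +θ is indistinguishable from −(360° − θ) when the
curve is sampled only at CA positions.  Validation: the α-helix control
(−57°, −47°, +180°) gives 3.62 residues/turn, 1.55 Å rise, right-handed;
PPII (−75°, +145°, +180°) gives 2.99 residues/turn, 9.21 Å/turn pitch,
left-handed; PPI (−75°, +160°, 0°) gives 3.08 residues/turn, 5.58 Å/turn
pitch, right-handed.  All agree to four decimals with an independent
estimator (the exact screw transformation between successive N/CA/C
triads).  Note that the commonly quoted "3.3 residues/turn" for PPI
corresponds to the classic ideal-PPI dihedrals near (−83°, +158°); at
(−75°, +160°) the geometry genuinely gives ≈ 3.08.

Radius of gyration is mass-weighted over the stored backbone atoms by
default (unit weights optional) and reported in nm, as is the
end-to-end distance N(1)→C(last).

## Ramachandran classification and profiles

The four windows (README and module docstring) are validated pairwise
disjoint at construction, including edge-inclusivity: β's φ upper edge is
strict (φ < −104°), PPII's is inclusive (φ ≥ −104°), so the shared
boundary belongs to PPII.  Anything outside the windows is random coil.
One deliberate reading: a printed source of such windows may order a ψ
range as "180° ≤ ψ ≤ 104°"; the only self-consistent interpretation,
used here, is 104° ≤ ψ ≤ 180°.

The per-residue profile mimics DSSP-PPII-style assignment with a
transparent run-length rule: a residue is PPII in a frame iff it sits in
a maximal run of ≥ `min_run` consecutive PPII-window residues
(default 2); helix-like (α<sub>R</sub> ∪ α<sub>L</sub>) and β-like runs
are treated identically, everything else is coil, and undefined terminal
residues break runs.  `min_run = 1` reduces exactly to the raw window
classification.  Because the true DSSP-PPII algorithm is
hydrogen-bond-aware, absolute PPII percentages from the run rule are not
directly comparable to it; when the choice matters, report min_run ∈
{1, 2, 3} side by side.

Ramachandran density maps are 2-D histograms on (−180°, 180°]² (default
bin width 4°) divided by their maximum count, so the peak is exactly 1.

## Scalar couplings

J(θ) = A·cos²(θ+δ) + B·cos(θ+δ) + C is evaluated per frame on the
selected torsion and then averaged; the nonlinearity makes ⟨J(θ)⟩ ≠
J(⟨θ⟩), which a two-point counterexample test pins down.  Selector
conventions: the four ³J couplings (HNHα, HαC′, HNC′, HNCβ) report on
φ(i) with δ = −60°, +120°, +180°, +60° respectively; ¹J<sub>NCα</sub> on
ψ(i); ²J<sub>NCα</sub> and ³J<sub>HNCα</sub> on ψ(i−1), following the
standard sequential-assignment protocol.  Rows whose torsion is
undefined (φ at residue 1, ψ at the C-terminus, ψ(i−1) at residue 1) are
omitted with a warning.

Coefficients, δ, and the parametrization error σ are **data, not code**:
they ship in `src/ppiikit/data/karplus.yaml` with per-entry citation
tags (Hu & Bax 1997; Wirmer & Schwalbe 2002; Ding & Gronenborn 2004;
Hennig et al. 2000) and can be replaced wholesale via
`load_karplus_registry(path)`.  The χ² score divides by the number of
compared couplings by default (reduced form), since per-ensemble scores
are conventionally reported on a fixed coupling set; `reduced=False`
gives the raw sum, and the choice is printed by the CLI.  Experimental
errors are not folded into σ — the parametrization error dominates.

## PCA, free-energy surfaces, clustering

Features are the cosine and sine of every torsion that is defined in all
frames (terminal columns are dropped consistently), so each angle
contributes a unit-norm pair and no scaling is needed; the PCA is a
plain covariance PCA on mean-centred features (scikit-learn, full SVD).
Concatenating the labelled ensembles first and projecting all sources
onto the *common* components is what makes per-source score
distributions comparable.  Free-energy surfaces are −ln(p/p<sub>max</sub>)
over the (PC1, PC2) histogram of one source, in kT units with the
temperature carried only as metadata; empty bins are masked and the
minimum is exactly 0.

GROMOS (Daura et al.) clustering: repeatedly the frame with the most
neighbours at distance < cutoff (strict inequality; a centre counts
itself) seeds a cluster, the members are removed, ties go to the lowest
frame index; cluster ids are then reordered by decreasing size.  The
distance is either Euclidean on feature vectors or best-fit backbone
RMSD (N/CA/C, Kabsch superposition) — the atom selection is this
package's choice.  The cutoff-selection rule scans cutoffs upward in
fixed steps (default 0.05 nm for RMSD) and returns the one whose top-k
(default 8) combined population is closest to the target fraction
(default 50%), preferring smaller cutoffs on ties; a scan that never
brackets the target returns the best cutoff found and logs a warning.
Per-cluster source compositions are normalised within each cluster, and
the per-source top-k population is the fraction of that source's own
frames inside the top-k clusters.

## Observables and trends

Block errors follow the Flyvbjerg–Petersen doubling schedule: block
sizes double from 1 until at most `max_blocks` (default 16) blocks
remain; the error is the first standard-error-of-block-means estimate
that changes by < 5% over a doubling, or the largest-block estimate
(with a warning) when no plateau appears.  The mean is schedule-independent.

The proline trend is ordinary least squares of PPII percentage on
proline count (scipy), with r² the squared Pearson correlation and the
two-sided t-test p-value on the slope.  The localization score is
deliberately simple: mean per-residue PPII fraction at the proline
positions minus the mean over the remaining (defined) residues; 0 means
no enrichment, 1 means complete localization.

## Problem sizes and determinism

Default test and demonstration sizes — ensembles of 2,000–10,000 frames
for recovery statistics, ≤ 100 frames for clustering-oracle checks, and
13-mer peptides — were chosen so that binomial error bands are a few
tenths of a percent and every pipeline stage runs in seconds on one
core.  All stochastic steps take an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bitwise-identical
ensembles, and the dihedral CSV dialect round-trips bit-exactly
(`float_precision="round_trip"` on read, shortest-repr floats on write).

## Known limitations

* The run-length PPII assignment is not the hydrogen-bond-based
  DSSP-PPII algorithm; absolute profile percentages differ.
* No side chains, sterics or energetics anywhere; built structures are
  idealized backbones.
* The synthetic generator has no temporal autocorrelation, so
  block-error behaviour on correlated data is exercised with explicit
  AR(1) series in the tests instead.
* Helix curvature (bent vs straight helices) is not measured — only the
  global axis fit is provided.
* Pairwise RMSD is computed densely (O(n²) superpositions) and is meant
  for ensembles of at most a few thousand frames.
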