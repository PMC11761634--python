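# Methods

This note documents the models, numerical choices and limitations behind
`foldcover`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py`, not asserted.

## Fréchet distance on embeddings

Reference and sample embedding clouds are each reduced to (μ, Σ) and
compared by the Fréchet (2-Wasserstein²) distance between Gaussians,
‖μa−μb‖² + Tr(Σa+Σb−2(ΣaΣb)^{1/2}). Choices:

- **Covariance divisor n−1** (unbiased). The difference to the n divisor
  is O(1/n) and immaterial at the sample counts the metric is meant for
  (tens of thousands); unbiasedness is the cleaner default and `summarize`
  documents it.
- **Matrix square root** via the symmetrized product: with S = Σa^{1/2}
  (eigendecomposition, eigenvalues clamped at zero), the trace of
  (S Σb S)^{1/2} equals Tr((ΣaΣb)^{1/2}). The product ΣaΣb itself is
  non-symmetric; the symmetrized route is the numerically stable standard
  for Fréchet-style metrics. Eigenvalues in (−1e-8·λmax, 0) are clamped to
  0; anything more negative raises a numerical error with diagnostics
  rather than silently proceeding. The final value is clamped at 0.
- **No regularization by default**; `ridge_regularize` adds ε·I with
  ε = 1e-6·trace/d as an explicit opt-in for n close to d.
- **Oracle independence**: `synth.analytic_fpd` evaluates the closed form
  on a spec's *true* moments through scipy's general `sqrtm` on the raw
  product — a deliberately different algorithm from the estimator path, so
  the two can check each other. Estimator-vs-oracle agreement at d=8,
  n=20,000 per side is within 2% relative (acceptance suite).
- **Stratification**: FPD-D/FPD-ND require at least d+1 rows per stratum;
  smaller strata are omitted with a warning rather than producing a
  rank-deficient covariance. The gap is only reported when both exist.
- The metric is computed in the native embedding dimension; PCA is for
  plots only and never feeds the distance.

Subsample convergence draws seeded without-replacement subsets of the
sample rows and reports mean ± sd of the distance per size. On synthetic
d=20 clouds the size-2,000 mean lies within a few tenths of a percent of
the size-20,000 estimate, which is why a few thousand samples suffice in
practice.

## Built-in geometric embedding

The built-in encoder is a deterministic, rotation/translation-invariant
stand-in for learned structure encoders, not a reproduction of any of
them. Per interior residue it computes 10 channels: sin/cos of φ and ψ;
CA distances d(i, i+2) and d(i, i+3) (Å); and nearest non-adjacent
neighbor (|i−j| > 2) features — CA distance, signed sequence separation
clipped to ±16, and sin/cos of the virtual dihedral
CA(i−1)–CA(i)–CA(j)–CA(j+1). The forward-only choice of the two short-range
distances keeps the descriptor exactly 10-dimensional. Distances and
torsions are invariant by construction; the signed virtual dihedral (and
the torsions) distinguish mirror images, which pure distance features
would not. Neighbor selection is tie-robust: among candidates within
1e-6 Å of the minimal distance the lowest index wins, so symmetric
geometries keep identical descriptors under rigid transforms (verified to
1e-6 over random transforms).

The structure embedding is the per-channel mean concatenated with the
per-channel standard deviation (d = 20). External per-structure embeddings
(e.g. 128-d or 4096-d mean-pooled encoder states) enter through the same
`EmbeddingMatrix` TSV and are first-class everywhere.

PCA axes are fit on the pooled reference+sample rows so both clouds share
one plane (a reference-only fit would be blind to sample-only regions of
variance); embeddings are not standardized before PCA by default (option
available). Per-axis sign is fixed by making the largest-magnitude loading
positive, so projections are fully deterministic.

## Structural tokens and KL divergence

The built-in alphabet quantizes the 10-d residue descriptors with seeded
k-means (default A = 20 tokens, requiring ≥ 10·A descriptor rows);
centroids are sorted lexicographically so token indices are canonical.
External 20-letter structural-alphabet strings map through a fixed
letter→integer table and bypass the codebook.

Frequencies are binned by protein length — width-50 bins from 0 to 500
plus one overflow bin — since no canonical edges exist for this kind of
analysis; the bins are configurable. Bigrams pair sequence-adjacent tokens
within one sequence only, never across sequences or chain breaks
(adjacency interruptions recorded at tokenization). Laplace smoothing
(pseudocount 1 per cell) keeps the A² bigram table strictly positive and
KL finite.

KL direction is KL(reference ‖ sample): mass the reference places on
geometries the samples lack dominates, which matches the undersampling
question the metric is meant to answer; the reverse direction is reported
alongside. Aggregation across bins weights by reference token counts, so
bins with more reference data dominate, mirroring length-distribution
matching. Natural log throughout (nats).

## Motif search

Motifs are ordered sets of CA segments with per-motif σmax (default
2.0 Å) and correlation length L = 20. The dynamic threshold c(t) is linear
in σmax and equals σmax when all segments have length 1; a brute-force
triple-sum oracle confirms the implementation to 1e-12 for every segment
partition of N ≤ 8, and splitting a fixed N into more segments never
lowers c(t).

Search enumerates per segment all contiguous CA windows (never spanning a
chain break) whose segment-local optimal RMSD is ≤ the threshold, then
scores every non-overlapping one-window-per-segment combination by the
joint Kabsch RMSD of the concatenated coordinates. The per-segment prune
is a heuristic admissibility argument — a joint superposition cannot beat
a segment's own optimum — validated against exhaustive search on small
fixtures. Segments may map to windows in any sequence order by default
(`ordered=True` enforces query order); windows only need to be disjoint
(no minimum gap). Counting defaults to at most one match per structure
per motif, with a flag for all placements. A combination-count guard
(500,000) truncates candidate lists by segment-local RMSD if a degenerate
query would explode the enumeration.

Superposition is CA-only (speed; the counting signal is threshold-driven)
and excludes reflections via determinant correction. RMSD is computed from
the explicit rotated residual rather than the singular-value identity,
which loses ~8 digits to cancellation near zero. One- and two-point
segments are handled by their exact closed forms (0, and half the
length mismatch).

## Designability and TM score

A backbone is designable iff the minimum over its design RMSDs (nominally
eight designed sequences) is strictly below 2.0 Å. The RMSD convention is
CA-only after global Kabsch superposition with the identity residue
correspondence — designed and predicted structures share indexing by
construction. Sequence design and structure prediction themselves happen
outside the package; per-design tables (TSV) are the supported input, with
the coordinate-level arithmetic provided for pairs the caller supplies.

TM score uses the standard normalization d0 = 1.24(L−15)^{1/3} − 1.8 with
L the common length, and an iterative superposition refinement: global fit,
then refits on residues with d_i < 8 Å, then d_i < 2·d0, up to 20 rounds
or convergence (< 1e-6 improvement), keeping the maximum TM over
iterations. This approximates a full TM-alignment search without fragment
seeding, which is adequate for the fixed-correspondence comparisons made
here; identical structures score exactly 1. `superpose=False` scores
coordinates as given (used to verify the all-distances-equal-d0 = 0.5
construction).

## Secondary structure

Assignment is a backbone-torsion window classifier: H for
φ∈[−100,−30], ψ∈[−80,−5]; E for φ∈[−170,−90], ψ∈[90,180]∪[−180,−170];
else L; followed by minimum-run smoothing (H runs ≥ 4, E runs ≥ 3,
shorter runs → L). Termini and residues flanking chain breaks have
undefined φ or ψ and are loops. This is a deterministic, backbone-only
stand-in for hydrogen-bond-based assignment; an adapter collapses external
8-state DSSP strings (H,G,I→H; E,B→E; else L) when exactness is needed.
Content fractions are computed over all residues, including termini.

The vector field over (α, β) content bins "before" points on a grid_n ×
grid_n partition of the unit square and reports per-cell mean
displacement and count; cells with fewer than 3 pairs are flagged
low-confidence. Binning conserves total displacement exactly (tested).

## Synthetic data

The generators define the conditions everything is validated under:

- **Backbones** are built by sequential internal-coordinate (NeRF)
  placement with ideal bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å;
  N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; carbonyl O at 1.231 Å,
  120.8°, anti to the next N in the peptide plane). Torsions recompute
  from coordinates to ~1e-13 degrees. Preset classes: ideal helix
  (−57, −47), ideal strand (−139, 135), β-hairpins, and helix+loop+hairpin
  mixtures; fixture sets draw 24–48-residue structures across these
  classes with 0.05 Å Cartesian jitter.
- **Gaussian clouds** use QΛQᵀ covariances with log-uniform eigenvalues in
  [1e-3, 10], deliberately ill-conditioned to exercise the matrix square
  root.
- **Markov token streams** start at the exact stationary distribution and
  are vectorized across sequences; determinism is seed-exact.

What the fixtures do *not* emulate: side chains, sterics, realistic
Ramachandran scatter, real experimental metadata distributions, or learned
encoder geometry. Passing tests therefore demonstrate the correctness of
the metrics and machinery, not biological conclusions about any particular
generative model; real evaluations should feed real reference sets and
external embeddings/tokens through the adapters.

## Pipeline and determinism

The pipeline defaults mirror the intended study settings: reference filter
resolution < 3.0 Å, R_free < 0.25, no NMR (strict inequalities; records
missing a field are rejected with reason "missing field"); length matching
exact (tolerance 0), without replacement, falling back to with-replacement
with a warning when a length bin is exhausted; designability threshold
2.0 Å; raster grid 16; subsample sizes 500/2000/20000 where row counts
permit. Multi-chain PDBs use the first chain unless one is named; altlocs
resolve to highest occupancy (ties by identifier order); residue indexing
is 0-based sequential after parsing with author numbering kept as
metadata; chain breaks are called at CA–CA > 4.5 Å or residue-number
jumps. Each input file is treated as one domain.

Raster-grid bounds come from the union of reference and sample
projections, so empty cells are meaningful for both clouds. Every source
of randomness flows from the config seed; reports are JSON with sorted
keys, and a rerun with identical config and inputs is byte-identical.
Plots are rendered from the emitted TSV artifacts, never by recomputing
metrics.

Problem sizes in the validation suite — 20 oracle pairs at n = 20,000,
d = 20 subsample clouds, 10⁶ Markov tokens, 12-structure pipeline bundles —
were chosen as the smallest sizes at which the statistical claims are
cleanly measurable on a single CPU.

## Known limitations

- The torsion-window secondary-structure classifier disagrees with
  hydrogen-bond-based assignment on irregular elements (3-10 overlaps,
  bulged strands); use the DSSP adapter when that matters.
- The built-in embedding is low-dimensional and geometric; it separates
  coarse fold classes well but is not a substitute for learned encoders on
  subtle architectural differences.
- TM refinement has no fragment seeding, so it assumes the identity
  correspondence is the right alignment; it is not a structure-alignment
  tool.
- Motif search is exhaustive per structure and meant for desk-scale sets,
  not PDB-scale indexing.
- mmCIF, multi-model NMR ensembles, ligands and side chains are out of
  scope for parsing.
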