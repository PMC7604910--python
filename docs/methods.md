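# Methods

## Model and assumptions

`xtalcluster` treats a screening campaign as N realisations of one
underlying crystal form, each observed through a reflection-amplitude list
F_{i,n} and a refined C-alpha trace c_{j,n}. Heterogeneity — concerted
deviation of a subset of crystals from the campaign average — is assumed
to express itself as correlated deviations of either the amplitudes or
the C-alpha positions from their across-campaign means. The method makes
no physical model of *why* crystals differ (cell drift, domain motion,
soaking time, cryo conditions); it only asks whether two data sets deviate
from the average in the same direction.

Key assumptions:

- Data sets need not share a space group or exact cell; every quantity
  that depends on geometry (d-spacings, fractional coordinates) is
  computed in each data set's own cell, and only the shell *boundaries*
  are global.
- Missing observations are handled by restriction: averages run over the
  recording subsets, pairwise series over the recorded-in-both subsets.
- Amplitude comparability across data sets requires removing per-data-set
  global isotropic B-factor damping first (the scaling step); no
  anisotropic correction is attempted.

## Pipeline and parameter choices

| parameter | default | units | rationale |
|---|---|---|---|
| `d_min` | 3.5 | Å | working resolution cutoff; low-resolution structure carries the conformational signal and keeps the comparison fast and insensitive to per-crystal resolution limits |
| `n_bins` | 20 | – | equal-volume shells; enough to track exp(−B·s²/4) curvature without starving shells of common reflections |
| `min_common` | 10 | observations | below this overlap a Pearson coefficient is noise; the pair scores 0 with a warning |
| `threshold_mads` | 5 | – | outlier models flagged above median + 5·MAD of mean-Cα deviation; MAD floored at 0.1 Å so degenerate all-identical inputs flag nothing |
| `k` | user | – | the number of clusters is a scientific decision; a silhouette suggestion is logged, never applied |

Stage order: cutoff → average (unscaled) → per-set shell scaling onto that
average → one refresh of the average from the scaled sets → correlation.
The refresh matters: an average computed over unscaled sets carries the
mean B-damping of the campaign, which would otherwise leak a common
resolution-dependent trend into every difference series.

The per-shell scale k = ΣF̄ᵢ/ΣFᵢ,ₙ is the least-squares-through-origin
scale linear in F: it makes each shell's amplitude sum (hence mean over
the common subset) match the average exactly, which is precisely the
contract the B-factor-removal test asserts. The outermost shell boundary
is the radius |s| of the furthest recorded reflection, so every reflection
falls in exactly one shell.

Clamping the pairwise Pearson coefficient to [0, 1] (rather than an
affine remap) encodes that anticorrelation carries no more evidence of
shared deviation than no correlation: both score 0.

## SVD embedding and assignment

The N×N matrix M (zero diagonal) is factorised as M = U W Vᵀ with numpy's
SVD. Column signs are canonicalised (largest-magnitude entry of each U
column made positive, V flipped in step) so repeated runs and plots are
bit-reproducible; for this symmetric matrix U and V columns agree up to
the sign of the corresponding eigenvalue.

The embedding uses the rows of U restricted to three axes — by default
the three largest weights. For the *automated* k-means path the columns
are additionally multiplied by their singular values. This is a
deliberate design choice: k-means is scale-sensitive, and raw orthonormal
columns give a noise axis the same leverage as a signal axis, which
matters exactly when fewer than three axes carry structure (e.g. a
two-cluster campaign has one shared mode and one contrast axis; the third
axis is noise). Weighting is the scriptable analogue of a human picking
large-weight axes by eye in a viewer. `project_axes` itself keeps raw
columns as its default so exported embeddings remain a plain submatrix of
U; `weight=True` reproduces what the clustering consumed.

k-means runs with `n_init=10` and a fixed seed, and labels are renumbered
by descending cluster size (ties by lexicographic first member), so the
full pipeline is deterministic at fixed config + seed. The assignment-file
path accepts a `dataset_id → label` table, reproducing a manually curated
selection from an exported embedding.

Subclustering reruns matrix → SVD → assignment on a node's members with
either a recalculated average (and, in reciprocal mode, recalculated
scaling) — letting subtler within-cluster variation dominate the new
axes — or the inherited parent average. Nodes smaller than twice the
minimum cluster size are marked complete.

## Symmetry collapse

Data sets refined in symmetry-related coordinate frames must be brought
to one frame before C-alpha averages and deviations mean anything. A
subtlety drives the implementation: the naive average of a mixed-frame
collection is itself (near-)invariant under the offending operator — for
a two-fold R, the average of x and Rx lies in R's invariant subspace, and
‖x − m‖ ≈ ‖Rx − m‖ up to noise — so "pick the operator closest to the
average" cannot discriminate when frames are balanced. The first model
therefore anchors the target frame: every model adopts the operator (in
fractional coordinates, identity listed first, ties broken by list order)
minimising its mean C-alpha deviation to that anchor; choices are then
refined against the recomputed average until they stop changing (at most
5 rounds — in practice 2). At the fixed point every model holds the
operator minimising its deviation to the collection average, and a second
collapse is a no-op. Operators can be supplied directly or generated from
a space-group symbol.

## Indexing-ambiguity resolution

In lattices where two geometrically equivalent but symmetry-inequivalent
index assignments exist, each candidate remapping (e.g. k,h,−l) is scored
per data set by the *unclamped* Pearson correlation of its amplitudes
against the current average over their common indices — the sign matters
here, and a wrong orientation shows up as a sharply lower correlation.
The best remapping is adopted per set, the average is recomputed from the
adopted orientations, and the loop repeats to a fixed point (cap 10
iterations; the majority orientation wins because it dominates the
initial average). Remappings leaving fewer than `min_common` common
indices are skipped with a warning.

## Synthetic data: what it emulates, what it does not

The generator plants known structure so every stage is testable without
any external download:

- a shared log-normal amplitude spectrum (amplitudes are positive and
  right-skewed);
- per-cluster multiplicative perturbation F·exp(p·g_c) along a
  cluster-specific random direction g_c — the reciprocal-space signature
  of a concerted conformational difference;
- per-data-set isotropic damping exp(−B·s²/4) with B uniform in a range,
  cell-length jitter, multiplicative observation noise F·exp(σ·ε),
  and binomial missing observations;
- optional index remapping of a fraction of sets (indexing ambiguity);
- a random-walk C-alpha fold (3.8 Å steps, weak recentring) moved
  rigidly per cluster, with per-atom Gaussian noise and dropout.

Defaults are the study conditions of the test suite: 3 clusters × 20 data
sets, ~400 reflections (the lowest-resolution index sphere, extended to
complete resolution-tie groups so the set is closed under a=b index
swaps), 60 residues, perturbation 0.05 vs noise 0.025 (SNR 2), B ∈ (0,
30) Å², 10% missing. With `n_reflections=None` the index universe fills
the whole sphere down to the generation cutoff — used where a realistic
resolution range matters (B-factor removal checks).

Not modelled: diffraction physics (no atoms→amplitudes calculation,
partiality, solvent), anisotropy, anchored-residue effects (cluster
shifts are rigid), or correlated missingness. Passing tests therefore
demonstrate the algebra and the recovery behaviour of the method under
its own assumptions, not performance on real refinement output, where
perturbations are not isotropic in index space and noise is
resolution-dependent.

## Numerical notes and degenerate inputs

- Averaging uses exact summation over recording subsets; permutation
  invariance holds to the order of float summation (~1e-15 relative).
- A data set identical to the average (zero-variance difference series)
  scores 0 with a warning rather than NaN; identical *pairs* of noiseless
  fixtures clamp to exactly 1 or 0 (their difference series are float
  epsilon around the mean).
- Shells with no common reflections keep k = 1 and warn; a zero amplitude
  sum in an occupied shell is an error (the scale would be infinite).
- The resolution cutoff is inclusive (d ≥ d_min); shell intervals are
  half-open with the outermost closed, so boundary radii are binned
  deterministically.
- All file outputs are lexicographically sorted with locale-independent
  formatting; negative zeros are normalised before printing.

## Known limitations

- Reciprocal-mode comparison assumes the index sets overlap; campaigns
  mixing unrelated crystal forms should be split upstream.
- The automated k-means path requires the user to choose k, as the
  original manual workflow did; the silhouette hint is advisory only.
- Symmetry collapse searches only the supplied operator list; it does not
  detect operators, and translations are applied as given (no origin
  search).
- Indexing resolution assumes one orientation class dominates the initial
  average; an exactly balanced 50/50 split converges to one class but
  which class wins depends on the draw.
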