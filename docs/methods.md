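# Methods

This note documents the models, numerical choices and known limitations of
`helixcharge`, in the spirit of the model documentation that phylogenetics
and statistics packages ship alongside their APIs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shannon entropy of alignment columns

Per-column variability is H = −Σₐ pₐ log₂ pₐ over the 20 standard residues.
Gaps and X are excluded from both the numerator and the denominator, so a
column's entropy reflects only the residues actually observed there; a
21-letter variant that counts the gap character is available behind
`include_gap=True` for cross-checks against tools that include gaps. Base 2
(bits) is used throughout — the base only rescales H and never changes a
comparison. Columns with fewer than `min_n_eff` (default 4) countable
residues are skipped and counted in a skip report rather than contributing
noisy estimates.

Group differences between (family × region) entropy distributions use
two-sided pairwise Tukey HSD: q = |μᵢ − μⱼ| / √(MSE/2 · (1/nᵢ + 1/nⱼ)) with
p-values from the studentized-range distribution (k groups, N − k error df;
`scipy.stats.studentized_range`, which integrates the standard double-integral
form). Because "Tukey followed by an additional Bonferroni correction" admits
more than one reading, the package reports two columns side by side — the
Tukey-adjusted p and a Welch-t Bonferroni p over all pairs — and the compact
letter display (CLD) is built from a chosen column (default Tukey, α = 0.01).
The CLD uses the insert-and-absorb construction: start from one letter
covering all groups and split any letter containing a significantly different
pair. This guarantees the exact sharing invariant (groups share a letter iff
not significantly different), which is asserted after every call; minimal
letter count is not guaranteed. Degenerate convention: when every group has
zero within-group variance, pairs with unequal means get p = 0 and pairs with
equal means p = 1.

## Composition LDA

`CompositionLDA` is a from-scratch linear discriminant classifier on
20-dimensional amino-acid frequency vectors (X and gaps excluded from both
numerator and denominator, matching the charge-length convention below).
The pooled within-class covariance S_W (ML pooling, divide by n) receives a
ridge λI with λ = 1e-6 by default: frequency vectors sum to one, so S_W is
structurally singular and every LDA on compositions regularizes somewhere —
here the choice is surfaced as a parameter instead of being made silently.
Discriminant axes are the leading eigenvectors of the symmetric-definite
generalized problem S_B w = λ S_W w (S_B the prior-weighted between-class
scatter of the class means), rescaled to unit Euclidean norm; they remain
S_W-orthogonal, which the tests assert. Classification uses the Gaussian
discriminant with shared covariance and empirical priors. Feature
contributions are per-residue loading norms across retained axes, each axis
weighted by its eigenvalue share.

Train/test splitting is stratified per class (round(n_k · frac) training
members, at least one per class on each side) with a fixed default seed
(20240131). Both held-out and resubstitution accuracy are always reported,
because a published "accuracy ≈ X%" rarely states which one it is; the
package's own headline number is the held-out one. scikit-learn's LDA serves
as an independent cross-check in the test suite only.

## Net charge at fixed pH

Each ionizable group contributes a Henderson–Hasselbalch term:
+1/(1 + 10^(pH−pKa)) for basic groups (K, R, H, α-amino) and
−1/(1 + 10^(pKa−pH)) for acidic ones (D, E, C, Y, α-carboxyl). The default
"bjellqvist" table (D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0;
termini 7.5/3.55) mirrors the constants of Biopython's charge-at-pH routine,
and the tests verify exact agreement with it; an EMBOSS-style table ships as
an alternative, and every output row records the table id. Terminal groups
default to **off**: the analyzed segments are fragments, and although the
N-terminal helix carries a real α-amino terminus, the internal comparator
does not — symmetric treatment keeps the regions comparable. The headline
statistic is q̃ = q_net/L with L the countable residues; segments are
admitted to charge tables only when strictly longer than `min_len`
(default 100 residues). q_net is additive over concatenation (termini off)
and monotone non-increasing in pH, both asserted as properties.
Normalization is by segment length, not full-protein length; the latter is a
defensible alternative but mixes segment charge with protein size.

## Ancestral reconstruction under Brownian motion

The trait (q̃) is modeled as Brownian motion with rate σ² on a rooted tree
with branch lengths. Two routes compute the ML ancestral states:

* **GLS oracle** (`ancestral_states_gls`): with V[i,j] the shared
  root-to-MRCA path length, â₀ = (1ᵀV⁻¹y)/(1ᵀV⁻¹1), each internal node by the
  conditional-expectation formula â = â₀ + cᵀV⁻¹(y − â₀1), and
  Var(â) = σ²[d − cᵀV⁻¹c + (1 − cᵀV⁻¹1)²/(1ᵀV⁻¹1)]. O(n³), kept as the
  validation oracle.
* **Fast two-pass** (`ancestral_states_fast`): a postorder pruning pass fuses
  tip messages toward the root (accumulating the squared standardized
  contrasts and log|V| as it goes), a preorder pass redistributes the
  complement information, and fusing both at a node yields that node's
  estimate — identical to the classical construction that re-roots the tree
  at every internal node and takes the contrasts root estimate there, but in
  O(n) total. The tests require agreement with the oracle within 1e-8 on
  random trees; observed agreement is ~1e-13.

σ²_ML = (y − â₀1)ᵀV⁻¹(y − â₀1)/n (ML, divide by n, matching the standard
fast implementation in the phylogenetics toolkits; a REML variant is a
one-line change but is not exposed). CI95 = â ± 1.96√Var; the variance is
scaled by the plugged-in σ²_ML and does **not** propagate the uncertainty of
σ² itself — a documented limitation shared with the tools this reimplements.
`prepare_tree` pairs a tree with a trait table: tips without traits are
pruned (reported), polytomies are resolved to zero-length binary form
(deterministic, child order as read), and zero-length terminal branches are
floored at 1e-8 so V stays positive definite.

### Shift attenuation

`shift_summary` reports Δ = â(clade stem) − â(root). Because the single-rate
BM smoother has no jump process, a true jump δ on a stem branch is always
attenuated: with three equal-length stems meeting at the root, the root
estimate itself absorbs ≈ δ/3, capping E[Δ] near 2δ/3 even when the family
means are estimated perfectly, and the Brownian noise accumulated on the stem
branches (σ² × stem length) adds irreducible spread. At the generator
defaults (δ = −0.25, σ² = 0.002, unit stems) the median recovered Δ is about
−0.14 with sd ≈ 0.04, so Δ < δ/2 is observed in roughly two thirds of
replicates — the sign is essentially always recovered, the magnitude is not.
Anyone using Δ as an effect-size estimate should treat it as a lower bound on
|δ|; detecting the shift is better served by the sign plus the null
distribution (no-jump simulations center on zero with |median| far below
2·SE(root), which the tests verify).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
real sequences:

* **Tree.** Three Yule (pure-birth, rate 1.0) family clades of
  `n_per_family` = 120 tips each, every clade rescaled to unit height and
  attached to the root by a stem branch of length 1 — so the duplications are
  as old as the radiations are deep, and the stems are labeled
  stemI/stemII/stemIII for downstream joins. `simulate_yule_tree` itself
  keeps the natural time scale unless asked to rescale.
* **Trait.** Brownian motion from an uncharged root (q̃ = 0) with rate
  σ² = 0.002 q̃²/unit length and a deterministic jump of −0.25 on the
  family-II stem.
* **Sequences.** Each tip's N-terminal segment (length ~ Normal(120, 15),
  truncated at 101 so the >100-residue charge filter passes by construction)
  realizes its trait through the pH-7 approximation D/E ≈ −1, K/R ≈ +1:
  the charged fractions solve f_KR − f_DE = q̃ with a baseline charged
  fraction of 0.30 (charge-rich helices). When trait coupling is disabled,
  families I/III sit at the balanced baseline and family II receives absolute
  composition deltas of +0.08 (D/E) and −0.08 (K/R). Non-charged positions
  follow a per-family founder sequence with substitution noise (rate 0.12
  for families I/III, 0.30 for the more diverse family II), with
  substitutions drawn from a per-family background (Dirichlet-perturbed from
  a shared global background, concentration 150). Paralogue families are
  clades, and real families differ in overall composition beyond their
  charge; without this family-level structure, families I and III would be
  statistically identical and no composition classifier could separate them.
  The internal region is one conserved profile shared by all families (5%
  substitution noise, length 450). The alignment is exact by construction
  (N-terminal block left-aligned with trailing gaps, then the internal
  block); a geometric-gap indel mode exists for trimming tests only.
* **Reproducibility.** All randomness flows from one seed through named
  substreams (tree, trait, sequence, pae), so stages are independently
  reproducible and the same seed yields byte-identical output files.

What passing tests on this generator do **not** show: robustness to real
indel patterns and alignment error, to non-Brownian trait evolution, to
biased taxon sampling, or to secondary-structure misannotation — the
generator has none of these.

## Other numerical choices

* Clustering identity = exact matches in one optimal global alignment
  (BLOSUM62, gap open/extend 10/1) divided by the shorter sequence's length —
  the convention of the standard greedy clustering tool, which also means a
  perfect substring counts as identity 1. Greedy order: longest first, ties
  by id.
* Gap-threshold trimming keeps columns with non-gap fraction ≥ gt (the
  trimAl `-gt` convention) and returns the kept column indices for coordinate
  mapping; it is idempotent. Region trimming defaults to trim-after-split
  (each family × region block trimmed separately); the opposite order is one
  call away since both operations are exposed.
* The helix-propensity heuristic (window 7, call H when mean propensity
  > 1.03) is an acknowledged simplification standing in for an external
  neural secondary-structure predictor; it is gated behind an explicit flag
  and never used silently.
* B/Z/U/O/J are mapped to X on input with a warning; X never counts toward
  composition, charge, entropy or identity.
* PEAK per model = the mean over both interchain PAE blocks (asymmetric
  matrices are averaged, not symmetrized — equivalent for the mean); a
  min-over-entries summary ships as an alternative column. Mean and max
  aggregations across models are always both available.
* Coordinates are 0-based half-open in the library, 1-based inclusive on the
  command line, converted only at that boundary.

## Problem sizes used in validation

The shipped validation uses desk-scale problems chosen to exercise every code
path: 360-taxon synthetic datasets (120 per family) for classification,
charge and entropy; 256-tip trees × 200 replicates for rate recovery and CI
coverage; 50 random trees × 10 trait draws for the oracle-equivalence sweep;
100 seeded replicates for shift recovery and its null; 1000 resamples for the
Tukey type-I rate; 10⁵ random columns for entropy bounds.
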