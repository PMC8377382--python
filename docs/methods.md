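# Methods

This note documents the model implemented by `psfunc`, the choices made
where the method description leaves room, and what the synthetic worlds do
and do not establish.

## Usage model

For a genus with a set of in-frame coding sequences, every overlapping
3-codon window (stride one codon, in the annotated frame) is counted as a
pair *(amino-acid trimer, 9-mer)*. The stop symbol `*` is a first-class
21st residue assigned to characteristic group L, so stop-containing windows
are counted rather than discarded; internal stops are legitimate content
for metagenomic fragments whose frame is uncertain. Two conditional
frequency families are derived from the counts:

* **amino-acid trimer usage** `u_aa(t) = n(t) / Σ_{t' ~ t} n(t')`, the
  trimer's share among all *reference* trimers with the same characteristic
  trimer (one table per characteristic trimer);
* **3-codon usage** `u_codon(m | t) = n(t, m) / n(t)`, the 9-mer's share
  among all observed synonymous spellings of its trimer (one table per
  trimer).

The **trimer usage bias** is their product. Normalisation denominators are
conditional in exactly this nesting because the database is organised as
one usage table per characteristic trimer and one codon table per trimer.
Unobserved events have frequency 0 — no pseudocounts: the method's outlier
logic depends on genuine absence showing up as zero bias, and zero-valued
landscape entries are meaningful output. Zero denominators yield empty
tables, never NaN. The 3-codon usage denominator is the trimer's total
count over *all observed* synonymous 9-mers, whether or not a 9-mer also
appears in the reference hierarchy's synonymous set; restricting to the
reference set would silently inflate the usage of rare spellings.

Trimers found in CDS but absent from the reference list are excluded from
both numerator and denominator (and logged): the reference defines the
trimer universe the statistics are conditioned on.

## Query scanning

Frame *f* ∈ {1,2,3} scans the forward strand at offset *f*−1; frames 4–6
(enabled with `--frames 6`) scan the reverse complement. A sequence of
length L has `max(0, ⌊(L−offset)/3⌋ − 2)` windows per frame; window indices
are zero-based and positional, so a window omitted for containing an
ambiguity code leaves a gap rather than renumbering its successors —
indices stay comparable across references and runs. Matching is at the
amino-acid-trimer level: a window whose trimer is in the reference is
retained even if its exact 9-mer was never observed in some genus (bias 0
there). This is consistent with the worked example, where the matching
window count equals the arithmetic maximum for the frame. No frame
selection is performed; every configured frame is analysed and reported
separately, since frame ranking belongs to a separate classification step
outside this package's scope.

## PCA

The pipeline is deliberately literal rather than textbook:

* Pearson correlation is computed on the centered columns of Z; windows
  with zero variance across genera cannot be correlated and are excluded
  with a warning ("degenerate windows"), not fatal — they reappear in the
  reports with `NA` cluster ids. Only an entirely constant Z aborts.
* Eigendecomposition uses `numpy.linalg.eigh` on the symmetrised matrix;
  negative eigenvalues from rounding are clamped to 0; eigenvalue ties are
  broken stably by original order; each eigenvector's sign is fixed so its
  largest-magnitude element is positive. Output is therefore deterministic.
* **Taxon scores multiply the centered — not column-standardized — Z into
  V.** Textbook correlation PCA would standardize; the score definition
  used here is the centered product, and per-component inertia is the
  column sum of squared scores. Consequently inertia is *not* proportional
  to the eigenvalues of X, and the "80% components" (shortest leading
  prefix with cumulative inertia share ≥ 0.80) are determined by the score
  inertia. A `score_scaling="standardized"` switch restores the textbook
  behaviour (under which inertia ∝ eigenvalues, a property the tests use as
  a cross-check); the default stays `"centered"` for fidelity to the
  method's stated definitions.
* Covariance mode replaces X with the sample covariance of centered Z and
  keeps zero-variance columns.
* Contributions are `score²/inertia` per component; columns with zero
  inertia contribute an all-zero column.

## Clustering and outliers

K-means (Euclidean, `sklearn.cluster.KMeans`) runs `restarts=10` random
initialisations and keeps the best within-cluster sum of squares;
`max_iter=100`. The upstream method leaves runs nondeterministic; here a
default seed of 0 makes every run reproducible, and `--no-seed` opts back
into nondeterminism. Cluster ids are relabelled in decreasing size order
(ties by first occurrence) so reports are stable. k is clamped to
[1, n_points]; clusters emptied by the solver vanish in relabelling.

Outliers are members of clusters with ≤ 2 members — the reference analysis
counts sole members and pairs as outliers — configurable via
`--outlier-max`. CSA/ASD annotation is second-residue identity membership
in user-supplied residue sets; with empty sets every trimer is `None`.
Annotation inputs are plain TSVs so real catalytic-/allosteric-site
extracts can be swapped in without code changes.

## Demonstration statistics

* **Landscape**: per window, genera ranked by descending usage (bias or
  3-codon usage); ties keep panel order; the maximum and its genus are
  reported.
* **Nucleotide ANOVA**: per nucleotide, each window contributes its raw
  count (0–9) in the 9-mer, grouped by loading cluster; textbook one-way
  fixed-effects ANOVA. Counts and per-9-mer proportions differ by the
  constant 1/9 and give identical F, so counts are used. Zero within-group
  variance with equal means reports F = 0; with unequal means F = ∞,
  p → 0; fewer than two groups or no residual degrees of freedom is an
  error.
* **Functional segments**: segment boundaries are user-supplied TSV ranges
  — merging outliers into segments is an analyst step, not code. Per
  segment, the windows × genera usage matrix is column-centered, genus ×
  genus Pearson correlations computed, and means taken per unordered pair
  of taxonomic groups, self-pairs excluded; a single-genus group has an
  undefined (NaN) same-group mean. A summary reports mean and SD across
  segments per group pair.

## Synthetic worlds

**Codon-preference worlds** emulate the premise that usage signatures vary
broadly *between* taxonomic groups and little *within* one: each group
draws a synonymous-codon preference profile per residue (Dirichlet,
concentration 0.5 — broad), each genus perturbs its group profile by a 5%
log-normal factor, and CDS are sampled codon-by-codon. Defaults (12 genera
in 4 groups, 20 CDS of 50–150 codons per genus) keep tests under a minute;
`full_panel_spec()` mirrors a 54-genus, 13-group panel shape. These worlds
have no secondary-structure signal, no phylogenetic correlation structure
beyond the two-level group hierarchy, and uniform residue composition — a
green test establishes that the pipeline separates group-level usage
signal, not that real genera behave this way.

**Planted-outlier worlds** control the across-genus usage profile of each
query window directly: per-genus count tables are constructed so that every
window's 3-codon usage follows a common genus baseline (evenly spread on
[0.15, 0.85], plus N(0, 0.03) noise), except planted positions whose
baseline is permuted across genera and mixed in with weight
`strength` ∈ [0, 1]. Counts flow through the ordinary usage-table
computation, so the experiment exercises the real pipeline from counts to
flags. Building the tables directly, rather than sampling CDS until 9-mer
frequencies converge, is what makes a calibrated decorrelation strength
possible at all; the CDS sampler is validated separately. Windows are
constrained to residues with ≥ 2 synonymous codons and pairwise-distinct
trimers so each window's usage can be set independently.

With the defaults (10 genera, 30 windows, one planted position, loading
k = 13), the planted window is flagged in ≥ 90% of 20 seeded runs at
strength 1.0, and the recovery rate is non-decreasing in strength. Note
that k = 13 over 30 near-concordant windows necessarily produces some
small clusters of *concordant* windows too: the guarantee is recovery of
the planted signal, not a bounded false-positive rate.

## Numerical conventions

Usage tables are checked to sum to 1 ± 1e-9; loading orthonormality to
1e-8; total inertia equals the squared Frobenius norm of centered Z to
1e-6 relative; eigenvalue agreement with an independent power-iteration
solver to 1e-6 on ≤ 12 × 12 problems. TSV floats are written with 6
decimals; usage TSVs use 17 significant digits so serialisation
round-trips exactly. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers, so identical
inputs and seeds give byte-identical databases and reports.

## Known limitations

* The curated reference trimer list (in the original workflow, subunits of
  protein secondary structures) is an *input*; no structure parsing or
  trimer selection is performed here, and synthetic references are built
  from observed or enumerated trimers instead.
* Matching at trimer level means a query 9-mer absent from every genus
  contributes an all-zero column, which is then dropped as degenerate in
  correlation mode.
* The first/second-component views are exposed alongside the 80%-component
  views, but no more than two highlight components are reported.
* Large panels (hundreds of genera) would want sparse Z handling and
  mini-batch K-means; the implementation targets desk-scale panels.
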