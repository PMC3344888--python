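# Methods

This note documents the models behind `fivedge`, the parameters that
matter, the numerical choices, and what the simulation-based tests do and
do not demonstrate about real data.

## The quantification model

A 5′-DGE library observes, for each mRNA molecule captured, a single 25 bp
tag anchored at (or near) the transcript's 5′ end. Quantification is
count-based: a gene's raw signal is the (possibly fractional) number of
tags falling in its counting region, and

TPM = count / total genome-mapped tags × 10⁶.

There is deliberately no length normalization (contrast RPKM): one tag
corresponds to one captured molecule, so tag counts are proportional to
transcript molarity regardless of length. The sampling noise floor follows
directly from Poisson statistics: a gene at *t* TPM sequenced to *N* mapped
tags yields λ = *Nt*/10⁶ expected tags and a relative error of 1/√λ — at
1 TPM and 16 million tags, λ = 16 and the error is 25%.

## Coordinates and orientation conventions

* Internally everything is 0-based half-open; GFF3 (1-based inclusive) is
  converted at the parsing boundary; BED/bedGraph are emitted natively
  0-based.
* Scaffolds are concatenated with 60 Ns after each segment. N encodes no
  valid color, so no 25 bp window can span a boundary; the mapper rejects
  any window containing N outright.
* Sequencing starts at the adaptor 25 bp *inside* the transcript and reads
  back toward the cap, so reads are antisense to their transcript: a gene
  on strand *s* is counted from tags mapped to strand −*s* (the
  `strand_convention` knob can flip this).
* A read is recorded at one array cell: the genomic position of the
  transcript's 5′-most base (window start for a minus-strand hit, window
  end for a plus-strand hit). A `window_start` convention is available
  because the original bookkeeping could plausibly have used either; the
  choice only translates the 5′ peak by a constant 24 bp.

## Color space and mapping

Colors are the XOR of consecutive 2-bit base codes (A=0, C=1, G=2, T=3),
which reproduces the canonical di-base matrix and makes colors
complement-invariant; minus-strand search therefore reduces to matching the
reversed color string on the plus strand. The first color of a read mixes
the synthetic primer base with the first real base; it is excluded from
mismatch counting by default (configurable), as adaptor-adjacent colors are
not sequence evidence.

Reads with ≤ 3 non-0 colors are removed before mapping: long runs of color
0 are homopolymer-like and align promiscuously.

The mapper partitions the 24 informative colors into 3 disjoint 8-color
seeds. Any alignment with ≤ 2 mismatches must contain at least one exact
seed (pigeonhole), so candidate windows are gathered from three exact-match
seed lookups per strand and verified by full color comparison. The output —
*all* windows within the budget, both strands — is defined to equal the
brute-force full scan, and the test suite enforces that equivalence
exhaustively on small genomes, including planted duplications and
error-laden reads. The index is a sorted-array lookup (no FM-index); at
the package's design scale (≤ a few Mb of reference, ≤ a few million
reads) mapping runs in well under a minute on one core.

## Extended counting regions

Gene models frequently lack UTR annotation, so the 5′ tag peak tends to
fall upstream of the annotated start. Each gene is therefore counted over
an extended interval: +2,000 bp on the 5′ side and +1,000 bp on the 3′
side, in transcription orientation. When two same-strand neighbors are
separated by a gap *d* ≤ 3,000 bp the gap is divided 1:2 — ⌊*d*/3⌋ to the
upstream gene's 3′ extension and the remainder to the downstream gene's 5′
extension — so the two regions abut exactly and never overlap. The 1:2
direction is forced by continuity: at *d* = 3,000 the split equals the
1,000/2,000 caps, making the rule continuous at the threshold (the
threshold branch itself is immaterial at exactly 3 kb). Flooring the 3′
share keeps the shares summing exactly to *d*. Opposite-strand neighbors
are ignored — counting is strand-resolved, so cross-strand overlap cannot
double-count — and nested or overlapping same-strand input genes are
rejected rather than guessed at. Extensions are clipped at scaffold edges
and the achieved per-side extensions are reported in an audit table.

## Fractional assignment

Accumulation uses a float array per (scaffold, strand). A uniquely best
hit adds 1.0; a read whose minimum mismatch count is achieved at *n*
locations adds 1/*n* at each of them (locations on different strands are
distinct positions and share the split). Total array mass therefore equals
the mapped-read count exactly, which the tests assert to 10⁻⁶ absolute.
A `unique_only` mode discards ambiguous reads entirely, for comparing
fractional vs unique-only counts on repeat-containing genes.

## The simulator

The generator reproduces what the pipeline *sees*, not the enzymology:

* **Tag positions.** Mixture per gene: weight `tss_peak_weight` (default
  0.6) on the annotated TSS; the remainder follows exp(−d/scale) over
  exonic transcript offsets *d* (default scale 500 bp), emulating truncated
  cDNAs and premature template switching. The peak fraction is a modeling
  choice — real libraries show a dominant 5′ peak with a substantial
  exon-body fraction, but the true split is not identifiable from published
  summaries — and the default is held fixed rather than fitted.
* **Counts.** Per-gene Poisson with mean depth × TPM/10⁶; true TPM sums to
  10⁶ per sample by construction.
* **Reads.** 25 bp, antisense to the transcript, color-encoded, with a
  uniform per-color error probability (default 0.01, a typical SOLiD-era
  raw error rate; at that rate ~0.2% of reads exceed the 2-mismatch budget
  and go unmapped). Tags never span splice junctions: candidate positions
  are restricted to windows inside a single exon.
* **Site bias.** Optional: candidate positions in the 20 bp window 3′ of a
  reverse EcoP15I site (genomic offsets [−20, 0) from the first C of
  CTGCTG) are down-weighted by the suppression factor before sampling, then
  per-gene weights are renormalized — the bias redistributes tags within a
  gene, as a cleavage-interference artifact would.
* **Digestion.** `digest_ecop15i` cuts 25/27 nt downstream of each
  CAGCAG/CTGCTG site in site orientation, returning the 25 bp tag and 2-nt
  5′ overhang; sites with < 27 nt of downstream sequence are dropped with a
  warning.
* **Expression truth.** Non-null genes cycle deterministically through a
  bank of temporal shapes (monotone up/down, bumps at chosen phases) scaled
  so max/min = `effect_fold`; null genes are flat. Base abundances are
  log-uniform over ~4 orders of magnitude (10⁻⁰·⁵–10²·⁵ TPM), matching the
  dynamic range such libraries span.
* **Replicate-level matrices.** For the statistics, `simulate_expression_matrix`
  adds N(0, σ) noise on log₂ TPM per replicate, σ = 0.4 by default — the
  scale of biological variation expected for clonal plant material
  (edgeR-style BCV ≈ 0.28). Planted effects default to *step* patterns
  (a contiguous block of time points at exactly `effect_fold` × baseline):
  with a smooth ramp scaled to the same range, most time points would see
  far less than the nominal fold change and "4-fold effect" would overstate
  the signal actually planted. The smooth bank remains available via
  `pattern_style="smooth"`.

What the simulator does **not** emulate: PCR amplification bias and
duplicate structure, quality-score-dependent errors, splice junctions,
antisense transcription, contamination, or annotation errors. Passing
parameter-recovery tests therefore demonstrates internal consistency of
the pipeline — mapping, assignment, region arithmetic, normalization — not
robustness to those real-data pathologies.

## Time-course statistics

Pipeline order is fixed: per-gene median normalization (genes with zero
median are excluded and reported), log₂ with a pseudo-count (default 0.01
on the median-normalized scale, so zeros map to a finite floor ~−6.6),
one-way heteroscedastic ANOVA across time points, Benjamini–Hochberg
step-up at 5% FDR. ANOVA is invariant to the per-gene median shift; the
normalization matters for the clustering input, where profiles must be
comparable across genes.

**Choice of test.** "Parametric one-way ANOVA not assuming equal
variance" has several standard realizations. Welch's F* (variance-weighted
group means, Welch–Satterthwaite df) is implemented and cross-checked
against pingouin, but at 3 replicates per group its variance weights are
so noisy that the test is measurably anti-conservative: with k = 6 groups
and n = 3, the null rejection rate at α = 0.05 is ~7.5% (the suite
verifies > 6%), which propagates into an inflated realized FDR. The
Brown–Forsythe test for means — the same numerator as classic ANOVA with a
heteroscedasticity-corrected pooled denominator and Satterthwaite df — is
slightly conservative at this design (null rejection ~2.6%) and delivers
both FDR control and better power, so it is the pipeline default; Welch
remains selectable (`method="welch"`). A consequence worth stating
plainly: *no* standard parametric heteroscedastic test has exactly uniform
null p-values at 3 replicates — the Satterthwaite approximation error is
detectable by a KS test at 5,000 genes for every variant — so calibration
at this design is approximate by nature, conservative under Brown–Forsythe.

Degenerate inputs: a gene whose values are all identical returns F = 0,
p = 1; a zero-variance group in an otherwise varying gene has its variance
floored at 10⁻¹² relative to the row scale so the statistic stays finite
(and highly significant when means differ, which is the correct reading of
such data).

## SOM clustering and trees

The SOM is the classic online algorithm on a 3×3 grid: 2,000 iterations,
learning rate 0.5 linearly decayed to 0.005, Gaussian neighborhood with
radius max(rows, cols)/2 decayed linearly to 0.5, BMU by Euclidean
distance (correlation distance available). The codebook initializes on the
grid spanned by the first two principal directions (deterministic, with an
SVD sign convention fixed for reproducibility across BLAS builds) and
falls back to seeded random sampling for degenerate inputs. Input profiles
are the median-normalized, log₂, replicate-averaged per-time-point values
of the significant genes. Given a seed, training is fully reproducible.

Pattern recovery is scored as adjusted Rand index after relabeling each
node by its majority planted pattern: with 9 nodes and 3 planted classes a
correct SOM necessarily refines each class over adjacent nodes, and the
relabeled ARI measures exactly the "members co-assigned with their
pattern" notion the per-node report is built on. Raw-node ARI is lower
(~0.7–0.8) for the same, correct, assignments.

Gene and condition trees use 1 − Spearman rank correlation with average
linkage (scipy). Constant items have undefined rank correlation and are
dropped with a warning; the distance matrix is symmetrized exactly before
linkage. Average linkage on a dissimilarity produces monotone merge
heights, asserted in tests. Newick export encodes branch lengths as merge
height differences.

## Problem sizes and tolerances

The validation suite runs everything at desk scale, chosen so results are
statistically decisive yet the whole suite completes in minutes: toy
genomes of 0.2–1 Mb, libraries of 10⁵–10⁶ tags, 5,000-gene statistical
simulations, 10-seed Monte-Carlo summaries. End-to-end TPM recovery is
asserted at Pearson r ≥ 0.95 (log scale, genes ≥ 10 true TPM; measured
~0.999); tag-mass conservation at 10⁻⁶ absolute; the bias factor within
[2, 4] for a simulated 3× suppression; FDR ≤ 7.5% and power ≥ 80% at
4-fold effects (measured ~1% and ~94%).

## Known limitations

* The mapper is exact but brute-force-backed; it is not meant for
  hundred-megabase genomes (the dense per-strand float arrays alone would
  be ~16 bytes/bp).
* Fractional assignment resolves ambiguity uniformly; no rescue by local
  context or mate information is attempted.
* The DE module assumes log-scale additivity and replicate independence;
  no variance shrinkage across genes is applied, which costs power at very
  low replicate counts relative to moderated methods.
* SOM hyperparameters follow common practice rather than any published
  reference configuration; conclusions about cluster *identity* (which
  gene lands in which node) are less stable than conclusions about the
  partition structure.
* The low-information filter threshold (3 non-0 colors) and the mismatch
  budget (2) are the method's published constants, not re-derived optima.
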