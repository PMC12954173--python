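# Methods

## Scope and model

The package quantifies codon-usage bias (CUB) in a set of protein-coding
sequences and separates its two classical drivers: mutational pressure on
nucleotide composition and translational selection. The unit of analysis is
one canonical coding sequence per gene; every metric is a function of the
sequence's 64-codon count table. Stop codons never enter RSCU, GC3, ENC,
CAI or tAI — the terminal stop feeds only the stop-usage tally — and the
standard nuclear code is assumed throughout (nine 2-fold families, Ile as
the single 3-fold, five 4-fold, and Leu/Ser/Arg as intact 6-fold families;
no 2+4 splitting of the 6-folds).

## ORF quality control

A sequence enters the atlas only as a complete open reading frame: length
divisible by three, canonical ATG start, one of TAA/TAG/TGA as the final
codon, no internal stop, and only A/C/G/T characters. Ambiguity codes fail
QC outright rather than being masked, because masking would silently distort
codon counts. Translated proteins shorter than 10 residues are excluded.
Duplicate (transcript, gene) pairs keep their first occurrence in file
order. Headers may be pipe- or space-delimited Ensembl dialect; IDs are
recognized by their ENS\*T/ENS\*G shape and version suffixes are stripped;
genomic coordinates are carried as parsed (1-based, inclusive) metadata and
never manipulated.

## ENC and its estimator

Wright's effective number of codons is assembled from per-family
homozygosities F averaged within each degeneracy class:
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Two estimators are provided:

- `frequency` (default): F = Σ p̂². Under this form the analytic limits are
  exact — Nc = 61 for uniform synonymous usage and Nc = 20 for
  one-codon-per-amino-acid usage — which makes it the right default for
  bounded, interpretable atlas values. Its drawback is a positive
  small-sample bias of F̂ (≈ (1−F)/n per family), which deflates Nc by
  roughly 4–6 units for 500-codon genes and therefore inflates ΔENC by the
  same amount.
- `wright_corrected`: F = (nΣp̂² − 1)/(n − 1), Wright's bias-corrected
  homozygosity (families need n ≥ 2; families yielding F ≤ 0 are treated as
  unobserved). This estimator is approximately unbiased, so ΔENC of truly
  neutral sequences averages near 0. Calibration checks of the neutral
  generator use it for exactly that reason; a ±1.5 tolerance around 0
  absorbs the residual approximation error of Wright's expectation curve,
  which is itself heuristic.

A missing 3-fold class (no Ile observed) is imputed as F̄₃ = (F̄₂ + F̄₄)/2,
and a missing 6-fold class analogously — a documented convention, since the
original method only sketches rare-amino-acid handling. Nc is clamped to
[20, 61]; values above 61 arise from finite-sample noise under the
corrected estimator and carry no signal. ENC is undefined (absent, not 0)
when no 2-fold or no 4-fold family is observed.

ΔENC = ENCexp − ENCobs uses ENCexp = 2 + GC3 + 29/(GC3² + (1−GC3)²),
evaluated with the same GC3 mode atlas-wide (default `all_sense`; `gc3s`,
which excludes ATG and TGG, is a flag). Region-level ΔENC uses the region's
own GC3.

## CAI and tAI

CAI weights come from the pooled codon counts of the entire QC-passing set
(the transcriptome-wide reference convention): within each family,
w = (X + 1)/(max X + 1). The +1 pseudocount keeps ln w finite for codons
unobserved in the reference. Scoring excludes Met, Trp and stops (they
admit no synonymous choice); CAI is the geometric mean of w over the
remaining codons. Because the reference is the analysis set itself, CAI is
self-referential by design and should be read as "agreement with the
majority usage", not as an external expression proxy.

tAI weights start from tRNA gene copy numbers (tGCN) per anticodon — read
from a two-column TSV or a GtRNAdb-style FASTA where each header is one
gene copy. Each sense codon's absolute weight sums (1 − s)·tGCN over its
decoding channels: the Watson–Crick anticodon (s = 0) plus one wobble
channel by third base — anticodon G reading codon-ending T (s = 0.41),
inosine (genomically A-starting anticodons) reading C (0.28) and A
(0.9999), anticodon U reading codon-ending G (0.68). Three codons are
special-cased so wobble never crosses an amino-acid or stop boundary: ATG
and TGG decode only via Watson–Crick (TGG's generic U:G partner would be
the selenocysteine TCA anticodon), and ATA uses its dedicated channel
(s = 0.89). The s-values are the standard selective-constraint defaults and
are configurable; no organism-specific re-optimization is attempted.
Relative weights are normalized by the maximum; codons with no decoding
anticodon receive the geometric mean of the non-zero relative weights. tAI
is the geometric mean over all sense codons (Met included, stops excluded).

## Gene classification

Quantiles are type-7 (linear interpolation) throughout. With thresholds at
the 20th/80th percentiles of the genes with defined ENC and ΔENC:
translational_selection = (ENC ≤ p20) ∧ (ΔENC ≥ p80);
mutational_bias = (ENC ≤ p20) ∧ (ΔENC < p80);
unbiased_control = ENC ≥ p80; everything else intermediate. Comparisons are
inclusive at the thresholds so toy datasets classify deterministically.
Genes with undefined metrics are excluded from threshold computation and
labelled intermediate. All-identical ENC raises (degenerate quantiles), and
fewer than 5 classifiable genes is an error at the API level; the pipeline
logs and skips classification in that case.

## Disorder-stratified regions

Per-residue disorder probabilities (IUPred3 long-format output, or any
position/score table; positions must be contiguous from 1, scores in
[0, 1]) are thresholded at 0.50, inclusive on the disordered side. Residue
i maps to codon i; the codons of each class are concatenated in residue
order into two sub-sequences whose counts exactly partition the
stop-stripped CDS. Profiles whose length disagrees with the protein length
are logged and skipped — a mismatch signals upstream inconsistency, not
data to be patched. ENC is unstable on very short sequences, so regions
under `min_codons` (default 20, configurable) report absent enc/ΔENC while
GC3/CAI/tAI are still computed from one codon up. When comparing region
classes, note that the frequency-estimator ENC bias depends on region
length; contrasts between region classes of systematically different
lengths are cleaner under `wright_corrected`.

## Statistics

All metric distributions are non-normal, so correlations are Spearman
(average ranks for ties; two-sided p via the asymptotic t approximation)
and group contrasts use the Wilcoxon rank-sum test (exact for small untied
samples, tie-corrected normal approximation otherwise) alongside Cliff's
Δ = (#{a>b} − #{a<b})/(n₁n₂). The Δ confidence interval uses the
consistent variance estimator of the dominance matrix with the asymmetric
transformation that keeps the interval inside [−1, 1]; degenerate cases
(complete separation, singleton groups) collapse the CI to the point
estimate. Magnitude labels follow |Δ| thresholds 0.147/0.33/0.474, with the
small band closed above so |Δ| = 0.33 is still "small". P-values are
floored at 2.2e−16 and displayed as "< 2.2e-16" below that.

IQR outlier filtering retains values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(type-7 quartiles). It is deliberately single-pass; on heavy-tailed data a
second application can trim further, so idempotence holds only for
moderate-tailed samples.

The RSCU–tGCN panel pairs each codon with its exact Watson–Crick cognate
anticodon's copy number (wobble-aware aggregation behind a flag) in two
variants: per-gene RSCU values IQR-filtered then averaged per codon, or the
single pooled genome-wide RSCU. The constraint panel joins the atlas to a
gene-level table (synonymous observed/expected ratio, synonymous LOEUF,
per-site synonymous mutation rate; column names mappable onto gnomAD-style
exports) and reports Spearman rho for ΔENC against each, plus ENC vs O/E.
No multiple-testing correction is applied across these panels; they are
reported as raw rho/p.

## Synthetic data: what it emulates and what it does not

All generators draw from named substreams of a single seed, so outputs are
reproducible and adding a generator never shifts existing draws.

- **Neutral regime**: amino acids uniform over the 20; within each
  degenerate family the probability of a G/C-ending codon equals a
  compensated target (adjusted for the fixed G-ending ATG and TGG, exact
  within the G/C and A/T subsets), so realized all-sense GC3 matches the
  request in expectation. This is the pure mutational-pressure null: codon
  choice depends on composition only.
- **Selected regime**: within-family probability ∝ w^strength against an
  optimality table (default: deterministic weights falling geometrically at
  ratio 0.45, with alternate families ranked in reverse order so strong
  selection stays roughly GC3-neutral). Strength 0 is uniform; large
  strength approaches one codon per amino acid.
- **tRNA pool**: one Watson–Crick anticodon per sense codon; copies either
  random positive integers or tied to an optimality ranking (strictly
  increasing for strict rankings), which plants codon–tRNA co-adaptation.
- **Disordered genes**: one contiguous disordered block covering the
  requested fraction of the protein (IDRs are segmental, not i.i.d. per
  residue), with per-region selection strengths and scores drawn on the
  matching side of 0.50.
- **Constraint table**: the synonymous O/E ratio is a monotone transform of
  a latent Gaussian mixing the normal scores of the ΔENC ranks with
  independent noise; the mixing coefficient comes from the bivariate-normal
  rank-correlation identity r = 2 sin(πρ/6), so realized Spearman rho
  concentrates on the target (±0.05 at n = 2000). `noise` is the latent
  noise SD; noise = 0 requires |ρ| = 1 and |ρ| = 1 with noise > 0 is
  rejected as unreachable. LOEUF is co-monotone with O/E; the mutation rate
  is independent noise on a ~1.5e−8 per-site scale.
- **Bundle** (`generate_atlas`): 400 genes × 500 codons by default, mixing
  10% selected (strength 3), 10% neutral at GC3 0.92 (composition-driven
  bias), 20% unbiased (GC3 0.5) and 60% neutral filler with GC3 spread over
  [0.74, 0.82]. The filler band is placed so the three planted populations
  are well separated in (ENC, ΔENC) — the regime-recovery checks presume
  separation, and with it the 20/80 quantile classifier recovers ≥ 90% of
  planted labels (typically ≥ 98%). Stop codons default to the
  TGA-majority preset (49.2/28.5/22.3); a uniform preset exists.

None of this mimics real gene-length distributions, non-uniform amino-acid
composition, isochore structure or tissue-specific tRNA expression.
Passing tests on synthetic bundles demonstrate that the machinery recovers
planted structure under its own assumptions — not that any particular
genome shows that structure.

## Numerical conventions

TSV outputs round floats to 6 significant digits so reruns with identical
inputs are byte-identical. Undefined metrics are absent (empty/NaN), never
0. Problem sizes in the test suite (300–400 genes of 120–500 codons,
100–200 replicate genes for the region and co-adaptation checks, n = 2000
for rank-correlation calibration) were chosen as the smallest sets at which
the planted signals are statistically unambiguous.

## Known limitations

- Wright's expectation curve is heuristic; ΔENC of neutral sequences is
  only approximately centred on 0, and the frequency-estimator variant adds
  a length-dependent offset (shared across genes of similar length, so rank
  analyses are unaffected).
- tAI depends on the completeness of the tRNA pool; absolute values are not
  comparable across pools, and no isoacceptor-specific s optimization is
  performed.
- CAI's transcriptome-wide reference makes it composition-confounded by
  construction; interpret alongside ΔENC, not instead of it.
- The canonical-transcript choice is delegated to the input FASTA; the
  package treats it as already filtered.
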