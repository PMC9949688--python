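# Methods

## Problem setting

`tepselect` implements the downstream analysis of tumour
immunopeptidomics cohorts: mass-spectrometry-identified HLA-presented
peptides per tumour sample are compared against a pooled benign
reference ligandome to find tumour-exclusive peptides (TEP), cohort
statistics are computed, and a peptide *warehouse* — an
HLA-allotype-indexed collection of QC-validated TEP — is assembled by
bi-objective optimisation so that semi-personalised vaccine
compositions can be drawn for individual patients from their HLA
typing. The motivating application is oropharyngeal squamous cell
carcinoma (OPSCC), where HPV status stratifies the cohort.

Raw spectral search, rescoring, read alignment and binding-predictor
internals are upstream of this package: it consumes their outputs
(per-sample peptide tables with PSM counts, Xcorr, ΔCn and q-values;
oncogene read-count tables; HLA typing).

## Identification filtering

Accepted identifications satisfy q ≤ 0.05 (FDR-calibrated rescoring
confidence) and a peptide length of 8–25 residues, both bounds
inclusive. The filter is order-preserving and idempotent. Sequences are
plain 20-letter strings; post-translational modifications are not
represented. Isoleucine and leucine, indistinguishable by MS, are kept
distinct by default; an `collapse_il` flag is available on exclusivity
comparisons and peptidome queries for the collapsed reading.

## HPV status calling

A patient is HPV-positive when, for any single HPV type, E6 ≥ 500
reads, or E7 ≥ 500 reads, or the eight transcripts E1, E2, E4, E5, E6,
E7, L1, L2 reach 500 in sum. The sum branch is evaluated *per type*;
read evidence is never mixed across types, since a summed call spanning
two viruses has no biological reading. The called type is the one with
the most reads over the eight genes; ties break on E6+E7, then on type
name, so output is deterministic. The rule is monotone: adding reads
can never turn a positive call negative.

## Binder annotation

The published workflow annotates class I ligands with external
predictors (motif databases / neural predictors). Re-implementing those
is out of scope; instead the package ships a pluggable additive
position-specific scoring matrix (PSSM) scorer with per-allele,
per-length (8–11) matrices and thresholds, plus an import path for
externally produced binder calls (TSV of sequence/allele/is_binder). A
peptide is a binder when any same-length motif of any patient allele
reaches its threshold (OR across motifs — the exact combination rule
used upstream of published datasets is not knowable, and OR is the
permissive reading; the choice is recorded in every run manifest). The
assigned allotype is the best-scoring passing motif. Purity is the
binder fraction of a sample's class I peptides. Class II peptides are
not binder-filtered; analyses use all accepted presented peptides, so
"ligands" below always refers to class I.

## Comparative profiling

A TEP is a peptide present in ≥ 1 tumour ligandome and absent from the
benign reference of the same HLA class, by exact sequence match. For
class I the comparison runs over binder-annotated ligands; for class II
over all presented peptides. Prevalence is the percentage of cohort
samples presenting the peptide (3 of 40 = 7.5%); a prevalence filter
keeps TEP found in ≥ k samples. HPV stratification partitions the union
peptide set into pos-exclusive / neg-exclusive / shared by the status
of presenting samples.

Source-protein saturation is estimated from a permutation-averaged
accumulation curve of unique source proteins versus number of samples
(all orderings when n ≤ 7, else 100 seeded random orderings) fitted
with S(n) = S_max·(1 − e^(−k·n)). The estimator behind the published
saturation figures is unnamed, so this saturating-exponential model is
the package's own choice and is surfaced in the result object. The fit
profiles S_max out analytically (for fixed k the least-squares S_max is
closed-form) and searches k on [1e−6, 50] with bounded Brent; this is
robust for flat curves (immediate saturation, 100%) and near-linear
curves (no saturation; S_max ≫ observed), where a joint two-parameter
fit diverges. S_max is floored at the observed protein count so the
attained percentage never exceeds 100.

## Cohort statistics

*Allele enrichment.* Carrier chromosomes are counted (two per
individual, homozygotes twice); reference counts are reconstructed as
round(f·2N) because public frequency tables report only f and N. The
odds ratio gets a Woolf (log) 95% CI, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`,
by default (the conditional exact interval is available via
`ci_method="exact"`); zero cells receive the Haldane–Anscombe 0.5
correction and are flagged. The p-value is a 1-df chi-square without
continuity correction unless any expected cell is < 5, in which case
Fisher's exact test is used; both p-values are always reported because
the test behind published single-allele p-values is usually unstated.
With the printed inputs of the motivating study (16.2% of 80 cohort
alleles vs 6.3% in 39,689 reference individuals) the reconstruction
gives a 13/67/5001/74377 table.

*Mass–yield correlation.* Pearson r with Fisher-z 95% CI and two-sided
p (scipy), requiring n ≥ 3, positive masses and non-zero variance.

*Population coverage.* Under Hardy–Weinberg equilibrium and locus
independence, P(an individual carries ≥ 1 covered allele) =
1 − ∏_locus (1 − Σ_covered f)². Verified against exhaustive diploid
genotype enumeration to 1e−12 in tests.

*Cohort summary.* Count/percentage table of clinicopathological fields
stratified by HPV status; percentages are computed within each status
column and rounded to one decimal, matching how such tables are
printed.

## Warehouse optimisation

For each of the top 5 class I allotypes per isotype (A, B, C) by
carrier count, the candidate pool is the set of TEP assigned to that
allotype and presented by ≥ 2 carrier patients; the incidence matrix
records which carriers present which candidate.

The optimisation is bi-objective: maximise carrier coverage, minimise
selection size. With ≤ 20 candidates the Pareto front is computed
exactly by subset enumeration (a bitmask dynamic program over all 2^n
subsets); above that, a greedy-seeded stochastic local search
(add/drop/swap moves, default budget 10^6 iterations, mandatory seed)
tracks the best coverage per size. The reported selection is the
smallest set attaining the maximal attainable coverage — the front
itself is retained so other trade-offs remain inspectable — with ties
broken by the lexicographically smallest peptide list, making output
deterministic.

Warehouse QC requires PSM count ≥ 2, Xcorr ≥ 1.5 and ΔCn ≥ 0.2
(inclusive; best value per peptide across samples; missing metrics
fail). QC is applied post hoc to the selection: failing peptides are
removed from the candidate pool and the optimisation re-runs, up to 3
runs in total, with every peptide that ever entered a selection
recorded as a warehouse candidate. If failures survive the final run
they are dropped from the reported selection, so output is always
QC-clean. A pre-filtering flag (passing only QC-clean candidates into
the first run) is available via `select_class_ii`-style usage.
Allotypes whose optimal selection covers ≤ 1 carrier are skipped as
negligible contributors; the skip is listed in the warehouse report.

Class II TEP are optimised once, allotype-agnostically, over the whole
cohort: candidates are class II TEP in ≥ 3 ligandomes passing QC (here
QC eliminates candidates up front, mirroring how class II candidate
counts are reported); coverage is reported overall and by HPV status.

A patient's semi-personalised composition is the union of the
selections for the class I allotypes they carry; the presented subset
is its intersection with their ligandome, and `pct_of_selected` is the
presented fraction (0 when nothing is selected).

## Synthetic cohorts

The generator produces cohorts with the structure the analysis assumes,
with planted ground truth for oracle tests:

- **Genotypes**: two alleles per locus per patient, drawn independently
  per locus from a German-population-like 2-field frequency table
  (Hardy–Weinberg), matching the population-coverage formula's
  assumptions. Each locus's table sums to 1 so no filler category is
  needed.
- **Ligandome sizes and tissue mass**: (log mass, log class I yield) is
  bivariate normal with correlation `mass_yield_r` (default 0.4645) and
  lognormal σ = 0.45 — the simplest generator achieving a target
  Pearson r; defaults give a mean of 1338 class I and 702 class II
  peptides per sample. Class II sizes are independent lognormals.
- **Peptides**: class I binders (default 94% of presented peptides) are
  sampled from the patient's own allele motifs — each motif's threshold
  is the minimum score attainable from its top-5 residues per position,
  so motif-sampled peptides pass by construction — partly from a shared
  pool of 2000 peptides attached to allotypes (each presented by a
  carrier with probability 0.5, creating the cross-patient sharing the
  warehouse needs), partly sample-private. Non-binders and class II
  peptides are uniform random sequences; lengths follow the class
  distributions (70% class I 9-mers; class II mode 15 at 17%).
- **Benign overlap**: each cohort-unique peptide is planted into the
  benign reference with probability `benign_overlap_frac` (default
  0.77, reproducing a ~23% class I TEP fraction); the complement is the
  planted TEP set. Background benign-only peptides (2× the tumour-unique
  count) and tissue labels complete the reference.
- **QC metrics**: a `qc_pass_frac` (default 0.90) of peptides receives
  metrics above all three gates; the rest violate one randomly chosen
  gate. A small decoy fraction of records carries q > 0.05 to exercise
  identification filtering.
- **HPV**: exactly round(n·0.55) patients are positive (type HPV-16
  with probability 19/22, else HPV-35/58/59), with E6/E7 planted above
  the 500-read threshold; negatives receive ~Poisson(8) total reads,
  far below threshold.
- **Source proteins**: one accession per peptide from a pool sized at
  unique-peptides/2.4 with mildly skewed usage, giving cross-sample
  protein overlap and a realistic accumulation curve.

One global seed drives a named `SeedSequence`-derived stream per table
(genotypes, HPV, mass/yield, pools, samples, benign, QC, proteins), so
adding a table never perturbs the others and output is byte-identical
across processes (RNG consumption never iterates unordered sets).

What the generator does **not** emulate: real motif structure (anchors,
shared binding cores between related allotypes), biological co-regulation
of source proteins, the long tail of peptide sharing between tumour and
benign tissues beyond an i.i.d. overlap fraction, batch effects, and
expression-level coupling. Passing planted-truth tests therefore
demonstrates the algorithms' correctness on data satisfying the model's
assumptions, not performance on real immunopeptidomes.

## Numerical and design choices

- Exhaustive-vs-stochastic crossover at 20 candidates: 2^20 subset
  states is the largest bitmask DP that stays interactive; the
  published workflow's optimiser configuration ("preset") is not
  public, so the exact/heuristic split is this package's design.
- All percentages reported by `cohort_summary` round half-up to one
  decimal; all other statistics are returned unrounded.
- HLA matching happens at 2-field resolution everywhere; 3-/4-field
  input and expression suffixes are truncated on parsing.
- Degenerate inputs: empty candidate matrices yield empty selections
  with coverage 0; an empty record set propagates through the pipeline
  as empty-but-valid outputs; an unannotated sample (no binder flags at
  all) is treated as unfiltered rather than all-non-binder.
- Problem sizes in the shipped tests and the acceptance script: unit
  tests run 6–10-patient cohorts with ~100-peptide ligandomes; the
  planted-truth and acceptance runs use the full default conditions
  (40 patients, full ligandome sizes) with a stochastic-search budget
  of 2×10^4–3×10^4 moves per allotype, which saturates on these
  candidate-pool sizes (typically ≤ 60 candidates per allotype).

## Known limitations

- The motif scorer is a stand-in: absolute purity values depend on its
  thresholds and are not comparable to predictor-based annotations.
- Reference allele counts reconstructed from rounded frequencies can
  differ by ±1 count from the true table behind a published frequency.
- The stochastic optimiser guarantees Pareto-optimality only on
  instances small enough for the exhaustive path; on larger instances
  it reports the best front found under the iteration budget.
- Class II coverage in synthetic cohorts saturates easily because the
  shared class II pool is presented cohort-wide; real class II sharing
  is sparser.
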