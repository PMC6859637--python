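# Methods

`organopept` re-implements, as a tested reusable package, the
computational analysis of tumour-organoid immunopeptidomes: from
somatic-variant retention through neoantigen candidate enumeration,
replicate-aware MS presence calling and differential presentation under
treatment, to the detection-versus-prediction neoantigen funnel.  Raw
patient data for studies of this kind is access-restricted, so the
package includes a first-class synthetic-data generator with known
ground truth plus a small fixture of in-print worked examples; every
stage runs end to end with no download.

## Somatic-variant retention and clonality

A call is retained iff (all thresholds inclusive, read literally from
the protocol wording "minimum X" ⇒ `>= X`):

* tumour VAF >= 10 % and >= 6 tumour variant reads,
* germline VAF <= 2.5 %, germline depth >= 25, <= 5 germline variant reads,
* indels additionally: tumour depth >= 15.

The filter is a pure per-row predicate (order-independent, idempotent);
the rejection log names the first failing rule in the order above.
Clonality is `CCF > 0.7` (strict).  CCF estimation itself requires
purity and copy number and is upstream of this package; CCF enters as
an input column.  Two deliberate interpretations, both surfaced here
because the protocol wording leaves them open: the germline
contamination rules are applied to indels as well as SNVs (conservative
— an indel with germline support is no more trustworthy than an SNV
with one), and the indel depth-15 rule is applied to the tumour sample
only.

## Mutant proteins and candidate enumeration

Residue positions are 1-based, matching protein mutation notation
("T224R").  Missense substitutes one residue; frameshifts keep the
wild type up to the residue before the edited codon and append the
shifted-frame translation of the edited CDS until the first stop codon
(standard genetic code via Biopython; a missing downstream stop raises
a truncation warning and the tail runs to the CDS end); stop-loss
appends a read-through tail.  Candidate HLA-I neoantigens are every
8/9/10/11-mer window of the mutant protein that overlaps >= 1 mutated
position and differs from the wild-type window aligned at the same
start, deduplicated by sequence and clipped at the termini.  An
interior missense therefore yields exactly 8+9+10+11 = 38 windows.
Splice-site and stop-gain mutations generate no predictable candidate
sequence and are excluded; silent trivially so.

Detection matching accepts peptides of any length (covering HLA-II):
a detected peptide is a neoantigen hit iff it occurs in a mutant
protein spanning a mutated position AND occurs nowhere in the whole
wild-type proteome — not merely differing from the aligned window,
because a peptide present anywhere in the wild type cannot be called
mutation-specific.  Leucine and isoleucine are distinct by default; an
optional I/L-collapsed mode reflects their indistinguishability by MS.

## Presence calling and peptidome statistics

MS evidence is one row per detected peptide per technical replicate
(two technical replicates nested in >= 2 biological replicates per
condition).  A peptide is **present** in a sample/condition iff it was
detected in both technical replicates of at least one biological
replicate; its intensity is the median raw intensity across all
detecting technical replicates.  The same criterion is used for HLA-I
and HLA-II; counting differs only in the length rule (all lengths for
class I, >= 12 aa for class II).  Source-protein counts use unique
mapping: a peptide found in more than one protein contributes to no
protein.  Pairwise overlaps report the shared-peptide count and its
percentage of each sample; the allotype-restricted variant partitions
each sample's peptides into predicted binders (best rank < 2 %) of the
shared versus non-shared allotypes before intersecting.  Intensity
correlations between HLA-matched samples are Pearson on log10 median
raw intensities over co-present peptides (raw intensities span
decades; the log base is configurable).  Normalized peptide appearance
of a gene is the number of distinct present peptides uniquely mapping
to its protein divided by protein length.

## Differential presentation

Per biological replicate, log2 of the mean raw intensity over
detecting technical replicates; missing where undetected.  Width
normalization is realized as median centring and scaling by
IQR/1.349 (the Gaussian-equivalent interquartile width): the protocol
names the Perseus "width" operation without a formula, and this is the
standard robust location/scale version — exactly median-0 columns,
affine-equivariant.  Missing values are imputed from a down-shifted
Gaussian per column: width 0.2 x column SD ("standard deviation of
20 %" read as 20 % of the column SD, the Perseus width convention) and
a down-shift of 1.8 SDs (not stated in the protocol; 1.8 is the
Perseus default and both knobs are configurable and surfaced in all
outputs).  Peptides are tested with paired t-tests across biological
replicates paired by index (an unpaired Welch mode serves unbalanced
designs, as when treated arms carry extra replicates), with
Benjamini–Hochberg q-values; significance is `q <= 0.05` and
`|log2FC| >= 1` (2-fold).  Annotation flags IFNγ-inducible source
genes (plain gene-list input) and chymotrypsin-like ligands
(C-terminal residue in {A, F, I, L, M, V, Y}).

## Binding model and percentile ranks

The rank predictor is a contract: `rank(peptide, allotype)` in
(0, 100], lower = stronger, total over lengths 8–11.  An adapter can
consume a pre-computed (peptide, allotype, rank) table from an external
neural predictor; the default is a synthetic position-weight-matrix
model so the package is self-contained.  Each allotype is a 9-column
PWM with 2–3 anchor columns (position 2 and the C-terminus, optionally
position 3) carrying one strong and two moderate residue preferences
over a mild random background.  Lengths 8–11 map deterministically
onto the 9 columns (first four residues to columns 1–4, last five —
four for 8-mers — to the C-terminal columns; central bulge residues of
10/11-mers are ignored, as in the groove).

Ranks are calibrated empirically per allotype and length against a
background of random peptides drawn from uniform residue frequencies
(configurable to proteome frequencies): `rank = 100 x max(#background
scoring >= peptide, 0.5) / N`.  The half-count floor keeps ranks
strictly positive for fresh peptides that outscore the entire
background while preserving tie-sharing and the property that the best
background peptide ranks `<= 100/N`.  Because fresh peptides are
ranked against one shared empirical background, uniformity checks use
the two-sample effective size `n·N/(n+N)` for KS critical values and
add the background sampling term `1/N` to binomial variances — the
statistically correct reference for empirical-vs-empirical comparisons.

Binder classes use strict thresholds on the best (lowest) rank across
autologous allotypes: strong `< 0.5`, weak `< 2`, else non-binder.

## The funnel

Mutation-level stages: all candidate mutations; those with >= 1
candidate peptide that is a strong binder for >= 1 autologous
allotype; the subset whose source gene is detectably expressed (mean
normalized expression > 0 exactly — the zero/non-zero dichotomy is
the protocol's own classification); and, on a separate lane, mutations
whose ligands were detected by MS.  Detected neoantigens are not
required to be predicted binders; detected-but-unpredicted mutations
are counted separately (in the packaged fixture the U2SURP ligand,
rank 5.78, is exactly such a case).  The protocol's mention of "core
peptides" for long candidates is realized as the candidate-level
minimum over windows, which yields the same mutation-level call.

## The synthetic generator

The generator emulates, with known ground truth: a proteome of
uniform-random sequences over the 20 standard residues (no ambiguity
codes, matching MS search practice); gene-level log2-normalized
expression with explicit zeros (~15 % of genes, so the zero-expression
filter is exercised); somatic mutations with read support constructed
to pass or fail the retention rules at a configured decoy fraction and
CCFs drawn to a configured clonal fraction (default 0.93, the observed
clonal share in microsatellite-stable colorectal lines); and MS
evidence in a (biological x technical) replicate grid.  Candidate
ligand windows are presented with probability
`sigmoid(-4 + 1.6·(-log10(rank/100)) + 0.25·expr)`, i.e. increasing
in predicted binding strength and log-expression; zero-expression
genes leak peptides at rate 0.002 (mirroring peptides observed from
transcripts below the RNA-seq detection limit).  Each technical
replicate independently drops a presented peptide with probability 0.2
by default, giving the closed-form presence rate
`1 − (1 − (1−d)²)^B`.  Raw intensities are log-normal (log2 location
22, scale 1.5) with biological (SD 0.3) and technical (SD 0.15) noise.
The IFNγ condition scales presentation probability by 1.3 (more HLA at
the surface), upregulates a deterministic 10 % subset of genes 4-fold,
and multiplies presentation probability of chymotrypsin-like ligands
by 1.5; the MEK-inhibitor condition applies no systematic effect.
Default problem sizes (200 proteins, 120 mutations, pool of 8000
candidate windows, rank background of 5000 per allotype and length)
keep a full run in seconds while leaving every statistical check
well-powered; tests scale them per scenario.

What the generator does **not** emulate: spectral identification
(m/z, retention time, FDR control — the evidence table is the input
boundary), real allotype binding motifs, correlated peptide
co-presentation along a protein, batch effects, and
intensity-dependent (MNAR beyond the dropout/leak model)
missingness.  Passing recovery tests therefore demonstrates
correctness of the analysis logic under the stated generative
assumptions, not performance on real immunopeptidomes.

## The in-print fixture

The fixture packages the published worked examples: 612 candidate
mutations distributed over the five organoid lines proportionally to
their non-silent loads (208/106/89/180/78; largest-remainder rounding
— the per-line split of the 612 is not published, only the total and
the per-line loads, which include the excluded splice-site/stop-gain
classes).  Exactly three mutations are flagged detected, with the
published ligands and ranks (U2SURP T224R wt IQEERDERHKT 75.8495 / mut
IQEERDERHKR 5.7765; MED25 K422T SVDANTKL 0.5336 / SVDANTTL 0.1586;
FMO5 S423N RYVESQRHTI 0.31911 / RYVENQRHTI 0.2692); 304 mutations are
flagged as predicted strong binders and 196 of those as expressed,
matching the published funnel.  Wild-type protein contexts are
synthetic flanking sequences (only the ligands are published) that
embed each wild-type ligand exactly once at its printed residue
position, long enough that all 8–11-mer windows around the mutation
exist, and verified not to contain any mutant ligand.

## Numerical and design notes

* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical configuration ⇒
  byte-identical outputs.
* Paired t-tests on identical values give a 0/0 t statistic; the
  resulting NaN p-value is mapped to 1 (no evidence of change).
* Width normalization refuses columns with < 4 observed values or zero
  IQR; imputation refuses entirely-missing columns.
* Percentages in the funnel are reported to two decimals
  (3/612 → 0.49 %).
* Thresholds are module-level constants surfaced in the pipeline
  config; the YAML config rejects unknown keys and validates before
  any stage runs (fail-fast), and stage failures preserve partial
  outputs and name the failing stage.

## Known limitations

The synthetic binding model is not a trained predictor: its anchor
preferences are random, so rank agreement with real allotypes is out
of scope by construction.  The differential module implements plain
paired t-tests as the protocol specifies; no variance moderation
(limma-style) is offered.  HLA-II analysis is limited to the length
rule and the length-agnostic detection matching; class II motif
deconvolution is out of scope.
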