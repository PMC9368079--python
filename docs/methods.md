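# Methods

This note records the models, parameter choices and known limitations of
the package, in the order the pipeline runs them.

## Study design emulated by the generator

The synthetic module reproduces the design of a dose-response small-RNA
experiment in cultured cells: three groups (control plus a low and a
high stress dose, labelled CON/LOS/MOS), three replicate libraries per
group, single-end reads of 36 or 50 bp from a TruSeq-style small-RNA
protocol. Defaults (all in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| `reads_per_library` | 100,000 | library depth is a free parameter of the design; this depth makes every planted effect measurable while keeping simulation fast. Tests and the analysis drivers use 4,000–20,000 reads; the depth only scales counting noise. |
| `read_length` | 50 nt | one of the two supported single-end lengths (36/50). |
| `adapter_sequence` | `TGGAATTCTCGGGTGCCAAGG` | the Illumina TruSeq small-RNA 3' adapter; configurable since only the kit, not the sequence, is fixed by the protocol. |
| `contamination_fraction` | 0.05 | total junk share, split 50% ncRNA-family fragments / 25% adapter dimers / 25% low-complexity reads. The split is fixed so that a 40% contamination setting yields 10% adapter dimers — a convenient round number for accounting checks. |
| `isomir_shift_window` | ±2 nt | the largest end-shift the naming grammar is exercised with (`L±2 … R±2`); shift probabilities 0.70 / 0.12 / 0.03 for 0/±1/±2 at each end. |
| `substitution_rate` | 0.02 per read | a single random substitution, matching the one-mismatch allowance of the mapping stage. |
| `de_fraction`, `planted_log2fc` | 0.10, ±2 | planted effects between the control and *each* stress group (a shared stress response), half up / half down. |
| `nb_dispersion` | 0.05 | negative-binomial dispersion typical of homogeneous cultured-cell replicate libraries; 0 recovers Poisson counting noise. At this dispersion a 3-vs-3 design has >95% power for |log2FC| = 2 at moderate depth, which is what makes the recovery properties meaningful rather than vacuous. |
| `genome_length` | 100 kb | i.i.d. uniform background, large enough to embed all loci with ≥80 nt of flank and make chance exact 22-mer matches vanishingly rare. |

Per-miRNA baseline abundances are Gamma(2)-distributed weights
normalised to the library depth — a heavy-ish tail without the extreme
dominance of a real miRNome, so that most planted entities are testable.

**What the generator does not emulate:** per-cycle sequencing error
profiles, base-quality variation (qualities are constant), ligation
bias, paired-end reads, multi-chromosome genomes, repeat families, and
the true skew of miRNA abundance distributions. Passing tests therefore
demonstrate correctness of the algorithms under controlled noise, not
performance on real libraries.

### Designed hairpins, decoys and their verification

Planted precursors are built by a constructive designer: a stem of
prescribed pairs (GC-biased with a small G:U wobble admixture), a
terminal loop, optional bulges/internal loops at chosen stem positions,
and a mature interval spanning chosen pairs. The wobbles also guarantee
the stem is not perfectly self-complementary — otherwise a mature would
exact-match the minus strand at its own 3' arm and create a spurious
second candidate locus (designs are additionally rejected unless the
mature occurs exactly once and its reverse complement not at all).

Eleven decoy layouts each violate exactly one criterion, e.g. a 14-nt
stem bulge outside the mature (c1 only), a 16-pair stem with a loop
sized so the hairpin still reaches 50 nt (c7 only), three 1-nt biased
mature bulges (c10 only). The free-energy decoy (c2) is special: it
needs >16 stem pairs *and* ΔG > −15 kcal/mol, which forces an all-A:U
stem, and any pairing partner in its neighbourhood would stabilise it
past the cutoff — its loop and immediate flanks are therefore C-only
(inert against an A/T/G arm). Other decoys get flanks drawn from {A, C},
which cannot pair with each other, so chance background helices cannot
extend a designed stem from outside and change which criterion fails.
Novel and homolog loci are embedded in unrestricted uniform background.

Every genomic construction is verified at generation time by folding its
final ±80 nt mature context through the classifier (novels must pass all
11 criteria; decoys must fail exactly the designated one) and
regenerated — fresh flanks first, then a fresh hairpin — on failure.
The genome is not screened for accidental criteria-passing background
hairpins: only loci that cleaned tags map to are ever folded, and a
planted 22-mer has essentially zero probability of a second exact
occurrence in 100 kb of uniform background.

## Read cleanup

Stage order is fixed: adapter trimming → junk/length gate → collapse to
unique tags → contaminant-family filter. The trimmer takes the read
prefix before the leftmost adapter occurrence, accepting partial 3'
overlaps of ≥6 nt and mismatch rates up to 10%; an exact match never
shadows an earlier acceptable fuzzy match. Reads with no adapter are
treated as degradation products and discarded (configurable). The
low-complexity rule is: base-composition entropy < 1.0 bits or a single
base ≥ 80% of positions; pure tandem repeats of period ≤ 3 are removed
separately; surviving inserts must be 18–26 nt. Contaminant matching is
exact substring against the family catalog (≤1 mismatch optional), ties
resolved rRNA > tRNA > snRNA > snoRNA. Removal is bookkept in read
units so that input = surviving + Σ removed holds exactly per library.

## Mapping cascade and names

A tag is a known species miRNA if it aligns ungapped within an annotated
mature arm allowing end offsets up to ±2 nt and at most one
substitution; the best hit minimises (mismatches, |left|+|right| offset,
precursor id). Remaining tags try other-species precursors under the
same rules, counting only when the foreign precursor itself occurs in
the study genome (exact substring search; a BLAST-like near-exact mode
is configurable). Remaining tags are placed exactly on both genome
strands; tags with more than 10 placements are set aside as repetitive.
Each placement is forwarded with ±80 nt context (reverse-complemented
for minus-strand hits), and overlapping placements — isomiR stacks —
are clustered, the highest-count tag representing the locus.

Names: `base` for an exact mature; `_L±x`/`R±y` appended for 5'/3' end
variation (positive = extension); `_1ss<pos><ref><alt>` for a single
substitution, with `pos` 1-based **on the tag** (the reference-indexed
alternative is equally defensible; tag-indexed was chosen and is what
the parser inverts). Novel candidates are `PC-<arm>-<serial>_<total>`,
the serial in discovery order and the trailing number the tag's total
read count — the printed convention never defines that number, and
total count is the reading adopted here. `format` and `parse` are exact
inverses on the grammar.

## Hairpin model and the 11 criteria

The default folding backend is an exact dynamic program over
single-hairpin topologies: nested pair chains with stacking energies for
adjacent pairs (standard Turner Watson–Crick ΔG°37 values; wobble stacks
approximated at −1.2 / −0.5 kcal/mol for one/two G:U pairs), tabulated
initiation penalties for hairpin loops, bulges and internal loops with
Jacobson–Stockmayer extrapolation, an asymmetry penalty (0.6/nt, capped
at 3.0), single-nucleotide bulges retaining the flanking stack, loop
sides bounded at 30 nt, and a minimum loop of 3. Multibranch structures
are deliberately excluded — the classification target *is* the best
single stem-loop. The empty structure is returned when no negative-energy
hairpin exists, so `mfe ≤ 0` whenever a pair is reported. ViennaRNA can
be plugged in as an alternative backend; the criteria engine is
backend-independent and, for multiloop input, evaluates the stem chain
that best covers the mature.

Terms the criteria use but folklore never defines precisely are fixed as:
a *bulge* is any unpaired run between consecutive stem pairs (size =
unpaired nucleotides on both strands); *biased* = unpaired on one strand
only; an *error* in the mature is an unpaired mature position; a bulge is
*in the mature region* when at least one of its unpaired positions falls
inside the mature interval; *maturity in the stem* is the fraction of
mature positions within the folded span excluding the terminal loop;
pairs *in the mature region* have at least one partner inside it.
Comparator strictness follows the printed rules: all limits inclusive
except the stem-pair count, which is strict (>16).

## Differential expression

Normalisation is CPM (the normalisation behind "normalized counts" is
not specified anywhere authoritative; CPM is the simplest defensible
choice and the column-sum identity makes it testable). The replicated
two-group test is Student's *t* on log2(CPM+1) — the pooled-variance
test named in the protocol; at n = 3 it is near-nominal where Welch's
correction is conservative. When both groups have zero variance with
unequal means the t statistic is undefined and the battery falls back to
the pooled 2×2 count test (Fisher when any expected cell < 5, else χ²),
which also serves unreplicated designs; more than two groups use one-way
ANOVA (replicated) or an n×n χ². The pseudo-count is 1 CPM. DE calls
gate on raw p (< α, default 0.05, warned outside [0.01, 0.05]) and
|log2FC| ≥ 1; BH q-values are reported but do not gate, since the
original thresholds filter on raw p. The in-package two-sided Fisher
test enumerates hypergeometric numerators as exact integers, so
equally-probable tables are included without floating-point tie
tolerances.

Low-count isomiR-level rows can fluctuate into marginal calls at shallow
depth (a handful of reads splitting cleanly between groups); no
abundance filter is imposed because the published thresholds do not
include one. Entity-level recovery — aggregating all isomiRs of a
planted miRNA — is the calibrated quantity the acceptance checks use.

## Target prediction

The seed scanner reports canonical site types on the UTR: 8mer
(complement of miRNA positions 2–8 plus A opposite position 1), 7mer-m8,
7mer-A1, and optionally 6mer (excluded by default, the common
TargetScan-style convention). Watson–Crick only in the seed.

The aligner is an affine-gap Smith–Waterman over complementarity:
match +5, G:U wobble +1, mismatch −3, gap open −9 / extend −4, all
doubled at miRNA positions 2–8; score threshold 140, duplex energy
threshold −20 kcal/mol. These mirror miRanda's conventional
parameterisation — the external tools' exact settings are unknowable, so
the values are declared stand-ins, all configurable. Duplex energy sums
the shared nearest-neighbour stacks over contiguously paired runs plus a
+4.09 initiation and a small per-interruption penalty. Non-overlapping
sites are extracted greedily best-first. The intersection keeps
(miRNA, transcript) pairs where both predictors report sites overlapping
by ≥1 nt — the "overlap of both algorithms" rule.

## Enrichment, networks, qPCR

Enrichment is the upper-tail hypergeometric over-representation test per
term (k ≥ 1), BH-adjusted within each ontology family (GO vs KEGG —
the source reports top-20 lists without naming a correction). Networks
are bipartite miRNA-vs-gene/term graphs; pathway networks keep terms
connected to at least 3 miRNAs by default (the text says "more than
three", a figure caption says "two/three"; 3 is the configurable
default). Hub ranking is by degree, ties alphabetical.

2^−ΔΔCt: per sample ΔCt = Ct(target) − Ct(reference); per group ΔΔCt =
mean ΔCt − mean control ΔCt (arithmetic means; the group summarisation
is unstated in most protocols); fold = 2^−ΔΔCt, control ≡ 1. The
reference gene is a per-assay input (U6 for miRNAs, GAPDH/β-actin for
mRNAs in the motivating study), never hard-coded. Folds are invariant
under any constant Ct shift, and log-folds antisymmetric under swapping
treated/control — both identities are tested.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 9 × 6,000 reads with a 30 kb
genome (about 15 s end-to-end); the analysis drivers use 9 × 20,000
reads with 60 kb; the acceptance script uses 100,000-read libraries for
the count-level statistics and the scaled pipeline for conservation
identities. These sizes were chosen so every planted effect is
detectable with margin at the stated dispersion; all scale linearly.
The folding DP and the aligner are numba-compiled; DP tie-breaks are
first-found under fixed iteration order, making structures
deterministic. All randomness descends from a single seed through
`numpy.random.SeedSequence`, and identical configurations produce
byte-identical output files.

## Interfaces

The library modules are the programmatic interface; the numbered scripts
under `analysis/` are the runnable surface for the end-to-end study, and
`mirforge.workflow.run_pipeline` orchestrates the same stages with a
manifest (stage parameters plus SHA-256 of every output) and a
truth-aware recovery report.

## Known limitations

* The energy model is a classification-grade nearest-neighbour
  approximation: no dangles, no coaxial-stack special cases, averaged
  wobble stacks, no multibranch loops. Absolute MFEs differ from
  ViennaRNA by a few kcal/mol; orderings of clearly-stable vs marginal
  stems agree.
* Homolog localisation is exact substring search, not alignment; a
  diverged precursor would be missed.
* The aligner reports at most one site per UTR region per round
  (greedy masking), so densely tiled sites may merge.
* Count-level tests ignore mapping multi-assignment: a read is credited
  to exactly one name.
* The generator's decoy flanks are composition-constrained (see above),
  a deliberate departure from uniform background local to those loci.
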