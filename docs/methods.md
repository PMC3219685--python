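# Methods

This note documents the models behind cvarkit, the defaults that matter, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and topology

Internal coordinates are 0-based half-open everywhere; GenBank/GFF3 1-based
inclusive coordinates are converted at the I/O boundary only, and all exports
are 1-based again. Replicons are circular by default: windows, scans and
upstream regions wrap the origin, and a feature spanning the origin is stored
with a `wraps_origin` flag as [start, L) ∪ [0, end). N bases are accepted in
sequences but excluded from every composition denominator, and any motif
window containing an N never matches.

## Composition tracks

G+C content and G/C skew (G−C)/(G+C) are computed in windows of 10 kb with a
10-kb step by default (non-overlapping windows at the plotted resolution of
typical circular genome figures; both configurable). Windows with G+C = 0
report a skew of 0 by convention.

## AIMS scan and the dif estimator

The two degenerate octamer families G(A/T/C)GGGGGA and (T/C)GGGGGAG expand
to exactly five forward 8-mers; their reverse complements form the
minus-strand set. The scan is exact string matching, counts overlapping
occurrences, and wraps the origin.

*dif* is inferred from the strand distribution of the hits anchored at
*oriC*. The model: each strand's hit process is Poisson with one rate per
replichore arc, and the rates switch at *dif* (forward octamers dominate the
*oriC*→*dif* arc). The default estimator maximizes the profile
log-likelihood Σ n·log(n/length) over the four (strand, arc) cells,
evaluated at each candidate boundary one base past a hit; ties break to the
smallest rotated coordinate. The classical raw reading — the global extremum
of the cumulative (+1/−1) curve — is available as `method="extremum"`, but
it is not the default because it fails in two reproducible ways: when total
plus and minus counts are unequal the cumulative curve drifts and its global
extremum can land at the arc boundary (a half-genome error), and local
random-walk excursions displace it by several kb even in balanced data. On
clean fixtures the two estimators coincide.

Known limitation: at the default synthetic study conditions (below), about
10% of runs place *dif* more than 2% of L from the planted truth. This is a
property of the data, not the estimator — at an i.i.d. 67% G+C background
the spurious octamer rate is ~0.4 hits/kb/strand against a planted density
of 1 hit/kb, and a large-deviation argument at this signal-to-noise ratio
predicts exactly this failure rate; a likelihood comparison shows the
misplaced optimum genuinely scores above the true position in those runs.
Real high-G+C chromosomes are less G-run-rich than an i.i.d. model of the
same composition, so the synthetic setting is conservative.

## oriC inference

*oriC* is placed at the densest cluster of DnaA boxes in the 1.5-kb region
downstream (in reading direction) of the *dnaA* stop codon. Defaults:
consensus TTGTCCACA (the corynebacterial box), ≤ 1 mismatch, both strands,
cluster = ≥ 4 boxes within 1 kb, position = midpoint between the first and
last box of the densest cluster. With fewer boxes the *dnaA* downstream
boundary is returned with a warning. All parameters are arguments.

## Replichores and strand bias

The *right* replichore is the clockwise (coordinate-increasing) arc
*oriC*→*dif*; *left* is the complementary arc. A gene's replichore is that
of its midpoint (computed circularly for origin-wrapping features) — robust
for genes straddling a boundary. Leading = (+ strand ∧ right) ∨ (− strand ∧
left). Strand-bias reports cover CDS features by default (RNA genes can be
included via `feature_types`) and accept a locus-tag subset, e.g. candidate
essential genes; per-replichore gene counts are always included since
left/right asymmetry is a separate observable from leading/lagging bias.

## Orthology and content partitioning

Pairwise scores are exact Smith–Waterman with affine gaps (a gap of length k
costs open + k·extend; defaults BLOSUM62, 11/1, floored at 0), computed by
Bio.Align.PairwiseAligner; an independent quadratic Gotoh DP in the test
suite verifies equality. Best hits take the maximal score with
deterministic tie-breaks (higher bitscore, lower e-value for hit tables,
then lexicographically smaller subject id), so results are independent of
input order. The acceptance threshold defaults to score/bitscore ≥ 50 with
no coverage filter; published Venn counts from genome papers depend on
unstated search cutoffs and are therefore treated as qualitative
reproduction goals only. RBH is strictly one-to-one: paralogs lose to the
single best hit. All-vs-all alignment beyond 10⁶ cell pairs warns and
recommends precomputed tables.

## PWM scanning and transcription units

PWMs use probabilities (count + c)/(n + 4c) with pseudocount c = 0.5 and
log2-odds against a background that defaults to uniform at build time; for
genome scans the genome's own mononucleotide frequencies are recommended
(`genome_background`), since at 67% G+C a uniform background misranks
G-rich sites. The scan threshold is 0.8 × max score by default,
overridable in absolute bits. Scanned regions are −300…+50 bp around each
annotated gene start, strand-aware, both strands; a window and its reverse
complement at one footprint are one operator reported on the + strand, and
a site upstream of divergent genes is one operator listing both targets.
Transcription units extend from each target gene downstream in transcription
direction over same-strand neighbours while the intergenic gap is ≤ 50 bp
(a common bacterial operon heuristic; configurable); the regulon's target
count is the union over units. Published operator/target counts depend on
unpublished site alignments and thresholds, so they are qualitative goals;
the binding-site alignment is user input.

## Secretome cascade

Classification order: no signal peptide → cytoplasmic; lipobox within the
first 40 residues → lipoprotein; predicted TM segments ≥ 1 → membrane;
twin-arginine motif within 35 residues followed by a 13-residue stretch of
mean Kyte–Doolittle hydropathy ≥ 1.0 → Tat substrate; otherwise SPase-I
secreted. Motif searches use the first 70 residues. The lipobox pattern and
window follow the DOLOP convention; the Tat rule approximates the published
TATFIND criteria. The precedence (lipobox before membrane before Tat)
mirrors the screening order used in genome-annotation practice and is
documented here because no single convention exists. External predictor
quality bounds the result: the classes are only as good as the
signal-peptide and TM calls supplied.

## Synthetic-data generators

`generate_genome` emulates a high-G+C circular chromosome: i.i.d. background
at G+C = 0.6715 (the genome-wide value of the high-G+C corynebacteria the
defaults model), L = 200 kb, *oriC* = 0, *dif* = L/2, 200 AIMS octamers at
leading-strand bias 0.9, 100 non-overlapping genes of 600–1500 bp (~52%
coding density — the highest the prescribed rejection-sampling placement
fills reliably) with leading-strand fraction 0.6, and optional operators
sampled from a PWM planted 80 bp upstream of randomly chosen genes. Planting
replaces bases in place so coordinates stay valid; genes are placed first,
then operators, then octamers (octamers may fall inside coding sequence, as
on real chromosomes, but never on an operator or each other). Everything is
a pure function of (spec, seed).

What it does not emulate: codon structure, operon organisation, repeats,
insertion sequences, G-run depletion, or compositional heterogeneity along
the chromosome. Consequences: spurious octamer hits are more frequent than
on real chromosomes of the same composition (see the dif limitation above),
and planted-recovery results bound what the pipeline would do on data whose
noise structure matches these assumptions, not on arbitrary real genomes.

`generate_ortholog_families` mutates one ancestor per family independently
per organism by per-site substitution at rate 1 − identity (no indels), so
two descendants of a family at target identity 0.7 share ≈ 0.49 pairwise
identity; organism-specific proteins are unrelated random sequences.
`generate_binding_sites` samples columns independently from the PWM's
implied probabilities.

## Problem sizes in the checks

The acceptance experiments run at: 50 × 200-kb genomes for dif recovery;
100-kb fixtures for scan-vs-naive equality; 50 protein pairs ≤ 60 aa for the
Smith–Waterman oracle; 20 seeds of 2 × 50-protein proteomes for RBH; 10,000
sampled sites for PWM weight recovery (a 12-column PWM without cells rarer
than p = 0.2, so the sampling error stays under the 0.1-bit check); 20 × 20
planted operators for scan sensitivity (a near-deterministic 14-bp PWM,
information content ≈ 28 bits — at a 0.8 × max threshold a single
off-consensus base already costs more than the scoring margin, so only
near-deterministic motifs can reach high self-recovery). Reported values in
`results/acceptance.json` are whatever these computations produce at the
given seed.
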