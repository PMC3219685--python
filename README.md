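# cvarkit

Replication-architecture, comparative gene-content, regulon and secretome
analysis for circular bacterial genomes — with seeded synthetic-genome
generators that carry planted ground truth, so every stage of the pipeline is
testable without downloading anything.

The package targets the kind of in-silico characterisation done for newly
sequenced actinobacterial chromosomes (its defaults are tuned to a high-G+C
corynebacterial genome of ~3.4 Mb), but every analysis works on any circular
replicon with a FASTA sequence and a CDS annotation.

## What it computes

**Replication architecture** (`cvarkit.architecture`). A bidirectionally
replicating circular chromosome is split by the replication origin (*oriC*)
and the terminus-region *dif* site into two replichores, each copied by one
fork. Three sequence signals locate this axis:

- the G/C skew, (G−C)/(G+C) in sliding windows, whose sign flips at *oriC*
  and *dif*;
- architecture-imparting sequences (AIMS) — the octamer families
  G(A/T/C)GGGGGA and (T/C)GGGGGAG, over-represented on the leading strand;
  walking clockwise from *oriC* and scoring +1 per forward-octamer hit and −1
  per reverse-octamer hit, the cumulative curve rises to *dif* and falls
  after it. `infer_dif` estimates the changepoint by maximum likelihood under
  a two-arc Poisson model of the per-strand hit rates (the raw
  cumulative-curve extremum is available as `method="extremum"`);
- the DnaA-box cluster (consensus TTGTCCACA, ≤1 mismatch, both strands)
  downstream of *dnaA*, whose densest cluster midpoint is *oriC*.

From the replichore model the package computes the leading-strand gene
fraction: a gene is *leading* when transcribed co-directionally with its
fork, i.e. a + strand gene in the *oriC*→*dif* arc or a − strand gene in the
other arc.

**Comparative content** (`cvarkit.comparative`). Orthologs between proteomes
are reciprocal best hits (RBH) under Smith–Waterman scores (BLOSUM62, affine
gaps; precomputed 12-column hit tables are accepted for genome-scale runs).
RBH maps against several reference proteomes partition the focal proteome
into Venn cells keyed by presence signature; the empty cell is the
species-specific gene set. Ortholog pairs projected onto chromosomal gene
ranks give synteny dot-plot coordinates.

**Regulon prediction** (`cvarkit.regulon`). A position weight matrix is
built from aligned binding sites, `weight(j,b) = log2[(count_j(b)+c)/(n+4c)
/ bg(b)]`, and the strand-aware upstream region (−300…+50 bp by default) of
every gene is scanned on both strands. Sites above threshold (default
0.8 × max score) are operators; a site shared by divergently transcribed
genes is one operator with two targets. Same-strand gene runs with
intergenic gaps ≤ 50 bp are chained into transcription units, giving
DtxR-/McbR-style regulon predictions.

**Secretome classification** (`cvarkit.secretome_motifs`). External
signal-peptide and transmembrane predictions (a 3-column table) are combined
with two motif rules — the lipobox [LVIFMSTAG][LVIASTG][GAS]C ending in the
lipidated cysteine, and the twin-arginine RRx[FGAVML][LITMVF] signature
followed by a hydrophobic stretch — into one class per protein:
lipoprotein, membrane, Tat substrate, Sec/SPase-I secreted, or cytoplasmic.

**Synthetic data** (`cvarkit.synthetic_data`). Seeded generators produce
circular chromosomes with planted AIMS octamers at a configurable
leading-strand bias around chosen *oriC*/*dif*, non-overlapping gene
annotations with a target leading-strand fraction, operator sites sampled
from a PWM, and proteome families with known ortholog pairings at controlled
divergence. All generators return the planted truth.

## Worked example

Generate a 200-kb synthetic chromosome (200 planted AIMS at bias 0.9,
planted *dif* at 100,000) and run the architecture report:

```sh
cvar-kit sim genome --seed 1 --out syn
cat > cfg.yaml <<EOF
genome: syn/genome.fasta
annotation: syn/genome.gff3
oric: 0
EOF
cvar-kit report --config cfg.yaml --out report.json
```

`report.json` (abridged):

```json
{
 "length_bp": 200000,
 "gc_percent": 67.34,
 "cds_count": 100,
 "aims": {"plus_hits": 184, "minus_hits": 189},
 "oric": {"position": 0, "source": "user"},
 "dif": {"position": 99815, "source": "AIMS strand-rate changepoint (mle)"},
 "replichores": {"right_bp": 99815, "left_bp": 100185},
 "strand_bias": {"n_total": 100, "n_leading": 54, "fraction_leading": 0.54}
}
```

The inferred *dif* (99,815) sits 185 bp from the planted truth (100,000,
recorded in `syn/truth.json`), the replichores are near-equal as planted,
and the leading-strand fraction 0.54 reflects the generator's target of 0.6
over 100 genes (binomial spread). Other subcommands follow the same
pattern: `cvar-kit arch tracks|aims|oric|dif|strandbias`, `cvar-kit comp
rbh|venn|synteny`, `cvar-kit reg build-pwm|scan|regulon`, `cvar-kit sec`,
`cvar-kit sim genome|families|sites`.

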