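"""Seeded generators for genomes, proteome families and binding sites.

Every generator is a pure function of its parameters and seed, and each
returns the planted ground truth alongside the data, so every pipeline stage
(AIMS/dif inference, RBH orthology, PWM scanning) can be validated against
known answers without external downloads.

The synthetic chromosome emulates the statistical structure of a real
high-G+C circular bacterial chromosome: background bases at a configurable
G+C (default 67.15%, typical of corynebacteria), the two AIMS octamer
families planted with a configurable leading-strand bias around chosen
oriC/dif positions, non-overlapping gene annotations with a target
leading-strand fraction, and optional operator sites drawn from a PWM planted
upstream of genes.  It does not emulate codon structure, operons, repeats or
mobile elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import build_replichore_model, expand_aims_motifs, revcomp
from .comparative import OrthologMap, Proteome
from .io_formats import FeatureTable, GeneFeature, Replicon
from .regulon import BASES, PWM, BindingSiteSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic circular chromosome."""

    length: int = 200_000
    oric: int = 0
    dif: int | None = None  # default: opposite oriC (length // 2)
    gc_content: float = 0.6715
    n_aims: int = 200
    aims_strand_bias: float = 0.9
    n_genes: int = 100
    gene_len_range: tuple[int, int] = (600, 1_500)
    leading_fraction: float = 0.6
    planted_pwm: PWM | None = None
    n_operators: int = 0
    operator_offset: int = 80  # bp between site start and gene start
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dif is None:
            self.dif = (self.oric + self.length // 2) % self.length
        if self.oric == self.dif:
            raise ValueError("oric must differ from dif")
        for name, frac in [("gc_content", self.gc_content),
                           ("leading_fraction", self.leading_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.5 <= self.aims_strand_bias <= 1.0:
            raise ValueError("aims_strand_bias outside [0.5, 1]")
        mean_len = sum(self.gene_len_range) / 2
        if self.n_genes * mean_len >= self.length:
            raise ValueError("spec infeasible: genes do not fit")


@dataclass
class SyntheticTruth:
    """A generated genome plus every planted coordinate."""

    replicon: Replicon
    table: FeatureTable
    true_oric: int
    true_dif: int
    planted_plus: list[int]
    planted_minus: list[int]
    planted_operator_positions: list[int] = field(default_factory=list)
    gene_leading_labels: dict[str, str] = field(default_factory=dict)


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticTruth:
    """Generate a chromosome with planted AIMS, genes and operators.

    Motifs and operator sites replace background bases in place, so all
    coordinates stay valid.  Identical spec + seed give identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    p_gc = spec.gc_content / 2
    p_at = (1 - spec.gc_content) / 2
    seq = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=L,
                     p=[p_at, p_gc, p_gc, p_at])
    model = build_replichore_model(L, spec.oric, spec.dif)
    motifs = expand_aims_motifs()

    # --- genes: non-overlapping, strand set to hit leading_fraction in expectation
    gene_occupied = np.zeros(L, dtype=bool)
    features: list[GeneFeature] = []
    labels: dict[str, str] = {}
    for i in range(spec.n_genes):
        glen = int(rng.integers(spec.gene_len_range[0], spec.gene_len_range[1] + 1))
        start = _place_interval(rng, gene_occupied, glen, L)
        mid = start + glen // 2
        leading_strand = "+" if model.in_right(mid) else "-"
        if rng.random() < spec.leading_fraction:
            strand, label = leading_strand, "leading"
        else:
            strand, label = ("-" if leading_strand == "+" else "+"), "lagging"
        tag = f"SYN_{i + 1:04d}"
        features.append(GeneFeature(tag, start, start + glen, strand, "CDS"))
        labels[tag] = label
    table = FeatureTable(replicon_id="synthetic", features=features)

    # --- operators planted upstream of randomly chosen genes
    reserved = np.zeros(L, dtype=bool)  # footprints no later planting may touch
    operator_positions: list[int] = []
    if spec.planted_pwm is not None and spec.n_operators > 0:
        w = spec.planted_pwm.width
        candidates = [f for f in table
                      if _upstream_start(f, spec.operator_offset, w, L) is not None]
        if len(candidates) < spec.n_operators:
            raise ValueError("spec infeasible: not enough genes for operators")
        idx = rng.choice(len(candidates), size=spec.n_operators, replace=False)
        for i in sorted(idx):
            gene = candidates[i]
            site = _sample_site(rng, spec.planted_pwm)
            pos = _upstream_start(gene, spec.operator_offset, w, L)
            planted = site if gene.strand == "+" else revcomp(site)
            seq[pos : pos + w] = np.frombuffer(planted.encode(), np.uint8)
            reserved[pos : pos + w] = True
            operator_positions.append(pos)

    # --- AIMS: forward octamer on + strand is "leading" in the right
    # replichore; a reverse octamer is "leading" in the left replichore.
    # Octamers may fall inside coding regions (as on real chromosomes) but
    # never on top of an operator or another planted octamer.
    planted_plus: list[int] = []
    planted_minus: list[int] = []
    for pos in _sample_clear_positions(rng, reserved, spec.n_aims, 8, L):
        octamer = motifs.forward_octamers[rng.integers(5)]
        leading_is_plus = model.in_right((pos + 4) % L)
        plus = leading_is_plus if rng.random() < spec.aims_strand_bias else not leading_is_plus
        if plus:
            planted_plus.append(pos)
        else:
            octamer = revcomp(octamer)
            planted_minus.append(pos)
        seq[pos : pos + 8] = np.frombuffer(octamer.encode(), np.uint8)

    rep = Replicon(id="synthetic", seq=seq.tobytes().decode("ascii"), circular=True)
    return SyntheticTruth(
        replicon=rep, table=table, true_oric=spec.oric, true_dif=spec.dif,
        planted_plus=sorted(planted_plus), planted_minus=sorted(planted_minus),
        planted_operator_positions=operator_positions,
        gene_leading_labels=labels,
    )


def _upstream_start(gene: GeneFeature, offset: int, width: int, L: int) -> int | None:
    """Forward-strand start of an operator ``offset`` bp upstream of the gene start."""
    if gene.strand == "+":
        pos = gene.start - offset - width
    else:
        pos = gene.end + offset
    if 0 <= pos and pos + width <= L:
        return pos
    return None


def _sample_clear_positions(rng, occupied, n, width, L, max_attempts=1_000):
    out = []
    for _ in range(n):
        for _ in range(max_attempts):
            pos = int(rng.integers(0, L - width))
            if not occupied[pos : pos + width].any():
                occupied[pos : pos + width] = True
                out.append(pos)
                break
        else:
            raise ValueError("spec infeasible: motif placement failed")
    return out


def _place_interval(rng, occupied, glen, L, max_attempts=1_000):
    for _ in range(max_attempts):
        start = int(rng.integers(0, L - glen))
        if not occupied[start : start + glen].any():
            occupied[start : start + glen] = True
            return start
    raise ValueError("spec infeasible: genes do not fit")


def _sample_site(rng, pwm: PWM) -> str:
    probs = pwm.probabilities()
    return "".join(BASES[rng.choice(4, p=probs[j])] for j in range(pwm.width))


# ---------------------------------------------------------------------------
# Proteome families


def generate_ortholog_families(
    n_organisms: int,
    n_core: int,
    n_specific_per_org: int,
    identity: float,
    seed: int,
    length_range: tuple[int, int] = (80, 200),
) -> tuple[list[Proteome], dict[tuple[str, str], OrthologMap]]:
    """Proteomes with planted one-to-one ortholog families.

    Each core family descends from one random ancestor, mutated independently
    per organism by per-site substitution at rate 1 − identity (no indels);
    specific proteins are unrelated random sequences.  Returns the proteomes
    and the true OrthologMap for every ordered organism pair.
    """
    if not 0.3 < identity <= 1.0:
        raise ValueError("identity outside (0.3, 1]")
    rng = np.random.default_rng(seed)
    orgs = [f"org{i + 1}" for i in range(n_organisms)]
    proteomes = {o: {} for o in orgs}
    for fam in range(n_core):
        ancestor = _random_protein(rng, length_range)
        for o in orgs:
            pid = f"{o}_core{fam + 1:04d}"
            proteomes[o][pid] = _mutate(rng, ancestor, 1 - identity)
    for o in orgs:
        for k in range(n_specific_per_org):
            proteomes[o][f"{o}_spec{k + 1:04d}"] = _random_protein(rng, length_range)
    out = [Proteome(organism_id=o, proteins=proteomes[o]) for o in orgs]
    maps = {}
    for i, a in enumerate(orgs):
        for b in orgs[i + 1 :]:
            pairs = frozenset(
                (f"{a}_core{f + 1:04d}", f"{b}_core{f + 1:04d}") for f in range(n_core)
            )
            maps[(a, b)] = OrthologMap(organism_pair=(a, b), pairs=pairs)
    return out, maps


def _random_protein(rng, length_range) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n - 1))


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = AMINO_ACIDS.replace(seq[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Binding sites


def generate_binding_sites(pwm: PWM, n: int, seed: int, regulator: str | None = None) -> BindingSiteSet:
    """Sample ``n`` sites column-independently from the PWM's probability model."""
    rng = np.random.default_rng(seed)
    probs = pwm.probabilities()
    sites = [
        "".join(BASES[rng.choice(4, p=probs[j])] for j in range(pwm.width))
        for _ in range(n)
    ]
    return BindingSiteSet(regulator=regulator or pwm.regulator, sites=sites,
                          source=f"sampled(seed={seed})")
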