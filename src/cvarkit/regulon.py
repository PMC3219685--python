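"""PWM-based operator scanning and regulon reconstruction.

A transcription-factor binding motif is modelled as a position weight matrix
(PWM) of per-position log-odds weights, built from an alignment of validated
binding sites.  The genome is scanned in the upstream regions of annotated
genes on both strands; windows scoring above a threshold become operator
hits, shared sites in front of divergently transcribed gene pairs collapse to
a single operator, and same-strand gene runs downstream of each target are
chained into transcription units — together a predicted regulon (DtxR-, McbR-,
GlxR- or LexA-style).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import revcomp
from .io_formats import FeatureTable, Replicon

logger = logging.getLogger(__name__)

BASES = "ACGT"
UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}

DEFAULT_UPSTREAM = 300
DEFAULT_DOWNSTREAM = 50
DEFAULT_THRESHOLD = 0.8  # fraction of max_score
DEFAULT_MAX_GAP = 50
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class BindingSiteSet:
    """An alignment of equal-length binding sites for one regulator."""

    regulator: str
    sites: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("empty site set" if not self.sites else "need >= 2 sites")
        widths = {len(s) for s in self.sites}
        if len(widths) != 1:
            raise ValueError("ragged site set")
        if self.width < 6:
            raise ValueError("sites shorter than 6 bp")
        for s in self.sites:
            if set(s) - set(BASES):
                raise ValueError(f"site {s!r} outside ACGT")

    @property
    def width(self) -> int:
        return len(self.sites[0])


def read_binding_sites(path: str | Path, regulator: str) -> BindingSiteSet:
    """Read aligned sites from FASTA or one-site-per-line plain text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        sites = []
        for chunk in text.split(">")[1:]:
            lines = chunk.splitlines()
            sites.append("".join(lines[1:]).upper())
    else:
        sites = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
    return BindingSiteSet(regulator=regulator, sites=sites, source=str(path))


@dataclass
class PWM:
    """Per-position log2-odds weights (bits) over A, C, G, T."""

    regulator: str
    weights: np.ndarray  # shape (width, 4), base order ACGT
    background: dict[str, float]
    pseudocount: float

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def information_content(self) -> float:
        """Total information (bits) relative to the background, summed over columns."""
        bg = np.array([self.background[b] for b in BASES])
        p = bg * np.exp2(self.weights)
        p /= p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
        return float(terms.sum())

    def probabilities(self) -> np.ndarray:
        """Recover the per-column base probabilities implied by the weights."""
        bg = np.array([self.background[b] for b in BASES])
        p = bg * np.exp2(self.weights)
        return p / p.sum(axis=1, keepdims=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "regulator": self.regulator,
            "width": self.width,
            "bases": BASES,
            "weights": self.weights.tolist(),
            "background": self.background,
            "pseudocount": self.pseudocount,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PWM":
        d = json.loads(Path(path).read_text())
        return cls(
            regulator=d["regulator"],
            weights=np.array(d["weights"], dtype=float),
            background=d["background"],
            pseudocount=d["pseudocount"],
        )


def build_pwm(
    sites: BindingSiteSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: dict[str, float] | None = None,
) -> PWM:
    """Log-odds PWM: weight(j, b) = log2[(count_j(b) + c) / (n + 4c) / bg(b)].

    ``pseudocount = 0`` is allowed but any zero count then yields a −inf
    weight; a warning is emitted.
    """
    if pseudocount < 0:
        raise ValueError("negative pseudocount")
    background = dict(background or UNIFORM_BACKGROUND)
    if abs(sum(background.values()) - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    n = len(sites.sites)
    counts = np.zeros((sites.width, 4))
    for s in sites.sites:
        for j, b in enumerate(s):
            counts[j, BASES.index(b)] += 1
    if pseudocount == 0 and (counts == 0).any():
        logger.warning("pseudocount 0 with zero counts: -inf weights in PWM")
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.array([background[b] for b in BASES])
    with np.errstate(divide="ignore"):
        weights = np.log2(probs / bg)
    return PWM(regulator=sites.regulator, weights=weights,
               background=background, pseudocount=pseudocount)


def genome_background(rep: Replicon) -> dict[str, float]:
    """Mononucleotide background frequencies of a replicon (N excluded)."""
    counts = {b: rep.seq.count(b) for b in BASES}
    total = sum(counts.values())
    return {b: counts[b] / total for b in BASES}


def score_window(pwm: PWM, window: str) -> float:
    """Sum of per-position weights for one window (no N allowed)."""
    if len(window) != pwm.width:
        raise ValueError(f"window width {len(window)} != PWM width {pwm.width}")
    return float(sum(pwm.weights[j, BASES.index(b)] for j, b in enumerate(window)))


# ---------------------------------------------------------------------------
# Genome-wide upstream scan


@dataclass
class OperatorHit:
    """One operator site: forward-strand window start, strand, score, targets."""

    position: int
    strand: str
    score: float
    upstream_of: list[str] = field(default_factory=list)


@dataclass
class RegulonPrediction:
    regulator: str
    operators: list[OperatorHit]
    transcription_units: list[tuple[str, ...]]

    @property
    def n_target_genes(self) -> int:
        return len({g for tu in self.transcription_units for g in tu})


def _resolve_threshold(pwm: PWM, threshold: float, kind: str) -> float:
    if kind == "fraction":
        if not 0 < threshold <= 1:
            raise ValueError("fraction threshold must be in (0, 1]")
        return threshold * pwm.max_score
    if kind == "bits":
        return threshold
    raise ValueError(f"unknown threshold kind {kind!r}")


def scan_upstream_regions(
    pwm: PWM,
    rep: Replicon,
    table: FeatureTable,
    upstream_len: int = DEFAULT_UPSTREAM,
    downstream_len: int = DEFAULT_DOWNSTREAM,
    threshold: float = DEFAULT_THRESHOLD,
    threshold_kind: str = "fraction",
    feature_types: tuple[str, ...] = ("CDS",),
) -> list[OperatorHit]:
    """Scan the strand-aware region around each gene start on both strands.

    For a + strand gene the region is [start − upstream, start + downstream);
    for a − strand gene it is the mirror image around the gene's start codon.
    A window and its reverse complement at one physical footprint are a single
    operator, reported on the + strand; a site shared by divergently
    transcribed genes is one hit listing both targets.  N-containing windows
    are skipped.
    """
    if upstream_len <= 0:
        raise ValueError("invalid region")
    cutoff = _resolve_threshold(pwm, threshold, threshold_kind)
    L, w = rep.length, pwm.width
    col = [np.array([pwm.weights[j, BASES.index(b)] if b in BASES else -np.inf
                     for b in "ACGTN"]) for j in range(w)]
    base_idx = {b: i for i, b in enumerate("ACGTN")}
    hits: dict[tuple[int, str], OperatorHit] = {}
    span = upstream_len + downstream_len
    for gene in table.of_type(*feature_types):
        if gene.strand == "+":
            region_start = (gene.start - upstream_len) % L
        else:
            region_start = (gene.end - downstream_len) % L
        region = _extract(rep, region_start, span + w - 1)
        for off in range(span):
            window = region[off : off + w]
            if len(window) < w or "N" in window:
                continue
            pos = (region_start + off) % L
            s_fwd = float(sum(c[base_idx[b]] for c, b in zip(col, window)))
            s_rev = score_window(pwm, revcomp(window))
            score, strand = max((s_fwd, "+"), (s_rev, "-"), key=lambda t: (t[0], t[1] == "+"))
            if score < cutoff:
                continue
            key = (pos, strand)
            hit = hits.get(key)
            if hit is None:
                hits[key] = OperatorHit(pos, strand, score, [gene.locus_tag])
            elif gene.locus_tag not in hit.upstream_of:
                hit.upstream_of.append(gene.locus_tag)
    out = sorted(hits.values(), key=lambda h: (h.position, h.strand))
    for h in out:
        h.upstream_of.sort()
    return out


def _extract(rep: Replicon, start: int, length: int) -> str:
    start %= rep.length
    end = start + length
    if end <= rep.length:
        return rep.seq[start:end]
    if rep.circular:
        return rep.seq[start:] + rep.seq[: end - rep.length]
    return rep.seq[start:]


# ---------------------------------------------------------------------------
# Transcription units


def chain_transcription_units(
    operators: list[OperatorHit],
    table: FeatureTable,
    max_gap: int = DEFAULT_MAX_GAP,
    regulator: str = "regulator",
) -> RegulonPrediction:
    """Chain each operator target into a transcription unit.

    From the target gene, extension proceeds downstream in the direction of
    transcription over same-strand neighbours while the intergenic gap stays
    <= ``max_gap``; units hit by several operators count once in the target
    union.
    """
    feats = list(table.features)
    index = {f.locus_tag: i for i, f in enumerate(feats)}
    units: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for op in operators:
        for tag in op.upstream_of:
            i = index[tag]
            unit = [feats[i].locus_tag]
            if feats[i].strand == "+":
                j = i
                while j + 1 < len(feats):
                    gap = feats[j + 1].start - feats[j].end
                    if feats[j + 1].strand != "+" or gap > max_gap or gap < -feats[j].span():
                        break
                    j += 1
                    unit.append(feats[j].locus_tag)
            else:
                j = i
                while j - 1 >= 0:
                    gap = feats[j].start - feats[j - 1].end
                    if feats[j - 1].strand != "-" or gap > max_gap or gap < -feats[j].span():
                        break
                    j -= 1
                    unit.append(feats[j].locus_tag)
            tu = tuple(unit)
            if tu not in seen:
                seen.add(tu)
                units.append(tu)
    return RegulonPrediction(regulator=regulator, operators=operators,
                             transcription_units=units)
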