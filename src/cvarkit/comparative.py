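"""Reciprocal-best-hit orthology, gene-content partitioning and synteny dots.

Orthologs between two proteomes are called as reciprocal best hits (RBH): a
pair (a, b) such that b is a's highest-scoring match and vice versa — the
standard one-to-one orthology proxy.  Scores come either from a precomputed
12-column similarity table or, at desk scale, from the built-in Smith–Waterman
aligner.  RBH maps against several comparison proteomes then partition the
focal proteome into presence/absence cells (a Venn partition), and ortholog
pairs projected onto chromosomal gene ranks give synteny dot-plot data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import SimilarityHit

logger = logging.getLogger(__name__)

#: all-vs-all cell count above which the internal aligner warns (use hit tables)
ALIGNER_GUARD_CELLS = 1_000_000

DEFAULT_MIN_SCORE = 50.0


@dataclass
class Proteome:
    """The predicted protein complement of one organism.

    ``order`` lists protein ids in chromosomal order and is only needed for
    synteny; it defaults to insertion order of ``proteins``.
    """

    organism_id: str
    proteins: dict[str, str]
    order: list[str] | None = None

    def __post_init__(self) -> None:
        if self.order is None:
            self.order = list(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)


def read_proteome(path, organism_id: str) -> Proteome:
    proteins = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins[rec.id] = str(rec.seq).upper().rstrip("*")
    return Proteome(organism_id=organism_id, proteins=proteins)


@dataclass
class OrthologMap:
    organism_pair: tuple[str, str]
    pairs: frozenset[tuple[str, str]]

    def transpose(self) -> "OrthologMap":
        return OrthologMap(
            organism_pair=(self.organism_pair[1], self.organism_pair[0]),
            pairs=frozenset((b, a) for a, b in self.pairs),
        )

    def partner_of(self) -> dict[str, str]:
        """Mapping from first-organism protein id to its ortholog."""
        return dict(self.pairs)


@dataclass
class ContentPartition:
    """Venn partition of a focal proteome by RBH presence in other organisms."""

    focal_organism: str
    cells: dict[frozenset[str], set[str]]

    @property
    def specific(self) -> set[str]:
        return self.cells.get(frozenset(), set())

    def cell_sizes(self) -> dict[str, int]:
        return {
            "+".join(sorted(sig)) if sig else "specific": len(prots)
            for sig, prots in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        }


# ---------------------------------------------------------------------------
# Alignment


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ValueError(f"matrix not available: {matrix_name!r}")
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    # first gap position costs open+extend, each further position costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith–Waterman local alignment score with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  The score is
    floored at 0 (the empty local alignment), hence symmetric and nonnegative.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    return max(float(_aligner(matrix_name, gap_open, gap_extend).score(a, b)), 0.0)


# ---------------------------------------------------------------------------
# Best hits / RBH


def best_hits(
    query: Proteome,
    subject: Proteome,
    hits: list[SimilarityHit] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    **align_kwargs,
) -> dict[str, str]:
    """Best subject per query.

    Ties break by higher bitscore, then lower e-value (hit tables only), then
    lexicographically smaller subject id, so the result is independent of
    input order.  Queries whose best score falls below ``min_score`` are
    absent from the mapping.
    """
    if hits is not None:
        return _best_from_table(query, subject, hits, min_score)
    n_cells = len(query) * len(subject)
    if n_cells > ALIGNER_GUARD_CELLS:
        logger.warning(
            "%d x %d all-vs-all (%d cells) with the internal aligner; "
            "precomputed hit tables are recommended at this scale",
            len(query), len(subject), n_cells,
        )
    out: dict[str, str] = {}
    for qid in sorted(query.proteins):
        best_sid, best_score = None, min_score
        for sid in sorted(subject.proteins):
            s = local_align_score(query.proteins[qid], subject.proteins[sid], **align_kwargs)
            if s > best_score or (s == best_score and best_sid is not None and sid < best_sid):
                best_sid, best_score = sid, s
        if best_sid is not None:
            out[qid] = best_sid
    return out


def _best_from_table(query, subject, hits, min_score):
    known_q, known_s = set(query.proteins), set(subject.proteins)
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id not in known_q or h.subject_id not in known_s:
            raise ValueError(f"unknown protein id in hit {h.query_id}->{h.subject_id}")
        if h.bitscore < min_score:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def _hit_key(h: SimilarityHit):
    return (-h.bitscore, h.evalue, h.subject_id)


def reciprocal_best_hits(
    p1: Proteome,
    p2: Proteome,
    hits12: list[SimilarityHit] | None = None,
    hits21: list[SimilarityHit] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    **align_kwargs,
) -> OrthologMap:
    """One-to-one ortholog pairs: mutual best hits between two proteomes."""
    fwd = best_hits(p1, p2, hits12, min_score, **align_kwargs)
    rev = best_hits(p2, p1, hits21, min_score, **align_kwargs)
    pairs = frozenset((a, b) for a, b in fwd.items() if rev.get(b) == a)
    return OrthologMap(organism_pair=(p1.organism_id, p2.organism_id), pairs=pairs)


# ---------------------------------------------------------------------------
# Content partition and synteny


def partition_content(
    focal: Proteome,
    others: list[Proteome],
    maps: list[OrthologMap],
) -> ContentPartition:
    """Assign each focal protein its presence signature across ``others``.

    The empty signature is the organism-"specific" cell; cells are disjoint by
    construction and jointly cover the focal proteome.
    """
    if len(others) != len(maps):
        raise ValueError("one OrthologMap required per comparison organism")
    partners: dict[str, set[str]] = {pid: set() for pid in focal.proteins}
    for other, omap in zip(others, maps):
        pair = omap.organism_pair
        if pair == (focal.organism_id, other.organism_id):
            oriented = omap
        elif pair == (other.organism_id, focal.organism_id):
            oriented = omap.transpose()
        else:
            raise ValueError(f"map/organism mismatch: {pair} vs {other.organism_id}")
        for a, _ in oriented.pairs:
            partners[a].add(other.organism_id)
    cells: dict[frozenset[str], set[str]] = {}
    for pid, sig in partners.items():
        cells.setdefault(frozenset(sig), set()).add(pid)
    return ContentPartition(focal_organism=focal.organism_id, cells=cells)


def synteny_map(
    order_a: list[str],
    order_b: list[str],
    omap: OrthologMap,
) -> list[tuple[int, int]]:
    """Dot-plot coordinates: (rank in genome A, rank in genome B) per ortholog pair."""
    rank_a = {pid: i for i, pid in enumerate(order_a)}
    rank_b = {pid: i for i, pid in enumerate(order_b)}
    dots = []
    for a, b in omap.pairs:
        if a not in rank_a or b not in rank_b:
            raise ValueError(f"protein absent from order: {a if a not in rank_a else b}")
        dots.append((rank_a[a], rank_b[b]))
    return sorted(dots)
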