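"""Readers, writers and container types for the external formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; GenBank and
GFF3 use 1-based inclusive coordinates, and the conversion happens here and
nowhere else.  Features spanning the origin of a circular replicon carry a
``wraps_origin`` flag and occupy ``[start, L) ∪ [0, end)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

DEFAULT_FEATURE_TYPES = ("CDS", "rRNA", "tRNA")


@dataclass(frozen=True)
class Replicon:
    """A single (normally circular) DNA replicon."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("no sequence")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"invalid alphabet: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneFeature:
    """One annotated feature in internal 0-based half-open coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # '+' or '-'
    ftype: str = "CDS"
    product: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("negative start")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(
                f"{self.locus_tag}: end must exceed start unless wraps_origin"
            )

    def span(self, length: int | None = None) -> int:
        if self.wraps_origin:
            if length is None:
                raise ValueError("length required for origin-wrapping feature")
            return (self.end - self.start) % length
        return self.end - self.start

    def midpoint(self, length: int | None = None) -> int:
        """Feature midpoint, computed circularly for origin-wrapping features."""
        if self.wraps_origin:
            if length is None:
                raise ValueError("length required for origin-wrapping feature")
            return (self.start + self.span(length) // 2) % length
        return self.start + (self.end - self.start) // 2


@dataclass
class FeatureTable:
    """Ordered gene features for one replicon, sorted by start coordinate."""

    replicon_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus tags: {dup}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_tag(self, tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == tag:
                return f
        raise KeyError(tag)

    def of_type(self, *ftypes: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype in ftypes]


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular similarity search (BLAST outfmt 6 layout)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("negative bitscore")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")


@dataclass(frozen=True)
class PredictorRecord:
    """External predictor summary for one protein (signal peptide + TM count)."""

    protein_id: str
    signal_peptide: bool
    tm_segment_count: int = 0

    def __post_init__(self) -> None:
        if self.tm_segment_count < 0:
            raise ValueError("negative tm_segment_count")


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path: str | Path, circular: bool = True) -> Replicon:
    """Read a single-replicon genome FASTA.

    Multi-record files are legal input for a single-chromosome study: the
    first record is used and a warning is logged, never silently.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequence in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if "U" in seq:
        raise ValueError("invalid alphabet: RNA (U) not accepted, DNA only")
    return Replicon(id=rec.id, seq=seq, circular=circular)


def write_genome_fasta(rep: Replicon, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(rep.seq), id=rep.id, description="")], str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> ordered mapping id -> sequence (insertion order kept)."""
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"{rec.id}: invalid amino-acid characters {sorted(bad)}")
        if rec.id in proteins:
            raise ValueError(f"duplicate protein id {rec.id}")
        proteins[rec.id] = seq
    return proteins


# ---------------------------------------------------------------------------
# Feature tables (GenBank / GFF3)


def read_feature_table(
    path: str | Path,
    dialect: str,
    replicon_length: int,
    keep_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
) -> FeatureTable:
    """Read CDS/rRNA/tRNA features from a GenBank flat file or GFF3.

    Source 1-based inclusive coordinates become internal 0-based half-open.
    Features without a locus tag get ``anon_<n>`` with a warning.
    """
    if dialect == "genbank":
        feats, rid = _read_genbank(path, replicon_length, keep_types)
    elif dialect == "gff3":
        feats, rid = _read_gff3(path, replicon_length, keep_types)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return FeatureTable(replicon_id=rid, features=feats)


def _check_range(start: int, end: int, length: int, where: str) -> None:
    if start < 0 or start >= length or end > length:
        raise ValueError(f"coordinate out of range in {where}: [{start}, {end}) vs L={length}")


def _anon_tag(counter: list[int]) -> str:
    counter[0] += 1
    logger.warning("feature without locus tag; assigned anon_%d", counter[0])
    return f"anon_{counter[0]}"


def _read_genbank(path, replicon_length, keep_types):
    rec = SeqIO.read(str(path), "genbank")
    feats: list[GeneFeature] = []
    anon = [0]
    for f in rec.features:
        if f.type not in keep_types:
            continue
        strand = "-" if f.location.strand == -1 else "+"
        tag = f.qualifiers.get("locus_tag", [None])[0] or _anon_tag(anon)
        product = f.qualifiers.get("product", [None])[0]
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        wraps = False
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == replicon_length:
            # join(x..L, 1..y): stored as [x, L) ∪ [0, y)
            start, end, wraps = int(parts[1].start), int(parts[0].end), True
        else:
            start, end = int(f.location.start), int(f.location.end)
            _check_range(start, end, replicon_length, tag)
        feats.append(GeneFeature(tag, start, end, strand, f.type, product, wraps))
    return feats, rec.id


def _read_gff3(path, replicon_length, keep_types):
    from gffutils.iterators import DataIterator

    feats: list[GeneFeature] = []
    anon = [0]
    rid = None
    for f in DataIterator(str(path)):
        if f.featuretype not in keep_types:
            continue
        rid = rid or f.seqid
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        tag = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [None])[0]
        tag = tag or _anon_tag(anon)
        _check_range(start, end, replicon_length, tag)
        product = (f.attributes.get("product") or [None])[0]
        strand = "-" if f.strand == "-" else "+"
        feats.append(GeneFeature(tag, start, end, strand, f.featuretype, product))
    return feats, rid or "unknown"


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    dialect: str,
    replicon_length: int,
    seq: str | None = None,
) -> None:
    """Write a FeatureTable as GFF3 or GenBank (1-based inclusive on disk)."""
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for f in table:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            lines.append(
                "\t".join(
                    [table.replicon_id, "cvarkit", f.ftype, str(f.start + 1),
                     str(f.end), ".", f.strand, ".", attrs]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")
    elif dialect == "genbank":
        rec = SeqRecord(
            Seq(seq if seq is not None else "N" * replicon_length),
            id=table.replicon_id, name=table.replicon_id[:16],
            annotations={"molecule_type": "DNA", "topology": "circular"},
        )
        for f in table:
            strand = -1 if f.strand == "-" else 1
            if f.wraps_origin:
                loc = CompoundLocation(
                    [SimpleLocation(f.start, replicon_length, strand),
                     SimpleLocation(0, f.end, strand)]
                )
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            quals = {"locus_tag": [f.locus_tag]}
            if f.product:
                quals["product"] = [f.product]
            rec.features.append(SeqFeature(loc, type=f.ftype, qualifiers=quals))
        SeqIO.write([rec], str(path), "genbank")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_TAG_RE = re.compile(r"^(.*?)(\d+)$")


def count_features_in_range(table: FeatureTable, first_tag: str, last_tag: str) -> int:
    """Count features whose locus-tag numeric suffix lies in the closed range.

    Both tags must share the prefix of a ``<prefix><zero-padded int>`` scheme,
    e.g. ``CVAR_0826`` .. ``CVAR_0886``.
    """
    m1, m2 = _TAG_RE.match(first_tag), _TAG_RE.match(last_tag)
    if not (m1 and m2) or m1.group(1) != m2.group(1):
        raise ValueError(f"incompatible tag range: {first_tag!r} .. {last_tag!r}")
    prefix = m1.group(1)
    lo, hi = int(m1.group(2)), int(m2.group(2))
    if lo > hi:
        lo, hi = hi, lo
    n = 0
    for f in table:
        m = _TAG_RE.match(f.locus_tag)
        if m and m.group(1) == prefix and lo <= int(m.group(2)) <= hi:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Tabular inputs


_HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Read a 12-column tab-separated similarity table (BLAST outfmt 6 layout)."""
    text = Path(path).read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not rows:
        return []
    for i, ln in enumerate(rows, start=1):
        if len(ln.split("\t")) != 12:
            raise ValueError(f"malformed hit row {i}: expected 12 columns")
    df = pd.read_csv(
        Path(path), sep="\t", comment="#", header=None, names=_HIT_COLUMNS,
        dtype={"query_id": str, "subject_id": str}, float_precision="round_trip",
    )
    return [
        SimilarityHit(
            query_id=r.query_id, subject_id=r.subject_id,
            pct_identity=float(r.pct_identity), aln_length=int(r.aln_length),
            evalue=float(r.evalue), bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def read_predictor_table(path: str | Path) -> list[PredictorRecord]:
    """Read the 3-column predictor table: protein_id, signal_peptide {0,1}, tm_segment_count."""
    records: list[PredictorRecord] = []
    seen: set[str] = set()
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 3:
            raise ValueError(f"malformed predictor row {i}: expected 3 columns")
        pid, sig, tm = cols
        if pid in seen:
            raise ValueError(f"ambiguous predictor input: duplicate rows for {pid}")
        seen.add(pid)
        records.append(PredictorRecord(pid, bool(int(sig)), int(tm)))
    return records
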