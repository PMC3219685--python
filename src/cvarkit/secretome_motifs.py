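"""Secretome classification from signal-peptide motifs and predictor tables.

Exported proteins carry N-terminal signal peptides.  Lipoproteins are
recognised by signal peptidase II at a four-residue lipobox ending in the
invariant lipidated cysteine; Tat substrates carry the twin-arginine
R-R-x-φ-φ signature followed by a hydrophobic stretch; membrane proteins are
flagged by transmembrane-helix predictors.  This module applies those motif
rules to protein sequences and combines them with external predictor calls
(signal peptide yes/no, transmembrane segment count) into one mutually
exclusive class per protein:

    no signal peptide              -> cytoplasmic
    signal + lipobox               -> lipoprotein
    signal + TM segments           -> membrane
    signal + twin-arginine motif   -> tat_substrate
    signal, none of the above      -> secreted_spaseI
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .io_formats import PredictorRecord

#: lipobox [L V I F M S T A G][L V I A S T G][G A S]C; the C is the +1 residue
LIPOBOX_PATTERN = r"[LVIFMSTAG][LVIASTG][GAS]C"
LIPOBOX_WINDOW = 40

#: twin-arginine signature RRx[FGAVML][LITMVF] + hydrophobic stretch
TAT_PATTERN = r"RR.[FGAVML][LITMVF]"
TAT_WINDOW = 35
TAT_HYDRO_LEN = 13
TAT_HYDRO_MIN = 1.0

#: Kyte–Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

CLASSES = ("lipoprotein", "membrane", "tat_substrate", "secreted_spaseI", "cytoplasmic")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")


@dataclass(frozen=True)
class MotifMatch:
    kind: str  # 'lipobox' or 'tat'
    start: int  # 0-based residue offset of the motif
    matched: str


def find_lipobox(
    p: ProteinRecord,
    window: int = LIPOBOX_WINDOW,
    pattern: str = LIPOBOX_PATTERN,
) -> MotifMatch | None:
    """First lipobox whose four residues lie entirely within the N-terminal window."""
    m = re.search(pattern, p.seq[:window])
    if m is None:
        return None
    return MotifMatch(kind="lipobox", start=m.start(), matched=m.group())


def mean_hydropathy(stretch: str) -> float:
    if not stretch:
        return float("-inf")
    return sum(KYTE_DOOLITTLE.get(a, 0.0) for a in stretch) / len(stretch)


def find_tat_motif(
    p: ProteinRecord,
    window: int = TAT_WINDOW,
    hydro_len: int = TAT_HYDRO_LEN,
    hydro_min: float = TAT_HYDRO_MIN,
    pattern: str = TAT_PATTERN,
) -> MotifMatch | None:
    """First twin-arginine motif in the window followed by a hydrophobic stretch.

    The stretch is the ``hydro_len`` residues directly after the 5-residue
    motif; its Kyte–Doolittle mean must reach ``hydro_min``.
    """
    for m in re.finditer(pattern, p.seq[:window]):
        stretch = p.seq[m.end() : m.end() + hydro_len]
        if len(stretch) == hydro_len and mean_hydropathy(stretch) >= hydro_min:
            return MotifMatch(kind="tat", start=m.start(), matched=m.group())
    return None


@dataclass
class SecretomeClassification:
    per_protein: dict[str, str]
    evidence: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.per_protein.values())
        return {cls: c.get(cls, 0) for cls in CLASSES}

    @property
    def n_secreted(self) -> int:
        """Signal-peptide-positive proteins (everything but cytoplasmic)."""
        return sum(v for k, v in self.counts.items() if k != "cytoplasmic")


def classify_secretome(
    proteins: list[ProteinRecord],
    predictors: list[PredictorRecord],
    tm_threshold: int = 1,
    n_terminal: int = 70,
) -> SecretomeClassification:
    """Apply the classification cascade to every protein.

    Motif searches use the first ``n_terminal`` residues.  Proteins absent
    from the predictor table default to no signal peptide and zero TM
    segments.  Precedence is lipoprotein > membrane > tat > secreted.
    """
    by_id: dict[str, PredictorRecord] = {}
    for r in predictors:
        if r.protein_id in by_id:
            raise ValueError(f"ambiguous predictor input: duplicate rows for {r.protein_id}")
        by_id[r.protein_id] = r
    per_protein: dict[str, str] = {}
    evidence: dict[str, str] = {}
    for p in proteins:
        rec = by_id.get(p.id)
        nterm = ProteinRecord(p.id, p.seq[:n_terminal])
        if rec is None or not rec.signal_peptide:
            per_protein[p.id] = "cytoplasmic"
            evidence[p.id] = "no_signal_peptide"
            continue
        lipo = find_lipobox(nterm)
        if lipo is not None:
            per_protein[p.id] = "lipoprotein"
            evidence[p.id] = f"lipobox@{lipo.start}:{lipo.matched}"
            continue
        if rec.tm_segment_count >= tm_threshold:
            per_protein[p.id] = "membrane"
            evidence[p.id] = f"tm_segments={rec.tm_segment_count}"
            continue
        tat = find_tat_motif(nterm)
        if tat is not None:
            per_protein[p.id] = "tat_substrate"
            evidence[p.id] = f"tat@{tat.start}:{tat.matched}"
            continue
        per_protein[p.id] = "secreted_spaseI"
        evidence[p.id] = "signal_peptide_only"
    return SecretomeClassification(per_protein=per_protein, evidence=evidence)
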