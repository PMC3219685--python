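"""Track export and the one-shot JSON architecture report.

``export_tracks`` resamples every per-position signal (CDS density by strand,
G+C content, G/C skew, cumulative AIMS) onto one common position axis for
circular-plot tools; ``run_report`` orchestrates the whole pipeline from a
config mapping and returns a single JSON-serialisable summary in which every
number is tagged with the producing parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .architecture import (
    AIMSProfile,
    SkewProfile,
    build_replichore_model,
    infer_dif,
    infer_oric,
    scan_aims,
    strand_bias_report,
    windowed_composition,
)
from .io_formats import (
    FeatureTable,
    Replicon,
    read_feature_table,
    read_genome_fasta,
)

logger = logging.getLogger(__name__)

RRN_CLUSTER_GAP = 10_000
RRN_RULE = f"rRNA features clustered when consecutive same-strand gaps <= {RRN_CLUSTER_GAP} bp"


@dataclass
class TrackBundle:
    replicon_id: str
    step: int
    positions: np.ndarray  # 0-based window starts; exported 1-based
    tracks: dict[str, np.ndarray]

    def to_tsv(self, path: str | Path) -> None:
        names = list(self.tracks)
        lines = ["\t".join(["position"] + names)]
        for i, pos in enumerate(self.positions):
            row = [str(int(pos) + 1)] + [f"{self.tracks[n][i]:.6g}" for n in names]
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


def export_tracks(
    rep: Replicon,
    table: FeatureTable,
    profile: SkewProfile,
    aims: AIMSProfile,
    step: int = 10_000,
) -> TrackBundle:
    """Resample all architecture signals onto one common step grid."""
    if table.replicon_id not in (rep.id, "synthetic") and table.replicon_id != rep.id:
        raise ValueError(f"inconsistent inputs: {table.replicon_id} vs {rep.id}")
    L = rep.length
    starts = np.arange(0, L, step)
    cov_plus = np.zeros(L, dtype=np.int8)
    cov_minus = np.zeros(L, dtype=np.int8)
    for f in table.of_type("CDS"):
        cov = cov_plus if f.strand == "+" else cov_minus
        if f.wraps_origin:
            cov[f.start :] = 1
            cov[: f.end] = 1
        else:
            cov[f.start : f.end] = 1
    csum_p = np.concatenate([[0], np.cumsum(cov_plus)])
    csum_m = np.concatenate([[0], np.cumsum(cov_minus)])
    ends = np.minimum(starts + step, L)
    widths = ends - starts
    cds_plus = (csum_p[ends] - csum_p[starts]) / widths
    cds_minus = (csum_m[ends] - csum_m[starts]) / widths

    def resample(centers, values):
        idx = np.searchsorted(np.sort(centers), starts, side="right") - 1
        order = np.argsort(centers)
        return np.asarray(values)[order][np.clip(idx, 0, len(values) - 1)]

    from bisect import bisect_right

    cum = np.array(
        [bisect_right(aims.plus_positions, s) - bisect_right(aims.minus_positions, s)
         for s in starts],
        dtype=float,
    )
    return TrackBundle(
        replicon_id=rep.id,
        step=step,
        positions=starts,
        tracks={
            "cds_plus": cds_plus,
            "cds_minus": cds_minus,
            "gc_content": resample(profile.centers, profile.gc_content),
            "gc_skew": resample(profile.centers, profile.gc_skew),
            "cumulative_aims": cum,
        },
    )


def count_rrn_operons(table: FeatureTable, max_gap: int = RRN_CLUSTER_GAP) -> int:
    """Count rRNA operons: runs of same-strand rRNA genes with gaps <= max_gap."""
    rrnas = sorted(table.of_type("rRNA"), key=lambda f: f.start)
    if not rrnas:
        return 0
    n = 1
    for prev, cur in zip(rrnas, rrnas[1:]):
        if cur.strand != prev.strand or cur.start - prev.end > max_gap:
            n += 1
    return n


def run_report(config: dict) -> dict:
    """Run the architecture pipeline per a config mapping and return the summary.

    Mandatory key: ``genome`` (FASTA path).  Optional: ``annotation`` +
    ``annotation_dialect``, ``dnaa_tag``, ``oric`` (explicit position),
    ``window``, ``step``, ``essential_subset`` (file of locus tags).
    Sections for which inputs are missing are simply omitted.
    """
    if "genome" not in config:
        raise ValueError("missing mandatory input: genome")
    window = int(config.get("window", 10_000))
    step = int(config.get("step", 10_000))
    rep = read_genome_fasta(config["genome"])
    counts = {b: rep.seq.count(b) for b in "ACGT"}
    acgt = sum(counts.values())
    out: dict = {
        "cvarkit_version": __version__,
        "replicon": rep.id,
        "length_bp": rep.length,
        "gc_percent": round(100 * (counts["G"] + counts["C"]) / acgt, 2),
        "parameters": {"window": window, "step": step},
    }
    if "annotation" not in config:
        return out

    table = read_feature_table(
        config["annotation"], config.get("annotation_dialect", "gff3"), rep.length
    )
    out["cds_count"] = len(table.of_type("CDS"))
    out["rrn_operons"] = {"count": count_rrn_operons(table), "rule": RRN_RULE}

    aims = scan_aims(rep)
    out["aims"] = {"plus_hits": len(aims.plus_positions),
                   "minus_hits": len(aims.minus_positions)}
    if "oric" in config:
        oric = int(config["oric"])
        oric_source = "user"
    else:
        try:
            oric = infer_oric(rep, table, config.get("dnaa_tag"))
            oric_source = "dnaA-box cluster"
        except ValueError as e:
            logger.warning("oriC inference failed (%s); skipping replichore analysis", e)
            return out
    try:
        dif = infer_dif(aims, oric)
    except ValueError as e:
        logger.warning("dif inference failed: %s", e)
        return out
    model = build_replichore_model(rep.length, oric, dif)
    out["oric"] = {"position": oric, "source": oric_source}
    out["dif"] = {"position": dif, "source": "AIMS strand-rate changepoint (mle)"}
    out["replichores"] = {"right_bp": model.right_size, "left_bp": model.left_size}
    bias = strand_bias_report(table, model)
    out["strand_bias"] = {
        "label": bias.subset_label,
        "n_total": bias.n_total,
        "n_leading": bias.n_leading,
        "fraction_leading": round(bias.fraction_leading, 4),
        "per_replichore": {"left": bias.n_left, "right": bias.n_right},
    }
    if "essential_subset" in config:
        tags = [t.strip() for t in Path(config["essential_subset"]).read_text().split()
                if t.strip()]
        sub = strand_bias_report(table, model, subset=tags, label="essential subset")
        out["strand_bias_essential"] = {
            "n_total": sub.n_total,
            "fraction_leading": round(sub.fraction_leading, 4),
            "per_replichore": {"left": sub.n_left, "right": sub.n_right},
        }
    return out
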