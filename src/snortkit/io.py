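"""Readers and writers for the standard formats the pipeline consumes.

Dialect conventions: GTF is 1-based inclusive on disk and converted to the
internal 0-based half-open coordinates on read; BED is already 0-based
half-open.  TSV outputs always carry a header line and a stable column
order so runs can be diffed.
"""
from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .annotation import (
    BiotypePartition,
    GenomicInterval,
    SnoRNARecord,
    SnoRTCall,
    TranscriptModel,
)
from .errors import AnnotationError

log = logging.getLogger(__name__)

_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type")


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    ``transcript_biotype`` and ``transcript_type`` are accepted as synonyms;
    the biotype may sit on the transcript or on its exon records.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        exons_by_tid.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
        if tid not in meta:
            meta[tid] = {"gene_id": f.attributes["gene_id"][0]}
        for key in _BIOTYPE_KEYS:
            if key in f.attributes:
                meta[tid].setdefault("biotype", f.attributes[key][0])
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        for key in _BIOTYPE_KEYS:
            if key in f.attributes and tid in meta:
                meta[tid]["biotype"] = f.attributes[key][0]
                break
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            exons=tuple(exons),
            biotype=meta[tid].get("biotype", "protein_coding"),
        )
        for tid, exons in exons_by_tid.items()
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            span = t.span
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "snortkit",
                        "transcript",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "snortkit",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_snorna_bed(
    bed_path: str | os.PathLike,
    classes_path: str | os.PathLike | None = None,
) -> list[SnoRNARecord]:
    """Read snoRNA loci from BED6(+1).

    The class may sit in BED column 7 or in a sidecar TSV
    (``sno_id  sno_class  [host_gene_id  pocket5  pocket3]``) given as
    ``classes_path``; the sidecar wins and is the only source of pockets.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#", dtype=str)
    if bed.shape[1] < 6:
        raise AnnotationError("snoRNA BED needs at least 6 columns")
    side = None
    if classes_path is not None:
        side = pd.read_csv(classes_path, sep="\t", dtype=str).set_index("sno_id")
    records = []
    for row in bed.itertuples(index=False):
        sno_id = row[3]
        sno_class = row[6] if bed.shape[1] > 6 else None
        host = pocket5 = pocket3 = None
        if side is not None and sno_id in side.index:
            s = side.loc[sno_id]
            sno_class = s["sno_class"]
            host = s.get("host_gene_id")
            pocket5 = s.get("pocket5")
            pocket3 = s.get("pocket3")
            host = None if pd.isna(host) else host
            pocket5 = None if pd.isna(pocket5) else pocket5
            pocket3 = None if pd.isna(pocket3) else pocket3
        if sno_class is None:
            raise AnnotationError(
                f"{sno_id}: no class in BED column 7 or sidecar TSV"
            )
        records.append(
            SnoRNARecord(
                sno_id=sno_id,
                interval=GenomicInterval(row[0], int(row[1]), int(row[2]), row[5]),
                sno_class=sno_class,
                host_gene_id=host,
                pocket5=pocket5,
                pocket3=pocket3,
            )
        )
    return records


def write_snorna_bed(
    snos: Sequence[SnoRNARecord],
    bed_path: str | os.PathLike,
    classes_path: str | os.PathLike,
) -> None:
    with open(bed_path, "w") as fh:
        for s in snos:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.sno_id}\t0\t{iv.strand}\n"
            )
    pd.DataFrame(
        {
            "sno_id": [s.sno_id for s in snos],
            "sno_class": [s.sno_class for s in snos],
            "host_gene_id": [s.host_gene_id or "" for s in snos],
            "pocket5": [s.pocket5 or "" for s in snos],
            "pocket3": [s.pocket3 or "" for s in snos],
        }
    ).to_csv(classes_path, sep="\t", index=False)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load all sequences of a FASTA file into memory (uppercased)."""
    fa = Fasta(str(path))
    return {name: str(rec[:]).upper() for name, rec in fa.items()}


def write_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_peaks_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, float]]:
    """Read a peak set from BED6+ (narrowPeak accepted; extra columns
    ignored).  Returns (interval, score) pairs."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if bed.shape[1] < 6:
        raise AnnotationError("peak BED needs at least 6 columns")
    peaks = []
    for row in bed.itertuples(index=False):
        score = float(row[4]) if row[4] not in (".", "") else 0.0
        peaks.append(
            (GenomicInterval(row[0], int(row[1]), int(row[2]), row[5]), score)
        )
    return peaks


def write_peaks_bed(
    peaks: Sequence[tuple[GenomicInterval, float]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for i, (iv, score) in enumerate(peaks):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i + 1}\t{score:g}\t{iv.strand}\n"
            )


def write_snort_calls(calls: Sequence[SnoRTCall], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "contained_sno_ids": [",".join(c.contained_sno_ids) for c in calls],
            "sno_classes": [",".join(sorted(c.sno_classes)) for c in calls],
            "retained_chrom": [c.retained_region.chrom for c in calls],
            "retained_start": [c.retained_region.start for c in calls],
            "retained_end": [c.retained_region.end for c in calls],
            "retained_strand": [c.retained_region.strand for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def write_partition(part: BiotypePartition, path: str | os.PathLike) -> None:
    shares = part.shares()
    rows = []
    for cat in part.CATEGORIES:
        for tid in getattr(part, cat):
            rows.append({"transcript_id": tid, "category": cat,
                         "category_percent": shares.get(cat, float("nan"))})
    pd.DataFrame(rows, columns=["transcript_id", "category", "category_percent"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts(
    counts_path: str | os.PathLike, samples_path: str | os.PathLike
):
    """Read a count matrix TSV (feature_id + one column per sample) and a
    sample sheet TSV (sample_id, condition[, replicate])."""
    from .enrichment import CountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    condition = dict(zip(samples["sample_id"], samples["condition"]))
    missing = set(condition) - set(counts.columns)
    if missing:
        raise AnnotationError(f"samples absent from count matrix: {sorted(missing)}")
    counts = counts[list(condition)]
    return CountMatrix(
        feature_ids=list(counts.index),
        sample_ids=list(counts.columns),
        condition=condition,
        counts=counts.to_numpy(dtype=int),
    )


def read_psi_sites(path: str | os.PathLike):
    """Read a pseudouridine-site catalogue TSV
    (site_id, transcript_id, position, flank5, flank3)."""
    from .psi import PsiSite

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PsiSite(
            site_id=r.site_id,
            transcript_id=r.transcript_id,
            position=int(r.position),
            flank5=r.flank5,
            flank3=r.flank3,
        )
        for r in df.itertuples(index=False)
    ]


def write_psi_sites(sites: Iterable, path: str | os.PathLike) -> None:
    sites = list(sites)
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "transcript_id": [s.transcript_id for s in sites],
            "position": [s.position for s in sites],
            "flank5": [s.flank5 for s in sites],
            "flank3": [s.flank3 for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)
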