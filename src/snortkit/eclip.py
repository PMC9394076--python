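"""Cross-classification of RIP targets against an eCLIP peak set.

eCLIP peaks mark direct protein-RNA contacts, so a RIP target overlapped
by a peak is classed as directly bound (subdivided by whether it is a
snoRNA/scaRNA, a snoRT, or any other transcript).  Targets without peak
coverage but carrying a binding-consensus sequence are "motif_supported";
everything else is presumed indirectly bound (e.g. tethered through a
guide snoRNA).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import (
    BiotypePartition,
    GenomicInterval,
    SnoRTCall,
    TranscriptModel,
)
from .errors import MissingAnnotationError

log = logging.getLogger(__name__)

CATEGORIES = (
    "direct_snoRNA",
    "direct_snoRT",
    "direct_other",
    "motif_supported",
    "indirect",
)


@dataclass(frozen=True)
class BindingClassification:
    transcript_id: str
    category: str
    n_overlapping_peaks: int


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def classify_binding(
    targets: Iterable[str],
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    snort_calls: Sequence[SnoRTCall],
    partition: BiotypePartition,
    peaks: Sequence[tuple[GenomicInterval, float]],
    consensus_hits: Iterable[str],
    mode: str = "any_overlap",
    min_cov_frac: float = 0.05,
    intron_restricted: bool = False,
) -> list[BindingClassification]:
    """Classify each target transcript by its eCLIP support.

    A transcript "has coverage" when >=1 peak overlaps its exonic span by
    >=1 bp (``mode='any_overlap'``) or when the covered fraction of the
    exonic span reaches ``min_cov_frac`` (``mode='fraction'``).  With
    ``intron_restricted=True``, snoRT coverage is assessed only over the
    retained region.  ``consensus_hits`` is the set of transcript ids with
    at least one binding-consensus occurrence.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    targets = list(targets)
    call_by_tid = {c.transcript_id: c for c in snort_calls}
    sno_set = set(partition.sno_and_sca)
    hits = set(consensus_hits)

    peak_chroms = {iv.chrom for iv, _ in peaks}
    target_chroms = {
        transcripts[t].chrom for t in targets if t in transcripts
    }
    if peaks and targets and not (peak_chroms & target_chroms):
        log.warning(
            "peak and transcript chromosome names are disjoint; "
            "possible coordinate-system mismatch"
        )

    out = []
    for tid in targets:
        t = transcripts.get(tid)
        if t is None:
            raise MissingAnnotationError(f"target {tid!r} not in annotation")
        call = call_by_tid.get(tid)
        if intron_restricted and call is not None:
            regions = [call.retained_region]
        else:
            regions = t.exonic_blocks()
        overlapping = [
            (iv, s)
            for iv, s in peaks
            if any(_overlap_bp(iv, r) > 0 for r in regions)
        ]
        if mode == "any_overlap":
            covered = bool(overlapping)
        elif mode == "fraction":
            span = sum(r.length for r in regions)
            bp = sum(
                max(_overlap_bp(iv, r) for r in regions) for iv, _ in overlapping
            ) if overlapping else 0
            covered = span > 0 and bp / span >= min_cov_frac
        else:
            raise ValueError(f"unknown coverage mode {mode!r}")

        if covered and tid in sno_set:
            category = "direct_snoRNA"
        elif covered and call is not None:
            category = "direct_snoRT"
        elif covered:
            category = "direct_other"
        elif tid in hits:
            category = "motif_supported"
        else:
            category = "indirect"
        out.append(
            BindingClassification(
                transcript_id=tid,
                category=category,
                n_overlapping_peaks=len(overlapping),
            )
        )
    return out


def category_counts(classifications: Sequence[BindingClassification]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        counts[cl.category] += 1
    return counts
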