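"""Transcript models, snoRT identification and biotype partitioning.

A snoRT (snoRNA-retaining transcript) is an mRNA isoform whose mature
(exonic) sequence fully contains a snoRNA that, in the canonical spliced
isoform of the same gene, lies inside an intron.  Host genes of intronic
H/ACA-box snoRNAs are the substrate of the cytoplasmic dyskerin interactome,
so the central verdict here is "this isoform retains an intron that carries
a complete snoRNA".

Coordinates are 0-based half-open throughout; GTF I/O converts at the
boundary (see :mod:`snortkit.io`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import percent
from .errors import AnnotationError, MissingAnnotationError

log = logging.getLogger(__name__)

#: snoRNA class labels.  scaRNAs are carried with their box sub-class so that
#: snoRT classification can treat them as H/ACA or C/D.
HACA_CLASSES = frozenset({"HACA", "SCA_HACA"})
CD_CLASSES = frozenset({"CD", "SCA_CD"})
SNO_CLASSES = HACA_CLASSES | CD_CLASSES


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully inside this interval (same chrom and
        strand)."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """An isoform: ordered exons on one chromosome/strand plus a biotype."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Mature (exonic) length."""
        return sum(e.length for e in self.exons)

    def exonic_blocks(self) -> list[GenomicInterval]:
        """Maximal contiguous exonic runs (abutting exons merged)."""
        blocks: list[list[int]] = []
        for e in self.exons:
            if blocks and e.start == blocks[-1][1]:
                blocks[-1][1] = e.end
            else:
                blocks.append([e.start, e.end])
        return [GenomicInterval(self.chrom, s, t, self.strand) for s, t in blocks]

    def contains_in_exons(self, iv: GenomicInterval) -> bool:
        """True if ``iv`` is fully covered by this transcript's exons."""
        return any(b.contains(iv) for b in self.exonic_blocks())


@dataclass(frozen=True)
class SnoRNARecord:
    """A snoRNA locus; pockets are the two antisense elements of one
    pseudouridylation pocket, used for guide-target matching."""

    sno_id: str
    interval: GenomicInterval
    sno_class: str
    host_gene_id: str | None = None
    pocket5: str | None = None
    pocket3: str | None = None

    def __post_init__(self) -> None:
        if self.sno_class not in SNO_CLASSES:
            raise AnnotationError(
                f"{self.sno_id}: unknown snoRNA class {self.sno_class!r}"
            )
        for name in ("pocket5", "pocket3"):
            p = getattr(self, name)
            if p is not None:
                if not (3 <= len(p) <= 12) or set(p) - set("ACGU"):
                    raise AnnotationError(
                        f"{self.sno_id}: {name} must be 3-12 nt over ACGU, got {p!r}"
                    )

    @property
    def is_haca(self) -> bool:
        return self.sno_class in HACA_CLASSES


@dataclass(frozen=True)
class SnoRTCall:
    """Verdict that an isoform retains an intron carrying >=1 snoRNA."""

    transcript_id: str
    contained_sno_ids: tuple[str, ...]
    sno_classes: frozenset[str]
    retained_region: GenomicInterval

    @property
    def is_haca(self) -> bool:
        return bool(self.sno_classes & HACA_CLASSES)


@dataclass
class BiotypePartition:
    """Disjoint partition of a transcript set into reporting categories."""

    sno_and_sca: list[str] = field(default_factory=list)
    haca_snort: list[str] = field(default_factory=list)
    other_snort: list[str] = field(default_factory=list)
    protein_coding_other: list[str] = field(default_factory=list)
    remaining: list[str] = field(default_factory=list)

    CATEGORIES = (
        "sno_and_sca",
        "haca_snort",
        "other_snort",
        "protein_coding_other",
        "remaining",
    )

    def sizes(self) -> dict[str, int]:
        return {c: len(getattr(self, c)) for c in self.CATEGORIES}

    @property
    def total(self) -> int:
        return sum(self.sizes().values())

    def shares(self) -> dict[str, float]:
        """Category percentages of the input size, rounded half-up to one
        decimal.  Empty input yields an empty mapping."""
        n = self.total
        if n == 0:
            return {}
        return {c: percent(len(getattr(self, c)), n) for c in self.CATEGORIES}

    def category_of(self, transcript_id: str) -> str:
        for c in self.CATEGORIES:
            if transcript_id in getattr(self, c):
                return c
        raise KeyError(transcript_id)


def derive_introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in genomic order.

    Single-exon transcripts (and abutting exons) yield no introns.
    """
    introns = []
    for a, b in zip(t.exons, t.exons[1:]):
        if b.start > a.end:
            introns.append(GenomicInterval(t.chrom, a.end, b.start, t.strand))
    return introns


def identify_snorts(
    transcripts: Sequence[TranscriptModel],
    snos: Sequence[SnoRNARecord],
    require_sibling_intron: bool = True,
) -> list[SnoRTCall]:
    """Identify snoRT isoforms.

    A transcript is called iff at least one same-strand snoRNA is fully
    contained in its exonic coverage and — when the gene has sibling
    isoforms — that snoRNA lies within an intron of at least one sibling
    (i.e. the region is retained relative to a spliced isoform).
    Single-isoform genes fall back to plain exonic containment, as do all
    genes when ``require_sibling_intron`` is False.
    """
    known_chroms = {t.chrom for t in transcripts}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    usable = []
    for sno in snos:
        if sno.interval.chrom not in known_chroms:
            log.warning(
                "snoRNA %s on chromosome %s absent from the annotation; skipped",
                sno.sno_id,
                sno.interval.chrom,
            )
            continue
        usable.append(sno)

    calls = []
    for t in transcripts:
        siblings = [s for s in by_gene[t.gene_id] if s.transcript_id != t.transcript_id]
        contained: list[SnoRNARecord] = []
        for sno in usable:
            if not t.contains_in_exons(sno.interval):
                continue
            if require_sibling_intron and siblings:
                in_sibling_intron = any(
                    intron.contains(sno.interval)
                    for sib in siblings
                    for intron in derive_introns(sib)
                )
                if not in_sibling_intron:
                    continue
            contained.append(sno)
        if contained:
            blocks = [
                b
                for b in t.exonic_blocks()
                if any(b.contains(s.interval) for s in contained)
            ]
            region = GenomicInterval(
                t.chrom,
                min(b.start for b in blocks),
                max(b.end for b in blocks),
                t.strand,
            )
            calls.append(
                SnoRTCall(
                    transcript_id=t.transcript_id,
                    contained_sno_ids=tuple(s.sno_id for s in contained),
                    sno_classes=frozenset(s.sno_class for s in contained),
                    retained_region=region,
                )
            )
    return calls


def partition_biotypes(
    ids: Iterable[str],
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    snort_calls: Sequence[SnoRTCall],
) -> BiotypePartition:
    """Partition transcript ids into the five reporting categories.

    Precedence: snoRNA/scaRNA biotype > H/ACA snoRT > other snoRT >
    protein_coding > remaining.  Every id must exist in the annotation.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    call_by_tid = {c.transcript_id: c for c in snort_calls}

    part = BiotypePartition()
    for tid in ids:
        t = transcripts.get(tid)
        if t is None:
            raise MissingAnnotationError(f"transcript {tid!r} not in annotation")
        call = call_by_tid.get(tid)
        if t.biotype in ("snoRNA", "scaRNA"):
            part.sno_and_sca.append(tid)
        elif call is not None and call.is_haca:
            part.haca_snort.append(tid)
        elif call is not None:
            part.other_snort.append(tid)
        elif t.biotype == "protein_coding":
            part.protein_coding_other.append(tid)
        else:
            part.remaining.append(tid)
    return part
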