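"""snoRT identification and biotype partitioning."""
import numpy as np
import pytest

from snortkit.annotation import (
    BiotypePartition,
    GenomicInterval,
    TranscriptModel,
    derive_introns,
    identify_snorts,
    partition_biotypes,
)
from snortkit.errors import AnnotationError, MissingAnnotationError

from conftest import make_sno, make_transcript


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(100, 200), (300, 400)], [(200, 300)]),
        ([(100, 400)], []),
        ([(0, 10), (10, 20)], []),  # abutting: zero-length gap dropped
        ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
    ],
)
def test_derive_introns(exons, expected):
    t = make_transcript("T1", "G1", exons)
    assert [(i.start, i.end) for i in derive_introns(t)] == expected


def test_overlapping_exons_rejected():
    with pytest.raises(AnnotationError):
        make_transcript("T1", "G1", [(0, 100), (50, 150)])


def test_interval_validation():
    with pytest.raises(AnnotationError):
        GenomicInterval("chr1", 10, 10, "+")
    with pytest.raises(AnnotationError):
        GenomicInterval("chr1", 0, 5, "*")


class TestIdentifySnorts:
    def _gene(self):
        spliced = make_transcript("A", "G1", [(0, 100), (300, 400)])
        retained = make_transcript(
            "B", "G1", [(0, 400)], biotype="retained_intron"
        )
        return spliced, retained

    def test_retained_isoform_called_spliced_not(self):
        spliced, retained = self._gene()
        sno = make_sno("S1", 150, 250)
        calls = identify_snorts([spliced, retained], [sno])
        assert [c.transcript_id for c in calls] == ["B"]
        assert calls[0].contained_sno_ids == ("S1",)
        assert calls[0].sno_classes == frozenset({"HACA"})

    def test_opposite_strand_sno_not_called(self):
        spliced, retained = self._gene()
        sno = make_sno("S1", 150, 250, strand="-")
        assert identify_snorts([spliced, retained], [sno]) == []

    def test_partial_overlap_not_called(self):
        # snoRNA straddling the transcript end: not fully contained
        spliced, retained = self._gene()
        sno = make_sno("S1", 350, 450)
        assert identify_snorts([spliced, retained], [sno]) == []

    def test_sibling_intron_requirement(self):
        # sno inside B's exon but NOT inside any sibling intron -> no call
        spliced = make_transcript("A", "G1", [(0, 100), (300, 400)])
        b = make_transcript("B", "G1", [(0, 400)])
        sno = make_sno("S1", 10, 90)  # inside A's first exon too
        assert identify_snorts([spliced, b], [sno]) == []

    def test_single_isoform_gene_falls_back_to_containment(self):
        only = make_transcript("L", "G2", [(0, 300)])
        sno = make_sno("S1", 50, 180)
        calls = identify_snorts([only], [sno])
        assert [c.transcript_id for c in calls] == ["L"]

    def test_unknown_chrom_sno_skipped_with_warning(self, caplog):
        spliced, retained = self._gene()
        sno = make_sno("S1", 150, 250, chrom="chrUnknown")
        with caplog.at_level("WARNING"):
            calls = identify_snorts([spliced, retained], [sno])
        assert calls == []
        assert "chrUnknown" in caplog.text

    def test_agrees_with_brute_force_scan(self):
        """Containment calls match an O(n*m) interval scan on random
        annotations (sibling rule disabled to isolate containment)."""
        rng = np.random.default_rng(11)
        transcripts, snos = [], []
        for i in range(200):
            s = int(rng.integers(0, 5000))
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], s
            for _ in range(n_ex):
                e = pos + int(rng.integers(50, 200))
                exons.append((pos, e))
                pos = e + int(rng.integers(1, 100))
            transcripts.append(
                make_transcript(
                    f"T{i}", f"G{i}", exons,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        for j in range(50):
            s = int(rng.integers(0, 6000))
            snos.append(
                make_sno(
                    f"S{j}", s, s + int(rng.integers(30, 150)),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        calls = identify_snorts(transcripts, snos, require_sibling_intron=False)
        got = {c.transcript_id: set(c.contained_sno_ids) for c in calls}
        expected = {}
        for t in transcripts:
            inside = {
                s.sno_id
                for s in snos
                if any(
                    e.chrom == s.interval.chrom
                    and e.strand == s.interval.strand
                    and e.start <= s.interval.start
                    and s.interval.end <= e.end
                    for e in t.exonic_blocks()
                )
            }
            if inside:
                expected[t.transcript_id] = inside
        assert got == expected

    def test_invariant_under_exon_permutation_and_chrom_renaming(self):
        spliced, retained = self._gene()
        sno = make_sno("S1", 150, 250)
        base = identify_snorts([spliced, retained], [sno])

        shuffled = make_transcript("A", "G1", [(300, 400), (0, 100)])
        again = identify_snorts([shuffled, retained], [sno])
        assert [c.transcript_id for c in again] == [
            c.transcript_id for c in base
        ]

        renamed = identify_snorts(
            [
                make_transcript("A", "G1", [(0, 100), (300, 400)], chrom="X"),
                make_transcript(
                    "B", "G1", [(0, 400)], chrom="X", biotype="retained_intron"
                ),
            ],
            [make_sno("S1", 150, 250, chrom="X")],
        )
        assert [c.transcript_id for c in renamed] == [
            c.transcript_id for c in base
        ]


class TestPartition:
    def _setup(self):
        ts = {
            "SNO1": make_transcript("SNO1", "GS1", [(0, 100)], biotype="snoRNA"),
            "SCA1": make_transcript("SCA1", "GS2", [(200, 300)], biotype="scaRNA"),
            "RT1": make_transcript(
                "RT1", "G1", [(400, 900)], biotype="retained_intron"
            ),
            "RT2": make_transcript(
                "RT2", "G2", [(1000, 1500)], biotype="retained_intron"
            ),
            "PC1": make_transcript("PC1", "G3", [(2000, 2300)]),
            "LNC1": make_transcript("LNC1", "G4", [(3000, 3200)], biotype="lncRNA"),
        }
        calls = identify_snorts(
            list(ts.values()),
            [
                make_sno("S1", 500, 630),
                make_sno("S2", 1100, 1230, sno_class="CD"),
            ],
            require_sibling_intron=False,
        )
        return ts, calls

    def test_precedence_and_percentages(self):
        ts, calls = self._setup()
        part = partition_biotypes(list(ts), ts, calls)
        assert part.sno_and_sca == ["SNO1", "SCA1"]
        assert part.haca_snort == ["RT1"]
        assert part.other_snort == ["RT2"]
        assert part.protein_coding_other == ["PC1"]
        assert part.remaining == ["LNC1"]
        shares = part.shares()
        assert shares["sno_and_sca"] == 33.3
        assert abs(sum(shares.values()) - 100.0) < 0.5

    def test_empty_input(self):
        ts, calls = self._setup()
        part = partition_biotypes([], ts, calls)
        assert part.total == 0
        assert part.shares() == {}

    def test_unknown_id_raises(self):
        ts, calls = self._setup()
        with pytest.raises(MissingAnnotationError, match="NOPE"):
            partition_biotypes(["NOPE"], ts, calls)

    def test_partition_matches_generator_labels(self, default_dataset):
        ds = default_dataset
        calls = identify_snorts(ds.transcripts, ds.snos)
        ids = list(ds.truth_transcripts["transcript_id"])
        part = partition_biotypes(ids, ds.transcripts, calls)
        truth = ds.truth_transcripts.set_index("transcript_id")[
            "partition_category"
        ]
        for cat in BiotypePartition.CATEGORIES:
            for tid in getattr(part, cat):
                assert truth[tid] == cat

    def test_disjoint_and_complete_on_random_subsets(self, default_dataset):
        ds = default_dataset
        calls = identify_snorts(ds.transcripts, ds.snos)
        rng = np.random.default_rng(3)
        all_ids = [t.transcript_id for t in ds.transcripts]
        for _ in range(5):
            ids = list(
                rng.choice(all_ids, size=int(rng.integers(1, 100)), replace=False)
            )
            part = partition_biotypes(ids, ds.transcripts, calls)
            cats = [set(getattr(part, c)) for c in BiotypePartition.CATEGORIES]
            union = set().union(*cats)
            assert union == set(ids)
            assert sum(len(c) for c in cats) == len(ids)
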