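"""Fully labelled synthetic dataset generator.

Emulates the experimental design the rest of the package assumes: a
five-replicate RIP / IgG / INPUT count experiment over a toy annotation in
which a fraction of genes host an intronic snoRNA and express both a
spliced and an intron-retaining (snoRT) isoform.  Planted H/ACA snoRNAs
carry an ANANNA H box, an ACA box ending 3 nt from their 3' end, and two
pocket antisense elements; a pseudouridine catalogue contains sites whose
flanks are reverse-complementary to planted pockets; eCLIP-style peaks are
placed over a configurable fraction of true targets.  Every generated
entity carries a ground-truth label, and generation is deterministic given
the seed (byte-identical output files).

Counts are negative-binomial with log10-uniform base means, a single
dispersion, and log-normal per-sample library factors.  True targets are
multiplied by 2**rip_log2fc in RIP only; IgG artifacts in both RIP and
IgG.  Target base means are drawn from the upper decade(s) of the mean
range: RIP-enriched transcripts are, by construction of the assay,
detectably expressed.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp_dna, revcomp_rna
from .annotation import GenomicInterval, SnoRNARecord, TranscriptModel
from .enrichment import CountMatrix
from .errors import ConfigError
from .psi import PsiSite, match_guides
from . import io as skio

_DNA = "ACGT"


@dataclass
class SimulationConfig:
    """Tunable study conditions for the generator."""

    seed: int = 20220822
    n_genes: int = 300
    frac_sno_host: float = 0.2
    frac_retained_isoform: float = 0.8
    frac_lnc: float = 0.1
    n_targets: int = 60
    rip_log2fc: float = 3.0
    igg_artifact_frac: float = 0.05
    nb_mean_log_range: tuple[float, float] = (0.0, 3.0)
    nb_dispersion: float = 0.1
    n_replicates: int = 5
    n_psi_sites: int = 30
    frac_psi_guided: float = 0.6
    peak_coverage_frac: float = 0.9
    consensus_motif: str = "UCGAUGGACU"

    def __post_init__(self) -> None:
        for name in (
            "frac_sno_host",
            "frac_retained_isoform",
            "frac_lnc",
            "igg_artifact_frac",
            "frac_psi_guided",
            "peak_coverage_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated data plus ground truth, with file writers."""

    config: SimulationConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    snos: list[SnoRNARecord]
    count_matrix: CountMatrix
    psi_sites: list[PsiSite]
    peaks: list[tuple[GenomicInterval, float]]
    truth_transcripts: pd.DataFrame
    truth_sites: pd.DataFrame
    transcript_seqs: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "transcripts_fasta": out / "transcripts.fa",
            "gtf": out / "annotation.gtf",
            "snorna_bed": out / "snorna.bed",
            "snorna_classes": out / "snorna_classes.tsv",
            "counts": out / "counts.tsv",
            "samples": out / "samples.tsv",
            "psi_sites": out / "psi_sites.tsv",
            "peaks": out / "peaks.bed",
            "truth_transcripts": out / "truth_transcripts.tsv",
            "truth_sites": out / "truth_sites.tsv",
        }
        skio.write_fasta(self.genome, paths["genome"])
        skio.write_fasta(self.transcript_seqs, paths["transcripts_fasta"])
        skio.write_gtf(self.transcripts, paths["gtf"])
        skio.write_snorna_bed(self.snos, paths["snorna_bed"], paths["snorna_classes"])
        cm = self.count_matrix
        pd.DataFrame(
            cm.counts, index=pd.Index(cm.feature_ids, name="feature_id"),
            columns=cm.sample_ids,
        ).to_csv(paths["counts"], sep="\t")
        pd.DataFrame(
            {
                "sample_id": cm.sample_ids,
                "condition": [cm.condition[s] for s in cm.sample_ids],
                "replicate": [s.rsplit("_", 1)[1] for s in cm.sample_ids],
            }
        ).to_csv(paths["samples"], sep="\t", index=False)
        skio.write_psi_sites(self.psi_sites, paths["psi_sites"])
        skio.write_peaks_bed(self.peaks, paths["peaks"])
        self.truth_transcripts.to_csv(paths["truth_transcripts"], sep="\t", index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        return paths


_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _DNA_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def _extract_transcript_seq(genome: dict[str, str], t: TranscriptModel) -> str:
    parts = [genome[t.chrom][e.start : e.end] for e in t.exons]
    seq = "".join(parts)
    return revcomp_dna(seq) if t.strand == "-" else seq


def _make_sno_seq(rng: np.random.Generator, motif_dna: str) -> tuple[str, str, str]:
    """A 130-nt snoRNA (DNA letters, sense strand) with planted pockets,
    H box at 55 and ACA ending 3 nt from the 3' end.  Returns
    (sequence, pocket5, pocket3) with pockets as RNA strings."""
    L = 130
    while True:
        seq = list(_random_seq(rng, L))
        pocket5 = _random_seq(rng, 7)
        pocket3 = _random_seq(rng, 7)
        seq[10:17] = pocket5
        seq[30:37] = pocket3
        # H box ANANNA: fix the three As, draw the Ns
        h = ["A", "", "A", "", "", "A"]
        for i in (1, 3, 4):
            h[i] = str(rng.choice(list(_DNA)))
        seq[55:61] = h
        seq[124:127] = "ACA"
        s = "".join(seq)
        if motif_dna not in s and revcomp_dna(motif_dna) not in s:
            return s, pocket5.replace("T", "U"), pocket3.replace("T", "U")


def _scrub_motif(genome: dict[str, str], motif_dna: str) -> None:
    """Mutate the middle base of every genomic occurrence of the consensus
    motif (either strand) so only planted occurrences remain."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for chrom, seq in genome.items():
        s = list(seq)
        for pat in (motif_dna, revcomp_dna(motif_dna)):
            start = 0
            while True:
                i = "".join(s).find(pat, start)
                if i < 0:
                    break
                mid = i + len(pat) // 2
                s[mid] = swap[s[mid]]
                start = i + 1
        genome[chrom] = "".join(s)


def generate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full labelled dataset for a configuration."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    motif_dna = cfg.consensus_motif.upper().replace("U", "T")

    n_host = round(cfg.frac_sno_host * cfg.n_genes)
    n_lnc = round(cfg.frac_lnc * (cfg.n_genes - n_host))

    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    cursors = {"chr1": 0, "chr2": 0}

    transcripts: list[TranscriptModel] = []
    snos: list[SnoRNARecord] = []
    snort_tids: list[str] = []
    snort_class: dict[str, str] = {}
    snort_sno: dict[str, str] = {}
    sno_tid_of: dict[str, str] = {}
    coding_tids: list[str] = []
    lnc_tids: list[str] = []

    for i in range(cfg.n_genes):
        gene_id = f"G{i + 1}"
        chrom = "chr1" if i < cfg.n_genes / 2 else "chr2"
        strand = "+" if i % 2 == 0 else "-"
        is_host = i < n_host
        is_lnc = (not is_host) and i >= cfg.n_genes - n_lnc

        exon_len = rng.integers(150, 401, size=3)
        intron_len = rng.integers(250, 801, size=2)
        start = cursors[chrom] + 500
        pos = start
        exons = []
        for j in range(3):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_len[j]), strand))
            pos += int(exon_len[j])
            if j < 2:
                pos += int(intron_len[j])
        gene_end = pos
        gene_seq = _random_seq(rng, gene_end - start)
        biotype = "lncRNA" if is_lnc else "protein_coding"
        spliced = TranscriptModel(
            transcript_id=f"T{i + 1}.1",
            gene_id=gene_id,
            exons=tuple(exons),
            biotype=biotype,
        )
        transcripts.append(spliced)
        if is_lnc:
            lnc_tids.append(spliced.transcript_id)
        elif not is_host:
            coding_tids.append(spliced.transcript_id)

        if is_host:
            u = rng.random()
            sno_class = "HACA" if u < 0.8 else ("CD" if u < 0.9 else "SCA_HACA")
            sno_len = 130
            intron_start = exons[0].end
            offset = int(rng.integers(30, int(intron_len[0]) - sno_len - 30))
            sno_iv = GenomicInterval(
                chrom, intron_start + offset, intron_start + offset + sno_len, strand
            )
            sno_seq, pocket5, pocket3 = _make_sno_seq(rng, motif_dna)
            planted = sno_seq if strand == "+" else revcomp_dna(sno_seq)
            rel = sno_iv.start - start
            gene_seq = gene_seq[:rel] + planted + gene_seq[rel + sno_len :]
            sno_id = f"SNO{i + 1}"
            is_haca = sno_class in ("HACA", "SCA_HACA")
            snos.append(
                SnoRNARecord(
                    sno_id=sno_id,
                    interval=sno_iv,
                    sno_class=sno_class,
                    host_gene_id=gene_id,
                    pocket5=pocket5 if is_haca else None,
                    pocket3=pocket3 if is_haca else None,
                )
            )
            sno_tid = f"SNOT{i + 1}"
            sno_tid_of[sno_id] = sno_tid
            transcripts.append(
                TranscriptModel(
                    transcript_id=sno_tid,
                    gene_id=f"SNOG{i + 1}",
                    exons=(sno_iv,),
                    biotype="scaRNA" if sno_class.startswith("SCA") else "snoRNA",
                )
            )
            if rng.random() < cfg.frac_retained_isoform:
                retained = TranscriptModel(
                    transcript_id=f"T{i + 1}.2",
                    gene_id=gene_id,
                    exons=(
                        GenomicInterval(chrom, exons[0].start, exons[1].end, strand),
                        exons[2],
                    ),
                    biotype="retained_intron",
                )
                transcripts.append(retained)
                snort_tids.append(retained.transcript_id)
                snort_class[retained.transcript_id] = sno_class
                snort_sno[retained.transcript_id] = sno_id

        chrom_seqs[chrom].append("N" * (start - cursors[chrom]) + gene_seq)
        cursors[chrom] = gene_end

    genome = {c: "".join(parts) for c, parts in chrom_seqs.items() if parts}
    # random N-free spacer genomes are not needed; replace N spacers with
    # random sequence so motif scrubbing and extraction stay simple
    for c in list(genome):
        arr = list(genome[c])
        n_idx = [k for k, b in enumerate(arr) if b == "N"]
        filler = _random_seq(rng, len(n_idx))
        for k, b in zip(n_idx, filler):
            arr[k] = b
        genome[c] = "".join(arr)

    _scrub_motif(genome, motif_dna)

    # ---- target / artifact assignment -----------------------------------
    feature_ids = [t.transcript_id for t in transcripts]
    if cfg.n_targets > len(feature_ids):
        raise ConfigError(
            f"n_targets={cfg.n_targets} exceeds {len(feature_ids)} transcripts"
        )
    sno_tids = [sno_tid_of[s.sno_id] for s in snos]
    n_snort_t = min(len(snort_tids), round(0.4 * cfg.n_targets))
    n_sno_t = min(len(sno_tids), round(0.3 * cfg.n_targets))
    n_cod_t = cfg.n_targets - n_snort_t - n_sno_t
    if n_cod_t > len(coding_tids):
        raise ConfigError("not enough protein-coding transcripts for n_targets")
    def _pick(pool: list[str], k: int) -> list[str]:
        return [str(x) for x in rng.choice(pool, size=k, replace=False)] if k else []

    target_ids = (
        _pick(snort_tids, n_snort_t)
        + _pick(sno_tids, n_sno_t)
        + _pick(coding_tids, n_cod_t)
    )
    target_set = set(target_ids)
    non_targets = [f for f in feature_ids if f not in target_set]
    n_artifacts = round(cfg.igg_artifact_frac * len(feature_ids))
    artifact_ids = set(_pick(non_targets, min(n_artifacts, len(non_targets))))

    # ---- counts ---------------------------------------------------------
    lo, hi = cfg.nb_mean_log_range
    base = 10 ** rng.uniform(lo, hi, size=len(feature_ids))
    t_lo = max(lo, 1.0) if hi > 1.0 else lo
    for k, fid in enumerate(feature_ids):
        if fid in target_set:
            base[k] = 10 ** rng.uniform(t_lo, hi)
    conditions = (
        [("RIP", r) for r in range(1, cfg.n_replicates + 1)]
        + [("IGG", r) for r in range(1, cfg.n_replicates + 1)]
        + [("INPUT", r) for r in range(1, cfg.n_replicates + 1)]
    )
    sample_ids = [f"{c}_{r}" for c, r in conditions]
    condition = {f"{c}_{r}": c for c, r in conditions}
    lib = np.exp(rng.normal(0.0, 0.2, size=len(sample_ids)))
    fold = 2.0 ** cfg.rip_log2fc
    mean = np.empty((len(feature_ids), len(sample_ids)))
    is_target_vec = np.array([f in target_set for f in feature_ids])
    is_artifact_vec = np.array([f in artifact_ids for f in feature_ids])
    for j, sid in enumerate(sample_ids):
        cond = condition[sid]
        m = base.copy()
        if cond == "RIP":
            m[is_target_vec | is_artifact_vec] *= fold
        elif cond == "IGG":
            m[is_artifact_vec] *= fold
        mean[:, j] = m * lib[j]
    r_nb = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean)).astype(np.int64)
    cm = CountMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        condition=condition,
        counts=counts,
    )

    # ---- pseudouridine catalogue ----------------------------------------
    tmodels = {t.transcript_id: t for t in transcripts}
    coding_targets = [t for t in target_ids if t in set(coding_tids)]
    coding_nontargets = [t for t in coding_tids if t not in target_set]
    n_sites_on_targets = min(len(coding_targets), round(0.6 * cfg.n_psi_sites))
    n_sites_off = min(
        len(coding_nontargets), cfg.n_psi_sites - n_sites_on_targets
    )
    site_tids = _pick(coding_targets, n_sites_on_targets) + _pick(
        coding_nontargets, n_sites_off
    )
    n_guided = round(cfg.frac_psi_guided * len(site_tids))

    # guide pool: H/ACA snoRNAs whose own transcript is a target or which
    # sit inside a target snoRT, so planted guides are always recoverable
    # as "in targets"
    in_target_guides = [
        s
        for s in snos
        if s.pocket5 is not None
        and (
            sno_tid_of[s.sno_id] in target_set
            or any(
                snort_sno.get(tid) == s.sno_id
                for tid in snort_tids
                if tid in target_set
            )
        )
    ]
    pocketed = [s for s in snos if s.pocket5 is not None]
    if n_guided > 0 and not in_target_guides:
        raise ConfigError("no in-target H/ACA snoRNA available to plant guides")

    rna4 = list("ACGU")
    psi_sites: list[PsiSite] = []
    site_guides: list[str] = []
    for idx, tid in enumerate(site_tids):
        site_id = f"PSI{idx + 1}"
        tlen = tmodels[tid].length
        position = int(rng.integers(20, max(21, tlen - 20)))
        if idx < n_guided:
            guide = in_target_guides[int(rng.integers(len(in_target_guides)))]
            flank5 = "".join(rng.choice(rna4, size=3)) + revcomp_rna(guide.pocket3)
            flank3 = (
                "".join(rng.choice(rna4, size=1))
                + revcomp_rna(guide.pocket5)
                + "".join(rng.choice(rna4, size=2))
            )
            site_guides.append(guide.sno_id)
        else:
            # rejection-sample flanks so unguided sites match no pocket
            for _ in range(2000):
                flank5 = "".join(rng.choice(rna4, size=10))
                flank3 = "".join(rng.choice(rna4, size=10))
                probe = PsiSite(site_id, tid, position, flank5, flank3)
                if not match_guides([probe], pocketed):
                    break
            else:
                raise ConfigError("could not sample unguided flanks")
            site_guides.append("")
        psi_sites.append(PsiSite(site_id, tid, position, flank5, flank3))

    # ---- eCLIP peaks and binding categories -----------------------------
    # A host gene's snoRNA transcript sits inside its snoRT's retained
    # exon, so when both are targets the peak decision is drawn once for
    # the pair (one peak over the snoRNA covers both); otherwise planted
    # labels would contradict the observable overlap.
    sno_tid_set, snort_tid_set = set(sno_tids), set(snort_tids)
    tid_of_sno = sno_tid_of
    snort_of_sno = {v: k for k, v in snort_sno.items()}  # sno_id -> snoRT tid
    units: list[list[str]] = []
    seen: set[str] = set()
    for tid in target_ids:
        if tid in seen:
            continue
        unit = [tid]
        if tid in sno_tid_set:
            sno_id = next(s for s, v in tid_of_sno.items() if v == tid)
            sibling = snort_of_sno.get(sno_id)
            if sibling in target_set:
                unit.append(sibling)
        elif tid in snort_tid_set:
            partner = tid_of_sno[snort_sno[tid]]
            if partner in target_set:
                unit.append(partner)
        seen.update(unit)
        units.append(unit)

    peaks: list[tuple[GenomicInterval, float]] = []
    binding: dict[str, str] = {}
    motif_targets: list[str] = []
    for unit in units:
        noncoding = any(t in sno_tid_set or t in snort_tid_set for t in unit)
        if rng.random() < cfg.peak_coverage_frac:
            # one peak per unit; for sno/snoRT pairs put it on the snoRNA
            anchor = next(
                (t for t in unit if t in sno_tid_set), unit[0]
            ) if len(unit) > 1 else unit[0]
            block = tmodels[anchor].exonic_blocks()[0]
            p_start = block.start + int(rng.integers(0, max(1, block.length - 60)))
            peaks.append(
                (
                    GenomicInterval(
                        tmodels[anchor].chrom,
                        p_start,
                        min(p_start + 60, block.end),
                        tmodels[anchor].strand,
                    ),
                    float(np.round(rng.uniform(1.0, 10.0), 3)),
                )
            )
            for tid in unit:
                binding[tid] = (
                    "direct_snoRNA" if tid in sno_tid_set
                    else "direct_snoRT" if tid in snort_tid_set
                    else "direct_other"
                )
        elif not noncoding and rng.random() < 0.5:
            for tid in unit:
                binding[tid] = "motif_supported"
                motif_targets.append(tid)
        else:
            for tid in unit:
                binding[tid] = "indirect"

    # plant the consensus motif inside exon 2 of motif-supported targets
    for tid in motif_targets:
        t = tmodels[tid]
        exon = t.exons[1]
        rel = int(rng.integers(10, exon.length - len(motif_dna) - 10))
        g_start = exon.start + rel
        insert = motif_dna if t.strand == "+" else revcomp_dna(motif_dna)
        chrom_seq = genome[t.chrom]
        genome[t.chrom] = (
            chrom_seq[:g_start] + insert + chrom_seq[g_start + len(insert) :]
        )

    transcript_seqs = {
        t.transcript_id: _extract_transcript_seq(genome, t) for t in transcripts
    }

    # ---- ground truth ---------------------------------------------------
    rows = []
    for t in transcripts:
        tid = t.transcript_id
        if t.biotype in ("snoRNA", "scaRNA"):
            part = "sno_and_sca"
            s_class = next(s.sno_class for s in snos if sno_tid_of[s.sno_id] == tid)
        elif tid in snort_class:
            s_class = snort_class[tid]
            part = (
                "haca_snort" if s_class in ("HACA", "SCA_HACA") else "other_snort"
            )
        elif t.biotype == "protein_coding":
            part, s_class = "protein_coding_other", ""
        else:
            part, s_class = "remaining", ""
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": t.gene_id,
                "biotype": t.biotype,
                "is_snort": tid in snort_class,
                "sno_class": s_class,
                "is_true_target": tid in target_set,
                "is_igg_artifact": tid in artifact_ids,
                "partition_category": part,
                "binding_category": binding.get(tid, ""),
            }
        )
    truth_transcripts = pd.DataFrame(rows)
    truth_sites = pd.DataFrame(
        {
            "site_id": [s.site_id for s in psi_sites],
            "transcript_id": [s.transcript_id for s in psi_sites],
            "guide_sno_id": site_guides,
        }
    )

    return SyntheticDataset(
        config=cfg,
        genome=genome,
        transcripts=transcripts,
        snos=snos,
        count_matrix=cm,
        psi_sites=psi_sites,
        peaks=peaks,
        truth_transcripts=truth_transcripts,
        truth_sites=truth_sites,
        transcript_seqs=transcript_seqs,
    )
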