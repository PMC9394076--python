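import numpy as np
import pytest

from snortkit.annotation import GenomicInterval, SnoRNARecord, TranscriptModel
from snortkit.enrichment import CountMatrix
from snortkit.simulate import SimulationConfig, generate

MC_SEED = 20220822  # default seed for Monte-Carlo validation fixtures


def make_transcript(tid, gene, exons, strand="+", chrom="chr1",
                    biotype="protein_coding"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


def make_sno(sid, start, end, strand="+", chrom="chr1", sno_class="HACA",
             **kw):
    return SnoRNARecord(
        sno_id=sid,
        interval=GenomicInterval(chrom, start, end, strand),
        sno_class=sno_class,
        **kw,
    )


def nb_counts(rng, mean, dispersion=0.1):
    """NB draws parameterised by mean and dispersion (var = m + a m^2)."""
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mean, dtype=float)))


def make_count_matrix(counts, n_rep=5, conditions=("RIP", "INPUT")):
    counts = np.asarray(counts, dtype=np.int64)
    sample_ids = [f"{c}_{r}" for c in conditions for r in range(1, n_rep + 1)]
    condition = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    return CountMatrix(
        feature_ids=[f"F{i}" for i in range(counts.shape[0])],
        sample_ids=sample_ids,
        condition=condition,
        counts=counts,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default scenario, shared across tests."""
    return generate(SimulationConfig())


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SimulationConfig(n_genes=60, n_targets=12, n_psi_sites=8))
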