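"""H/ACA box motif scanning and PWM comparison.

H/ACA box snoRNAs carry a degenerate H box (consensus ANANNA) in the hinge
between their two hairpins and an ACA box near the 3' end.  Because the H
box is highly degenerate and ACA is extremely short, these motifs are
scanned directly (sense strand only) rather than with a PWM model, and a
pair is deemed plausible when the ACA lies 10-300 nt downstream of the H
box (distance measured as the gap between the end of the H box and the
start of the ACA).

DNA input is transliterated T->U once per scan.
"""
from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlphabetError, PatternError, SnortkitError

log = logging.getLogger(__name__)

#: IUPAC nucleotide codes over the RNA alphabet.  ``N`` in a pattern matches
#: any base, but an ``N`` in the sequence matches nothing (no code includes
#: it in its base set).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

H_BOX = "ANANNA"
ACA_BOX = "ACA"
ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

_warned_dna = False


def normalize_sequence(sequence: str) -> str:
    """Uppercase and transliterate T->U; reject anything outside ACGUN."""
    global _warned_dna
    seq = sequence.upper()
    if "T" in seq:
        if not _warned_dna:
            log.info("DNA input detected; transliterating T->U")
            _warned_dna = True
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise AlphabetError(f"illegal sequence characters: {sorted(bad)}")
    return seq


def scan_consensus(sequence: str, iupac_pattern: str) -> list[int]:
    """All sense-strand start positions of an IUPAC consensus pattern
    (overlapping occurrences included)."""
    pattern = iupac_pattern.upper().replace("T", "U")
    try:
        allowed = [frozenset(IUPAC[c]) for c in pattern]
    except KeyError as exc:
        raise PatternError(f"invalid IUPAC code {exc.args[0]!r}") from None
    seq = normalize_sequence(sequence)
    k = len(allowed)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in allowed[j] for j in range(k)):
            hits.append(i)
    return hits


@dataclass(frozen=True)
class MotifMatch:
    """An H box paired with a downstream ACA box on one sequence."""

    seq_id: str
    h_start: int
    h_end: int
    aca_start: int

    @property
    def distance(self) -> int:
        """Gap between the end of the H box and the start of the ACA."""
        return self.aca_start - self.h_end


def scan_h_aca(
    seq_id: str,
    sequence: str,
    d_min: int = 10,
    d_max: int = 300,
    all_pairs: bool = False,
) -> list[MotifMatch]:
    """Find H-box/ACA-box pairs at a plausible distance.

    For every ANANNA occurrence, the nearest downstream ACA with
    ``d_min <= distance <= d_max`` is reported (all qualifying ACAs with
    ``all_pairs=True``).  Sense strand only.
    """
    if d_min < 0 or d_max < d_min:
        raise SnortkitError(f"invalid distance window [{d_min}, {d_max}]")
    if not sequence:
        return []
    h_starts = scan_consensus(sequence, H_BOX)
    aca_starts = np.array(scan_consensus(sequence, ACA_BOX), dtype=int)
    matches = []
    for h in h_starts:
        h_end = h + len(H_BOX)
        lo = np.searchsorted(aca_starts, h_end + d_min, side="left")
        hi = np.searchsorted(aca_starts, h_end + d_max, side="right")
        for a in aca_starts[lo:hi]:
            matches.append(MotifMatch(seq_id, h, h_end, int(a)))
            if not all_pairs:
                break
    return matches


@dataclass(frozen=True)
class BoxFlags:
    """Per-sequence H/ACA presence flags; truthy iff a plausible pair
    exists."""

    has_h: bool
    has_downstream_aca: bool
    has_plausible_pair: bool

    def __bool__(self) -> bool:
        return self.has_plausible_pair


def has_plausible_box(
    sequence: str, d_min: int = 10, d_max: int = 300
) -> BoxFlags:
    """Flags for H-box presence, downstream ACA presence, and a plausible
    H-ACA pair within the distance window."""
    if not sequence:
        return BoxFlags(False, False, False)
    h_starts = scan_consensus(sequence, H_BOX)
    aca_starts = scan_consensus(sequence, ACA_BOX)
    has_h = bool(h_starts)
    has_downstream = bool(
        h_starts and aca_starts and max(aca_starts) >= min(h_starts) + len(H_BOX)
    )
    pair = bool(scan_h_aca("", sequence, d_min=d_min, d_max=d_max))
    return BoxFlags(has_h, has_downstream, pair)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Column-stochastic PWM over the ACGU alphabet."""

    motif_id: str
    columns: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        mat = np.asarray(self.columns, dtype=float)
        if mat.ndim != 2 or mat.shape[0] < 4 or mat.shape[1] != 4:
            raise SnortkitError(
                f"{self.motif_id}: PWM needs >=4 columns of 4 probabilities"
            )
        if np.any(mat < 0):
            raise SnortkitError(f"{self.motif_id}: negative PWM entries")
        if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
            raise SnortkitError(f"{self.motif_id}: PWM columns must sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.columns, dtype=float)

    def __len__(self) -> int:
        return len(self.columns)


def read_meme_pwms(path: str | os.PathLike) -> list[PositionWeightMatrix]:
    """Read PWMs from a MEME minimal-format text file (RNA or DNA
    alphabet; T columns are reported under U)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    pwms = []
    for m in parsed:
        norm = m.counts.normalize()
        letters = ["A", "C", "G", "U" if "U" in m.alphabet else "T"]
        cols = tuple(
            tuple(float(norm[letter][i]) for letter in letters)
            for i in range(m.length)
        )
        pwms.append(PositionWeightMatrix(motif_id=m.name, columns=cols))
    return pwms


def compare_pwms(
    a: PositionWeightMatrix,
    b: PositionWeightMatrix,
    min_overlap: int = 4,
) -> float:
    """Best Pearson correlation between two PWMs over all ungapped offsets
    with at least ``min_overlap`` aligned columns (sense orientation only).

    Offsets where either aligned stretch is constant (zero variance) are
    skipped.
    """
    if len(a) < min_overlap or len(b) < min_overlap:
        raise SnortkitError("PWMs shorter than the minimum overlap")
    ma, mb = a.matrix, b.matrix
    best = -np.inf
    for offset in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        a_lo, a_hi = max(0, offset), min(len(a), offset + len(b))
        if a_hi - a_lo < min_overlap:
            continue
        xa = ma[a_lo:a_hi].ravel()
        xb = mb[a_lo - offset : a_hi - offset].ravel()
        if np.std(xa) == 0 or np.std(xb) == 0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        best = max(best, r)
    if not np.isfinite(best):
        raise SnortkitError("no comparable offsets between the PWMs")
    return best
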