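"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported
    percentages), unlike Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Share of ``count`` in ``total`` as a percentage rounded half-up."""
    if total <= 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    return round_half_up(100.0 * count / total, ndigits)


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    return seq.upper().replace("T", "U").translate(RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.upper().translate(DNA_COMPLEMENT)[::-1]
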