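"""Pseudouridylation-overlap enrichment and guide-target pocket matching.

Two questions are answered here.  First: are known-pseudouridylated
transcripts over-represented among RIP targets?  This is a one-sided
binomial test of the observed overlap count against the background
frequency of pseudouridylated transcripts in the transcriptome.  Second:
for a catalogued pseudouridine, is there an H/ACA snoRNA whose
pseudouridylation pocket could guide the modification?  The matcher pairs
the two antisense elements of a pocket with the sequences flanking the
site, antiparallel, allowing G-U wobble pairs, and requires the target's
"PsiN" dinucleotide (the modified U and the base 3' of it) to remain
unpaired — the canonical geometry of the H/ACA internal loop.  This is a
deliberately simple annotation-driven surrogate: it scores no secondary
structure and predicts no hairpins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from ._util import percent
from .annotation import SnoRNARecord, SnoRTCall
from .errors import SnortkitError

log = logging.getLogger(__name__)

#: Watson-Crick plus G-U wobble, as unordered antiparallel pairs.
_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)


@dataclass(frozen=True)
class PsiSite:
    """A catalogued pseudouridine with its transcript flanks (the modified
    U itself is excluded from both flanks)."""

    site_id: str
    transcript_id: str
    position: int
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3"):
            f = getattr(self, name)
            if len(f) > 15 or set(f) - set("ACGU"):
                raise SnortkitError(
                    f"{self.site_id}: {name} must be <=15 nt over ACGU"
                )
        if self.position < 0:
            raise SnortkitError(f"{self.site_id}: negative position")


@dataclass(frozen=True)
class GuideMatch:
    """A scored pairing between a Psi-site flank pair and a snoRNA pocket."""

    site_id: str
    sno_id: str
    bp_left: int
    bp_right: int
    pocket_unpaired_ok: bool

    @property
    def bp_total(self) -> int:
        return self.bp_left + self.bp_right


@dataclass(frozen=True)
class OverlapEnrichment:
    """Binomial over-representation of pseudouridylated transcripts among
    targets: k of n targets vs a background of K of N transcripts."""

    k: int
    n: int
    K: int
    N: int
    p_upper: float

    @property
    def observed_frac(self) -> float:
        return self.k / self.n

    @property
    def expected_frac(self) -> float:
        return self.K / self.N

    @property
    def observed_percent(self) -> float:
        return percent(self.k, self.n)

    @property
    def expected_percent(self) -> float:
        return percent(self.K, self.N)


def binomial_overlap(k: int, n: int, K: int, N: int) -> OverlapEnrichment:
    """Upper-tail binomial test: P(X >= k) for X ~ Binomial(n, K/N)."""
    if not (0 <= k <= n) or not (0 <= K <= N) or n < 1 or N < 1:
        raise SnortkitError(f"invalid overlap counts k={k} n={n} K={K} N={N}")
    p0 = K / N
    p_upper = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return OverlapEnrichment(k=k, n=n, K=K, N=N, p_upper=min(p_upper, 1.0))


def longest_antiparallel_duplex(x: str, y: str) -> int:
    """Length of the longest contiguous antiparallel duplex between two
    strands (both given 5'->3'), allowing G-U wobble."""
    x = x.upper().replace("T", "U")
    yr = y.upper().replace("T", "U")[::-1]
    best = 0
    prev = [0] * (len(yr) + 1)
    for xi in x:
        cur = [0]
        for j, yj in enumerate(yr, start=1):
            run = prev[j - 1] + 1 if (xi, yj) in _PAIRS else 0
            cur.append(run)
            best = max(best, run)
        prev = cur
    return best


def match_guides(
    sites: Sequence[PsiSite],
    snos: Sequence[SnoRNARecord],
    min_side: int = 3,
    min_total: int = 9,
) -> list[GuideMatch]:
    """Match Psi-site flanks against snoRNA pseudouridylation pockets.

    For each (site, sno) pair the 5' flank is paired with the pocket's 3'
    antisense element and the 3' flank with the 5' element.  The base
    immediately 3' of the Psi (the N of the PsiN dinucleotide) is excluded
    from pairing, keeping the dinucleotide unpaired as in the canonical
    pocket.  A match requires both sides >= ``min_side`` and the sum
    >= ``min_total``.
    """
    usable = []
    for sno in snos:
        if sno.pocket5 is None or sno.pocket3 is None:
            log.warning("snoRNA %s has no pocket annotation; skipped", sno.sno_id)
            continue
        usable.append(sno)

    matches = []
    for site in sites:
        for sno in usable:
            bp_left = longest_antiparallel_duplex(site.flank5, sno.pocket3)
            bp_right = longest_antiparallel_duplex(site.flank3[1:], sno.pocket5)
            if (
                bp_left >= min_side
                and bp_right >= min_side
                and bp_left + bp_right >= min_total
            ):
                matches.append(
                    GuideMatch(
                        site_id=site.site_id,
                        sno_id=sno.sno_id,
                        bp_left=bp_left,
                        bp_right=bp_right,
                        pocket_unpaired_ok=True,
                    )
                )
    return matches


def guides_in_targets(
    matches: Iterable[GuideMatch],
    target_ids: Iterable[str],
    snort_calls: Sequence[SnoRTCall],
    sno_transcript_of: dict[str, str] | None = None,
) -> tuple[int, int]:
    """Count matched sites whose guide snoRNA is itself in the target set.

    A guide counts as "in targets" if its own transcript is a target or if
    it is contained in a target snoRT.  ``sno_transcript_of`` maps sno_id
    to the transcript id of the snoRNA itself (identity map by default).
    Returns ``(covered_sites, sites_with_guide)``.
    """
    targets = set(target_ids)
    sno_to_snorts: dict[str, set[str]] = {}
    for call in snort_calls:
        for sid in call.contained_sno_ids:
            sno_to_snorts.setdefault(sid, set()).add(call.transcript_id)

    by_site: dict[str, set[str]] = {}
    for m in matches:
        by_site.setdefault(m.site_id, set()).add(m.sno_id)

    covered = 0
    for snos_of_site in by_site.values():
        for sid in snos_of_site:
            tid = (sno_transcript_of or {}).get(sid, sid)
            if tid in targets or sno_to_snorts.get(sid, set()) & targets:
                covered += 1
                break
    return covered, len(by_site)
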