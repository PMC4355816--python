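"""Overlap resolution: keep the biggest of excessively overlapping repeats.

Candidates from all motif lengths are pooled per sequence, sorted by start
position (ties: longer first), and swept left to right.  Each element is
compared to the most recently kept element; if their loci overlap by more
than the permitted percentage, the smaller of the two is deleted and the
sweep moves on.  With the default permitted overlap of 0%, any shared
position triggers a deletion, so phase rotations of the same tandem run
(e.g. the CA-phase copy of an AC run) collapse onto the longest copy.

The overlap degree between two loci is defined as the shared length as a
percentage of the *smaller* locus — the element the deletion rule targets.
Equal-span conflicts keep the earlier-starting element; identical loci keep
the lexicographically smaller motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

from .scanner import CandidateRepeat

__all__ = ["ResolvedRepeat", "overlap_degree", "resolve", "kept_candidates"]


@dataclass(frozen=True)
class ResolvedRepeat:
    """A candidate plus its resolution: kept, or deleted in favor of whom."""

    candidate: CandidateRepeat
    kept: bool
    deleted_in_favor_of: CandidateRepeat | None = None


def overlap_degree(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Shared positions of two 1-based closed intervals, as a percentage of
    the shorter interval; 0 when disjoint."""
    (a1, a2), (b1, b2) = a, b
    if a1 > a2 or b1 > b2:
        raise ValueError("intervals must be non-empty and closed")
    shared = min(a2, b2) - max(a1, b1) + 1
    if shared <= 0:
        return 0.0
    return 100.0 * shared / min(a2 - a1 + 1, b2 - b1 + 1)


def _wins(a: CandidateRepeat, b: CandidateRepeat) -> CandidateRepeat:
    """The element retained out of two excessively overlapping ones: the
    longer; ties by earlier start, then lexicographically smaller motif."""
    ka = (-a.span, a.sp, a.motif)
    kb = (-b.span, b.sp, b.motif)
    return a if ka <= kb else b


def resolve(
    candidates: Sequence[CandidateRepeat], overlap_percent: float
) -> list[ResolvedRepeat]:
    """Single sweep per sequence; see the module docstring.

    Returns one :class:`ResolvedRepeat` per input candidate, in sweep order
    (sequence id, then start position, longer-first on ties), with deleted
    elements pointing at the element that displaced them.
    """
    if not 0 <= overlap_percent <= 100:
        raise ValueError("overlap_percent must be in [0, 100]")
    ordered = sorted(candidates, key=lambda c: (c.sequence_id, c.sp, -c.fp, c.motif))
    out: list[ResolvedRepeat] = []
    for _, group in groupby(ordered, key=lambda c: c.sequence_id):
        # index in `out` of the most recently kept element of this sequence
        last: int | None = None
        for cand in group:
            if last is None:
                last = len(out)
                out.append(ResolvedRepeat(cand, kept=True))
                continue
            prev = out[last].candidate
            if cand.sp <= prev.fp:
                degree = overlap_degree((prev.sp, prev.fp), (cand.sp, cand.fp))
                if degree > overlap_percent:
                    winner = _wins(prev, cand)
                    if winner is cand:
                        out[last] = ResolvedRepeat(
                            prev, kept=False, deleted_in_favor_of=cand
                        )
                        last = len(out)
                        out.append(ResolvedRepeat(cand, kept=True))
                    else:
                        out.append(
                            ResolvedRepeat(cand, kept=False, deleted_in_favor_of=prev)
                        )
                    continue
            last = len(out)
            out.append(ResolvedRepeat(cand, kept=True))
    return out


def kept_candidates(resolved: Sequence[ResolvedRepeat]) -> list[CandidateRepeat]:
    """The kept set of a resolution, in sweep order."""
    return [r.candidate for r in resolved if r.kept]
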