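"""Synthetic sequences with planted repeats, and a brute-force repeat finder.

Two independent checks of the scanner live here:

* :func:`generate_sequence` plants perfect or imperfect tandem repeats with
  known ⟨sp, fp, mt, g, lt⟩ ground truth into a uniform random background,
  re-drawing the background if chance runs would confound the truth; and
* :func:`brute_force_repeats`, a deliberately different algorithm — direct
  substring dictionaries and per-motif Hamming comparisons instead of a
  single rolling-hash pass — whose agreement with the scanner on small
  instances is therefore meaningful evidence rather than shared-code
  tautology.  Its cost is quadratic in sequence length, so it is only for
  sequences up to a few hundred symbols.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .degeneration import max_mismatches
from .encoding import Alphabet
from .overlap import kept_candidates, resolve
from .scanner import CandidateRepeat, RunParams, SingleBucket

__all__ = ["PlantSpec", "generate_sequence", "brute_force_repeats"]


@dataclass(frozen=True)
class PlantSpec:
    """One repeat to plant: motif × units, optional substitutions and gaps.

    ``substitutions`` are ``(unit_index, position_in_unit, symbol)`` triples
    (0-based); the first unit must stay exact, since a repeat locus opens at
    an exact occurrence of its motif.  ``gap_lengths`` has one entry per
    inter-unit junction (``units − 1``); missing entries mean 0.
    ``insert_position`` is the 1-based start of the repeat in the final
    sequence.
    """

    motif: str
    units: int
    insert_position: int
    substitutions: tuple[tuple[int, int, str], ...] = ()
    gap_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.units < 1 or not self.motif or self.insert_position < 1:
            raise ValueError(f"malformed plant {self}")
        if len(self.gap_lengths) > self.units - 1:
            raise ValueError("more gap lengths than inter-unit junctions")
        for u, pos, sym in self.substitutions:
            if not (1 <= u < self.units) or not (0 <= pos < len(self.motif)):
                raise ValueError(
                    f"substitution ({u}, {pos}, {sym!r}) outside units 1..{self.units - 1} "
                    f"or motif positions 0..{len(self.motif) - 1}"
                )
            if sym == self.motif[pos]:
                raise ValueError("substitution must change the symbol")

    @property
    def total_gaps(self) -> int:
        return sum(self.gap_lengths)

    @property
    def span(self) -> int:
        return self.units * len(self.motif) + self.total_gaps

    @property
    def end_position(self) -> int:
        return self.insert_position + self.span - 1

    def truth_bucket(self) -> SingleBucket:
        return SingleBucket(
            sp=self.insert_position,
            fp=self.end_position,
            mt=self.motif,
            g=self.total_gaps,
            lt=self.units,
        )

    def render(self, rng: random.Random, alphabet: Alphabet) -> str:
        subs: dict[int, dict[int, str]] = {}
        for u, pos, sym in self.substitutions:
            subs.setdefault(u, {})[pos] = sym
        pieces = []
        for u in range(self.units):
            unit = list(self.motif)
            for pos, sym in subs.get(u, {}).items():
                unit[pos] = sym
            pieces.append("".join(unit))
            gap = self.gap_lengths[u] if u < len(self.gap_lengths) else 0
            if u < self.units - 1 and gap:
                pieces.append("".join(rng.choices(alphabet.symbols, k=gap)))
        return "".join(pieces)


def generate_sequence(
    length: int,
    alphabet: Alphabet,
    plants: list[PlantSpec] | tuple[PlantSpec, ...],
    seed: int,
    *,
    check_params: RunParams | None = None,
    max_attempts: int = 80,
) -> tuple[str, list[SingleBucket]]:
    """Uniform random background with *plants* written in at their positions.

    Returns the sequence and the ground-truth loci.  When *check_params* is
    given, the finished sequence is vetted with the brute-force finder: after
    overlap resolution at 0% it must report exactly the planted loci — no
    chance background run, no accidental extension of a plant into its
    flanks — otherwise the background is re-drawn (deterministically from
    *seed*) and the check repeated.
    """
    ordered = sorted(plants, key=lambda pl: pl.insert_position)
    for a, b in zip(ordered, ordered[1:]):
        if b.insert_position <= a.end_position:
            raise ValueError(
                f"plants overlap: [{a.insert_position}, {a.end_position}] and "
                f"[{b.insert_position}, {b.end_position}]"
            )
    if ordered and ordered[-1].end_position > length:
        raise ValueError("plants do not fit inside the requested length")
    truth = [pl.truth_bucket() for pl in ordered]

    for attempt in range(max_attempts):
        rng = random.Random((seed * 100003 + attempt) % (2**31 - 1))
        chars = rng.choices(alphabet.symbols, k=length)
        for pl in ordered:
            rendered = pl.render(rng, alphabet)
            chars[pl.insert_position - 1 : pl.end_position] = rendered
        sequence = "".join(chars)
        if check_params is None:
            return sequence, truth
        found = resolve(
            brute_force_repeats(sequence, check_params), overlap_percent=0
        )
        observed = [c.bucket for c in kept_candidates(found)]
        if observed == truth:
            return sequence, truth
    raise RuntimeError(
        f"could not draw a clean background in {max_attempts} attempts "
        f"(seed {seed}); plants too dense for the check parameters?"
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_repeats(
    sequence: str, params: RunParams, sequence_id: str = "seq"
) -> list[CandidateRepeat]:
    """Quadratic reference repeat finder over all configured motif lengths.

    For each motif length it collects the occurrence positions of every
    distinct encodable window by direct substring comparison, widens each
    motif's position list with the positions of windows within its
    substitution budget (plain Hamming distance), and walks the merged list
    left to right with the extension rules of the scan: units never overlap,
    an inter-unit gap of at most ``max_gap`` extends the locus, an exact
    occurrence beyond the gap tolerance restarts it, and a degenerate
    occurrence beyond tolerance is ignored.  Only loci opened at an exact
    occurrence and reaching the minimum unit count are reported, sorted like
    the scanner's output.
    """
    seq = sequence.upper()
    alphabet = params.alphabet
    encodable = set(alphabet.symbols)
    out: list[CandidateRepeat] = []
    min_reps_for = params.min_repeats_for
    ga = params.max_gap

    for j in range(params.min_motif, params.max_motif + 1):
        occurrences: dict[str, list[int]] = {}
        for s in range(len(seq) - j + 1):
            w = seq[s : s + j]
            if all(c in encodable for c in w):
                occurrences.setdefault(w, []).append(s + 1)
        mm = max_mismatches(j, params.degeneration_percent)
        min_reps = min_reps_for(j)
        buckets: list[SingleBucket] = []
        for motif in sorted(occurrences):
            hits: list[tuple[int, bool]] = [(p, True) for p in occurrences[motif]]
            if mm > 0:
                for other, positions in occurrences.items():
                    if other != motif and _hamming(other, motif) <= mm:
                        hits.extend((p, False) for p in positions)
                hits.sort()
            state: list[int] | None = None  # [sp, fp, lt, g]
            def flush() -> None:
                if state is not None and state[2] >= min_reps:
                    buckets.append(
                        SingleBucket(
                            sp=state[0], fp=state[1], mt=motif, g=state[3], lt=state[2]
                        )
                    )
            for p, exact in hits:
                if state is None:
                    if exact:
                        state = [p, p + j - 1, 1, 0]
                    continue
                if p <= state[1]:
                    continue
                gap = p - state[1] - 1
                if gap <= ga:
                    state[3] += gap
                    state[1] = p + j - 1
                    state[2] += 1
                elif exact:
                    flush()
                    state = [p, p + j - 1, 1, 0]
            flush()
        buckets.sort(key=lambda b: (b.sp, b.fp, b.mt))
        out.extend(
            CandidateRepeat(sequence_id=sequence_id, bucket=b, motif_length=j)
            for b in buckets
        )
    out.sort(key=CandidateRepeat.sort_key)
    return out
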