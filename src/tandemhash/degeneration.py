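"""Degenerate-motif tables: which imperfect variants of a motif may extend it.

An imperfect (degenerate) unit of a repeat differs from the motif by a
bounded number of substitutions — at most ``floor(j·d/100)`` for motif
length ``j`` and degeneration percentage ``d`` (``d ≤ 35``), and never more
than two.  Before scanning a sequence, two structures are built per motif
length:

* a *presence table* flagging every motif key that actually occurs in the
  sequence (one sliding-window pass), and
* a *degeneration buffer* mapping each present key to the present keys
  within the substitution budget of it.

Restricting neighbourhoods to present motifs keeps the per-window work
bounded by the neighbourhood size, which depends on ``j`` and the radix but
not on the sequence length — the source of the scan's linear running time.
Both structures are stored sparsely (occupied keys only) so protein motif
lengths up to 6 (20**6 possible keys) never force dense allocation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

from .encoding import Alphabet, decode_key, encode_word, iter_window_keys

__all__ = [
    "PresenceTable",
    "DegenerationBuffer",
    "build_presence_table",
    "max_mismatches",
    "generate_degenerations",
    "build_degeneration_buffers",
    "neighborhood_size",
    "neighborhood_size_quadratic_bound",
]

#: Hard cap on substitutions per motif unit, and the largest degeneration
#: percentage accepted (35% of a 7-mer = 2.45 → 2 substitutions).
MAX_SUBSTITUTIONS = 2
MAX_DEGENERATION_PERCENT = 35


@dataclass(frozen=True)
class PresenceTable:
    """Flags of motif keys occurring in one sequence at one word length."""

    word_length: int
    flags: frozenset[int]

    def __contains__(self, key: int) -> bool:
        return key in self.flags


@dataclass(frozen=True)
class DegenerationBuffer:
    """Per present key, the present keys within the substitution budget.

    A key is never listed in its own entry; entries are sorted tuples so
    iteration order is deterministic.
    """

    word_length: int
    entries: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def variants_of(self, key: int) -> tuple[int, ...]:
        return self.entries.get(key, ())


def build_presence_table(sequence: str, j: int, alphabet: Alphabet) -> PresenceTable:
    """Flag the key of every encodable window of length *j* in *sequence*.

    A sequence shorter than *j* yields an empty table (no windows), which is
    not an error.
    """
    return PresenceTable(
        word_length=j,
        flags=frozenset(k for _, k in iter_window_keys(sequence, j, alphabet)),
    )


def max_mismatches(j: int, degeneration_percent: float) -> int:
    """Substitution budget for a motif of length *j*: floor(j·d/100), capped at 2."""
    if not 0 <= degeneration_percent <= MAX_DEGENERATION_PERCENT:
        raise ValueError(
            f"degeneration percentage must be in [0, {MAX_DEGENERATION_PERCENT}], "
            f"got {degeneration_percent}"
        )
    return min(MAX_SUBSTITUTIONS, int(j * degeneration_percent // 100))


def generate_degenerations(motif: str, max_mm: int, alphabet: Alphabet) -> set[str]:
    """All words at Hamming distance 1..*max_mm* from *motif* (substitutions only).

    Empty for ``max_mm = 0``; the motif itself is never included.
    """
    if not 0 <= max_mm <= MAX_SUBSTITUTIONS:
        raise ValueError(f"max_mm must be in [0, {MAX_SUBSTITUTIONS}], got {max_mm}")
    word = motif.upper()
    if not alphabet.is_encodable(word):
        raise ValueError(f"motif {motif!r} is not encodable in {alphabet.name}")
    out: set[str] = set()
    chars = alphabet.symbols
    for t in range(1, min(max_mm, len(word)) + 1):
        for positions in itertools.combinations(range(len(word)), t):
            alternates = [[c for c in chars if c != word[i]] for i in positions]
            for repl in itertools.product(*alternates):
                variant = list(word)
                for i, c in zip(positions, repl):
                    variant[i] = c
                out.add("".join(variant))
    return out


def build_degeneration_buffers(
    presence: PresenceTable, max_mm: int, alphabet: Alphabet
) -> DegenerationBuffer:
    """For every present key, list the present keys in its substitution ball.

    With ``max_mm = 0`` every entry is empty; keys absent from the presence
    table get no entry at all.  Hamming distance is symmetric, so
    ``k' ∈ entry(k)`` iff ``k ∈ entry(k')``.
    """
    j = presence.word_length
    entries: dict[int, tuple[int, ...]] = {}
    for k in sorted(presence.flags):
        variants = generate_degenerations(decode_key(k, j, alphabet), max_mm, alphabet)
        entries[k] = tuple(
            sorted(
                kv
                for kv in (encode_word(v, alphabet) for v in variants)
                if kv in presence.flags
            )
        )
    return DegenerationBuffer(word_length=j, entries=entries)


def neighborhood_size(j: int, radix: int, max_mm: int = MAX_SUBSTITUTIONS) -> int:
    """Exact count of words within Hamming distance 1..*max_mm* of a *j*-mer:
    Σ_t C(j,t)·(r−1)^t."""
    return sum(comb(j, t) * (radix - 1) ** t for t in range(1, max_mm + 1))


def neighborhood_size_quadratic_bound(j: int, radix: int) -> float:
    """Closed-form quadratic bound (1/2)(r−1)²j² + (r−1)j on the
    two-substitution neighbourhood; ≥ :func:`neighborhood_size` for all j."""
    return 0.5 * (radix - 1) ** 2 * j**2 + (radix - 1) * j
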