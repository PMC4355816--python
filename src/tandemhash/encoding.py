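"""Radix encoding of fixed-length sequence words.

A word of length ``j`` over an alphabet of radix ``r`` (4 for DNA, 20 for
protein) is read as a number in a positional number system: each symbol maps
to a digit in ``[0, r)`` and the word maps bijectively to an integer key in
``[0, r**j)``.  Every hash-table stage of the repeat scan indexes motifs by
this key, so a window of the input can be located in its table in O(1).

The DNA digit assignment is A=0, C=1, G=2, T=3; the protein assignment runs
G=0, P=1, A=2, V=3, L=4, I=5, M=6, C=7, F=8, Y=9, W=10, H=11, K=12, R=13,
Q=14, N=15, E=16, D=17, S=18, T=19.  Symbols outside the alphabet (N or
IUPAC ambiguity codes in DNA, X/B/Z/* in protein, gap characters) have no
digit; windows containing them are non-encodable and are skipped by callers,
never coerced.  Input is uppercased before mapping so soft-masked FASTA is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterator

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "NonEncodableWordError",
    "alphabet_for_mode",
    "encode_word",
    "decode_key",
    "iter_window_keys",
]


class NonEncodableWordError(ValueError):
    """A word contains a symbol with no digit in the alphabet."""


@dataclass(frozen=True)
class Alphabet:
    """A symbol→digit bijection defining a radix-``r`` positional system.

    ``symbols[i]`` is the symbol whose digit is ``i``; ``radix`` is
    ``len(symbols)``.
    """

    name: str
    symbols: str

    @property
    def radix(self) -> int:
        return len(self.symbols)

    @cached_property
    def digit_of(self) -> dict[str, int]:
        """Symbol → digit map (uppercase symbols only)."""
        return {s: i for i, s in enumerate(self.symbols)}

    def is_encodable(self, word: str) -> bool:
        d = self.digit_of
        return all(s in d for s in word.upper())


DNA = Alphabet("dna", "ACGT")
PROTEIN = Alphabet("protein", "GPAVLIMCFYWHKRQNEDST")


def alphabet_for_mode(run_mode: str) -> Alphabet:
    """Map a run mode name (``dna``/``protein``, or CLI ``n``/``p``)."""
    mode = run_mode.lower()
    if mode in ("dna", "n", "nucleotide"):
        return DNA
    if mode in ("protein", "p", "aminoacid", "amino_acid"):
        return PROTEIN
    raise ValueError(f"unknown run mode {run_mode!r}")


def encode_word(word: str, alphabet: Alphabet) -> int:
    """Positional hash of *word*: h(Q) = Σ m(q_i)·r^(|Q|−1−i).

    The map is a bijection between words of length ``len(word)`` and
    integers in ``[0, r**len(word))``; :func:`decode_key` inverts it.

    Raises
    ------
    NonEncodableWordError
        If a symbol has no digit (e.g. ``N`` in DNA, ``X`` in protein).
    """
    digit = alphabet.digit_of
    r = alphabet.radix
    key = 0
    for s in word.upper():
        d = digit.get(s)
        if d is None:
            raise NonEncodableWordError(
                f"symbol {s!r} is not encodable in the {alphabet.name} alphabet"
            )
        key = key * r + d
    return key


def decode_key(key: int, word_length: int, alphabet: Alphabet) -> str:
    """Inverse of :func:`encode_word`; left-pads with the digit-0 symbol."""
    r = alphabet.radix
    if not 0 <= key < r**word_length:
        raise ValueError(
            f"key {key} out of range for {alphabet.name} words of length {word_length}"
        )
    out = []
    for _ in range(word_length):
        key, d = divmod(key, r)
        out.append(alphabet.symbols[d])
    return "".join(reversed(out))


def iter_window_keys(
    sequence: str, j: int, alphabet: Alphabet
) -> Iterator[tuple[int, int]]:
    """Yield ``(p, key)`` for every encodable window of length *j*.

    Positions ``p`` are 1-based window starts, ``p = 1 .. n−j+1``.  The key
    is maintained as a rolling radix hash, one multiply-add per symbol, so a
    full pass is O(n) independent of ``j``.  Windows containing a
    non-encodable symbol are silently skipped.
    """
    if j < 1:
        raise ValueError("window length must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < j:
        return
    digit = alphabet.digit_of
    r = alphabet.radix
    modulus = r**j
    key = 0
    last_bad = -1  # 0-based index of the most recent non-encodable symbol
    for i in range(n):
        d = digit.get(seq[i])
        if d is None:
            last_bad = i
            d = 0
        key = (key * r + d) % modulus
        # the window [i-j+1, i] is clean iff the last bad symbol precedes it
        if i >= j - 1 and last_bad < i - j + 1:
            yield i - j + 2, key
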