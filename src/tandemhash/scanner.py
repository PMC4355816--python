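"""Single-pass tandem-repeat scan over one sequence and one motif length.

A window of length ``j`` slides along the sequence; each encodable window is
hashed to its motif key and drives a store of *single buckets*, one open
bucket per motif key.  A bucket ⟨sp, fp, mt, g, lt⟩ records a growing repeat
locus: start and final position (1-based, closed), motif, total gap
characters between units, and unit count.

Per window at position ``p`` with key ``k``:

* exact step — if no bucket is open at ``k``, open one (``sp = p``,
  ``fp = p+j−1``, ``lt = 1``, ``g = 0``).  Otherwise, windows starting at or
  before the bucket's end are ignored (units never overlap), and for
  ``p > fp`` the inter-unit gap is ``p − fp − 1``: within the tolerance
  ``gap ≤ ga`` the bucket extends (``g += gap``, ``fp = p+j−1``,
  ``lt += 1``); beyond it the bucket is closed — emitted if it reached the
  minimum unit count, discarded otherwise — and a fresh bucket opens at
  ``p``.
* degenerate step — every present key ``k′`` within the substitution budget
  of ``k`` (from the degeneration buffer) has its open bucket extended by
  the same rule, except that falling out of tolerance never closes a bucket
  on this path: only an exact occurrence of a motif restarts its locus.

At the end of the sequence every open bucket meeting the minimum unit count
is emitted.  Output is sorted by (sp, fp, motif) and is identical whether
motif lengths are scanned serially or in parallel.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

from .degeneration import (
    DegenerationBuffer,
    build_degeneration_buffers,
    build_presence_table,
    max_mismatches,
)
from .encoding import Alphabet, alphabet_for_mode, iter_window_keys

__all__ = [
    "SingleBucket",
    "RunParams",
    "CandidateRepeat",
    "OpCounter",
    "scan_sequence",
    "scan_all",
]

MAX_MOTIF_LENGTH = 12


@dataclass(frozen=True)
class SingleBucket:
    """One repeat locus: ⟨sp, fp, mt, g, lt⟩, 1-based closed coordinates."""

    sp: int
    fp: int
    mt: str
    g: int
    lt: int

    def __post_init__(self) -> None:
        if self.sp > self.fp or self.lt < 1 or self.g < 0:
            raise ValueError(f"malformed bucket {self}")
        if self.fp - self.sp + 1 != self.lt * len(self.mt) + self.g:
            raise ValueError(f"span inconsistency in bucket {self}")

    @property
    def span(self) -> int:
        return self.fp - self.sp + 1


@dataclass(frozen=True)
class RunParams:
    """Full parameter set of one run.

    ``min_repeats`` is either one global minimum unit count or a tuple with
    one value per motif length in ``[min_motif, max_motif]``.
    """

    min_motif: int = 1
    max_motif: int = 6
    min_repeats: int | tuple[int, ...] = 5
    max_gap: int = 0
    degeneration_percent: float = 0
    overlap_percent: float = 0
    run_mode: str = "dna"

    def __post_init__(self) -> None:
        if not 1 <= self.min_motif <= self.max_motif <= MAX_MOTIF_LENGTH:
            raise ValueError(
                f"motif length range must satisfy 1 <= min <= max <= "
                f"{MAX_MOTIF_LENGTH}, got [{self.min_motif}, {self.max_motif}]"
            )
        reps = (
            (self.min_repeats,)
            if isinstance(self.min_repeats, int)
            else tuple(self.min_repeats)
        )
        if not isinstance(self.min_repeats, int) and len(reps) != (
            self.max_motif - self.min_motif + 1
        ):
            raise ValueError(
                "per-motif-length min_repeats must have one value per length "
                f"in [{self.min_motif}, {self.max_motif}]"
            )
        if any(r < 2 for r in reps):
            raise ValueError("min_repeats must be >= 2")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not 0 <= self.overlap_percent <= 100:
            raise ValueError("overlap_percent must be in [0, 100]")
        # validates the degeneration percentage range as a side effect
        max_mismatches(1, self.degeneration_percent)
        alphabet_for_mode(self.run_mode)

    @property
    def alphabet(self) -> Alphabet:
        return alphabet_for_mode(self.run_mode)

    def min_repeats_for(self, j: int) -> int:
        if isinstance(self.min_repeats, int):
            return self.min_repeats
        return self.min_repeats[j - self.min_motif]

    def max_mm_for(self, j: int) -> int:
        return max_mismatches(j, self.degeneration_percent)


@dataclass(frozen=True)
class CandidateRepeat:
    """A finalized repeat locus on one sequence, before overlap resolution."""

    sequence_id: str
    bucket: SingleBucket
    motif_length: int

    @property
    def sp(self) -> int:
        return self.bucket.sp

    @property
    def fp(self) -> int:
        return self.bucket.fp

    @property
    def motif(self) -> str:
        return self.bucket.mt

    @property
    def span(self) -> int:
        return self.bucket.span

    def sort_key(self) -> tuple:
        return (self.sequence_id, self.sp, self.fp, self.motif)


@dataclass
class OpCounter:
    """Counts bucket operations, for empirical running-time checks."""

    windows: int = 0
    bucket_ops: int = 0


# open buckets are mutable [sp, fp, lt, g] lists keyed by motif key
_SP, _FP, _LT, _G = range(4)


def scan_sequence(
    sequence: str,
    sequence_id: str,
    j: int,
    buffers: DegenerationBuffer,
    params: RunParams,
    *,
    counter: OpCounter | None = None,
) -> list[CandidateRepeat]:
    """Scan one sequence at one motif length; see the module docstring.

    *buffers* must have been built from this sequence at this ``j`` (its
    substitution budget defines which imperfect units may extend a locus).
    """
    if buffers.word_length != j:
        raise ValueError(
            f"degeneration buffers built for word length {buffers.word_length}, "
            f"scan requested at {j}"
        )
    seq = sequence.upper()
    ga = params.max_gap
    min_reps = params.min_repeats_for(j)
    open_buckets: dict[int, list[int]] = {}
    emitted: list[SingleBucket] = []

    def close(bucket: list[int], key: int) -> None:
        if bucket[_LT] >= min_reps:
            emitted.append(
                SingleBucket(
                    sp=bucket[_SP],
                    fp=bucket[_FP],
                    mt=seq[bucket[_SP] - 1 : bucket[_SP] - 1 + j],
                    g=bucket[_G],
                    lt=bucket[_LT],
                )
            )

    variants_of = buffers.variants_of
    for p, k in iter_window_keys(seq, j, params.alphabet):
        fp = p + j - 1
        if counter is not None:
            counter.windows += 1
            counter.bucket_ops += 1
        # exact step: the window's own motif
        bucket = open_buckets.get(k)
        if bucket is None:
            open_buckets[k] = [p, fp, 1, 0]
        elif p > bucket[_FP]:
            gap = p - bucket[_FP] - 1
            if gap <= ga:
                bucket[_G] += gap
                bucket[_FP] = fp
                bucket[_LT] += 1
            else:
                close(bucket, k)
                open_buckets[k] = [p, fp, 1, 0]
        # degenerate step: extend loci of present motifs within the budget;
        # never close a bucket from here
        for k2 in variants_of(k):
            if counter is not None:
                counter.bucket_ops += 1
            b2 = open_buckets.get(k2)
            if b2 is not None and p > b2[_FP]:
                gap = p - b2[_FP] - 1
                if gap <= ga:
                    b2[_G] += gap
                    b2[_FP] = fp
                    b2[_LT] += 1

    for k, bucket in open_buckets.items():
        close(bucket, k)

    emitted.sort(key=lambda b: (b.sp, b.fp, b.mt))
    return [
        CandidateRepeat(sequence_id=sequence_id, bucket=b, motif_length=j)
        for b in emitted
    ]


def _scan_record_at_length(
    record_id: str, sequence: str, j: int, params: RunParams
) -> list[CandidateRepeat]:
    alphabet = params.alphabet
    presence = build_presence_table(sequence, j, alphabet)
    buffers = build_degeneration_buffers(presence, params.max_mm_for(j), alphabet)
    return scan_sequence(sequence, record_id, j, buffers, params)


def _scan_length_over_records(
    records: Sequence[tuple[str, str]], j: int, params: RunParams
) -> list[CandidateRepeat]:
    out: list[CandidateRepeat] = []
    for record_id, sequence in records:
        out.extend(_scan_record_at_length(record_id, sequence, j, params))
    return out


def scan_all(
    records: Iterable,
    params: RunParams,
    *,
    processes: int = 1,
) -> list[CandidateRepeat]:
    """Scan every record at every motif length in the configured range.

    *records* yields FASTA records (anything with ``id`` and ``sequence``
    attributes, or ``(id, sequence)`` pairs).  With ``processes > 1`` motif
    lengths are scanned in parallel worker processes; the merged output is
    sorted by (sequence id, sp, fp, motif) and is byte-identical to the
    serial result.
    """
    pairs: list[tuple[str, str]] = []
    for rec in records:
        if isinstance(rec, tuple):
            rec_id, seq = rec
        else:
            rec_id, seq = rec.id, rec.sequence
        if not rec_id or not seq:
            raise ValueError(f"unreadable record {rec_id!r}: empty id or sequence")
        pairs.append((rec_id, seq))

    lengths = range(params.min_motif, params.max_motif + 1)
    candidates: list[CandidateRepeat] = []
    if processes > 1:
        with ProcessPoolExecutor(max_workers=processes) as pool:
            for chunk in pool.map(
                _scan_length_over_records,
                [pairs] * len(lengths),
                lengths,
                [params] * len(lengths),
            ):
                candidates.extend(chunk)
    else:
        for j in lengths:
            candidates.extend(_scan_length_over_records(pairs, j, params))
    candidates.sort(key=CandidateRepeat.sort_key)
    return candidates
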