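"""FASTA input and the tab-separated results table.

Record assembly is delegated to Biopython's ``SimpleFastaParser`` (which
normalizes line wrapping, Windows line endings and embedded whitespace); a
thin wrapper adds the validation this tool requires: data before the first
``>`` header, empty headers and empty sequences are errors that name the
offending line or record.  Reading is streaming, so input size is bounded
only by what downstream stages hold.

The results table is a TSV with one commented header line and one row per
kept repeat, columns in order: sequence id, sequence length, minimum
repetitions allowed, repetition count, start, end, gaps, statistics
(base-composition percentages of the repeat region; nucleotide mode only),
and the complete repeated substring.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterator, Sequence, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .encoding import Alphabet, DNA
from .overlap import ResolvedRepeat, kept_candidates
from .scanner import RunParams

__all__ = [
    "FastaRecord",
    "FastaFormatError",
    "ResultRow",
    "read_fasta",
    "iter_fasta",
    "compute_stats",
    "build_result_rows",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = (
    "sequence_id",
    "sequence_length",
    "min_repeats_allowed",
    "repetition_amount",
    "start",
    "end",
    "gaps",
    "statistics",
    "repeat",
)


class FastaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


def _open_text(source: str | PathLike | TextIO) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # caller-owned handle
    return open(source, "r"), True


def iter_fasta(source: str | PathLike | TextIO) -> Iterator[FastaRecord]:
    """Stream records from a FASTA file or text handle.

    Raises :class:`FastaFormatError` for sequence data before the first
    header (naming the line), an empty header, an empty sequence (naming the
    record) or a file with no records at all.
    """
    handle, own = _open_text(source)
    try:
        # pre-scan to the first header so pre-header junk is caught with a
        # line number; SimpleFastaParser would silently skip it
        prefix: list[str] = []
        lineno = 0
        for line in handle:
            lineno += 1
            if line.startswith(">"):
                prefix.append(line)
                break
            if line.strip():
                raise FastaFormatError(
                    f"line {lineno}: sequence data before the first FASTA header"
                )
        if not prefix:
            raise FastaFormatError("no FASTA records found (empty input?)")

        chained = _Chain(prefix, handle)
        any_record = False
        for title, seq in SimpleFastaParser(chained):
            any_record = True
            rec_id, _, description = title.partition(" ")
            if not rec_id:
                raise FastaFormatError("record with empty FASTA header")
            if not seq:
                raise FastaFormatError(f"record {rec_id!r} has an empty sequence")
            yield FastaRecord(id=rec_id, description=description.strip(), sequence=seq)
        if not any_record:
            raise FastaFormatError("no FASTA records found (empty input?)")
    finally:
        if own:
            handle.close()


class _Chain:
    """Minimal read-by-line file object chaining buffered lines to a handle."""

    def __init__(self, prefix: list[str], handle: TextIO) -> None:
        self._iter = iter(prefix)
        self._handle = handle
        self._in_prefix = True

    def __iter__(self) -> Iterator[str]:
        yield from self._iter
        yield from self._handle

    def readline(self) -> str:
        if self._in_prefix:
            try:
                return next(self._iter)
            except StopIteration:
                self._in_prefix = False
        return self._handle.readline()


def read_fasta(source: str | PathLike | TextIO) -> list[FastaRecord]:
    """Read all records of a (multi)FASTA file, in file order."""
    return list(iter_fasta(source))


def compute_stats(repeat_string: str, alphabet: Alphabet = DNA) -> str:
    """Symbol-composition percentages of a repeat region.

    Percentages are over encodable symbols only and sum to 100; formatted as
    ``A:50.00;C:50.00;G:0.00;T:0.00``.
    """
    seq = repeat_string.upper()
    counts = {s: 0 for s in alphabet.symbols}
    total = 0
    for c in seq:
        if c in counts:
            counts[c] += 1
            total += 1
    if total == 0:
        return ";".join(f"{s}:0.00" for s in alphabet.symbols)
    return ";".join(f"{s}:{100.0 * counts[s] / total:.2f}" for s in alphabet.symbols)


@dataclass(frozen=True)
class ResultRow:
    """One line of the results table."""

    sequence_id: str
    sequence_length: int
    min_repeats_allowed: int
    repetition_amount: int
    start: int
    end: int
    gaps: int
    statistics: str
    repeat: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.repeat):
            raise ValueError(
                f"repeat string length {len(self.repeat)} does not match locus "
                f"[{self.start}, {self.end}]"
            )
        if self.repetition_amount < self.min_repeats_allowed:
            raise ValueError("repetition amount below the allowed minimum")


def build_result_rows(
    resolved: Sequence[ResolvedRepeat],
    sequences: dict[str, str],
    params: RunParams,
) -> list[ResultRow]:
    """Turn the kept set of a resolution into result rows.

    The statistics column is filled in nucleotide mode only and left empty
    for protein runs.
    """
    nucleotide = params.alphabet is DNA or params.alphabet.name == "dna"
    rows = []
    for cand in kept_candidates(resolved):
        seq = sequences[cand.sequence_id]
        repeat = seq[cand.sp - 1 : cand.fp].upper()
        rows.append(
            ResultRow(
                sequence_id=cand.sequence_id,
                sequence_length=len(seq),
                min_repeats_allowed=params.min_repeats_for(cand.motif_length),
                repetition_amount=cand.bucket.lt,
                start=cand.sp,
                end=cand.fp,
                gaps=cand.bucket.g,
                statistics=compute_stats(repeat, params.alphabet) if nucleotide else "",
                repeat=repeat,
            )
        )
    rows.sort(key=lambda r: (r.sequence_id, r.start, r.end))
    return rows


def write_results(rows: Sequence[ResultRow], destination: str | PathLike | TextIO) -> None:
    """Write the results table as TSV with one commented header line."""
    handle, own = (
        (destination, False)
        if hasattr(destination, "write")
        else (open(destination, "w"), True)
    )
    try:
        handle.write("# " + "\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                "\t".join(
                    (
                        r.sequence_id,
                        str(r.sequence_length),
                        str(r.min_repeats_allowed),
                        str(r.repetition_amount),
                        str(r.start),
                        str(r.end),
                        str(r.gaps),
                        r.statistics,
                        r.repeat,
                    )
                )
                + "\n"
            )
    finally:
        if own:
            handle.close()


def read_results(source: str | PathLike | TextIO) -> list[ResultRow]:
    """Parse a results table back into rows (inverse of :func:`write_results`)."""
    handle, own = _open_text(source)
    try:
        rows = []
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(RESULT_COLUMNS):
                raise ValueError(f"malformed results line: {line!r}")
            rows.append(
                ResultRow(
                    sequence_id=parts[0],
                    sequence_length=int(parts[1]),
                    min_repeats_allowed=int(parts[2]),
                    repetition_amount=int(parts[3]),
                    start=int(parts[4]),
                    end=int(parts[5]),
                    gaps=int(parts[6]),
                    statistics=parts[7],
                    repeat=parts[8],
                )
            )
        return rows
    finally:
        if own:
            handle.close()
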