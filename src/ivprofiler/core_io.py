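"""Sequence containers, coordinate conventions, and FASTA/FASTQ I/O.

Coordinate conventions used throughout the package:

* Internal arithmetic is 0-based half-open.
* Everything *reported* (dataclass fields, tables, junctions) is 1-based
  inclusive, the convention used for polydnavirus circle annotation.
* A junction is a *between-base* position written ``a–a+1``; on a circular
  molecule of size ``n`` the wrap junction ``n–1`` is legal.
* Viral circles are circular: any position arithmetic wraps modulo the
  circle size.

Nucleotide alphabet is A, C, G, T plus N.  N is tolerated in host scaffolds
(assembly gaps) but never inside viral circles; the read mapper treats N as
mismatching everything.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement, uppercase.

    Accepts A/C/G/T/N case-insensitively; applying it twice returns the
    input (uppercased).  Any other character raises ``ValueError`` naming
    the offender.
    """
    up = s.upper()
    bad = set(up) - _VALID
    if bad:
        raise ValueError(
            f"non-nucleotide character {sorted(bad)[0]!r} in sequence"
        )
    return up.translate(_COMPLEMENT)[::-1]


def _validate_residues(residues: str, *, allow_n: bool, what: str) -> str:
    up = residues.upper()
    allowed = _VALID if allow_n else frozenset("ACGT")
    bad = set(up) - allowed
    if bad:
        raise ValueError(f"invalid residue {sorted(bad)[0]!r} in {what}")
    return up


@dataclass(frozen=True)
class CircularSequence:
    """One circular viral DNA segment (e.g. an ichnovirus circle)."""

    circle_id: str
    residues: str
    accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "residues",
            _validate_residues(
                self.residues, allow_n=False, what=f"circle {self.circle_id}"
            ),
        )
        if not self.residues:
            raise ValueError(f"circle {self.circle_id} is empty")

    @property
    def size(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, length: int) -> str:
        return circular_subsequence(self, start, length)


@dataclass(frozen=True)
class GenomeScaffold:
    """A linear host genome scaffold."""

    scaffold_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"scaffold {self.scaffold_id} is empty")
        object.__setattr__(
            self,
            "residues",
            _validate_residues(
                self.residues, allow_n=True, what=f"scaffold {self.scaffold_id}"
            ),
        )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequencingRead:
    """A single sequenced read (one mate of a pair)."""

    read_id: str
    mate: int
    residues: str

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        object.__setattr__(
            self,
            "residues",
            _validate_residues(
                self.residues, allow_n=True, what=f"read {self.read_id}"
            ),
        )
        if not self.residues:
            raise ValueError(f"read {self.read_id} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class BetweenBaseJunction:
    """A between-base position ``left–right`` on a named target.

    ``right == left + 1`` always, except that on a circular target of size
    ``n`` the origin-spanning junction ``(n, 1)`` is legal; use
    :meth:`on_circle` to build wrap-safe junctions.
    """

    target_id: str
    left_position: int
    right_position: int

    def __post_init__(self) -> None:
        ok = self.right_position == self.left_position + 1 or (
            self.right_position == 1 and self.left_position > 1
        )
        if not ok or self.left_position < 1:
            raise ValueError(
                f"invalid between-base junction "
                f"{self.left_position}-{self.right_position}"
            )

    @classmethod
    def on_circle(
        cls, target_id: str, left: int, size: int
    ) -> "BetweenBaseJunction":
        """Junction after 1-based position ``left`` on a circle, wrap-aware."""
        left = (left - 1) % size + 1
        right = left % size + 1
        return cls(target_id, left, right)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.target_id}:{self.left_position}-{self.right_position}"


def circular_subsequence(c: CircularSequence, start: int, length: int) -> str:
    """``length`` residues starting at 1-based ``start``, wrapping the origin."""
    if not 1 <= start <= c.size:
        raise ValueError(f"start {start} outside 1..{c.size}")
    if length > c.size:
        raise ValueError(f"length {length} exceeds circle size {c.size}")
    if length < 0:
        raise ValueError("length must be non-negative")
    doubled = c.residues + c.residues
    return doubled[start - 1 : start - 1 + length]


# ---------------------------------------------------------------------------
# FASTA / FASTQ (plain or gzip, chosen by .gz suffix)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-line, possibly gzipped) FASTA file.

    Returns ``(id, residues)`` pairs with residues uppercased.
    """
    records: list[tuple[str, str]] = []
    with _open_text(path, "r") as fh:
        # reject junk before the first header with a line number, which
        # Bio.SeqIO silently skips
        pos = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, "
                    f"got {line.strip()[:30]!r}"
                )
            break
        fh.seek(pos)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with _open_text(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _mate_from_id(read_id: str) -> tuple[str, int]:
    if read_id.endswith("/1"):
        return read_id[:-2], 1
    if read_id.endswith("/2"):
        return read_id[:-2], 2
    return read_id, 1


def read_fastq(path: str | Path) -> list[SequencingRead]:
    """Read a 4-line FASTQ file (optionally gzipped) into reads.

    Mate numbers are recovered from trailing ``/1`` / ``/2`` id suffixes
    (defaulting to 1).  Malformed records are rejected with the offending
    record's position in the file.
    """
    reads: list[SequencingRead] = []
    with _open_text(path, "r") as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                base, mate = _mate_from_id(rec.id)
                reads.append(SequencingRead(base, mate, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near record {len(reads) + 1} "
                f"(line ~{len(reads) * 4 + 1}): {exc}"
            ) from exc
    return reads


def write_fastq(
    reads: Iterable[SequencingRead], path: str | Path, quality_char: str = "I"
) -> None:
    """Write reads as 4-line FASTQ with a constant placeholder quality."""
    with _open_text(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}/{r.mate}\n{r.residues}\n+\n")
            fh.write(quality_char * r.length + "\n")
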