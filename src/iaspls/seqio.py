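"""Reading, validating and organizing short DNA sequences.

Sequences are handled in their putative reading orientation; no
reverse-complement scanning or ORF extraction is performed. Length
classes follow a half-open convention ``[low, high)`` except the top
bin, which is closed at its upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

#: Unambiguous bases.
ACGT = "ACGT"

#: Full IUPAC nucleotide alphabet accepted on input.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Default cap on the fraction of non-ACGT characters per sequence.
DEFAULT_AMBIGUITY_CAP = 0.1


@dataclass(frozen=True)
class DnaSequence:
    """A validated nucleotide string with identifier and optional label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    bases : str
        Nucleotide string; normalized to uppercase on construction.
    label : int or None
        ``+1`` for coding, ``-1`` for noncoding, ``None`` if unknown.
    """

    id: str
    bases: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence identifier must be non-empty")
        if not self.bases:
            raise DataError(f"sequence {self.id!r}: empty sequence")
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - IUPAC_ALPHABET
        if bad:
            raise DataError(
                f"sequence {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.label is not None and self.label not in (-1, 1):
            raise DataError(
                f"sequence {self.id!r}: label must be +1 or -1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def ambiguous_fraction(self) -> float:
        """Fraction of characters outside {A, C, G, T}."""
        n_bad = sum(1 for b in self.bases if b not in ACGT)
        return n_bad / len(self.bases)

    def check_ambiguity(self, cap: float = DEFAULT_AMBIGUITY_CAP) -> "DnaSequence":
        """Raise :class:`DataError` if the ambiguous fraction exceeds *cap*."""
        frac = self.ambiguous_fraction
        if frac > cap:
            raise DataError(
                f"sequence {self.id!r}: ambiguous-base fraction {frac:.3f} "
                f"exceeds cap {cap:.3f}"
            )
        return self

    def with_label(self, label: int | None) -> "DnaSequence":
        return DnaSequence(self.id, self.bases, label)


@dataclass(frozen=True)
class LengthClass:
    """A length bin ``[low, high)``, or ``[low, high]`` when ``closed_top``."""

    low: int
    high: int
    name: str = ""
    closed_top: bool = False

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise DataError(f"length class bounds out of order: {self.low}..{self.high}")
        if not self.name:
            bracket = "]" if self.closed_top else ")"
            object.__setattr__(self, "name", f"[{self.low},{self.high}{bracket}")

    def contains(self, length: int) -> bool:
        if self.closed_top:
            return self.low <= length <= self.high
        return self.low <= length < self.high


#: The four default bins tiling [60, 400].
DEFAULT_LENGTH_CLASSES: tuple[LengthClass, ...] = (
    LengthClass(60, 100),
    LengthClass(100, 200),
    LengthClass(200, 300),
    LengthClass(300, 400, closed_top=True),
)


def validate_length_classes(bins: Sequence[LengthClass]) -> None:
    """Check that *bins* tile a contiguous integer range without overlap."""
    if not bins:
        raise DataError("no length classes given")
    ordered = sorted(bins, key=lambda b: b.low)
    for left, right in zip(ordered, ordered[1:]):
        if left.closed_top:
            raise DataError(f"non-final bin {left.name} must be half-open")
        if left.high != right.low:
            raise DataError(
                f"length classes {left.name} and {right.name} do not tile contiguously"
            )
    if not ordered[-1].closed_top:
        raise DataError(f"final bin {ordered[-1].name} must be closed at the top")


def assign_length_class(
    seq: DnaSequence | int, bins: Sequence[LengthClass] = DEFAULT_LENGTH_CLASSES
) -> LengthClass:
    """Return the unique bin containing the sequence length.

    Accepts either a :class:`DnaSequence` or a bare integer length.
    """
    validate_length_classes(bins)
    length = len(seq) if isinstance(seq, DnaSequence) else int(seq)
    for b in bins:
        if b.contains(length):
            return b
    lo = min(b.low for b in bins)
    hi = max(b.high for b in bins)
    raise DataError(f"length {length} nt outside admissible range [{lo}, {hi}]")


def read_fasta(
    path: str | Path,
    max_ambiguous_fraction: float = DEFAULT_AMBIGUITY_CAP,
) -> list[DnaSequence]:
    """Read a multi-record FASTA file into a list of :class:`DnaSequence`.

    Order is preserved; sequences are uppercased. Records whose fraction
    of non-ACGT characters exceeds *max_ambiguous_fraction* are rejected
    with an error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"FASTA file {path} contains no records")
    out: list[DnaSequence] = []
    for rec in records:
        if len(rec.seq) == 0:
            raise DataError(f"record {rec.id!r} in {path} has an empty sequence")
        seq = DnaSequence(rec.id, str(rec.seq))
        out.append(seq.check_ambiguity(max_ambiguous_fraction))
    return out


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to *path* in FASTA format with fixed line wrapping."""
    seqs = list(seqs)
    if not seqs:
        raise DataError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


_LABEL_ALIASES = {
    "+1": 1,
    "1": 1,
    "-1": -1,
    "coding": 1,
    "noncoding": -1,
    "non-coding": -1,
}


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) plain-text file.

    Labels may be ``+1``/``-1`` or ``coding``/``noncoding``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"label file not found: {path}")
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            ident, raw = parts
            key = raw.lower()
            if key not in _LABEL_ALIASES:
                raise DataError(f"{path}:{lineno}: unrecognized label {raw!r}")
            if ident in labels:
                raise DataError(f"{path}:{lineno}: duplicate id {ident!r}")
            labels[ident] = _LABEL_ALIASES[key]
    if not labels:
        raise DataError(f"label file {path} contains no entries")
    return labels


def write_labels(seqs: Iterable[DnaSequence], path: str | Path) -> None:
    """Write a two-column (id, ±1) label file for labeled sequences."""
    with open(path, "w") as fh:
        for s in seqs:
            if s.label is None:
                raise DataError(f"sequence {s.id!r} has no label to write")
            fh.write(f"{s.id}\t{'+1' if s.label > 0 else '-1'}\n")


def attach_labels(
    seqs: Sequence[DnaSequence], labels: dict[str, int]
) -> list[DnaSequence]:
    """Return sequences with labels attached; every id must be present."""
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise DataError(f"no label for sequence ids: {missing[:5]!r}...")
    return [s.with_label(labels[s.id]) for s in seqs]
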