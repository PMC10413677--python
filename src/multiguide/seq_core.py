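"""Core sequence model: IUPAC-aware matching, reverse complement, motif
scanning, and FASTA input/output.

Coordinates are 0-based, half-open intervals on the top strand throughout;
strand is stored separately as ``"+"`` or ``"-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_SETS",
    "COMPLEMENT",
    "NucSequence",
    "GenomicSite",
    "reverse_complement",
    "iupac_match",
    "scan_motif",
    "read_fasta",
    "write_fasta",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

#: Complement over the full IUPAC alphabet.
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_CONCRETE = frozenset("ACGT")


class SequenceError(ValueError):
    """Raised for malformed sequences or sequence files."""


def _validate_residues(residues: str, *, context: str = "sequence") -> str:
    if not residues:
        raise SequenceError(f"empty {context}")
    upper = residues.upper()
    for i, ch in enumerate(upper):
        if ch not in IUPAC_ALPHABET:
            raise SequenceError(
                f"non-IUPAC character {ch!r} at position {i} in {context}"
            )
    return upper


@dataclass(frozen=True)
class NucSequence:
    """An identified DNA sequence, optionally tagged with a species label.

    Residues are uppercased on construction and must be gap-free IUPAC DNA.
    """

    id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _validate_residues(self.residues, context=f"sequence {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(
            id=self.id, residues=reverse_complement(self.residues), species=self.species
        )


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A located interval on a named sequence: 0-based, half-open, top-strand
    coordinates with the strand of the matched feature stored separately."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over the full IUPAC alphabet."""
    out = []
    for i, ch in enumerate(seq.upper()):
        comp = COMPLEMENT.get(ch)
        if comp is None:
            raise SequenceError(f"non-IUPAC character {ch!r} at position {i}")
        out.append(comp)
    return "".join(reversed(out))


def iupac_match(pattern: str, window: str) -> bool:
    """True iff ``window`` satisfies ``pattern`` position by position.

    Ambiguity codes in the pattern are permissive (N matches any concrete
    base); ambiguity codes in the window always count as mismatches, so a
    low-quality target base can never produce a spurious "perfect" call.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern.upper(), window.upper()):
        if w not in _CONCRETE:
            return False
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise SequenceError(f"non-IUPAC pattern character {p!r}")
        if w not in allowed:
            return False
    return True


def scan_motif(
    seq: NucSequence,
    pattern: str,
    strands: Iterable[str] = ("+", "-"),
) -> list[GenomicSite]:
    """All sites where ``pattern`` matches ``seq`` on the requested strands.

    Minus-strand hits are reported as top-strand intervals with strand "-".
    Output is sorted by (start, strand).
    """
    if not pattern:
        raise ValueError("empty pattern")
    strands = set(strands)
    if not strands <= {"+", "-"}:
        raise ValueError(f"strands must be subset of {{'+','-'}}, got {strands}")
    m = len(pattern)
    residues = seq.residues
    sites: list[GenomicSite] = []
    rc_pattern = reverse_complement(pattern) if "-" in strands else None
    for i in range(len(residues) - m + 1):
        window = residues[i : i + m]
        if "+" in strands and iupac_match(pattern, window):
            sites.append(GenomicSite(seq.id, i, i + m, "+"))
        if rc_pattern is not None and iupac_match(rc_pattern, window):
            sites.append(GenomicSite(seq.id, i, i + m, "-"))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Headers are ">id" or ">id [species=...]"; species round-trips through the
# bracketed attribute. Output wraps residues at 60 columns.

_WRAP = 60


def _parse_header(line: str) -> tuple[str, str | None]:
    header = line[1:].strip()
    species = None
    if "[species=" in header:
        head, _, rest = header.partition("[species=")
        species = rest.split("]", 1)[0].strip()
        header = head.strip()
    seq_id = header.split()[0] if header else ""
    if not seq_id:
        raise SequenceError("FASTA record with empty id")
    return seq_id, species


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a multi-record FASTA file into ``NucSequence`` objects.

    Duplicate ids and empty records are rejected.
    """
    path = Path(path)
    records: list[NucSequence] = []
    seen: set[str] = set()
    seq_id: str | None = None
    species: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal seq_id, species, chunks
        if seq_id is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise SequenceError(f"empty FASTA record {seq_id!r} in {path}")
        records.append(NucSequence(id=seq_id, residues=residues, species=species))
        seq_id, species, chunks = None, None, []

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                seq_id, species = _parse_header(line)
                if seq_id in seen:
                    raise SequenceError(f"duplicate FASTA id {seq_id!r} in {path}")
                seen.add(seq_id)
            else:
                if seq_id is None:
                    raise SequenceError(f"residues before first header in {path}")
                chunks.append(line)
    flush()
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    """Write sequences as multi-record FASTA, wrapped at 60 columns."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            header = f">{seq.id}"
            if seq.species is not None:
                header += f" [species={seq.species}]"
            fh.write(header + "\n")
            for i in range(0, len(seq.residues), _WRAP):
                fh.write(seq.residues[i : i + _WRAP] + "\n")
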