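"""In-silico genotyping: PCR amplicon extraction, Cas9 cut placement, T7
endonuclease fragment sizes, and the frameshift fraction of an indel
spectrum.

Primer matching is exact (case-insensitive); the cut model is the
canonical blunt cut 3 nt 5' of the PAM, exposed as a knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .prediction import DEFAULT_PAM, find_perfect_sites
from .seq_core import NucSequence, reverse_complement

__all__ = [
    "PrimerPair",
    "Amplicon",
    "CutModel",
    "NoAmplificationError",
    "AmbiguousAmplificationError",
    "find_amplicon",
    "cut_positions",
    "t7_fragment_sizes",
    "frameshift_fraction",
    "fragment_report",
]

MIN_PRIMER_LEN = 15


class NoAmplificationError(ValueError):
    """Neither primer pair orientation yields a product."""


class AmbiguousAmplificationError(ValueError):
    """More than one product; carries all (start, end) intervals."""

    def __init__(self, products: list[tuple[int, int]]):
        self.products = products
        super().__init__(
            f"ambiguous amplification: {len(products)} products at {products}"
        )


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, each written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < MIN_PRIMER_LEN:
                raise ValueError(
                    f"{name} primer length {len(p)} < {MIN_PRIMER_LEN}"
                )
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A PCR product: top-strand half-open interval on the template plus
    its sequence. Starts with the forward primer, ends with the reverse
    complement of the reverse primer."""

    template_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length does not match interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CutModel:
    """Blunt Cas9 cut ``cut_offset`` nucleotides 5' of the PAM."""

    cut_offset: int = 3

    def validate(self, guide_len: int) -> None:
        if not 0 < self.cut_offset < guide_len:
            raise ValueError(
                f"cut_offset {self.cut_offset} outside (0, {guide_len})"
            )


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def find_amplicon(template: NucSequence, primers: PrimerPair) -> Amplicon:
    """The unique product where the forward primer matches the top strand
    and the reverse primer matches the bottom strand downstream of it.

    Raises NoAmplificationError with zero products and
    AmbiguousAmplificationError listing all intervals with more than one.
    """
    seq = template.residues
    fw, rv = primers.forward, primers.reverse
    if len(seq) <= max(len(fw), len(rv)):
        raise ValueError("template not longer than the primers")
    rv_rc = reverse_complement(rv)
    fw_sites = _find_all(seq, fw)
    rv_sites = _find_all(seq, rv_rc)  # top-strand intervals of reverse binding
    products = [
        (f, r + len(rv_rc))
        for f in fw_sites
        for r in rv_sites
        if r >= f + len(fw)
    ]
    if not products:
        raise NoAmplificationError(
            f"no amplification of {template.id!r} with this primer pair"
        )
    if len(products) > 1:
        raise AmbiguousAmplificationError(sorted(products))
    start, end = products[0]
    return Amplicon(
        template_id=template.id, start=start, end=end, sequence=seq[start:end]
    )


def cut_positions(
    amplicon: Amplicon,
    guide: str,
    pam: str = DEFAULT_PAM,
    cut_model: CutModel = CutModel(),
) -> list[int]:
    """Top-strand cut coordinates (amplicon-local) for every perfect
    protospacer+PAM site on either strand.

    For a plus-strand site [s, e) the blunt cut falls at e - offset; for a
    minus-strand site (PAM on the top strand at [s-3, s)) it falls at
    s + offset. No site yields an empty list, not an error.
    """
    guide = guide.upper()
    cut_model.validate(len(guide))
    target = NucSequence(id="amplicon", residues=amplicon.sequence)
    sites = find_perfect_sites(guide, target, pam=pam, require_pam=True)
    cuts = sorted(
        {
            site.end - cut_model.cut_offset
            if site.strand == "+"
            else site.start + cut_model.cut_offset
            for site in sites
        }
    )
    return cuts


def t7_fragment_sizes(amplicon: Amplicon, cuts: Sequence[int]) -> list[int]:
    """Fragment lengths produced by cleaving the amplicon at every cut.

    The sizes partition the amplicon: they always sum to its length.
    """
    length = amplicon.length
    cuts = sorted(cuts)
    for c in cuts:
        if not 0 < c < length:
            raise ValueError(f"cut {c} outside amplicon (0, {length})")
    bounds = [0, *cuts, length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def frameshift_fraction(weights: Mapping[int, float]) -> float:
    """Weighted fraction of indel lengths that shift the reading frame
    (length not divisible by 3)."""
    if 0 in weights:
        raise ValueError("indel length 0 is not an indel")
    total = 0.0
    shifted = 0.0
    for length, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for indel length {length}")
        total += w
        if length % 3 != 0:
            shifted += w
    if total <= 0:
        raise ValueError("total weight must be positive")
    return shifted / total


def fragment_report(
    amplicon: Amplicon, guide: str, cuts: Sequence[int], sizes: Sequence[int]
) -> str:
    """Human-readable virtual-gel summary of a T7 digestion."""
    lines = [
        f"template   {amplicon.template_id}",
        f"amplicon   [{amplicon.start},{amplicon.end})  length {amplicon.length}",
        f"guide      {guide}",
        f"cuts       {', '.join(map(str, cuts)) if cuts else '(none)'}",
        "virtual gel:",
    ]
    for size in sorted(sizes, reverse=True):
        lines.append(f"  {size:>6} nt")
    return "\n".join(lines) + "\n"
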