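"""Seeded synthetic-data generators and packaged fixtures.

Generators produce ortholog families under a star phylogeny with iid
substitutions, optionally with planted conserved windows, per-species PAM
knockouts, and paralogs at a chosen mismatch distance from a guide site —
enough structure to exercise every pipeline stage without downloads.

Fixtures expose the published species prediction tables (as TSV
transcriptions) and the printed guide/primer sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .insilico_validation import PrimerPair
from .prediction import PredictionTable
from .seq_core import GenomicSite, NucSequence

__all__ = [
    "GRNA_OXTR1",
    "GRNA_OXTR2",
    "GRNA_OXTR3",
    "GRNA_CTRL",
    "GUIDES",
    "T7_PRIMERS",
    "FamilySpec",
    "ParalogSpec",
    "generate_ancestor",
    "evolve_family",
    "plant_paralog",
    "load_fixture",
]

# Published guide spacer sequences (5'->3').
GRNA_OXTR1 = "GGTGCTTCATGAAAAAGAAG"
GRNA_OXTR2 = "GTGATGTCCCACAGCAGCTG"
GRNA_OXTR3 = "GCCCGACCTGCTGTGTCGTC"
GRNA_CTRL = "GTGAGCGAGTAACAACCCGT"

GUIDES: dict[str, str] = {
    "gRNA_OXTR.1": GRNA_OXTR1,
    "gRNA_OXTR.2": GRNA_OXTR2,
    "gRNA_OXTR.3": GRNA_OXTR3,
    "gRNA_CTRL": GRNA_CTRL,
}

# Published genotyping primer pair (5'->3').
T7_PRIMERS = PrimerPair(
    forward="AGCAGTCAAAAACACCGTCC",
    reverse="GACACCTGGACAACTCATCGG",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters for a star-phylogeny ortholog family.

    ``conserved_intervals`` are disjoint (start, end, pam_terminal) triples;
    substitution probability is ``divergence`` per site outside them and 0
    inside. Intervals flagged pam_terminal end with "GG" in every species
    except those in ``pam_knockout``, whose terminal dinucleotide is forced
    to a non-GG value.
    """

    n_species: int
    length: int
    divergence: float
    conserved_intervals: tuple[tuple[int, int, bool], ...] = ()
    pam_knockout: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        ivals = sorted(self.conserved_intervals)
        for (s, e, _), nxt in zip(ivals, ivals[1:] + [None]):
            if not 0 <= s < e <= self.length:
                raise ValueError(f"interval ({s},{e}) out of bounds")
            if nxt is not None and e > nxt[0]:
                raise ValueError("conserved intervals overlap")
        object.__setattr__(self, "conserved_intervals", tuple(ivals))
        object.__setattr__(self, "pam_knockout", frozenset(self.pam_knockout))

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass(frozen=True)
class ParalogSpec:
    """A paralog derived from a source sequence: exactly ``k`` mismatches
    planted inside the guide site, background divergence elsewhere."""

    source: NucSequence
    guide_site: GenomicSite
    k: int
    background_divergence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        glen = self.guide_site.end - self.guide_site.start
        if not 0 <= self.k <= glen:
            raise ValueError(f"k={self.k} outside [0, {glen}]")
        if not 0 <= self.background_divergence < 1:
            raise ValueError("background_divergence must be in [0, 1)")


def generate_ancestor(
    length: int, gc_fraction: float = 0.5, seed: int = 0
) -> NucSequence:
    """Random ancestor sequence with the requested GC content in
    expectation; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    residues = "".join(rng.choice(_BASES, size=length, p=p))
    return NucSequence(id="ancestor", residues=residues)


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[rng.integers(len(alternatives))]


def evolve_family(ancestor: NucSequence, spec: FamilySpec) -> list[NucSequence]:
    """Evolve a star-phylogeny family from the ancestor.

    Substitutions are iid per site (uniform over the three alternatives) at
    rate ``spec.divergence`` outside conserved intervals and zero inside.
    pam_terminal intervals end with "GG" everywhere except knockout species,
    which get "TT" in that slot. No indels. Deterministic per seed.
    """
    ids = spec.species_ids()
    unknown = spec.pam_knockout - set(ids)
    if unknown:
        raise ValueError(f"pam_knockout species not in family: {sorted(unknown)}")
    base = list(ancestor.residues)
    if len(base) != spec.length:
        raise ValueError(
            f"ancestor length {len(base)} != spec length {spec.length}"
        )
    conserved = np.zeros(spec.length, dtype=bool)
    for s, e, _ in spec.conserved_intervals:
        conserved[s:e] = True
    # Force the shared PAM dinucleotide in the ancestor so conserved copies
    # inherit it.
    for s, e, pam_terminal in spec.conserved_intervals:
        if pam_terminal:
            base[e - 2 : e] = ["G", "G"]
    ancestral = "".join(base)

    rng = np.random.default_rng(spec.seed)
    family: list[NucSequence] = []
    for sp in ids:
        residues = list(ancestral)
        if spec.divergence > 0:
            hits = rng.random(spec.length) < spec.divergence
            hits &= ~conserved
            for pos in np.flatnonzero(hits):
                residues[pos] = _mutate_base(residues[pos], rng)
        else:
            rng.random(spec.length)  # keep the stream aligned across specs
        if sp in spec.pam_knockout:
            for s, e, pam_terminal in spec.conserved_intervals:
                if pam_terminal:
                    residues[e - 2 : e] = ["T", "T"]
        family.append(NucSequence(id=sp, residues="".join(residues), species=sp))
    return family


def plant_paralog(spec: ParalogSpec) -> NucSequence:
    """Derive a paralog with exactly ``k`` mismatches inside the guide site.

    Mismatch positions are drawn without replacement; background divergence
    applies everywhere outside the guide site and its 3-nt PAM slot, which
    are otherwise copied verbatim so a mismatch scan recovers exactly k.
    """
    rng = np.random.default_rng(spec.seed)
    residues = list(spec.source.residues)
    s, e = spec.guide_site.start, spec.guide_site.end
    if spec.guide_site.strand == "+":
        pam_lo, pam_hi = e, min(e + 3, len(residues))
    else:
        pam_lo, pam_hi = max(0, s - 3), s
    protected = set(range(s, e)) | set(range(pam_lo, pam_hi))
    if spec.background_divergence > 0:
        hits = rng.random(len(residues)) < spec.background_divergence
        for pos in np.flatnonzero(hits):
            if pos not in protected:
                residues[pos] = _mutate_base(residues[pos], rng)
    if spec.k > 0:
        positions = rng.choice(np.arange(s, e), size=spec.k, replace=False)
        for pos in positions:
            residues[pos] = _mutate_base(residues[pos], rng)
    return NucSequence(
        id=f"{spec.source.id}_paralog_k{spec.k}",
        residues="".join(residues),
        species=spec.source.species,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures

_TABLE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "table3": "table3.tsv",
}


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Names: ``table1``/``table2``/``table3`` -> PredictionTable of the
    published species lists; ``guides`` -> dict of printed spacer
    sequences; ``t7_primers`` -> the printed genotyping PrimerPair.
    """
    if name in _TABLE_FILES:
        ref = resources.files("multiguide.data") / _TABLE_FILES[name]
        with resources.as_file(ref) as path:
            return PredictionTable.from_tsv(path)
    if name == "guides":
        return dict(GUIDES)
    if name == "t7_primers":
        return T7_PRIMERS
    raise KeyError(
        f"unknown fixture {name!r}; available: "
        f"{sorted([*_TABLE_FILES, 'guides', 't7_primers'])}"
    )
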