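"""Per-species guide functionality prediction and off-target scanning.

The functional call mirrors the design criterion: a guide is predicted
functional in a species iff its protospacer occurs with zero mismatches
somewhere in that species' target sequences with a valid PAM immediately
3' of it. Off-target risk is the genome-/paralog-wide minimum Hamming
distance of the protospacer over both strands (ungapped; bulges are out of
scope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .msa import AlignParams, DEFAULT_PARAMS, pairwise_align_affine
from .seq_core import GenomicSite, NucSequence, iupac_match, reverse_complement

__all__ = [
    "MatchStatus",
    "SpeciesPrediction",
    "PredictionTable",
    "OffTargetHit",
    "FlankIdentity",
    "find_perfect_sites",
    "min_mismatch_scan",
    "classify_species",
    "flank_identity",
    "aggregate",
]

DEFAULT_PAM = "NGG"
DEFAULT_REPORT_THRESHOLD = 10

_STATUS_KINDS = ("predicted_functional", "pam_absent", "mismatched", "absent")


@dataclass(frozen=True)
class MatchStatus:
    """Outcome of matching one guide against one species' sequences.

    kind:
      - predicted_functional: 0-mismatch protospacer site with a valid PAM.
      - pam_absent: 0-mismatch protospacer site exists, but none has a PAM.
      - mismatched: best site has k >= 1 mismatches (k = minimum found).
      - absent: minimum mismatch count exceeds the reporting threshold.
    """

    kind: str
    k: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _STATUS_KINDS:
            raise ValueError(f"unknown status kind {self.kind!r}")
        if self.kind == "mismatched" and (self.k is None or self.k < 1):
            raise ValueError("mismatched status requires k >= 1")

    @property
    def functional(self) -> bool:
        return self.kind == "predicted_functional"

    def sort_key(self) -> tuple[int, int]:
        order = {s: i for i, s in enumerate(_STATUS_KINDS)}
        return (order[self.kind], self.k if self.k is not None else 0)

    def __str__(self) -> str:
        if self.kind == "mismatched":
            return f"mismatched({self.k})"
        return self.kind


@dataclass(frozen=True)
class SpeciesPrediction:
    species: str
    guide_id: str
    status: MatchStatus
    site: GenomicSite | None = None
    flank_pct: float | None = None

    def __post_init__(self) -> None:
        if self.status.kind != "absent" and self.site is None:
            raise ValueError(
                f"{self.species}/{self.guide_id}: status {self.status} needs a site"
            )


@dataclass(frozen=True)
class OffTargetHit:
    target_id: str
    site: GenomicSite
    k: int
    pam_valid: bool
    guide_seq: str
    target_seq: str


@dataclass(frozen=True)
class FlankIdentity:
    percent: float
    clipped: bool = False


# ---------------------------------------------------------------------------
# Site scanning


def _pam_at(target: str, start: int, end: int, strand: str, pam: str) -> str | None:
    """PAM trinucleotide 3' of a protospacer site, protospacer-strand
    oriented; None if the slot runs off the sequence."""
    m = len(pam)
    if strand == "+":
        if end + m > len(target):
            return None
        return target[end : end + m]
    if start - m < 0:
        return None
    return reverse_complement(target[start - m : start])


def find_perfect_sites(
    guide: str,
    target: NucSequence,
    pam: str = DEFAULT_PAM,
    require_pam: bool = True,
) -> list[GenomicSite]:
    """All 0-mismatch occurrences of the protospacer on both strands.

    With ``require_pam``, the PAM slot immediately 3' of the protospacer
    (on its strand) must be in-bounds and satisfy the pattern; edge sites
    lacking a full slot are excluded.
    """
    guide = guide.upper()
    if len(guide) < 17:
        raise ValueError(f"guide length {len(guide)} < 17")
    if not target.residues:
        raise ValueError("empty target")
    sites: list[GenomicSite] = []
    residues = target.residues
    n, m = len(residues), len(guide)
    rc_guide = reverse_complement(guide)
    for i in range(n - m + 1):
        window = residues[i : i + m]
        if window == guide:
            strand = "+"
        elif window == rc_guide:
            strand = "-"
        else:
            continue
        if require_pam:
            tri = _pam_at(residues, i, i + m, strand, pam)
            if tri is None or not iupac_match(pam, tri):
                # The same window may match both strands (palindromes);
                # check the other orientation before giving up.
                if window == guide == rc_guide:
                    other = "-" if strand == "+" else "+"
                    tri2 = _pam_at(residues, i, i + m, other, pam)
                    if tri2 is not None and iupac_match(pam, tri2):
                        sites.append(GenomicSite(target.id, i, i + m, other))
                continue
        sites.append(GenomicSite(target.id, i, i + m, strand))
    return sites


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def min_mismatch_scan(
    guide: str,
    target: NucSequence,
    pam_mode: str = "ignored",
    pam: str = DEFAULT_PAM,
) -> tuple[int, list[OffTargetHit]]:
    """Slide the protospacer over both strands and Hamming-count mismatches.

    Returns the minimum count and every hit achieving it. Ambiguity codes in
    the target count as mismatches. ``pam_mode="required"`` restricts the
    scan to PAM-adjacent offsets.
    """
    if pam_mode not in ("required", "ignored"):
        raise ValueError(f"pam_mode must be 'required' or 'ignored', got {pam_mode!r}")
    guide = guide.upper()
    m = len(guide)
    residues = target.residues
    if len(residues) < m:
        raise ValueError(
            f"target {target.id!r} shorter ({len(residues)}) than guide ({m})"
        )
    enc_t = _encode(residues)
    n = len(residues)
    n_off = n - m + 1
    # Sliding windows without copying; mismatch counts per offset per strand.
    windows = np.lib.stride_tricks.sliding_window_view(enc_t, m)
    results: list[tuple[int, int, str]] = []  # (k, offset, strand)
    for strand, g in (("+", guide), ("-", reverse_complement(guide))):
        enc_g = _encode(g)
        ks = (windows != enc_g).sum(axis=1)
        for off in range(n_off):
            if pam_mode == "required":
                tri = _pam_at(residues, off, off + m, strand, pam)
                if tri is None or not iupac_match(pam, tri):
                    continue
            results.append((int(ks[off]), off, strand))
    if not results:
        return m, []
    k_min = min(k for k, _, _ in results)
    hits: list[OffTargetHit] = []
    for k, off, strand in results:
        if k != k_min:
            continue
        observed = residues[off : off + m]
        if strand == "-":
            observed = reverse_complement(observed)
        tri = _pam_at(residues, off, off + m, strand, pam)
        hits.append(
            OffTargetHit(
                target_id=target.id,
                site=GenomicSite(target.id, off, off + m, strand),
                k=k,
                pam_valid=tri is not None and iupac_match(pam, tri),
                guide_seq=guide,
                target_seq=observed,
            )
        )
    return k_min, hits


def classify_species(
    guide: str,
    species_sequences: Sequence[NucSequence],
    guide_id: str = "guide",
    pam: str = DEFAULT_PAM,
    report_threshold: int = DEFAULT_REPORT_THRESHOLD,
) -> SpeciesPrediction:
    """Classify one guide against all sequences supplied for one species.

    The best status over the sequence set wins: predicted_functional >
    pam_absent > mismatched(k), smaller k better > absent.
    """
    if not species_sequences:
        raise ValueError("empty sequence set")
    species = species_sequences[0].species or species_sequences[0].id
    guide = guide.upper()
    best: tuple[MatchStatus, GenomicSite | None] | None = None

    for seq in species_sequences:
        if len(seq.residues) < len(guide):
            continue
        perfect_with_pam = find_perfect_sites(guide, seq, pam=pam, require_pam=True)
        if perfect_with_pam:
            status, site = MatchStatus("predicted_functional"), perfect_with_pam[0]
        else:
            perfect = find_perfect_sites(guide, seq, pam=pam, require_pam=False)
            if perfect:
                status, site = MatchStatus("pam_absent"), perfect[0]
            else:
                k_min, hits = min_mismatch_scan(guide, seq, pam_mode="ignored", pam=pam)
                if k_min > report_threshold:
                    status, site = MatchStatus("absent"), None
                else:
                    status, site = MatchStatus("mismatched", k=k_min), hits[0].site
        if best is None or status.sort_key() < best[0].sort_key():
            best = (status, site)

    if best is None:
        best = (MatchStatus("absent"), None)
    return SpeciesPrediction(
        species=species, guide_id=guide_id, status=best[0], site=best[1]
    )


def flank_identity(
    guide_site: GenomicSite,
    target: NucSequence,
    reference_context: NucSequence,
    flank_len: int = 50,
    params: AlignParams = DEFAULT_PARAMS,
) -> FlankIdentity:
    """Percent identity of the sequence flanking a hit vs the reference
    flanks, via global alignment of the concatenated left+right flanks.

    The reference context must contain the guide sequence (the subsequence
    at the hit site, strand-adjusted). Clipped flanks are allowed; the
    result is then flagged.
    """
    t = target.residues
    guide_seq = t[guide_site.start : guide_site.end]
    if guide_site.strand == "-":
        guide_seq = reverse_complement(guide_seq)
    ref = reference_context.residues
    idx = ref.find(guide_seq)
    ref_strand = "+"
    if idx < 0:
        idx = ref.find(reverse_complement(guide_seq))
        ref_strand = "-"
    if idx < 0:
        raise ValueError("reference context does not contain the guide sequence")

    def flanks(seq: str, start: int, end: int) -> tuple[str, str, bool]:
        left = seq[max(0, start - flank_len) : start]
        right = seq[end : end + flank_len]
        clipped = len(left) < flank_len or len(right) < flank_len
        return left, right, clipped

    t_left, t_right, t_clip = flanks(t, guide_site.start, guide_site.end)
    r_left, r_right, r_clip = flanks(ref, idx, idx + len(guide_seq))
    if guide_site.strand == "-":
        t_left, t_right = reverse_complement(t_right), reverse_complement(t_left)
    if ref_strand == "-":
        r_left, r_right = reverse_complement(r_right), reverse_complement(r_left)
    hit_flank = t_left + t_right
    ref_flank = r_left + r_right
    if not hit_flank or not ref_flank:
        raise ValueError("no flanking sequence available on either side")
    ga, gb, _ = pairwise_align_affine(hit_flank, ref_flank, params)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    pct = 100.0 * ident / len(ga)
    return FlankIdentity(percent=pct, clipped=t_clip or r_clip)


# ---------------------------------------------------------------------------
# Prediction tables (Table 1-3 analogue)


class PredictionTable:
    """Complete guides x species matrix of SpeciesPrediction."""

    def __init__(
        self,
        guide_ids: Sequence[str],
        species: Sequence[str],
        predictions: Iterable[SpeciesPrediction],
    ):
        self.guide_ids = list(guide_ids)
        self.species = list(species)
        self._cells: dict[tuple[str, str], SpeciesPrediction] = {}
        for pred in predictions:
            self._cells[(pred.guide_id, pred.species)] = pred
        missing = [
            (g, s)
            for g in self.guide_ids
            for s in self.species
            if (g, s) not in self._cells
        ]
        if missing:
            raise ValueError(f"incomplete prediction table; missing {missing[:5]}")

    def get(self, guide_id: str, species: str) -> SpeciesPrediction:
        return self._cells[(guide_id, species)]

    def __iter__(self):
        for g in self.guide_ids:
            for s in self.species:
                yield self._cells[(g, s)]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Table-1 style view: Species column plus Yes/No per guide."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("species\t" + "\t".join(self.guide_ids) + "\n")
            for s in self.species:
                cells = [
                    "Yes" if self._cells[(g, s)].status.functional else "No"
                    for g in self.guide_ids
                ]
                fh.write(s + "\t" + "\t".join(cells) + "\n")

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "guides": self.guide_ids,
            "species": self.species,
            "predictions": [
                {
                    "guide_id": p.guide_id,
                    "species": p.species,
                    "status": str(p.status),
                    "site": None
                    if p.site is None
                    else {
                        "seq_id": p.site.seq_id,
                        "start": p.site.start,
                        "end": p.site.end,
                        "strand": p.site.strand,
                    },
                }
                for p in self
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictionTable":
        """Parse a Table-1 style TSV (Yes -> predicted_functional, No ->
        absent). A Yes cell gets a placeholder site since the source table
        does not record coordinates."""
        path = Path(path)
        lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise ValueError(f"empty table file {path}")
        header = lines[0].split("\t")
        guide_ids = header[1:]
        species: list[str] = []
        preds: list[SpeciesPrediction] = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            if len(cells) != len(header):
                raise ValueError(f"bad row in {path}: {ln!r}")
            sp = cells[0]
            species.append(sp)
            for g, val in zip(guide_ids, cells[1:]):
                if val == "Yes":
                    preds.append(
                        SpeciesPrediction(
                            species=sp,
                            guide_id=g,
                            status=MatchStatus("predicted_functional"),
                            site=GenomicSite(sp, 0, 1, "+"),
                        )
                    )
                elif val == "No":
                    preds.append(
                        SpeciesPrediction(
                            species=sp, guide_id=g, status=MatchStatus("absent")
                        )
                    )
                else:
                    raise ValueError(f"unexpected cell {val!r} in {path}")
        return cls(guide_ids, species, preds)


def aggregate(table: PredictionTable) -> dict:
    """Per-guide predicted_functional counts plus the union count over
    guides (species functional for at least one guide)."""
    per_guide: dict[str, int] = {}
    union: set[str] = set()
    for g in table.guide_ids:
        count = 0
        for s in table.species:
            if table.get(g, s).status.functional:
                count += 1
                union.add(s)
        per_guide[g] = count
    return {
        "per_guide": per_guide,
        "union": len(union),
        "n_species": len(table.species),
    }
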