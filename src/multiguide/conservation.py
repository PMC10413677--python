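"""Conserved-window detection and PAM-adjacent guide enumeration.

A conserved column is one where every alignment row carries the identical,
unambiguous base with no gap. Guide candidates are guide-length windows
inside maximal conserved runs whose 3' PAM slot (which may extend beyond
the run) is gap-free in every row; each row's observed PAM trinucleotide is
checked against the permissive PAM pattern per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .msa import Alignment
from .seq_core import GenomicSite, iupac_match, reverse_complement

__all__ = [
    "ConservedRun",
    "GuideCandidate",
    "find_conserved_runs",
    "enumerate_guides",
    "annotate_guides_on_alignment",
    "write_guides_tsv",
    "write_guides_fasta",
]

_CONCRETE = frozenset("ACGT")

MIN_GUIDE_LEN = 17
MAX_GUIDE_LEN = 25


@dataclass(frozen=True)
class ConservedRun:
    """A maximal run of conserved alignment columns, half-open."""

    col_start: int
    col_end: int

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + PAM designed from a conserved run.

    ``protospacer`` is 5'->3' on the protospacer strand; per-row sites are
    top-strand intervals in each row's ungapped sequence. ``pam_observed``
    holds each row's PAM trinucleotide (protospacer-strand orientation) and
    ``pam_ok`` whether it satisfies the pattern.
    """

    guide_id: str
    protospacer: str
    strand: str
    pam_pattern: str
    col_start: int
    col_end: int
    sites: dict[str, GenomicSite]
    pam_observed: dict[str, str]
    pam_ok: dict[str, bool]
    run: ConservedRun

    @property
    def pam_conserved(self) -> bool:
        return all(self.pam_ok.values())

    @property
    def pam_absent_rows(self) -> list[str]:
        return [rid for rid, ok in self.pam_ok.items() if not ok]


def _is_conserved_column(column: str) -> bool:
    chars = set(column)
    return len(chars) == 1 and chars <= _CONCRETE


def find_conserved_runs(alignment: Alignment, min_len: int) -> list[ConservedRun]:
    """All maximal conserved runs of length >= min_len, sorted by start."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    runs: list[ConservedRun] = []
    start = None
    for col in range(alignment.n_cols):
        if _is_conserved_column(alignment.column(col)):
            if start is None:
                start = col
        elif start is not None:
            if col - start >= min_len:
                runs.append(ConservedRun(start, col))
            start = None
    if start is not None and alignment.n_cols - start >= min_len:
        runs.append(ConservedRun(start, alignment.n_cols))
    return runs


def _pam_slot_columns(
    alignment: Alignment, strand: str, w_start: int, w_end: int, pam_len: int
) -> list[int] | None:
    """Alignment columns of the PAM slot 3' of the window on its strand, in
    protospacer-strand 5'->3' order; None if out of bounds."""
    if strand == "+":
        cols = list(range(w_end, w_end + pam_len))
    else:
        cols = list(range(w_start - pam_len, w_start))[::-1]
    if not cols or cols[0] < 0 or cols[-1] < 0:
        return None
    if max(cols) >= alignment.n_cols or min(cols) < 0:
        return None
    return cols


def enumerate_guides(
    alignment: Alignment,
    runs: Sequence[ConservedRun],
    guide_len: int = 20,
    pam: str = "NGG",
    require_pam_conserved: bool = True,
) -> list[GuideCandidate]:
    """Enumerate guide candidates on both strands inside conserved runs.

    A window qualifies when the PAM slot immediately 3' of it (on the
    protospacer strand) is gap-free in every row and, when
    ``require_pam_conserved``, every row's observed PAM trinucleotide
    satisfies the pattern. Candidates are deduplicated by (protospacer,
    strand) and ordered by (col_start, strand).
    """
    if not MIN_GUIDE_LEN <= guide_len <= MAX_GUIDE_LEN:
        raise ValueError(
            f"guide_len {guide_len} outside sane range "
            f"[{MIN_GUIDE_LEN},{MAX_GUIDE_LEN}]"
        )
    pam_len = len(pam)
    seen: set[tuple[str, str]] = set()
    candidates: list[GuideCandidate] = []
    for run in runs:
        for w_start in range(run.col_start, run.col_end - guide_len + 1):
            w_end = w_start + guide_len
            top = "".join(alignment.column(c)[0] for c in range(w_start, w_end))
            for strand in ("+", "-"):
                pam_cols = _pam_slot_columns(alignment, strand, w_start, w_end, pam_len)
                if pam_cols is None:
                    continue
                # PAM slot must be gap-free in every row.
                if any(
                    alignment.column_to_residue(rid, c) is None
                    for rid in alignment.row_ids
                    for c in pam_cols
                ):
                    continue
                protospacer = top if strand == "+" else reverse_complement(top)
                pam_observed: dict[str, str] = {}
                pam_ok: dict[str, bool] = {}
                sites: dict[str, GenomicSite] = {}
                for rid, gapped in alignment.rows:
                    tri = "".join(gapped[c] for c in pam_cols)
                    if strand == "-":
                        tri = "".join(
                            reverse_complement(gapped[c])[0] if gapped[c] != "-" else "-"
                            for c in pam_cols
                        )
                    pam_observed[rid] = tri
                    pam_ok[rid] = "-" not in tri and iupac_match(pam, tri)
                    r_start = alignment.column_to_residue(rid, w_start)
                    sites[rid] = GenomicSite(rid, r_start, r_start + guide_len, strand)
                if require_pam_conserved and not all(pam_ok.values()):
                    continue
                key = (protospacer, strand)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append(
                    GuideCandidate(
                        guide_id=f"guide_{len(candidates) + 1:03d}",
                        protospacer=protospacer,
                        strand=strand,
                        pam_pattern=pam,
                        col_start=w_start,
                        col_end=w_end,
                        sites=sites,
                        pam_observed=pam_observed,
                        pam_ok=pam_ok,
                        run=run,
                    )
                )
    candidates.sort(key=lambda c: (c.col_start, c.strand))
    # Re-number after sorting so ids follow output order.
    renumbered = [
        GuideCandidate(
            guide_id=f"guide_{i + 1:03d}",
            protospacer=c.protospacer,
            strand=c.strand,
            pam_pattern=c.pam_pattern,
            col_start=c.col_start,
            col_end=c.col_end,
            sites=c.sites,
            pam_observed=c.pam_observed,
            pam_ok=c.pam_ok,
            run=c.run,
        )
        for i, c in enumerate(candidates)
    ]
    return renumbered


def annotate_guides_on_alignment(
    alignment: Alignment, candidates: Sequence[GuideCandidate]
) -> list[dict]:
    """Per-candidate annotation: column interval plus a per-row perfect/
    imperfect marker (protospacer matches AND the row's PAM is valid)."""
    annotations = []
    for cand in candidates:
        for rid in cand.sites:
            if rid not in alignment.row_ids:
                raise ValueError(
                    f"candidate {cand.guide_id} references row {rid!r} "
                    "absent from this alignment"
                )
        markers: dict[str, bool] = {}
        for rid in alignment.row_ids:
            site = cand.sites[rid]
            seq = alignment.ungapped(rid)
            observed = seq[site.start : site.end]
            if cand.strand == "-":
                observed = reverse_complement(observed)
            markers[rid] = observed == cand.protospacer and cand.pam_ok[rid]
        annotations.append(
            {
                "guide_id": cand.guide_id,
                "col_start": cand.col_start,
                "col_end": cand.col_end,
                "strand": cand.strand,
                "perfect": markers,
            }
        )
    return annotations


def write_guides_tsv(
    candidates: Sequence[GuideCandidate], path: str | Path
) -> None:
    """Emit candidates as TSV: one row per guide, per-row site columns."""
    path = Path(path)
    row_ids: list[str] = []
    for cand in candidates:
        for rid in cand.sites:
            if rid not in row_ids:
                row_ids.append(rid)
    with path.open("w") as fh:
        header = ["guide_id", "protospacer", "strand", "pam_pattern", "pam_conserved"]
        header += [f"site_{rid}" for rid in row_ids]
        fh.write("\t".join(header) + "\n")
        for cand in candidates:
            cells = [
                cand.guide_id,
                cand.protospacer,
                cand.strand,
                cand.pam_pattern,
                "yes" if cand.pam_conserved else "no",
            ]
            for rid in row_ids:
                site = cand.sites.get(rid)
                cells.append(
                    f"{site.start}-{site.end}({site.strand})" if site else "."
                )
            fh.write("\t".join(cells) + "\n")


def write_guides_fasta(
    candidates: Sequence[GuideCandidate], path: str | Path
) -> None:
    from .seq_core import NucSequence, write_fasta

    write_fasta(
        [NucSequence(id=c.guide_id, residues=c.protospacer) for c in candidates],
        path,
    )
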