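"""Progressive multiple alignment of ortholog coding sequences.

The pipeline is the classic progressive strategy: k-mer distances feed a
UPGMA guide tree, profiles are merged bottom-up with an affine-gap global
aligner ("once a gap, always a gap"), and all tie-breaking is fixed so
results are bit-reproducible. Alignment objects carry bidirectional
column<->residue coordinate maps.

Users who prefer an external aligner can import its output via
:func:`read_alignment` (aligned FASTA or CLUSTAL).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_core import IUPAC_ALPHABET, NucSequence, SequenceError

__all__ = [
    "AlignParams",
    "GuideTree",
    "TreeNode",
    "Alignment",
    "kmer_distance",
    "build_guide_tree",
    "pairwise_align_affine",
    "progressive_align",
    "read_alignment",
    "write_alignment",
]

GAP = "-"


class AlignmentError(ValueError):
    """Raised for malformed alignments or alignment files."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters. Gap penalties are negative contributions: the
    first position of a gap run costs ``gap_open``, each further position
    ``gap_extend``."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    k: int = 4

    def score(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


DEFAULT_PARAMS = AlignParams()


# ---------------------------------------------------------------------------
# Alignment container


class Alignment:
    """Equal-length gapped rows over named sequences.

    Rows keep their construction order; coordinate maps translate between
    alignment columns and ungapped residue indices per row.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise AlignmentError("alignment needs at least one row")
        lengths = {len(r[1]) for r in rows}
        if len(lengths) != 1:
            shortest = min(rows, key=lambda r: len(r[1]))
            raise AlignmentError(
                f"ragged alignment rows; shortest is {shortest[0]!r} "
                f"({len(shortest[1])} columns)"
            )
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate row id {dup!r}")
        self._rows: list[tuple[str, str]] = []
        for row_id, gapped in rows:
            gapped = gapped.upper()
            for ch in gapped:
                if ch != GAP and ch not in IUPAC_ALPHABET:
                    raise AlignmentError(
                        f"invalid character {ch!r} in row {row_id!r}"
                    )
            self._rows.append((row_id, gapped))
        self.n_cols = lengths.pop()
        self._col2res: dict[str, list[int | None]] = {}
        self._res2col: dict[str, list[int]] = {}

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(self._rows)

    @property
    def row_ids(self) -> list[str]:
        return [r[0] for r in self._rows]

    def __len__(self) -> int:
        return len(self._rows)

    def row(self, row_id: str) -> str:
        for rid, gapped in self._rows:
            if rid == row_id:
                return gapped
        raise KeyError(row_id)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def _maps(self, row_id: str) -> tuple[list[int | None], list[int]]:
        if row_id not in self._col2res:
            gapped = self.row(row_id)
            c2r: list[int | None] = []
            r2c: list[int] = []
            pos = 0
            for col, ch in enumerate(gapped):
                if ch == GAP:
                    c2r.append(None)
                else:
                    c2r.append(pos)
                    r2c.append(col)
                    pos += 1
            self._col2res[row_id] = c2r
            self._res2col[row_id] = r2c
        return self._col2res[row_id], self._res2col[row_id]

    def column_to_residue(self, row_id: str, col: int) -> int | None:
        """Residue index at an alignment column, or None on a gap."""
        c2r, _ = self._maps(row_id)
        if not 0 <= col < self.n_cols:
            raise IndexError(f"column {col} out of range [0,{self.n_cols})")
        return c2r[col]

    def residue_to_column(self, row_id: str, pos: int) -> int:
        """Alignment column holding residue ``pos`` of a row."""
        _, r2c = self._maps(row_id)
        if not 0 <= pos < len(r2c):
            raise IndexError(f"residue {pos} out of range [0,{len(r2c)})")
        return r2c[pos]

    def column(self, col: int) -> str:
        return "".join(gapped[col] for _, gapped in self._rows)

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [c for c in range(self.n_cols) if set(self.column(c)) != {GAP}]
        return Alignment(
            [(rid, "".join(g[c] for c in keep)) for rid, g in self._rows]
        )


# ---------------------------------------------------------------------------
# Distances and guide tree


def kmer_distance(a: NucSequence, b: NucSequence, k: int = 4) -> float:
    """1 - |shared distinct k-mers| / min(|kmers(a)|, |kmers(b)|), in [0,1]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(a) or k > len(b):
        raise ValueError(
            f"k={k} exceeds a sequence length ({len(a)}, {len(b)})"
        )
    ka = {a.residues[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b.residues[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted ultrametric guide tree."""

    height: float
    leaf: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.leaf is not None:
            return (self.leaf,)
        return tuple(itertools.chain.from_iterable(c.leaves for c in self.children))

    def newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.leaf is not None:
                return f"{node.leaf}:{blen:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{blen:g}"

        if self.leaf is not None:
            return f"{self.leaf};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves


def build_guide_tree(ids: Sequence[str], dist: np.ndarray) -> GuideTree:
    """UPGMA tree from a symmetric distance matrix.

    Ties are broken by the lexicographically smallest (sorted-leaf-tuple)
    pair, so the tree is deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if dist.shape != (n, n):
        raise ValueError(f"distance matrix shape {dist.shape} != ({n},{n})")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix diagonal is not zero")
    if len(set(ids)) != n:
        raise ValueError("duplicate ids")

    clusters: dict[tuple[str, ...], TreeNode] = {
        (i,): TreeNode(height=0.0, leaf=i) for i in ids
    }
    sizes: dict[tuple[str, ...], int] = {(i,): 1 for i in ids}
    d: dict[frozenset[tuple[str, ...]], float] = {}
    keys = list(clusters)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((keys[i], keys[j]))] = dist[i, j]

    while len(clusters) > 1:
        best = min(
            (
                (d[frozenset((a, b))], tuple(sorted((a, b))))
                for a, b in itertools.combinations(clusters, 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (ka, kb) = best
        node = TreeNode(
            height=dmin / 2.0,
            children=(clusters[ka], clusters[kb]),
        )
        merged = tuple(sorted(ka + kb))
        na, nb = sizes[ka], sizes[kb]
        for other in list(clusters):
            if other in (ka, kb):
                continue
            dm = (
                na * d[frozenset((ka, other))] + nb * d[frozenset((kb, other))]
            ) / (na + nb)
            d[frozenset((merged, other))] = dm
        for key in (ka, kb):
            del clusters[key], sizes[key]
        clusters[merged] = node
        sizes[merged] = na + nb

    return GuideTree(root=next(iter(clusters.values())))


# ---------------------------------------------------------------------------
# Pairwise and profile alignment (three-state Gotoh)

_NEG = float("-inf")


def _gotoh(
    n: int,
    m: int,
    sub_score,
    params: AlignParams,
) -> list[tuple[bool, bool]]:
    """Generic affine-gap global DP over index pairs.

    ``sub_score(i, j)`` scores pairing element i of the first series with
    element j of the second (0-based). Returns the traceback as a list of
    (consume_a, consume_b) steps; ties prefer diagonal > vertical (consume a)
    > horizontal (consume b).
    """
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b: consumes a
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a: consumes b
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        srow = [sub_score(i - 1, j - 1) for j in range(1, m + 1)]
        for j in range(1, m + 1):
            M[i, j] = srow[j - 1] + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)

    # Traceback; state priority M > X > Y on exact ties.
    i, j = n, m
    finals = [(M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")]
    best = max(v for v, _ in finals)
    state = next(s for v, s in finals if v == best)
    steps: list[tuple[bool, bool]] = []
    while i > 0 or j > 0:
        if state == "M":
            steps.append((True, True))
            prev = [(M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"), (Y[i - 1, j - 1], "Y")]
            top = max(v for v, _ in prev)
            state = next(s for v, s in prev if v == top)
            i, j = i - 1, j - 1
        elif state == "X":
            steps.append((True, False))
            prev = [(M[i - 1, j] + go, "M"), (X[i - 1, j] + ge, "X"), (Y[i - 1, j] + go, "Y")]
            top = max(v for v, _ in prev)
            state = next(s for v, s in prev if v == top)
            i -= 1
        else:
            steps.append((False, True))
            prev = [(M[i, j - 1] + go, "M"), (X[i, j - 1] + go, "X"), (Y[i, j - 1] + ge, "Y")]
            top = max(v for v, _ in prev)
            state = next(s for v, s in prev if v == top)
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    steps.reverse()
    return steps, best


def pairwise_align_affine(
    a: str | NucSequence,
    b: str | NucSequence,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps (Needleman-Wunsch/Gotoh).

    Returns (gapped a, gapped b, score). Traceback tie-breaking prefers
    diagonal over vertical over horizontal, so output is deterministic.
    """
    sa = a.residues if isinstance(a, NucSequence) else a.upper()
    sb = b.residues if isinstance(b, NucSequence) else b.upper()
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    steps, score = _gotoh(
        len(sa), len(sb), lambda i, j: params.score(sa[i], sb[j]), params
    )
    ga, gb = [], []
    i = j = 0
    for ca, cb in steps:
        ga.append(sa[i] if ca else GAP)
        gb.append(sb[j] if cb else GAP)
        i += ca
        j += cb
    return "".join(ga), "".join(gb), float(score)


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _profile_freqs(rows: list[str], params: AlignParams) -> np.ndarray:
    """Per-column base frequencies (A,C,G,T), normalised by row count so gap
    positions dilute the column."""
    n_rows = len(rows)
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, 4))
    for row in rows:
        for c, ch in enumerate(row):
            idx = _BASE_IDX.get(ch)
            if idx is not None:
                freqs[c, idx] += 1.0
    return freqs / n_rows


def _align_profiles(
    pa: list[tuple[str, str]],
    pb: list[tuple[str, str]],
    params: AlignParams,
) -> list[tuple[str, str]]:
    rows_a = [r for _, r in pa]
    rows_b = [r for _, r in pb]
    fa = _profile_freqs(rows_a, params)
    fb = _profile_freqs(rows_b, params)
    # Expected substitution score between two columns under the frequency
    # profiles; mismatch applies to all cross terms.
    smat = params.match * (fa @ fb.T) + params.mismatch * (
        fa.sum(axis=1)[:, None] * fb.sum(axis=1)[None, :] - fa @ fb.T
    )
    steps, _ = _gotoh(len(rows_a[0]), len(rows_b[0]), lambda i, j: smat[i, j], params)
    out: list[tuple[str, str]] = []
    for rid, row in pa:
        chars, i = [], 0
        for ca, _ in steps:
            chars.append(row[i] if ca else GAP)
            i += ca
        out.append((rid, "".join(chars)))
    for rid, row in pb:
        chars, j = [], 0
        for _, cb in steps:
            chars.append(row[j] if cb else GAP)
            j += cb
        out.append((rid, "".join(chars)))
    return out


def progressive_align(
    seqs: Sequence[NucSequence],
    params: AlignParams = DEFAULT_PARAMS,
) -> Alignment:
    """ClustalW-style progressive alignment.

    Deterministic for fixed parameters; ungapping any output row reproduces
    its input sequence exactly. Rows appear in input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {s.id: s for s in seqs}
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(seqs[i], seqs[j], params.k)
    tree = build_guide_tree(ids, dist)

    def merge(node: TreeNode) -> list[tuple[str, str]]:
        if node.leaf is not None:
            return [(node.leaf, by_id[node.leaf].residues)]
        profiles = [merge(c) for c in node.children]
        result = profiles[0]
        for prof in profiles[1:]:
            result = _align_profiles(result, prof, params)
        return result

    merged = dict(merge(tree.root))
    aln = Alignment([(i, merged[i]) for i in ids]).drop_all_gap_columns()
    return aln


# ---------------------------------------------------------------------------
# Alignment I/O

_DIALECTS = ("fasta", "clustal")


def read_alignment(path: str | Path, dialect: str = "fasta") -> Alignment:
    """Read an alignment in aligned-FASTA or CLUSTAL format."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "fasta":
        from Bio import SeqIO

        rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not rows:
            raise AlignmentError(f"no records in {path}")
        return Alignment(rows)
    from Bio import AlignIO

    try:
        msa = AlignIO.read(str(path), "clustal")
    except ValueError as exc:
        raise AlignmentError(f"cannot parse CLUSTAL file {path}: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq)) for rec in msa])


def write_alignment(alignment: Alignment, path: str | Path, dialect: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or CLUSTAL (blocks of 60)."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "fasta":
        with path.open("w") as fh:
            for rid, gapped in alignment.rows:
                fh.write(f">{rid}\n")
                for i in range(0, len(gapped), 60):
                    fh.write(gapped[i : i + 60] + "\n")
        return
    width = max(len(rid) for rid in alignment.row_ids) + 3
    with path.open("w") as fh:
        fh.write("CLUSTAL W multiple sequence alignment\n\n")
        for start in range(0, alignment.n_cols, 60):
            for rid, gapped in alignment.rows:
                fh.write(f"{rid:<{width}}{gapped[start : start + 60]}\n")
            fh.write("\n")
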