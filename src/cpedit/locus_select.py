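"""Parsimony-informative characters, PIC/length gene ranking, supermatrix
concatenation/export, and a neighbor-joining smoke-test tree.

A column is parsimony-informative (PIC) when at least two states each occur
in at least two taxa; gaps and N are treated as missing, not as a fifth
state. Genes whose PIC/aligned-length ratio exceeds a threshold (0.3 by
default, strict inequality) are selected as phylogenetically useful loci.
Tree inference proper (ML/Bayesian) is deliberately external: the module
exports FASTA/PHYLIP/NEXUS supermatrices with partition files for those
tools, and offers only a deterministic NJ tree on p-distances as a sanity
check.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, InputError

MISSING = set("-N?")


@dataclass
class AlignmentMatrix:
    """Aligned characters for a set of taxa, with per-gene partitions.

    ``partitions`` is a list of (gene_id, start, end), 1-based inclusive,
    tiling the alignment length exactly.
    """

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon names")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise FormatError("ragged alignment rows")
            expect = 1
            for gid, start, end in self.partitions:
                if start != expect or end < start:
                    raise FormatError(f"partition {gid} does not tile the alignment")
                expect = end + 1
            if self.partitions and expect != L + 1:
                raise FormatError("partitions do not cover the alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """0-based column as a string over taxa."""
        return "".join(r[j] for r in self.rows)

    @classmethod
    def single_gene(cls, gene_id: str, taxa: Sequence[str], rows: Sequence[str]) -> "AlignmentMatrix":
        rows = [r.upper() for r in rows]
        L = len(rows[0]) if rows else 0
        return cls(list(taxa), list(rows), [(gene_id, 1, L)] if L else [])


def is_parsimony_informative(column: str | Sequence[str]) -> bool:
    """True iff >=2 distinct states each occur in >=2 taxa (gaps/N missing)."""
    if len(column) == 0:
        raise InputError("empty column")
    counts = Counter(c.upper() for c in column if c.upper() not in MISSING)
    return sum(1 for v in counts.values() if v >= 2) >= 2


def count_pic(alignment: AlignmentMatrix) -> int:
    return sum(
        1 for j in range(alignment.length) if is_parsimony_informative(alignment.column(j))
    )


@dataclass(frozen=True)
class GenePicScore:
    gene_id: str
    aligned_length: int
    pic_count: int

    @property
    def pic_ratio(self) -> float:
        return self.pic_count / self.aligned_length if self.aligned_length else 0.0


def rank_genes_by_pic(
    alignments: Mapping[str, AlignmentMatrix],
    threshold: float = 0.3,
    *,
    inclusive: bool = False,
) -> tuple[list[GenePicScore], set[str]]:
    """Score each gene alignment and select those above the PIC/length cutoff.

    Strict ``ratio > threshold`` by default; ``inclusive`` switches to >=.
    Scores are sorted by descending ratio, ties broken by gene name.
    """
    scores = [
        GenePicScore(gid, aln.length, count_pic(aln))
        for gid, aln in alignments.items()
    ]
    scores.sort(key=lambda s: (-s.pic_ratio, s.gene_id))
    if inclusive:
        selected = {s.gene_id for s in scores if s.pic_ratio >= threshold}
    else:
        selected = {s.gene_id for s in scores if s.pic_ratio > threshold}
    return scores, selected


def concatenate(
    alignments: Mapping[str, AlignmentMatrix],
    order: Sequence[str] | None = None,
) -> AlignmentMatrix:
    """Concatenate per-gene alignments into a supermatrix.

    Taxa are the union over genes in first-seen order; a taxon missing from
    a gene is filled with '-' across that partition.
    """
    if order is None:
        order = list(alignments)
    taxa: list[str] = []
    for gid in order:
        for t in alignments[gid].taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for gid in order:
        aln = alignments[gid]
        L = aln.length
        by_taxon = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            rows[t].append(by_taxon.get(t, "-" * L))
        partitions.append((gid, pos, pos + L - 1))
        pos += L
    return AlignmentMatrix(taxa, ["".join(rows[t]) for t in taxa], partitions)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_supermatrix_fasta(aln: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def write_phylip(aln: AlignmentMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: full names, space-separated."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.taxa)} {aln.length}\n")
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f"{t}  {r}\n")


def write_nexus(aln: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(aln.taxa)} nchar={aln.length};\n")
        fh.write("  format datatype=dna missing=N gap=-;\n  matrix\n")
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f"    {t}  {r}\n")
        fh.write("  ;\nend;\n")
        if aln.partitions:
            fh.write("begin sets;\n")
            for gid, start, end in aln.partitions:
                fh.write(f"  charset {gid} = {start}-{end};\n")
            fh.write("end;\n")


def write_raxml_partitions(aln: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, start, end in aln.partitions:
            fh.write(f"DNA, {gid} = {start}-{end}\n")


# ---------------------------------------------------------------------------
# neighbor joining (smoke test; real inference is exported to ML/Bayes tools)
# ---------------------------------------------------------------------------


def p_distance_matrix(aln: AlignmentMatrix) -> np.ndarray:
    """Uncorrected p-distances; columns with missing data in a pair are
    skipped for that pair. Identical (or incomparable) pairs get 0."""
    n = len(aln.taxa)
    arr = np.array([list(r) for r in aln.rows])
    ok = ~np.isin(arr, list(MISSING))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            total = int(both.sum())
            if total:
                d[i, j] = d[j, i] = float(np.sum(arr[i][both] != arr[j][both])) / total
    return d


def nj_tree(aln: AlignmentMatrix) -> str:
    """Neighbor-joining tree (newick, unrooted) on p-distances.

    Deterministic: among minimal-Q pairs the lowest (i, j) index pair is
    joined. Negative branch lengths are clamped to 0.
    """
    n = len(aln.taxa)
    if n < 3:
        raise InputError("nj_tree needs at least 3 taxa")
    d = p_distance_matrix(aln)
    nodes = list(aln.taxa)  # newick fragments
    active = list(range(n))
    D = d.copy()

    while len(active) > 2:
        r = len(active)
        totals = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = len(nodes)
        nodes.append(f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})")
        # grow matrices
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = max(0.5 * (D[i, k] + D[j, k] - dij), 0.0)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    half = max(D[i, j], 0.0) / 2.0
    return f"({nodes[i]}:{half:.6f},{nodes[j]}:{half:.6f});"
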