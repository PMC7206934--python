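"""Sequence primitives: records, genetic code, translation, CDS extraction,
and global pairwise alignment.

Transcripts are held in DNA alphabet (T, not U); reporting layers render
C->T mismatches as "C-to-U". Coordinates are 1-based on the coding strand:
``codon_index = ceil(pos/3)`` and ``codon_pos = ((pos-1) % 3) + 1``, which is
the convention behind site labels such as ``ndhB_50SL``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError, InputError, LookupError_

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# records and the genetic code
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One CDS, strand-normalized to coding orientation.

    Parameters
    ----------
    gene_id
        Short gene name, e.g. ``"ndhB"``. Must be non-empty.
    seq
        DNA over ``{A, C, G, T, N}`` in coding orientation, length >= 3.
    source_accession
        Free-text provenance (e.g. a GenBank accession).
    frame_offset
        Number of leading bases before the first complete codon (>= 0).
    """

    gene_id: str
    seq: str
    source_accession: str = ""
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if len(self.seq) < 3:
            raise InputError(f"{self.gene_id}: sequence shorter than one codon")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise InputError(f"{self.gene_id}: illegal characters {sorted(bad)}")
        if self.frame_offset < 0:
            raise InputError("frame_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)

    def codon(self, codon_index: int) -> str:
        """1-based codon by index (relative to frame_offset)."""
        start = self.frame_offset + 3 * (codon_index - 1)
        if start < 0 or start + 3 > len(self.seq):
            raise InputError(f"codon {codon_index} out of range for {self.gene_id}")
        return self.seq[start : start + 3]


def codon_index_of(cds_pos: int) -> int:
    """1-based codon index for a 1-based CDS position."""
    return math.ceil(cds_pos / 3)


def codon_pos_of(cds_pos: int) -> int:
    """Position within the codon (1, 2 or 3) for a 1-based CDS position."""
    return (cds_pos - 1) % 3 + 1


@dataclass(frozen=True)
class CodonTable:
    """64-entry codon -> one-letter amino acid map; stops are ``"*"``."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise InputError(f"codon table has {len(self.mapping)} entries, need 64")

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon]

    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.mapping.items() if aa != "*")

    def stop_codons(self) -> list[str]:
        return sorted(c for c, aa in self.mapping.items() if aa == "*")


def default_codon_table() -> CodonTable:
    """The bacterial/plastid genetic code (NCBI translation table 11)."""
    t = _BioCodonTable.unambiguous_dna_by_id[11]
    mapping = dict(t.forward_table)
    for stop in t.stop_codons:
        mapping[stop] = "*"
    return CodonTable(mapping)


def translate(
    cds: str,
    table: CodonTable | None = None,
    *,
    allow_partial: bool = False,
) -> str:
    """Translate a CDS codon-by-codon.

    Internal stops are kept in the output as ``"*"`` rather than truncating.
    Codons containing a base outside ``{A,C,G,T}`` translate as ``"X"``.
    A trailing partial codon is an error unless ``allow_partial`` is set, in
    which case it is dropped.
    """
    if table is None:
        table = default_codon_table()
    if len(cds) % 3 != 0 and not allow_partial:
        raise InputError(
            f"CDS length {len(cds)} not divisible by 3 (pass allow_partial to drop the tail)"
        )
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        out.append(table.mapping.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GeneRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GeneRecord(gene_id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.gene_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def extract_cds(genbank_record: SeqRecord, gene_id: str) -> GeneRecord:
    """Pull one CDS feature out of an annotated (GenBank) record.

    Exons are concatenated in transcript order and minus-strand features
    reverse-complemented; ``codon_start`` becomes ``frame_offset``.
    """
    available = []
    for feat in genbank_record.features:
        if feat.type != "CDS":
            continue
        names = feat.qualifiers.get("gene", []) + feat.qualifiers.get("locus_tag", [])
        available.extend(names)
        if gene_id not in names:
            continue
        strands = {p.strand for p in feat.location.parts}
        if len(strands) > 1:
            raise FormatError(f"{gene_id}: compound CDS mixes strands {strands}")
        seq = str(feat.extract(genbank_record.seq)).upper()
        codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
        return GeneRecord(
            gene_id=gene_id,
            seq=seq,
            source_accession=genbank_record.id,
            frame_offset=codon_start - 1,
        )
    raise LookupError_(
        f"no CDS feature for {gene_id!r}; available: {sorted(set(available))}"
    )


# ---------------------------------------------------------------------------
# global pairwise alignment (Gotoh, affine gaps)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignParams:
    """Scoring for global alignment.

    A gap run of length ``g`` scores ``gap_open + (g - 1) * gap_extend``
    (the opening base pays ``gap_open``). Defaults suit near-identical
    transcript/CDS pairs, where any sane scheme recovers the same mismatch
    set.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of ``alt`` against ``ref``.

    ``coordinate_map[i]`` is the 0-based alignment column holding 1-based
    reference position ``i + 1``; it is strictly increasing.
    """

    ref_aln: str
    alt_aln: str
    score: float
    coordinate_map: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.alt_aln):
            raise ConsistencyError("aligned strings differ in length")

    @property
    def ref(self) -> str:
        return self.ref_aln.replace("-", "")

    @property
    def alt(self) -> str:
        return self.alt_aln.replace("-", "")

    def columns(self) -> Iterator[tuple[int, str, str]]:
        """Yield (alignment column, ref char, alt char)."""
        for k, (r, a) in enumerate(zip(self.ref_aln, self.alt_aln)):
            yield k, r, a


_NEG = -1e30
# traceback state codes, in tie-break preference order
_M, _UP, _LEFT = 0, 1, 2


def align_pair(ref: str, alt: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch/Gotoh) alignment with affine gaps.

    Deterministic: ties in the traceback prefer diagonal (substitution)
    over up (gap in ``alt``) over left (gap in ``ref``). Row-wise numpy
    recurrences keep long near-identical pairs fast; the horizontal-gap
    state is closed over each row with a running maximum.
    """
    if params is None:
        params = AlignParams()
    if not ref or not alt:
        raise InputError("align_pair requires two non-empty sequences")

    n, m = len(ref), len(alt)
    go, ge = params.gap_open, params.gap_extend
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    alt_arr = np.frombuffer(alt.encode(), dtype="S1")

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in alt (vertical / "up")
    Y = np.full((n + 1, m + 1), _NEG)  # gap in ref (horizontal / "left")
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = go + (j - 1) * ge
    i_idx = np.arange(1, n + 1)
    X[1:, 0] = go + (i_idx - 1) * ge

    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(alt_arr == ref_arr[i - 1], params.match, params.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev_best + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go, X[i - 1, 1:] + ge
        )
        # Y[i, j] = max_{k<j} (max(M,X)[i, k] + go + ge*(j-1-k)); running max.
        row_best = np.maximum(M[i], X[i])
        acc = np.maximum.accumulate(row_best - ge * jj)
        Y[i, 1:] = go + ge * (jj[1:] - 1) + acc[:-1]

    # traceback
    eps = 1e-9
    i, jcol = n, m
    scores = (M[n, m], X[n, m], Y[n, m])
    best = max(scores)
    state = min(s for s in (_M, _UP, _LEFT) if scores[s] >= best - eps)

    ref_out: list[str] = []
    alt_out: list[str] = []
    while i > 0 or jcol > 0:
        if state == _M:
            ref_out.append(ref[i - 1])
            alt_out.append(alt[jcol - 1])
            prev = (M[i - 1, jcol - 1], X[i - 1, jcol - 1], Y[i - 1, jcol - 1])
            target = max(prev)
            state = min(s for s in (_M, _UP, _LEFT) if prev[s] >= target - eps)
            i -= 1
            jcol -= 1
        elif state == _UP:
            ref_out.append(ref[i - 1])
            alt_out.append("-")
            # opened here (from M or Y) or extended from X above
            opened = max(M[i - 1, jcol], Y[i - 1, jcol]) + go
            extended = X[i - 1, jcol] + ge
            if i == 1 and jcol == 0:
                state = _M
            elif opened >= extended - eps:
                prev = (M[i - 1, jcol], _NEG, Y[i - 1, jcol])
                target = max(prev)
                state = min(s for s in (_M, _LEFT) if prev[s] >= target - eps)
            else:
                state = _UP
            i -= 1
        else:  # _LEFT
            ref_out.append("-")
            alt_out.append(alt[jcol - 1])
            opened = max(M[i, jcol - 1], X[i, jcol - 1]) + go
            extended = Y[i, jcol - 1] + ge
            if jcol == 1 and i == 0:
                state = _M
            elif opened >= extended - eps:
                prev = (M[i, jcol - 1], X[i, jcol - 1])
                target = max(prev)
                state = _M if prev[0] >= target - eps else _UP
            else:
                state = _LEFT
            jcol -= 1

    ref_aln = "".join(reversed(ref_out))
    alt_aln = "".join(reversed(alt_out))
    coord_map = tuple(k for k, c in enumerate(ref_aln) if c != "-")
    return PairwiseAlignment(
        ref_aln=ref_aln, alt_aln=alt_aln, score=float(best), coordinate_map=coord_map
    )
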