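"""Editing-site calling from a transcript/CDS alignment.

A site is one aligned substitution column: genomic base vs transcript base.
In seed-plant plastids nearly all editing is C-to-U, observed here as a
C (genome) vs T (cDNA) mismatch; T-vs-C mismatches are typed "U-to-C" and
anything else "other" (flagged as possible sequencing error rather than
silently dropped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .errors import ConsistencyError, InputError
from .seqcore import GeneRecord, PairwiseAlignment, codon_index_of, codon_pos_of


@dataclass(frozen=True)
class EditingSite:
    """One editing event on a gene, in 1-based CDS coordinates."""

    gene_id: str
    cds_pos: int
    codon_index: int
    codon_pos: int
    ref_base: str
    alt_base: str
    edit_type: str  # "C-to-U" | "U-to-C" | "other"
    site_name: str = ""
    frame_disrupted: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise InputError("ref_base and alt_base must differ")
        if self.codon_index != codon_index_of(self.cds_pos) or self.codon_pos != codon_pos_of(
            self.cds_pos
        ):
            raise InputError(
                f"codon coordinates inconsistent with cds_pos={self.cds_pos}"
            )
        expected = classify_edit_type(self.ref_base, self.alt_base)
        if self.edit_type != expected:
            raise InputError(f"edit_type {self.edit_type!r} should be {expected!r}")


def classify_edit_type(ref_base: str, alt_base: str) -> str:
    if ref_base == "C" and alt_base == "T":
        return "C-to-U"
    if ref_base == "T" and alt_base == "C":
        return "U-to-C"
    return "other"


def detect_edits(aln: PairwiseAlignment, gene: GeneRecord) -> list[EditingSite]:
    """Call editing sites from a transcript-vs-gene alignment.

    The alignment's ungapped reference must equal ``gene.seq``. Substitution
    columns become sites; indel columns never do, but a site whose codon
    contains an indel column elsewhere is flagged ``frame_disrupted``.
    N on either strand never calls an edit.
    """
    if aln.ref != gene.seq:
        raise ConsistencyError(
            f"alignment reference does not match {gene.gene_id} sequence"
        )
    # codons touched by an indel column: a deleted ref base belongs to its
    # own codon; an inserted transcript base falls between ref positions and
    # is charged to the following codon
    disrupted_codons: set[int] = set()
    ref_pos = 0
    for _, r, a in aln.columns():
        if r != "-":
            ref_pos += 1
            if a == "-":
                disrupted_codons.add(codon_index_of(ref_pos))
        else:
            disrupted_codons.add(codon_index_of(min(ref_pos + 1, len(gene.seq))))

    sites: list[EditingSite] = []
    ref_pos = 0
    for _, r, a in aln.columns():
        if r != "-":
            ref_pos += 1
        if r == "-" or a == "-" or r == a or r == "N" or a == "N":
            continue
        ci = codon_index_of(ref_pos)
        sites.append(
            EditingSite(
                gene_id=gene.gene_id,
                cds_pos=ref_pos,
                codon_index=ci,
                codon_pos=codon_pos_of(ref_pos),
                ref_base=r,
                alt_base=a,
                edit_type=classify_edit_type(r, a),
                frame_disrupted=ci in disrupted_codons,
            )
        )
    sites.sort(key=lambda s: s.cds_pos)
    return sites


# ---------------------------------------------------------------------------
# site naming
# ---------------------------------------------------------------------------


def name_site(site: EditingSite, ref_aa: str, edited_aa: str) -> str:
    """Canonical label ``<gene>_<codonIndex><refAA><altAA>``, e.g. ndhB_50SL.

    Silent edits repeat the amino acid; stop gain uses ``*``.
    """
    return f"{site.gene_id}_{site.codon_index}{ref_aa}{edited_aa}"


_NAME_IDX_FIRST = re.compile(
    r"^(?P<gene>[A-Za-z][A-Za-z0-9.]*?)[_-](?P<idx>\d+)(?P<ref>[A-Z*])(?P<alt>[A-Z*])$"
)
_NAME_AA_FIRST = re.compile(
    r"^(?P<gene>[A-Za-z][A-Za-z0-9.]*?)[_-](?P<ref>[A-Z*])(?P<idx>\d+)(?P<alt>[A-Z*])$"
)
_NAME_NO_SEP = re.compile(
    r"^(?P<gene>[A-Za-z][A-Za-z0-9.]*[A-Za-z])(?P<idx>\d+)(?P<ref>[A-Z*])(?P<alt>[A-Z*])$"
)


def parse_site_name(label: str) -> tuple[str, int, str, str]:
    """Parse a site label into (gene, codon_index, ref_aa, alt_aa).

    Accepts both field orders seen in the literature (``ndhB_50SL`` and
    ``ndhA_S159L``), hyphen or underscore separators, and the
    separator-free form (``matK426HY``).
    """
    for pat in (_NAME_IDX_FIRST, _NAME_AA_FIRST, _NAME_NO_SEP):
        m = pat.match(label)
        if m:
            return (m["gene"], int(m["idx"]), m["ref"], m["alt"])
    raise InputError(f"unparseable site name: {label!r}")


# ---------------------------------------------------------------------------
# codon-position summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionSummary:
    """Counts (and half-up percentages) of sites at codon positions 1/2/3."""

    n1: int
    n2: int
    n3: int

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def percentages(self) -> tuple[float, float, float] | None:
        """Half-up 2-decimal percentages, or None for an empty summary."""
        if self.total == 0:
            return None
        return tuple(round_half_up(100.0 * n / self.total) for n in (self.n1, self.n2, self.n3))


def codon_position_summary(sites: Iterable[EditingSite]) -> PositionSummary:
    counts = {1: 0, 2: 0, 3: 0}
    for s in sites:
        counts[s.codon_pos] += 1
    return PositionSummary(counts[1], counts[2], counts[3])


# ---------------------------------------------------------------------------
# site table I/O
# ---------------------------------------------------------------------------

SITE_COLUMNS = [
    "gene_id",
    "cds_pos",
    "codon_index",
    "codon_pos",
    "ref_base",
    "alt_base",
    "edit_type",
    "site_name",
    "frame_disrupted",
]


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(s, c) for c in SITE_COLUMNS} for s in sites], columns=SITE_COLUMNS
    )


def write_sites_tsv(sites: Sequence[EditingSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "site_name": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EditingSite(
                gene_id=row.gene_id,
                cds_pos=int(row.cds_pos),
                codon_index=int(row.codon_index),
                codon_pos=int(row.codon_pos),
                ref_base=row.ref_base,
                alt_base=row.alt_base,
                edit_type=row.edit_type,
                site_name="" if pd.isna(row.site_name) else str(row.site_name),
                frame_disrupted=bool(row.frame_disrupted),
            )
        )
    return out
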