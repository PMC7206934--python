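"""Codon-level consequences of editing and amino-acid property changes.

Amino acids are grouped into three hydropathy classes. The default scheme —
hydrophobic {A,V,L,I,M,F,W}, hydrophilic {R,K,D,E,N,Q,H,P}, neutral
{G,S,T,C,Y} — is a package choice (config-overridable): it pins the three
anchors the analysis relies on (S neutral, P hydrophilic, L hydrophobic),
which is what the headline "neutral/hydrophilic to hydrophobic" tallies
need; the remaining assignments follow common hydropathy groupings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .editing import EditingSite, name_site
from .errors import InputError
from .seqcore import CodonTable, GeneRecord, default_codon_table

HYDROPHOBIC = "hydrophobic"
HYDROPHILIC = "hydrophilic"
NEUTRAL = "neutral"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PropertyScheme:
    """Total map of the 20 amino acids onto the three hydropathy classes."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(AA20) - set(self.mapping)
        if missing:
            raise InputError(f"property scheme missing amino acids: {sorted(missing)}")
        bad = set(self.mapping.values()) - {HYDROPHOBIC, HYDROPHILIC, NEUTRAL}
        if bad:
            raise InputError(f"unknown property classes: {sorted(bad)}")

    def __getitem__(self, aa: str) -> str:
        return self.mapping[aa]


def default_property_scheme() -> PropertyScheme:
    mapping: dict[str, str] = {}
    for aa in "AVLIMFW":
        mapping[aa] = HYDROPHOBIC
    for aa in "RKDENQHP":
        mapping[aa] = HYDROPHILIC
    for aa in "GSTCY":
        mapping[aa] = NEUTRAL
    return PropertyScheme(mapping)


@dataclass(frozen=True)
class Consequence:
    """Effect of one codon substitution.

    ``kind`` is one of silent / missense / stop_gain / start_gain /
    start_loss_candidate / stop_loss / stop_retained. ``truncation_aa`` is
    the number of residues lost to a premature stop (0 unless stop_gain
    with a known protein length).
    """

    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    kind: str
    ref_class: str | None
    alt_class: str | None
    truncation_aa: int = 0


def classify_codon_change(
    ref_codon: str,
    alt_codon: str,
    codon_index: int,
    scheme: PropertyScheme | None = None,
    table: CodonTable | None = None,
    *,
    protein_length: int | None = None,
) -> Consequence:
    """Classify a single codon substitution.

    ``codon_index`` is 1-based within the CDS; index 1 with ACG->ATG is a
    start gain (C-to-U editing creating the canonical AUG initiator), and
    index 1 losing ATG is flagged ``start_loss_candidate``. For a stop gain,
    ``protein_length`` (in residues, stop excluded) yields the number of
    C-terminal residues deleted.
    """
    if scheme is None:
        scheme = default_property_scheme()
    if table is None:
        table = default_codon_table()
    if ref_codon == alt_codon:
        raise InputError("codons must differ")
    ref_aa = table[ref_codon]
    alt_aa = table[alt_codon]

    if codon_index == 1 and ref_codon == "ACG" and alt_codon == "ATG":
        kind = "start_gain"
    elif codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        kind = "start_loss_candidate"
    elif alt_aa == "*" and ref_aa != "*":
        kind = "stop_gain"
    elif ref_aa == "*" and alt_aa != "*":
        kind = "stop_loss"
    elif ref_aa == "*" and alt_aa == "*":
        kind = "stop_retained"
    elif ref_aa == alt_aa:
        kind = "silent"
    else:
        kind = "missense"

    trunc = 0
    if kind == "stop_gain" and protein_length is not None:
        trunc = truncation_length(codon_index, protein_length)

    return Consequence(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        kind=kind,
        ref_class=scheme[ref_aa] if ref_aa in scheme.mapping else None,
        alt_class=scheme[alt_aa] if alt_aa in scheme.mapping else None,
        truncation_aa=trunc,
    )


def truncation_length(stop_codon_index: int, protein_length: int) -> int:
    """Residues lost to a premature stop, counting the codon that became one.

    A stop at codon 93 of a 100-residue protein deletes 8 residues.
    """
    if not 1 <= stop_codon_index <= protein_length:
        raise InputError(
            f"stop codon index {stop_codon_index} outside 1..{protein_length}"
        )
    return protein_length - stop_codon_index + 1


@dataclass(frozen=True)
class ConsequenceSummary:
    """Kind tallies plus the missense class-transition matrix."""

    kind_counts: Mapping[str, int]
    class_transitions: Mapping[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.kind_counts.values())


def consequence_summary(consequences: Iterable[Consequence]) -> ConsequenceSummary:
    kinds: Counter[str] = Counter()
    transitions: Counter[tuple[str, str]] = Counter()
    for c in consequences:
        kinds[c.kind] += 1
        if c.kind == "missense" and c.ref_class and c.alt_class:
            transitions[(c.ref_class, c.alt_class)] += 1
    return ConsequenceSummary(dict(kinds), dict(transitions))


# ---------------------------------------------------------------------------
# site annotation
# ---------------------------------------------------------------------------


def annotate_sites(
    sites: Sequence[EditingSite],
    genes: Mapping[str, GeneRecord],
    scheme: PropertyScheme | None = None,
    table: CodonTable | None = None,
) -> list[tuple[EditingSite, Consequence]]:
    """Attach a Consequence and canonical site name to each detected site.

    Each site is classified on its own: the genomic codon with only that
    site's substitution applied.
    """
    from dataclasses import replace

    if table is None:
        table = default_codon_table()
    out = []
    for s in sites:
        gene = genes[s.gene_id]
        ref_codon = gene.codon(s.codon_index)
        alt_codon = (
            ref_codon[: s.codon_pos - 1] + s.alt_base + ref_codon[s.codon_pos :]
        )
        protein_length = (len(gene.seq) - gene.frame_offset) // 3
        cons = classify_codon_change(
            ref_codon,
            alt_codon,
            s.codon_index,
            scheme,
            table,
            protein_length=protein_length,
        )
        named = replace(s, site_name=name_site(s, cons.ref_aa, cons.alt_aa))
        out.append((named, cons))
    return out


def genes_lacking_start_edit(
    genes: Mapping[str, GeneRecord], sites: Sequence[EditingSite]
) -> list[str]:
    """Genes whose first codon is ACG with no observed edit in codon 1.

    Descriptive scan for "loss of ACG start-codon editing": an ACG
    initiator that editing would normally restore to AUG.
    """
    edited_first = {
        (s.gene_id, s.codon_index) for s in sites if s.codon_index == 1
    }
    out = []
    for gid, gene in genes.items():
        if gene.codon(1) == "ACG" and (gid, 1) not in edited_first:
            out.append(gid)
    return sorted(out)
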