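"""Synthetic data with the statistical structure of plastid C-to-U editing.

The generator emulates the study conditions the analysis assumes: random
chloroplast-gene-like CDSs (ATG start, sense-codon body, single terminal
stop), planted C->T edits whose codon-position distribution is skewed to
the second base (defaults 0.1521/0.8043/0.0436) with a 5'U / 3'A context
bias (defaults 0.6521 / 0.7391), and species-level site presence/absence
evolving by a two-state gain/loss Markov chain along a tree. Every planted
edit is recorded in a truth ledger so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .compare import SpeciesSiteMatrix
from .errors import FormatError, InfeasibleError, InputError
from .seqcore import (
    CodonTable,
    GeneRecord,
    codon_index_of,
    codon_pos_of,
    default_codon_table,
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study conditions.

    ``gene_length_range`` is in codons (inclusive), spanning the bulk of a
    chloroplast editing-gene panel (short subunits to ndhB/rpoC1-sized).
    ``codon_pos_probs`` and the context probabilities are the planted-edit
    sampling distribution; ``p_reverse_edit`` plants U-to-C (T->C) edits.
    """

    seed: int
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (100, 500)
    n_edits: int = 46
    codon_pos_probs: tuple[float, float, float] = (0.1521, 0.8043, 0.0436)
    p_context_5U: float = 0.6521
    p_context_3A: float = 0.7391
    p_reverse_edit: float = 0.0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InputError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo < 3 or hi < lo:
            raise InputError("gene_length_range must be >= 3 codons and ordered")
        probs = self.codon_pos_probs
        if abs(sum(probs) - 1.0) > 1e-6 or any(p < 0 for p in probs):
            raise InputError("codon_pos_probs must be a probability 3-vector")
        for p in (self.p_context_5U, self.p_context_3A, self.p_reverse_edit):
            if not 0.0 <= p <= 1.0:
                raise InputError("probabilities must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        raw["gene_length_range"] = tuple(raw["gene_length_range"])
        raw["codon_pos_probs"] = tuple(raw["codon_pos_probs"])
        return cls(**raw)


@dataclass(frozen=True)
class PlantedEdit:
    gene_id: str
    cds_pos: int
    ref_base: str
    alt_base: str
    codon_index: int
    codon_pos: int
    intended_kind: str  # silent | missense | stop_gain | start_gain | ...


@dataclass(frozen=True)
class SyntheticTruth:
    """The generator's ledger: ground truth for recovery tests."""

    edits: tuple[PlantedEdit, ...]
    config: SimConfig

    def keys(self) -> set[tuple[str, int]]:
        return {(e.gene_id, e.cds_pos) for e in self.edits}

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(e) for e in self.edits]).to_csv(
            path, sep="\t", index=False
        )


def simulate_genes(config: SimConfig, table: CodonTable | None = None) -> list[GeneRecord]:
    """Random CDSs: ATG start, uniform sense-codon body, one terminal stop."""
    if table is None:
        table = default_codon_table()
    rng = np.random.default_rng(config.seed)
    sense = [c for c in table.sense_codons() if c != "ATG"] + ["ATG"]
    sense = sorted(sense)
    stops = table.stop_codons()
    genes = []
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(sense, size=n_codons - 2)
        stop = stops[int(rng.integers(len(stops)))]
        seq = "ATG" + "".join(body) + stop
        genes.append(GeneRecord(gene_id=f"gene{i + 1:03d}", seq=seq, source_accession="synthetic"))
    return genes


def plant_edits(
    genes: Sequence[GeneRecord],
    config: SimConfig,
    table: CodonTable | None = None,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Plant edits into transcripts; return (transcripts, truth ledger).

    For each edit the codon position is drawn from ``codon_pos_probs`` and
    the 5'/3' context requirement from the context probabilities (a "no"
    draw requires a non-U / non-A neighbour, so the marginal context
    frequencies match the probabilities exactly). A candidate genomic C
    (T for reverse edits) satisfying the draw is then chosen uniformly;
    if no candidate exists the generator fails loudly rather than silently
    relaxing the constraint. The terminal stop codon and base 1 / last base
    are never edited, and positions are unique per gene.
    """
    if table is None:
        table = default_codon_table()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    seqs = {g.gene_id: list(g.seq) for g in genes}
    gene_by_id = {g.gene_id: g for g in genes}
    used: set[tuple[str, int]] = set()

    # candidate pools, indexed once by (base, codon_pos, has-5'U, has-3'A);
    # positions 1 and n and the terminal stop codon are never editable
    pools: dict[tuple[str, int, bool, bool], list[tuple[str, int]]] = {}
    for g in genes:
        s = g.seq
        n = len(s)
        for p in range(2, n - 3 + 1):  # 1-based, excludes terminal stop codon
            base = s[p - 1]
            if base not in "CT":
                continue
            key = (base, codon_pos_of(p), s[p - 2] == "T", s[p] == "A")
            pools.setdefault(key, []).append((g.gene_id, p))

    def draw(base: str, codon_pos: int, want5U: bool, want3A: bool):
        pool = pools.get((base, codon_pos, want5U, want3A))
        if not pool:
            return None
        # reject already-used positions; compact the pool when it gets stale
        for _ in range(min(20, config.max_attempts)):
            cand = pool[int(rng.integers(len(pool)))]
            if cand not in used:
                return cand
        fresh = [c for c in pool if c not in used]
        pools[(base, codon_pos, want5U, want3A)] = fresh
        if not fresh:
            return None
        return fresh[int(rng.integers(len(fresh)))]

    edits: list[PlantedEdit] = []
    for _ in range(config.n_edits):
        reverse = bool(rng.random() < config.p_reverse_edit)
        ref, alt = ("T", "C") if reverse else ("C", "T")
        codon_pos = int(rng.choice(3, p=config.codon_pos_probs)) + 1
        want5U = bool(rng.random() < config.p_context_5U)
        want3A = bool(rng.random() < config.p_context_3A)
        cand = draw(ref, codon_pos, want5U, want3A)
        if cand is None:
            # relaxing the constraint here would silently skew the planted
            # codon-position/context marginals, so fail loudly instead
            raise InfeasibleError(
                f"no remaining {ref} position with codon_pos={codon_pos}, "
                f"5'U={want5U}, 3'A={want3A} for edit "
                f"{len(edits) + 1}/{config.n_edits}; use more/longer genes"
            )
        gid, pos = cand
        used.add((gid, pos))
        ci = codon_index_of(pos)
        gene = gene_by_id[gid]
        ref_codon = gene.codon(ci)
        cp = codon_pos_of(pos)
        alt_codon = ref_codon[: cp - 1] + alt + ref_codon[cp:]
        edits.append(
            PlantedEdit(
                gene_id=gid,
                cds_pos=pos,
                ref_base=ref,
                alt_base=alt,
                codon_index=ci,
                codon_pos=cp,
                intended_kind=_intended_kind(ref_codon, alt_codon, ci, table),
            )
        )

    for e in edits:
        seqs[e.gene_id][e.cds_pos - 1] = e.alt_base
    transcripts = [
        replace(g, seq="".join(seqs[g.gene_id])) for g in genes
    ]
    edits.sort(key=lambda e: (e.gene_id, e.cds_pos))
    return transcripts, SyntheticTruth(tuple(edits), config)


def _intended_kind(ref_codon: str, alt_codon: str, codon_index: int, table: CodonTable) -> str:
    # direct table lookups; mirrors the classifier's contract
    ref_aa, alt_aa = table[ref_codon], table[alt_codon]
    if codon_index == 1 and ref_codon == "ACG" and alt_codon == "ATG":
        return "start_gain"
    if codon_index == 1 and ref_codon == "ATG":
        return "start_loss_candidate"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    if ref_aa == "*" and alt_aa == "*":
        return "stop_retained"
    return "silent" if ref_aa == alt_aa else "missense"


# ---------------------------------------------------------------------------
# species-level presence/absence evolution
# ---------------------------------------------------------------------------


def simulate_species_sites(
    tree_newick: str,
    gain_rate: float,
    loss_rate: float,
    n_sites: int,
    seed: int,
    *,
    root_present_prob: float | None = None,
    clade_labels: dict[str, str] | None = None,
) -> SpeciesSiteMatrix:
    """Evolve site presence/absence along a tree as a 2-state Markov chain.

    Along a branch of length t the switch probability from a state is
    ``(r_away / (g + l)) * (1 - exp(-(g + l) t))`` with r_away the rate out
    of that state. Root states are Bernoulli(``root_present_prob``),
    defaulting to the stationary probability g/(g+l); with both rates 0 the
    root probability must be given explicitly.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise InputError("rates must be >= 0")
    total = gain_rate + loss_rate
    if root_present_prob is None:
        if total == 0:
            raise InputError("root_present_prob required when both rates are 0")
        root_present_prob = gain_rate / total
    try:
        tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    except Exception as exc:
        raise FormatError(f"malformed newick: {exc}") from exc

    rng = np.random.default_rng(seed)
    state: dict[int, np.ndarray] = {}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            s = rng.random(n_sites) < root_present_prob
        else:
            t = node.edge.length or 0.0
            parent = state[id(node.parent_node)]
            if total > 0 and t > 0:
                p_change_total = 1.0 - np.exp(-total * t)
                p01 = (gain_rate / total) * p_change_total  # absent -> present
                p10 = (loss_rate / total) * p_change_total  # present -> absent
            else:
                p01 = p10 = 0.0
            u = rng.random(n_sites)
            s = np.where(parent, u >= p10, u < p01)
        state[id(node)] = s
        if node.is_leaf():
            leaves.append((node.taxon.label, s))

    species = [name for name, _ in leaves]
    clades = clade_labels or {name: "sim" for name in species}
    presence = np.stack([s for _, s in leaves])
    site_names = [f"site{i + 1:04d}" for i in range(n_sites)]
    return SpeciesSiteMatrix(species=species, clades=clades, site_names=site_names, presence=presence)


def write_fixture_bundle(
    out_dir: str | Path,
    config: SimConfig,
    table: CodonTable | None = None,
) -> tuple[list[GeneRecord], list[GeneRecord], SyntheticTruth]:
    """Generate and write genes.fasta, transcripts.fasta, truth.tsv, config.json."""
    from .seqcore import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = simulate_genes(config, table)
    transcripts, truth = plant_edits(genes, config, table)
    write_fasta(genes, out / "genes.fasta")
    write_fasta(transcripts, out / "transcripts.fasta")
    truth.to_tsv(out / "truth.tsv")
    config.to_json(out / "config.json")
    return genes, transcripts, truth
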