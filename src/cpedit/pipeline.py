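"""End-to-end orchestration: align, detect, annotate, profile, summarize.

``run_pipeline`` is deterministic given its inputs and config; it writes a
site TSV plus a JSON report whose content (excluding the timestamp field)
is byte-stable across reruns. Percentages in the report are rendered
half-up to 2 decimals while exact fractions are kept alongside, so
rounding never infects stored data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from ._util import round_half_up
from .compare import compare_predictions, read_predicted_sites_tsv
from .consequence import (
    Consequence,
    annotate_sites,
    consequence_summary,
    default_property_scheme,
    genes_lacking_start_edit,
)
from .context import context_profile
from .editing import (
    EditingSite,
    codon_position_summary,
    detect_edits,
    write_sites_tsv,
)
from .errors import InputError
from .seqcore import AlignParams, align_pair, default_codon_table, read_fasta

log = logging.getLogger("cpedit")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline inputs and knobs (all semantic fields enter the config hash)."""

    genes_fasta: str
    transcripts_fasta: str
    predicted_sites_tsv: str | None = None
    out_dir: str = "cpedit_out"
    flank: int = 1
    align_params: AlignParams = field(default_factory=AlignParams)
    seed: int | None = None

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")  # where outputs land is not semantic
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated results of one pipeline run."""

    per_gene_counts: dict[str, int]
    n_sites: int
    n_genes_with_sites: int
    n_genes_analyzed: int
    edit_type_counts: dict[str, int]
    position_counts: dict[str, int]
    position_percentages: dict[str, float] | None
    context: dict
    consequences: dict
    acg_start_genes_without_edit: list[str]
    prediction: dict | None
    warnings: list[str]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict_report(self), indent=1, sort_keys=True)


def asdict_report(report: RunReport) -> dict:
    d = dict(report.__dict__)
    return d


def run_pipeline(config: RunConfig) -> RunReport:
    """Run detect -> annotate -> summarize and write artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = read_fasta(config.genes_fasta)
    transcripts = {r.gene_id: r for r in read_fasta(config.transcripts_fasta)}
    gene_map = {g.gene_id: g for g in genes}
    log.info("loaded %d genes, %d transcripts", len(genes), len(transcripts))

    warnings_: list[str] = []
    if not transcripts:
        warnings_.append("no transcripts supplied; report has zero sites")

    all_sites: list[EditingSite] = []
    all_cons: list[Consequence] = []
    scheme = default_property_scheme()
    table = default_codon_table()
    for gene in genes:
        tr = transcripts.get(gene.gene_id)
        if tr is None:
            warnings_.append(f"no transcript for {gene.gene_id}; skipped")
            continue
        aln = align_pair(gene.seq, tr.seq, config.align_params)
        sites = detect_edits(aln, gene)
        annotated = annotate_sites(sites, gene_map, scheme, table)
        all_sites.extend(s for s, _ in annotated)
        all_cons.extend(c for _, c in annotated)
        log.info("%s: %d sites", gene.gene_id, len(sites))

    write_sites_tsv(all_sites, out / "sites.tsv")

    pos = codon_position_summary(all_sites)
    ctx = context_profile(all_sites, gene_map, flank=config.flank)
    cons = consequence_summary(all_cons)

    per_gene: dict[str, int] = {}
    type_counts: dict[str, int] = {}
    for s in all_sites:
        per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + 1
        type_counts[s.edit_type] = type_counts.get(s.edit_type, 0) + 1
    if any(t != "C-to-U" for t in type_counts):
        non_ctu = {t: c for t, c in type_counts.items() if t != "C-to-U"}
        warnings_.append(
            f"non-C-to-U mismatches present (possible sequencing error): {non_ctu}"
        )

    prediction = None
    if config.predicted_sites_tsv:
        predicted = read_predicted_sites_tsv(config.predicted_sites_tsv)
        observed = {(s.gene_id, s.cds_pos) for s in all_sites}
        pc = compare_predictions(predicted, observed)
        prediction = asdict(pc)

    top = ctx.top_joint_context()
    report = RunReport(
        per_gene_counts=dict(sorted(per_gene.items())),
        n_sites=len(all_sites),
        n_genes_with_sites=len(per_gene),
        n_genes_analyzed=len(genes),
        edit_type_counts=dict(sorted(type_counts.items())),
        position_counts={"pos1": pos.n1, "pos2": pos.n2, "pos3": pos.n3},
        position_percentages=(
            None
            if pos.percentages is None
            else dict(zip(("pos1", "pos2", "pos3"), pos.percentages))
        ),
        context={
            "preceding_freq": dict(ctx.preceding_freq),
            "following_freq": dict(ctx.following_freq),
            "joint_freq": {f"{a}_{b}": v for (a, b), v in ctx.joint_freq.items()},
            "top_joint_context": None if top is None else list(top),
            "n_sites": ctx.n_sites,
            "n_excluded_boundary": ctx.n_excluded_boundary,
            "n_excluded_ambiguous": ctx.n_excluded_ambiguous,
        },
        consequences={
            "kind_counts": dict(sorted(cons.kind_counts.items())),
            "class_transitions": {
                f"{a}->{b}": v for (a, b), v in sorted(cons.class_transitions.items())
            },
        },
        acg_start_genes_without_edit=genes_lacking_start_edit(gene_map, all_sites),
        prediction=prediction,
        warnings=warnings_,
        provenance={
            "inputs": {
                "genes_fasta": str(config.genes_fasta),
                "transcripts_fasta": str(config.transcripts_fasta),
                "predicted_sites_tsv": config.predicted_sites_tsv,
            },
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )

    (out / "report.json").write_text(report.to_json())
    _write_summary(report, out / "summary.txt")
    return report


def _write_summary(report: RunReport, path: Path) -> None:
    lines = [
        f"cpedit v{__version__} run {report.provenance['config_hash']}",
        f"genes analyzed: {report.n_genes_analyzed}",
        f"editing sites: {report.n_sites} in {report.n_genes_with_sites} genes",
        f"edit types: {report.edit_type_counts}",
        f"codon positions (1/2/3): {report.position_counts['pos1']}/"
        f"{report.position_counts['pos2']}/{report.position_counts['pos3']}"
        + (
            f" = {tuple(report.position_percentages.values())} %"
            if report.position_percentages
            else ""
        ),
        f"consequence kinds: {report.consequences['kind_counts']}",
        f"class transitions (missense): {report.consequences['class_transitions']}",
        f"top 5'_3' context: {report.context['top_joint_context']}",
    ]
    if report.prediction:
        p = report.prediction
        lines.append(
            f"prediction: {p['n_correct']}/{p['n_predicted']} correct "
            f"(precision {p['precision_pct']}%, recall {p['recall_pct']}%)"
        )
    for w in report.warnings:
        lines.append(f"WARNING: {w}")
    path.write_text("\n".join(lines) + "\n")
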