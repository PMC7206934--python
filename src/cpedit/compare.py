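"""Cross-species shared-site matrices and predicted-vs-observed comparison.

Orthologous-site identity is by canonical label (gene, codon index, amino
acid change); mapping coordinates between species is the caller's job.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import FormatError, InputError, LookupError_


@dataclass
class SpeciesSiteMatrix:
    """Presence/absence of named orthologous editing sites across species."""

    species: list[str]
    clades: dict[str, str]
    site_names: list[str]
    presence: np.ndarray  # bool, shape (n_species, n_sites)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species), len(self.site_names)):
            raise FormatError("presence matrix shape does not match labels")
        if len(set(self.species)) != len(self.species):
            raise FormatError("duplicate species names")
        if len(set(self.site_names)) != len(self.site_names):
            raise FormatError("duplicate site names")
        missing = set(self.species) - set(self.clades)
        if missing:
            raise FormatError(f"species without clade label: {sorted(missing)}")

    def row(self, species: str) -> np.ndarray:
        try:
            return self.presence[self.species.index(species)]
        except ValueError:
            raise LookupError_(
                f"unknown species {species!r}; have {self.species}"
            ) from None

    # -- I/O: TSV matrix (species rows, 0/1) + clade sidecar JSON ----------

    def to_tsv(self, path: str | Path, clades_path: str | Path | None = None) -> None:
        df = pd.DataFrame(
            self.presence.astype(int), index=self.species, columns=self.site_names
        )
        df.index.name = "species"
        df.to_csv(path, sep="\t")
        if clades_path is not None:
            Path(clades_path).write_text(json.dumps(self.clades, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path, clades_path: str | Path) -> "SpeciesSiteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        clades = json.loads(Path(clades_path).read_text())
        return cls(
            species=[str(s) for s in df.index],
            clades=clades,
            site_names=[str(c) for c in df.columns],
            presence=df.to_numpy(dtype=bool),
        )


@dataclass(frozen=True)
class SharedCounts:
    """Focal-species sharing: per-clade counts plus species-unique sites."""

    focal: str
    n_focal_sites: int
    per_clade: Mapping[str, int]
    unique: int
    unique_sites: tuple[str, ...]


def shared_counts(
    matrix: SpeciesSiteMatrix,
    focal_species: str,
    clade_groups: Mapping[str, Iterable[str]] | None = None,
) -> SharedCounts:
    """Count focal-species sites shared with each clade and unique overall.

    A focal site is shared with a clade when >=1 member of that clade
    (excluding the focal species) also has it; unique when no other species
    has it. ``clade_groups`` optionally maps a reported clade name to the
    set of clade labels it covers — e.g. counting palms inside "monocots"
    (nested mode) versus keeping them separate.
    """
    focal_row = matrix.row(focal_species)
    if clade_groups is None:
        clade_groups = {c: {c} for c in sorted(set(matrix.clades.values()))}

    others = [s for s in matrix.species if s != focal_species]
    per_clade: dict[str, int] = {}
    for name, labels in clade_groups.items():
        labels = set(labels)
        members = [s for s in others if matrix.clades[s] in labels]
        if members:
            any_member = np.any(
                np.stack([matrix.row(s) for s in members]), axis=0
            )
            per_clade[name] = int(np.sum(focal_row & any_member))
        else:
            per_clade[name] = 0

    if others:
        any_other = np.any(np.stack([matrix.row(s) for s in others]), axis=0)
    else:
        any_other = np.zeros_like(focal_row)
    unique_mask = focal_row & ~any_other
    unique_sites = tuple(
        n for n, u in zip(matrix.site_names, unique_mask) if u
    )
    return SharedCounts(
        focal=focal_species,
        n_focal_sites=int(focal_row.sum()),
        per_clade=per_clade,
        unique=int(unique_mask.sum()),
        unique_sites=unique_sites,
    )


def shared_between(
    matrix: SpeciesSiteMatrix,
    focal_species: str,
    clade_a: Iterable[str] | str,
    clade_b: Iterable[str] | str,
) -> int:
    """Focal sites present in >=1 member of clade A AND >=1 of clade B."""
    focal_row = matrix.row(focal_species)
    result = focal_row.copy()
    for clade in (clade_a, clade_b):
        labels = {clade} if isinstance(clade, str) else set(clade)
        members = [
            s
            for s in matrix.species
            if s != focal_species and matrix.clades[s] in labels
        ]
        if not members:
            return 0
        result &= np.any(np.stack([matrix.row(s) for s in members]), axis=0)
    return int(result.sum())


@dataclass(frozen=True)
class PredictionComparison:
    """Predicted-vs-observed site sets, keyed by (gene, CDS position)."""

    n_predicted: int
    n_observed: int
    n_correct: int
    precision_pct: float | None
    recall_pct: float | None


SiteKey = tuple[str, int]


def compare_predictions(
    predicted: Iterable[SiteKey], observed: Iterable[SiteKey]
) -> PredictionComparison:
    """Intersect predicted and observed sites by (gene_id, cds_pos).

    Precision/recall are half-up percentages; an empty predicted (observed)
    set leaves precision (recall) undefined as None rather than 0.
    """
    pred = {_as_key(k) for k in predicted}
    obs = {_as_key(k) for k in observed}
    correct = len(pred & obs)
    return PredictionComparison(
        n_predicted=len(pred),
        n_observed=len(obs),
        n_correct=correct,
        precision_pct=round_half_up(100.0 * correct / len(pred)) if pred else None,
        recall_pct=round_half_up(100.0 * correct / len(obs)) if obs else None,
    )


def _as_key(k: SiteKey) -> SiteKey:
    try:
        gene, pos = k
        return (str(gene), int(pos))
    except (TypeError, ValueError) as exc:
        raise InputError(f"malformed site key: {k!r}") from exc


def read_predicted_sites_tsv(path: str | Path) -> set[SiteKey]:
    """Read a predicted-site list (columns gene_id, cds_pos) into keys."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "cds_pos" not in df.columns:
        raise FormatError(f"{path}: need columns gene_id and cds_pos")
    return {(str(g), int(p)) for g, p in zip(df["gene_id"], df["cds_pos"])}
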