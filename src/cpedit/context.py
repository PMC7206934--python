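"""Sequence context around editing sites.

Context is read from the genomic strand in coding orientation (pre-editing
state) and reported in RNA alphabet, so a 5'T neighbour is tallied as "U".
Sites too close to a CDS end for the requested flank are excluded from the
tallies and surfaced in ``n_excluded_boundary``; flanking N bases likewise
exclude a site (``n_excluded_ambiguous``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .editing import EditingSite
from .errors import ConsistencyError, InputError
from .seqcore import GeneRecord

RNA_OF = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass(frozen=True)
class ContextProfile:
    """Frequencies of the bases flanking editing sites.

    ``joint_freq`` is over ordered (5' base, 3' base) pairs; its marginals
    equal ``preceding_freq`` / ``following_freq`` exactly because all three
    are tallied over the same included sites.
    """

    preceding_freq: Mapping[str, float]
    following_freq: Mapping[str, float]
    joint_freq: Mapping[tuple[str, str], float]
    n_sites: int
    n_excluded_boundary: int
    n_excluded_ambiguous: int = 0

    def top_joint_context(self) -> tuple[str, float] | None:
        """Most frequent 5'_3' context, e.g. ("U_A", 0.52)."""
        if not self.joint_freq:
            return None
        (five, three), frac = max(
            self.joint_freq.items(), key=lambda kv: (kv[1], kv[0])
        )
        return f"{five}_{three}", frac


def context_profile(
    sites: Iterable[EditingSite],
    genes: Mapping[str, GeneRecord] | Sequence[GeneRecord],
    flank: int = 1,
) -> ContextProfile:
    """Tally the genomic base at distance ``flank`` on each side of each site."""
    if flank < 1:
        raise InputError("flank must be >= 1")
    gene_map = _as_map(genes)
    pre: Counter[str] = Counter()
    post: Counter[str] = Counter()
    joint: Counter[tuple[str, str]] = Counter()
    n = 0
    n_boundary = 0
    n_ambig = 0
    for s in sites:
        gene = gene_map.get(s.gene_id)
        if gene is None:
            raise ConsistencyError(f"site references unknown gene {s.gene_id}")
        if not 1 <= s.cds_pos <= len(gene.seq):
            raise ConsistencyError(
                f"{s.gene_id}: cds_pos {s.cds_pos} outside gene of length {len(gene.seq)}"
            )
        if s.cds_pos - flank < 1 or s.cds_pos + flank > len(gene.seq):
            n_boundary += 1
            continue
        five = gene.seq[s.cds_pos - 1 - flank]
        three = gene.seq[s.cds_pos - 1 + flank]
        if five == "N" or three == "N":
            n_ambig += 1
            continue
        five, three = RNA_OF[five], RNA_OF[three]
        pre[five] += 1
        post[three] += 1
        joint[(five, three)] += 1
        n += 1
    if n == 0:
        return ContextProfile({}, {}, {}, 0, n_boundary, n_ambig)
    return ContextProfile(
        preceding_freq={b: c / n for b, c in sorted(pre.items())},
        following_freq={b: c / n for b, c in sorted(post.items())},
        joint_freq={k: c / n for k, c in sorted(joint.items())},
        n_sites=n,
        n_excluded_boundary=n_boundary,
        n_excluded_ambiguous=n_ambig,
    )


def extract_windows(
    sites: Iterable[EditingSite],
    genes: Mapping[str, GeneRecord] | Sequence[GeneRecord],
    halfwidth: int = 15,
) -> list[str]:
    """Genomic windows centred on each site, '-'-padded at CDS boundaries.

    Every window has length ``2*halfwidth + 1`` with the edited base (the
    genomic C for a C-to-U site) at the centre.
    """
    if halfwidth < 1:
        raise InputError("halfwidth must be >= 1")
    gene_map = _as_map(genes)
    out = []
    for s in sites:
        gene = gene_map[s.gene_id]
        i = s.cds_pos - 1
        lo, hi = i - halfwidth, i + halfwidth + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(gene.seq))
        out.append(
            "-" * left_pad
            + gene.seq[max(lo, 0) : min(hi, len(gene.seq))]
            + "-" * right_pad
        )
    return out


def column_information(windows: Sequence[str]) -> np.ndarray:
    """Per-column information content in bits: 2 - Shannon entropy over
    {A,C,G,U}, with gaps (and N) excluded per column.

    A column with no informative characters scores 0.0.
    """
    if len(windows) < 2:
        raise InputError("need at least two windows")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise InputError("windows must have equal length")
    info = np.zeros(width)
    for j in range(width):
        # T and U are the same state; windows are usually genomic DNA
        counts = Counter("U" if w[j] == "T" else w[j] for w in windows)
        total = sum(v for b, v in counts.items() if b in "ACGU")
        if total == 0:
            continue
        h = 0.0
        for b in "ACGU":
            c = counts.get(b, 0)
            if c:
                p = c / total
                h -= p * math.log2(p)
        info[j] = 2.0 - h
    return info


def _as_map(
    genes: Mapping[str, GeneRecord] | Sequence[GeneRecord]
) -> Mapping[str, GeneRecord]:
    if isinstance(genes, Mapping):
        return genes
    return {g.gene_id: g for g in genes}
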