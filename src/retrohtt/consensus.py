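"""Strain-specific consensus sequences for a subfamily's internal region.

Because a strain's TE copies are homogenized by within-genome (concerted)
evolution, the majority base across all copies at each site is a reasonable
proxy for the strain's ancestral element.  Consensi are built from per-site
base counts after mapping/base-quality filters, and a strain is kept only if
its normalized internal depth exceeds 0.75 and its breadth exceeds 0.9 —
below that, the consensus would be biased toward the reference query.
Sites with no passing depth (or ties) emit 'N', never the query base.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phylo

BASE_ORDER = "ACGT"

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 20
DEFAULT_QC_DEPTH = 0.75
DEFAULT_QC_BREADTH = 0.9


@dataclass
class Pileup:
    query_id: str
    counts: np.ndarray  # (L, 4) base counts in A,C,G,T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) matrix")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class StrainConsensus:
    strain_id: str
    sequence: str  # over {A,C,G,T,N}
    qc_pass: bool
    cn_internal: float
    breadth: float


def filter_sites(
    records,
    length: int,
    query_id: str = "query",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> Pileup:
    """Tally base counts from per-read site records after quality filters.

    ``records`` iterates (pos, base, mapq, baseq) with 0-based positions;
    only records with mapq >= min_mapq and baseq >= min_baseq are counted.
    """
    counts = np.zeros((length, 4), dtype=np.int64)
    for pos, base, mapq, baseq in records:
        if mapq < min_mapq or baseq < min_baseq:
            continue
        idx = BASE_ORDER.find(base.upper())
        if idx < 0 or not (0 <= pos < length):
            continue
        counts[pos, idx] += 1
    return Pileup(query_id=query_id, counts=counts)


def majority_consensus(pileup: Pileup, min_depth: int = 1, tie_policy: str = "N") -> str:
    """Per-site majority base; 'N' on ties or depth below ``min_depth``.

    Only substitutions are considered (counts carry no indels), so the
    consensus has exactly the query length.
    """
    if tie_policy != "N":
        raise ValueError("only tie_policy='N' is supported")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    best_count = counts.max(axis=1)
    # a tie exists when more than one base attains the maximum count
    n_at_max = (counts == best_count[:, None]).sum(axis=1)
    seq = np.array(list(BASE_ORDER))[best]
    seq[(depth < min_depth) | (n_at_max > 1)] = "N"
    return "".join(seq)


def qc_strain(
    cn_internal: float,
    breadth: float,
    depth_min: float = DEFAULT_QC_DEPTH,
    breadth_min: float = DEFAULT_QC_BREADTH,
) -> bool:
    """QC gate: strict ``cn_internal > depth_min`` and ``breadth > breadth_min``."""
    if cn_internal < 0 or breadth < 0:
        raise ValueError("inputs must be non-negative")
    return cn_internal > depth_min and breadth > breadth_min


def build_consensus(
    strain_id: str,
    pileup: Pileup,
    cn_internal: float,
    breadth: float,
    min_depth: int = 1,
    depth_min: float = DEFAULT_QC_DEPTH,
    breadth_min: float = DEFAULT_QC_BREADTH,
) -> StrainConsensus:
    return StrainConsensus(
        strain_id=strain_id,
        sequence=majority_consensus(pileup, min_depth=min_depth),
        qc_pass=qc_strain(cn_internal, breadth, depth_min, breadth_min),
        cn_internal=cn_internal,
        breadth=breadth,
    )


class NoMultiCopyStrainError(ValueError):
    """No strain with >= 2 elements: monophyly fraction undefined."""


def concerted_evolution_check(fle_tree, strain_of: dict[str, str]) -> float:
    """Fraction of multi-element strains whose own elements form a clade.

    Validates the consensus-as-ancestor-proxy assumption: under concerted
    evolution, a strain's copies cluster together before joining copies from
    other strains.  ``strain_of`` maps tree tip labels to strain ids; only
    strains with >= 2 tips are scored.
    """
    tips = phylo.tip_labels(fle_tree)
    unknown = set(tips) - set(strain_of)
    if unknown:
        raise ValueError(f"tips without strain label: {sorted(unknown)[:5]}")
    by_strain: dict[str, list[str]] = {}
    for t in tips:
        by_strain.setdefault(strain_of[t], []).append(t)
    multi = {s: ts for s, ts in by_strain.items() if len(ts) >= 2}
    if not multi:
        raise NoMultiCopyStrainError("no strain has >= 2 elements in the tree")
    mono = sum(phylo.is_monophyletic(fle_tree, ts) for ts in multi.values())
    return mono / len(multi)
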