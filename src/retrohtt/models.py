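"""Shared domain types used across the pipeline.

Coordinates are 0-based half-open everywhere in memory; 1-based positions
appear only in human-readable TSV output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"


@dataclass
class TEQueryModel:
    """A subfamily reference (query) sequence with its LTR/internal region map.

    The query is the anchor for all copy-number and consensus coordinates:
    a full-length element is ``5'LTR + internal + 3'LTR``, with the internal
    region encoding the overlapping Gag/Pol open reading frames.
    """

    query_id: str
    sequence: str
    regions: dict[str, tuple[int, int]]  # keys: ltr5, internal, ltr3

    def __post_init__(self) -> None:
        L = len(self.sequence)
        expected = {"ltr5", "internal", "ltr3"}
        if set(self.regions) != expected:
            raise ValueError(f"regions must have keys {expected}")
        spans = sorted(self.regions.values())
        if spans[0][0] != 0 or spans[-1][1] != L:
            raise ValueError("regions must tile the query")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if b != c:
                raise ValueError("regions must be contiguous and non-overlapping")
        l5 = self.regions["ltr5"][1] - self.regions["ltr5"][0]
        l3 = self.regions["ltr3"][1] - self.regions["ltr3"][0]
        if l5 <= 0 or l3 <= 0 or abs(l5 - l3) > 0.2 * max(l5, l3):
            raise ValueError("LTR lengths must be positive and within 20% of each other")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_seq(self, name: str) -> str:
        a, b = self.regions[name]
        return self.sequence[a:b]


@dataclass
class DepthProfile:
    """Per-base read depth over a query plus the single-copy baseline depth."""

    query_id: str
    depth: np.ndarray  # int counts, length == query length
    baseline_depth: float
    fold_coverage_original: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be positive")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")


@dataclass
class CopyNumberEstimate:
    strain_id: str
    cn_ltr: float
    cn_internal: float
    breadth_internal: float
    presence_ltr: bool
    presence_internal: bool


@dataclass
class ElementRecord:
    """One annotated TE copy in an assembly."""

    element_id: str
    target_seq: str
    start: int
    end: int
    strand: str
    subfamily: str
    element_class: str  # FLE | truncated | solo_LTR
    region_coverage: dict[str, float] = field(default_factory=dict)
    member_hits: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("element locus must be non-degenerate")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
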