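"""Kimura 2-parameter divergence, sliding-window profiles and breakpoint calls.

The K2P model corrects observed divergence for multiple hits while treating
transitions (A<->G, C<->T) and transversions at different rates:

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

with P and Q the observed transition and transversion proportions over
comparable (gap/N-free in both sequences) sites.  Sliding-window profiles of
d between a candidate sequence and two putative parent subfamilies localize
recombination breakpoints: within a segment inherited from parent A the
candidate is closer to A than to B, and the sign of d(cand,A) - d(cand,B)
flips at a breakpoint.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturatedDistanceError(ValueError):
    """K2P distance undefined: log argument non-positive (sequences saturated)."""


class NoComparableSitesError(ValueError):
    """No gap/N-free site shared by the two sequences."""


@dataclass
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions/site
    n_sites: int


@dataclass
class DivergenceProfile:
    centers: np.ndarray  # window centers, alignment columns
    d: dict[str, np.ndarray]  # parent id -> per-window distance (NaN = missing)
    window: int
    step: int


@dataclass
class BreakpointCall:
    positions: list[float]  # alignment columns, strictly increasing
    segment_parents: list[str]  # one per segment, alternating
    confidence: list[float] = field(default_factory=list)  # mean |delta d| per segment


@dataclass
class PartitionSpec:
    """Named, ordered, non-overlapping column intervals (0-based half-open)."""

    intervals: dict[str, tuple[int, int]]

    def validate(self, aln_length: int) -> None:
        prev_end = -1
        for name, (a, b) in self.intervals.items():
            if not (0 <= a < b <= aln_length):
                raise ValueError(f"partition {name!r} out of bounds for length {aln_length}")
            if a < prev_end:
                raise ValueError(f"partition {name!r} overlaps its predecessor")
            prev_end = b


# byte lookup tables: validity (unambiguous base) and purine membership
_VALID_LUT = np.zeros(256, dtype=bool)
_VALID_LUT[list(b"ACGT")] = True
_PURINE_LUT = np.zeros(256, dtype=bool)
_PURINE_LUT[list(b"AG")] = True


def _classify_pairs(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Count (comparable, transitions, transversions) between two byte arrays."""
    valid = _VALID_LUT[a] & _VALID_LUT[b]
    n = int(valid.sum())
    if n == 0:
        return 0, 0, 0
    diff = (a != b) & valid
    # same chemical class (purine/purine or pyrimidine/pyrimidine) -> transition
    ts = int((diff & (_PURINE_LUT[a] == _PURINE_LUT[b])).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _to_bytes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return np.frombuffer(str(seq).upper().encode(), dtype=np.uint8)


def k2p(seq_a, seq_b) -> K2PResult:
    """Kimura 2-parameter distance between two aligned sequences.

    Sites with a gap or ambiguous base in either sequence are excluded
    (pairwise deletion).  Raises :class:`SaturatedDistanceError` when the
    closed form is undefined and :class:`NoComparableSitesError` when no
    comparable site exists.
    """
    a, b = _to_bytes(seq_a), _to_bytes(seq_b)
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n, ts, tv = _classify_pairs(a, b)
    if n == 0:
        raise NoComparableSitesError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated pair: P={P:.3f}, Q={Q:.3f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, n_sites=n)


def k2p_or_nan(seq_a, seq_b, min_frac_sites: float = 0.0) -> float:
    """K2P distance, or NaN where it is undefined.

    ``min_frac_sites``: minimum fraction of columns that must be comparable.
    """
    a, b = _to_bytes(seq_a), _to_bytes(seq_b)
    n, ts, tv = _classify_pairs(a, b)
    if n == 0 or n < min_frac_sites * len(a):
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def sliding_window_divergence(
    candidate,
    parents: dict[str, object],
    w: int = 50,
    s: int = 10,
    min_comparable_frac: float = 0.5,
) -> DivergenceProfile:
    """Per-window K2P distance between a candidate and each parent.

    Windows start at columns 0, s, 2s, ...; a window with fewer than
    ``min_comparable_frac`` of its columns comparable yields NaN.
    """
    cand = _to_bytes(candidate)
    L = len(cand)
    if w <= 0 or s <= 0:
        raise ValueError("window and step must be positive")
    if L < w:
        raise ValueError(f"alignment length {L} shorter than window {w}")
    starts = np.arange(0, L - w + 1, s)
    centers = starts + (w - 1) / 2.0
    out: dict[str, np.ndarray] = {}
    for name, pseq in parents.items():
        p = _to_bytes(pseq)
        if len(p) != L:
            raise ValueError("all sequences must share the alignment length")
        # window counts via cumulative sums of per-site indicators
        valid = _VALID_LUT[cand] & _VALID_LUT[p]
        diff = (cand != p) & valid
        ts = diff & (_PURINE_LUT[cand] == _PURINE_LUT[p])
        cv = np.concatenate([[0], np.cumsum(valid)])
        cd = np.concatenate([[0], np.cumsum(diff)])
        ct = np.concatenate([[0], np.cumsum(ts)])
        n = (cv[starts + w] - cv[starts]).astype(float)
        nd = (cd[starts + w] - cd[starts]).astype(float)
        nt = (ct[starts + w] - ct[starts]).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = nt / n
            Q = (nd - nt) / n
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            vals = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        bad = (n < min_comparable_frac * w) | (w1 <= 0) | (w2 <= 0) | (n == 0)
        vals[bad] = np.nan
        out[name] = vals
    return DivergenceProfile(centers=centers.astype(float), d=out, window=w, step=s)


def infer_breakpoints(
    profile: DivergenceProfile,
    min_seg: int = 3,
    min_delta_ratio: float = 0.5,
) -> BreakpointCall:
    """Call recombination breakpoints from a two-parent divergence profile.

    Per window, delta = d(cand, A) - d(cand, B).  Sign changes of delta mark
    candidate breakpoints; only changes bounding runs of at least ``min_seg``
    consecutive same-sign windows are kept.  Because adjacent windows share
    columns, a local cluster of private mutations can flip the sign of a few
    consecutive windows without real parent switching; runs whose mean
    |delta| is below ``min_delta_ratio`` times the profile's median |delta|
    are therefore discarded as weak evidence.  Missing-value windows break
    runs so no breakpoint is called across gaps of evidence.  The breakpoint
    column is the midpoint between the flanking window centers.
    """
    if len(profile.d) != 2:
        raise ValueError("breakpoint inference requires exactly two parents")
    (name_a, da), (name_b, db) = sorted(profile.d.items())
    delta = da - db
    centers = profile.centers
    # runs of consecutive same-sign windows (zero/NaN breaks a run)
    runs: list[tuple[int, int, int]] = []  # (start_idx, end_idx_inclusive, sign)
    cur_sign, cur_start = 0, -1
    for i, v in enumerate(delta):
        sign = 0 if (math.isnan(v) or v == 0) else (1 if v > 0 else -1)
        if sign != cur_sign:
            if cur_sign != 0:
                runs.append((cur_start, i - 1, cur_sign))
            cur_sign, cur_start = sign, i
    if cur_sign != 0:
        runs.append((cur_start, len(delta) - 1, cur_sign))
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_seg]
    finite = np.abs(delta[~np.isnan(delta)])
    scale = float(np.median(finite)) if finite.size else 0.0
    runs = [r for r in runs
            if float(np.nanmean(np.abs(delta[r[0]:r[1] + 1])))
            >= min_delta_ratio * scale]
    if not runs:
        raise ValueError("no informative windows: profile all-missing or all-ambiguous")
    # merge adjacent same-sign runs (separated only by dropped short/ambiguous runs)
    merged: list[tuple[int, int, int]] = []
    for r in runs:
        if merged and merged[-1][2] == r[2]:
            merged[-1] = (merged[-1][0], r[1], r[2])
        else:
            merged.append(r)
    positions: list[float] = []
    parents: list[str] = []
    confidence: list[float] = []
    for i, (a, b, sign) in enumerate(merged):
        # delta > 0 means farther from A -> segment derived from parent B
        parents.append(name_b if sign > 0 else name_a)
        seg = delta[a : b + 1]
        confidence.append(float(np.nanmean(np.abs(seg))))
        if i > 0:
            prev_end = merged[i - 1][1]
            positions.append(float((centers[prev_end] + centers[a]) / 2.0))
    return BreakpointCall(positions=positions, segment_parents=parents, confidence=confidence)


def partition_alignment(msa: dict[str, str], spec: PartitionSpec) -> dict[str, dict[str, str]]:
    """Column-exact named slices of an alignment (dict of id -> row)."""
    if not msa:
        raise ValueError("empty alignment")
    L = len(next(iter(msa.values())))
    if any(len(v) != L for v in msa.values()):
        raise ValueError("ragged alignment")
    spec.validate(L)
    return {
        name: {sid: seq[a:b] for sid, seq in msa.items()}
        for name, (a, b) in spec.intervals.items()
    }


def spec_from_breakpoints(call: BreakpointCall, aln_length: int) -> PartitionSpec:
    """Partition spec whose intervals are bounded by the called breakpoints.

    One breakpoint yields {five_prime, three_prime}; two yield
    {left, middle, right}; otherwise segments are numbered.
    """
    bounds = [0] + [int(round(p)) for p in call.positions] + [aln_length]
    n_seg = len(bounds) - 1
    if n_seg == 2:
        names = ["five_prime", "three_prime"]
    elif n_seg == 3:
        names = ["left", "middle", "right"]
    else:
        names = [f"segment_{i}" for i in range(n_seg)]
    return PartitionSpec(
        intervals={name: (bounds[i], bounds[i + 1]) for i, name in enumerate(names)}
    )
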