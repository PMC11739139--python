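"""Copy-number and breadth estimation from normalized read depth.

A TE subfamily's copy number in a strain is estimated as the mean read depth
over a query region divided by the single-copy baseline depth of that
genome.  Region edges are included in the mean (no edge trimming).  Presence
calls use separate thresholds for LTRs and internal regions: LTRs persist as
solo LTRs long after internal sequences are lost, so LTR presence with
internal absence indicates past (or recent) activity while internal presence
indicates relatively recent activity.
"""
from __future__ import annotations

import numpy as np

from .models import CopyNumberEstimate, DepthProfile

DEFAULT_LTR_THRESHOLD = 1.0
DEFAULT_INTERNAL_THRESHOLD = 0.5


def _check_region(profile: DepthProfile, region: tuple[int, int]) -> tuple[int, int]:
    a, b = int(region[0]), int(region[1])
    if not (0 <= a < b <= len(profile.depth)):
        raise ValueError(f"region {region} empty or outside query bounds")
    return a, b


def normalize_copy_number(profile: DepthProfile, region: tuple[int, int]) -> float:
    """Mean depth over ``region`` (edges included) / baseline depth."""
    a, b = _check_region(profile, region)
    return float(profile.depth[a:b].mean() / profile.baseline_depth)


def copy_number_regions(
    profile: DepthProfile, regions: dict[str, tuple[int, int]]
) -> tuple[float, float]:
    """(cn_ltr, cn_internal): LTR copy number uses the mean depth over the
    union of the 5' and 3' LTR intervals, normalized once."""
    l5a, l5b = _check_region(profile, regions["ltr5"])
    l3a, l3b = _check_region(profile, regions["ltr3"])
    ltr_depth = np.concatenate([profile.depth[l5a:l5b], profile.depth[l3a:l3b]])
    cn_ltr = float(ltr_depth.mean() / profile.baseline_depth)
    cn_internal = normalize_copy_number(profile, regions["internal"])
    return cn_ltr, cn_internal


def compute_breadth(
    profile: DepthProfile, region: tuple[int, int], min_depth: int = 1
) -> float:
    """Fraction of region positions with depth >= ``min_depth``."""
    a, b = _check_region(profile, region)
    return float((profile.depth[a:b] >= min_depth).mean())


def downsample_depth(profile: DepthProfile, cap: float = 100.0, seed: int = 0) -> DepthProfile:
    """Cap effective fold coverage by random read thinning.

    If the original fold coverage is at or below ``cap`` the profile is
    returned unchanged; otherwise each depth count is binomially thinned
    with probability ``cap / fold_coverage_original`` (seeded, so repeated
    thinning with the same seed is identical) and the baseline is rescaled.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    orig = profile.fold_coverage_original
    if orig <= cap:
        return profile
    p = cap / orig
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(profile.depth, p)
    return DepthProfile(
        query_id=profile.query_id,
        depth=thinned,
        baseline_depth=profile.baseline_depth * p,
        fold_coverage_original=cap,
    )


def call_presence(
    cn_ltr: float,
    cn_internal: float,
    ltr_threshold: float = DEFAULT_LTR_THRESHOLD,
    internal_threshold: float = DEFAULT_INTERNAL_THRESHOLD,
) -> tuple[bool, bool]:
    """Presence calls: LTRs present when copy number > 1, internal regions
    when > 0.5 (strict inequalities; thresholds configurable)."""
    if cn_ltr < 0 or cn_internal < 0:
        raise ValueError("copy numbers must be non-negative")
    return cn_ltr > ltr_threshold, cn_internal > internal_threshold


def interpret_activity(presence_ltr: bool, presence_internal: bool, n_fle: int) -> str:
    """Activity category for a subfamily in a strain.

    Internal sequence (or any FLE) implies relatively recent activity;
    LTR-only presence is compatible with recent or past activity.
    """
    if n_fle < 0:
        raise ValueError("n_fle must be non-negative")
    if presence_internal or n_fle > 0:
        return "recent_activity"
    if presence_ltr:
        return "past_or_recent"
    return "no_evidence"


def estimate_strain(
    strain_id: str,
    profile: DepthProfile,
    regions: dict[str, tuple[int, int]],
    ltr_threshold: float = DEFAULT_LTR_THRESHOLD,
    internal_threshold: float = DEFAULT_INTERNAL_THRESHOLD,
    min_depth: int = 1,
) -> CopyNumberEstimate:
    """Full per-strain estimate: copy numbers, internal breadth, presence."""
    cn_ltr, cn_internal = copy_number_regions(profile, regions)
    breadth = compute_breadth(profile, regions["internal"], min_depth=min_depth)
    p_ltr, p_int = call_presence(cn_ltr, cn_internal, ltr_threshold, internal_threshold)
    return CopyNumberEstimate(
        strain_id=strain_id,
        cn_ltr=cn_ltr,
        cn_internal=cn_internal,
        breadth_internal=breadth,
        presence_ltr=p_ltr,
        presence_internal=p_int,
    )
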