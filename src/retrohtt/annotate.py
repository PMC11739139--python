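"""Element annotation: homology hits -> classified TE copies.

Hits against a subfamily query are defragmented into elements and classified
structurally: a full-length element (FLE) retains both LTRs and the internal
gag/pol region; a solo LTR is the single-LTR product of intra-element
LTR-LTR recombination; everything else is truncated.  A structural rescue
path promotes groups of mutually similar, dispersed truncated elements that
coincide with de novo LTR-pair predictions — the situation that arises when
a subfamily is too diverged from the query for homology coverage to reach
the full-length thresholds.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .models import ElementRecord, TEQueryModel

HIT_COLUMNS = ["target_seq", "t_start", "t_end", "strand",
               "query_id", "q_start", "q_end", "pct_div"]

DEFAULT_MAX_GAP = 250
DEFAULT_MIN_FULL_FRAC = 0.9
DEFAULT_LTR_ONLY_FRAC = 0.8
DEFAULT_MAX_INTERNAL_SOLO = 0.05


@dataclass
class Hit:
    target_seq: str
    t_start: int
    t_end: int
    strand: str
    query_id: str
    q_start: int
    q_end: int
    pct_divergence: float
    hit_id: int = -1

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start or self.q_end <= self.q_start:
            raise ValueError("hit intervals must be non-degenerate")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not (0.0 <= self.pct_divergence <= 100.0):
            raise ValueError("pct_divergence must be in [0, 100]")


@dataclass
class MergedElement:
    target_seq: str
    t_start: int
    t_end: int
    strand: str
    query_id: str
    query_intervals: list[tuple[int, int]]  # union of member query intervals
    member_hits: list[int]
    pct_divergence: float

    def query_coverage(self, region: tuple[int, int]) -> float:
        a, b = region
        covered = 0
        for qa, qb in self.query_intervals:
            covered += max(0, min(qb, b) - max(qa, a))
        return covered / max(b - a, 1)


@dataclass
class LTRPairCandidate:
    left: tuple[int, int]
    right: tuple[int, int]
    identity: float
    spacer: int  # gap between the repeats
    tsd: str
    motif_present: bool
    score: float = 0.0

    @property
    def full_span(self) -> tuple[int, int]:
        return self.left[0], self.right[1]


class HitParseError(ValueError):
    pass


def parse_hits(table: str | io.TextIOBase) -> list[Hit]:
    """Parse a whitespace-delimited hit table.

    Comment lines (``#``) and a leading header row are skipped; every data
    row yields one :class:`Hit`.  Coordinates in the table are 0-based
    half-open on the plus strand of both target and query (minus-strand hits
    already carry plus-frame query coordinates).
    """
    if hasattr(table, "read"):
        table = table.read()
    hits: list[Hit] = []
    for lineno, line in enumerate(str(table).splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == HIT_COLUMNS[0]:  # header row
            continue
        if len(fields) < 8:
            raise HitParseError(f"line {lineno}: expected 8 fields, got {len(fields)}")
        try:
            hit = Hit(
                target_seq=fields[0],
                t_start=int(fields[1]),
                t_end=int(fields[2]),
                strand=fields[3],
                query_id=fields[4],
                q_start=int(fields[5]),
                q_end=int(fields[6]),
                pct_divergence=float(fields[7]),
                hit_id=len(hits),
            )
        except ValueError as exc:
            raise HitParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits(hits: list[Hit]) -> str:
    lines = ["\t".join(HIT_COLUMNS)]
    for h in hits:
        lines.append("\t".join(str(x) for x in (
            h.target_seq, h.t_start, h.t_end, h.strand,
            h.query_id, h.q_start, h.q_end, h.pct_divergence)))
    return "\n".join(lines) + "\n"


def _collinear(prev: Hit, nxt: Hit) -> bool:
    """Query intervals ordered consistently with the strand, non-overlapping."""
    if prev.strand == "+":
        return nxt.q_start >= prev.q_end
    return nxt.q_end <= prev.q_start


def defragment(hits: list[Hit], max_gap: int = DEFAULT_MAX_GAP) -> list[MergedElement]:
    """Merge collinear same-target/strand/query hit chains into elements.

    Hits are chained when the target-coordinate gap is at most ``max_gap``
    and their query intervals are non-overlapping and correctly ordered for
    the strand.
    """
    groups: dict[tuple[str, str, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.target_seq, h.strand, h.query_id), []).append(h)
    elements: list[MergedElement] = []
    for (target, strand, query_id), ghits in sorted(groups.items()):
        ghits = sorted(ghits, key=lambda h: (h.t_start, h.t_end))
        chain: list[Hit] = []
        for h in ghits:
            if chain and (h.t_start - chain[-1].t_end) <= max_gap and _collinear(chain[-1], h):
                chain.append(h)
            else:
                if chain:
                    elements.append(_merge_chain(chain))
                chain = [h]
        if chain:
            elements.append(_merge_chain(chain))
    return elements


def _merge_chain(chain: list[Hit]) -> MergedElement:
    total = sum(h.q_end - h.q_start for h in chain)
    div = sum(h.pct_divergence * (h.q_end - h.q_start) for h in chain) / total
    return MergedElement(
        target_seq=chain[0].target_seq,
        t_start=min(h.t_start for h in chain),
        t_end=max(h.t_end for h in chain),
        strand=chain[0].strand,
        query_id=chain[0].query_id,
        query_intervals=sorted((h.q_start, h.q_end) for h in chain),
        member_hits=[h.hit_id for h in chain],
        pct_divergence=div,
    )


def classify_element(
    elem: MergedElement,
    query: TEQueryModel,
    min_full_frac: float = DEFAULT_MIN_FULL_FRAC,
    ltr_only_frac: float = DEFAULT_LTR_ONLY_FRAC,
    max_internal_solo: float = DEFAULT_MAX_INTERNAL_SOLO,
) -> str:
    """Structural class from per-region query coverage."""
    c5 = elem.query_coverage(query.regions["ltr5"])
    ci = elem.query_coverage(query.regions["internal"])
    c3 = elem.query_coverage(query.regions["ltr3"])
    if ci < max_internal_solo and max(c5, c3) >= ltr_only_frac:
        return "solo_LTR"
    if ci >= min_full_frac and c5 >= ltr_only_frac and c3 >= ltr_only_frac:
        return "FLE"
    return "truncated"


def annotate_elements(
    hits: list[Hit],
    queries: dict[str, TEQueryModel],
    max_gap: int = DEFAULT_MAX_GAP,
    min_full_frac: float = DEFAULT_MIN_FULL_FRAC,
    ltr_only_frac: float = DEFAULT_LTR_ONLY_FRAC,
) -> list[ElementRecord]:
    """Defragment and classify hits into :class:`ElementRecord` annotations."""
    records = []
    for i, elem in enumerate(defragment(hits, max_gap=max_gap)):
        query = queries[elem.query_id]
        cls = classify_element(elem, query, min_full_frac, ltr_only_frac)
        records.append(ElementRecord(
            element_id=f"{elem.target_seq}:el{i:04d}",
            target_seq=elem.target_seq,
            start=elem.t_start,
            end=elem.t_end,
            strand=elem.strand,
            subfamily=elem.query_id,
            element_class=cls,
            region_coverage={r: elem.query_coverage(query.regions[r])
                             for r in ("ltr5", "internal", "ltr3")},
            member_hits=elem.member_hits,
        ))
    return records


# ---------------------------------------------------------------------------
# de novo LTR pair detection


def _extend_pair(seq: str, i: int, j: int, k: int, max_len: int,
                 match: int = 2, mismatch: int = -3, xdrop: int = 20):
    """Ungapped X-drop extension of a seed match seq[i:i+k] == seq[j:j+k].
    Returns (i0, j0, length) of the best-scoring extended repeat pair."""
    n = len(seq)
    # rightward
    best_r, score, ext_r, step = 0, 0, 0, 0
    while i + k + step < j and j + k + step < n:
        score += match if seq[i + k + step] == seq[j + k + step] else mismatch
        step += 1
        if score > best_r:
            best_r, ext_r = score, step
        if best_r - score > xdrop:
            break
    # leftward
    best_l, score, ext_l, step = 0, 0, 0, 0
    while i - 1 - step >= 0 and j - 1 - step > i + k - 1:
        score += match if seq[i - 1 - step] == seq[j - 1 - step] else mismatch
        step += 1
        if score > best_l:
            best_l, ext_l = score, step
        if best_l - score > xdrop:
            break
    length = k + ext_l + ext_r
    if length > max_len:  # trim overshoot from the right
        ext_r = max(0, ext_r - (length - max_len))
        length = k + ext_l + ext_r
    return i - ext_l, j - ext_l, length


def _refine_motif_boundaries(seq: str, i0: int, j0: int, length: int,
                             motif: str, min_len: int, vic: int = 10):
    """Boundary adjustments within a vicinity so both repeats start with the
    motif's first dinucleotide and end with its last (cf. terminal
    ``tg...ca``).  Chance matches in the flanks can drag the maximal-score
    extension a few bases past the true repeat ends; the motif anchors the
    boundary.  Yields (i0, j0, length) candidates in order of increasing
    total shift — a chance motif occurrence near the boundary can shadow the
    true one, so callers should keep the first candidate that passes their
    remaining checks (TSD, identity) rather than the first candidate alone."""
    starts = [dl for dl in range(-vic, vic + 1)
              if i0 + dl >= 0
              and seq[i0 + dl:i0 + dl + 2] == motif[:2]
              and seq[j0 + dl:j0 + dl + 2] == motif[:2]]
    ends = [dr for dr in range(-vic, vic + 1)
            if j0 + length + dr <= len(seq)
            and seq[i0 + length + dr - 2:i0 + length + dr] == motif[2:]
            and seq[j0 + length + dr - 2:j0 + length + dr] == motif[2:]]
    combos = sorted(((dl, dr) for dl in starts for dr in ends),
                    key=lambda p: abs(p[0]) + abs(p[1]))
    for dl, dr in combos:
        new_len = length - dl + dr
        if new_len >= min_len:
            yield i0 + dl, j0 + dl, new_len


def detect_ltr_pairs(
    genome: str,
    min_len: int = 100,
    max_len: int = 1000,
    min_dist: int = 1500,
    max_dist: int = 15000,
    min_identity: float = 0.80,
    tsd_len: int = 5,
    motif: str = "tgca",
    motif_required: bool = True,
    tsd_required: bool = True,
    seed_len: int = 12,
) -> list[LTRPairCandidate]:
    """Detect direct-repeat (LTR) pairs by seeded ungapped extension.

    A candidate is a pair of direct repeats whose lengths, start-to-start
    distance and identity satisfy the configured bounds, optionally flanked
    by an identical ``tsd_len``-bp target-site duplication and carrying the
    terminal dinucleotide motif (element starts ``tg``..., ends ...``ca``).
    Overlapping candidates are resolved best-first by ``identity x length``.
    """
    seq = genome.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty genome")
    motif = motif.upper()
    index: dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        index.setdefault(seq[i:i + seed_len], []).append(i)

    raw: list[LTRPairCandidate] = []
    seen_spans: set[tuple[int, int, int, int]] = set()
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 50:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                dist = j - i
                if dist < min_dist - max_len or dist > max_dist + max_len:
                    continue
                i0, j0, length = _extend_pair(seq, i, j, seed_len, max_len)
                if length < min_len:
                    continue
                if motif_required:
                    boundaries = _refine_motif_boundaries(
                        seq, i0, j0, length, motif, min_len)
                else:
                    boundaries = [(i0, j0, length)]
                for i0, j0, length in boundaries:
                    if length > max_len:
                        continue
                    if not (min_dist <= j0 - i0 <= max_dist):
                        continue
                    if j0 < i0 + length:  # repeats overlap
                        continue
                    key = (i0, i0 + length, j0, j0 + length)
                    if key in seen_spans:
                        continue
                    left, right = seq[i0:i0 + length], seq[j0:j0 + length]
                    ident = sum(x == y for x, y in zip(left, right)) / length
                    if ident < min_identity:
                        continue
                    tsd_l = seq[max(0, i0 - tsd_len):i0]
                    tsd_r = seq[j0 + length:j0 + length + tsd_len]
                    has_tsd = len(tsd_l) == tsd_len and tsd_l == tsd_r
                    if tsd_required and not has_tsd:
                        continue
                    has_motif = (seq[i0:i0 + 2] == motif[:2]
                                 and seq[j0 + length - 2:j0 + length] == motif[2:])
                    if motif_required and not has_motif:
                        continue
                    seen_spans.add(key)
                    raw.append(LTRPairCandidate(
                        left=(i0, i0 + length), right=(j0, j0 + length),
                        identity=ident, spacer=j0 - (i0 + length),
                        tsd=tsd_l if has_tsd else "",
                        motif_present=has_motif, score=ident * length,
                    ))
                    break
    # best-overlap selection on full spans
    raw.sort(key=lambda c: (-c.score, c.left[0]))
    kept: list[LTRPairCandidate] = []
    for cand in raw:
        a, b = cand.full_span
        if all(b <= k.full_span[0] or a >= k.full_span[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.left[0])
    return kept


def _pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global identity via edit distance (1 - dist / longer length)."""
    import edlib

    if not seq_a or not seq_b:
        return 0.0
    res = edlib.align(seq_a, seq_b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(seq_a), len(seq_b))


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(ov / max(a[1] - a[0], 1), ov / max(b[1] - b[0], 1))


def rescue_divergent_fle(
    elements: list[ElementRecord],
    candidates_by_target: dict[str, list[LTRPairCandidate]],
    sequences: dict[str, str],
    min_mutual_identity: float = 0.8,
    min_count: int = 3,
    min_reciprocal_overlap: float = 0.8,
) -> list[ElementRecord]:
    """Promote truncated elements that are structurally full length.

    A truncated element is reclassified as FLE when (a) its span overlaps a
    de novo LTR-pair prediction reciprocally by at least
    ``min_reciprocal_overlap``, and (b) it belongs to a group of at least
    ``min_count`` elements with pairwise identity >= ``min_mutual_identity``
    dispersed over >= 2 distinct target sequences.  ``sequences`` maps
    element ids to their genomic sequences.  Returns the input list with
    promoted copies reclassified (inputs are not mutated).
    """
    import copy as _copy

    out = [_copy.copy(e) for e in elements]
    truncated = [e for e in out if e.element_class == "truncated"]
    # (a) structural support from LTR-pair predictions
    supported = []
    for e in truncated:
        for cand in candidates_by_target.get(e.target_seq, []):
            if _reciprocal_overlap((e.start, e.end), cand.full_span) >= min_reciprocal_overlap:
                supported.append(e)
                break
    # (b) mutual-similarity groups dispersed over targets
    ids = [e.element_id for e in supported]
    adj = {i: set() for i in ids}
    for x in range(len(supported)):
        for y in range(x + 1, len(supported)):
            ex, ey = supported[x], supported[y]
            ident = _pairwise_identity(sequences.get(ex.element_id, ""),
                                       sequences.get(ey.element_id, ""))
            if ident >= min_mutual_identity:
                adj[ex.element_id].add(ey.element_id)
                adj[ey.element_id].add(ex.element_id)
    visited: set[str] = set()
    promoted: set[str] = set()
    by_id = {e.element_id: e for e in supported}
    for root in ids:
        if root in visited:
            continue
        comp, stack = set(), [root]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        visited |= comp
        targets = {by_id[i].target_seq for i in comp}
        if len(comp) >= min_count and len(targets) >= 2:
            promoted |= comp
    for e in out:
        if e.element_id in promoted:
            e.element_class = "FLE"
    return out
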