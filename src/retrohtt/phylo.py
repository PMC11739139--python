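"""Distance-based phylogenetics: NJ/BIONJ, midpoint rooting, bootstrap,
clade queries, and host-vs-TE discordance flags for HTT inference.

Horizontal transposon transfer (HTT) leaves three classic signatures, each of
which is operationalized here as a flag:

* ``incongruence`` — a well-supported TE clade from one species is sister to
  TE sequences from a species that is not the host-tree sister of its own;
* ``excess_similarity`` — TE copies from divergent hosts are far more similar
  than the host divergence allows under vertical descent;
* ``patchy_distribution`` — a subfamily is present in a non-monophyletic
  subset of a species' lineages.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .divergence import SaturatedDistanceError, k2p, k2p_or_nan


class UndefinedSisterError(ValueError):
    """Sister group requested for the full tip set (or the root clade)."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal; NaN marks saturated pairs
    model: str = "K2P"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.matrix[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


@dataclass
class HTTFlag:
    clade: frozenset
    evidence: str  # incongruence | excess_similarity | patchy_distribution
    details: dict = field(default_factory=dict)


def _codes_matrix(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(msa)
    arr = np.vstack([np.frombuffer(msa[i].upper().encode(), dtype=np.uint8)
                     for i in ids])
    return ids, arr


def _k2p_matrix(arr: np.ndarray) -> np.ndarray:
    """All-pairs K2P distances on an (n, L) byte matrix; NaN when undefined."""
    from .divergence import _PURINE_LUT, _VALID_LUT

    n = arr.shape[0]
    valid = _VALID_LUT[arr]
    pur = _PURINE_LUT[arr]
    m = np.zeros((n, n))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1:]
        diff = (arr[i] != arr[i + 1:]) & v
        ts = diff & (pur[i] == pur[i + 1:])
        nv = v.sum(axis=1).astype(float)
        nd = diff.sum(axis=1).astype(float)
        nt = ts.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = nt / nv
            Q = (nd - nt) / nv
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        d[(nv == 0) | (w1 <= 0) | (w2 <= 0)] = np.nan
        m[i, i + 1:] = d
        m[i + 1:, i] = d
    return m


def distance_matrix(msa: dict[str, str], model: str = "K2P") -> DistanceMatrix:
    """Pairwise K2P distance matrix from an alignment; saturated pairs -> NaN."""
    if len(msa) < 3:
        raise ValueError("need at least 3 sequences")
    if model.upper() != "K2P":
        raise ValueError(f"unsupported model {model!r}")
    ids, arr = _codes_matrix(msa)
    return DistanceMatrix(ids=ids, matrix=_k2p_matrix(arr), model="K2P")


def _finish_three(nodes, labels, d) -> dendropy.Node:
    """Three-point formulas for the final star join."""
    a, b, c = 0, 1, 2
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    center = dendropy.Node()
    for node, ln in zip(nodes, (la, lb, lc)):
        center.add_child(node)
        node.edge.length = max(0.0, ln)
    return center


def nj_tree(dm: DistanceMatrix, variant: str = "classic") -> dendropy.Tree:
    """Neighbor-joining (``classic``) or BIONJ (``bionj``) tree.

    For additive input distances both variants recover the generating tree's
    topology and branch lengths exactly.  Negative branch-length estimates
    are clamped to zero with the deficit transferred to the paired branch.
    Ties in the Q criterion are broken by the lexicographically smallest
    (representative-label) pair, so results are platform-independent.
    """
    if variant not in ("classic", "bionj"):
        raise ValueError(f"unknown NJ variant {variant!r}")
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(dm.matrix).any():
        pairs = dm.saturated_pairs
        raise SaturatedDistanceError(
            f"distance matrix has {len(pairs)} saturated pair(s), e.g. {pairs[0]}; "
            "remove or re-align the offending taxa before tree building"
        )
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.ids]
    reps = list(dm.ids)  # lexicographic representative per cluster, for tie-breaks
    d = dm.matrix.astype(float).copy()
    v = d.copy()  # BIONJ variance estimates

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ti, tj = np.where(q == qmin)
        # deterministic tie-break: lexicographically smallest representative pair
        pairs = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(ti, tj)}
        i, j = min(pairs, key=lambda ij: (min(reps[ij[0]], reps[ij[1]]),
                                          max(reps[ij[0]], reps[ij[1]])))
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(0.0, li + lj), 0.0
        new = dendropy.Node()
        new.add_child(nodes[i])
        nodes[i].edge.length = li
        new.add_child(nodes[j])
        nodes[j].edge.length = lj
        if variant == "bionj":
            if v[i, j] > 0:
                others = [k for k in range(n) if k not in (i, j)]
                lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (
                    2.0 * (n - 2) * v[i, j]
                )
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
            du = lam * (d[i] - li) + (1.0 - lam) * (d[j] - lj)
            vu = lam * v[i] + (1.0 - lam) * v[j] - lam * (1.0 - lam) * v[i, j]
        else:
            du = (d[i] + d[j] - d[i, j]) / 2.0
            vu = None
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[: n - 2, : n - 2] = d[np.ix_(keep, keep)]
        d_new[-1, : n - 2] = d_new[: n - 2, -1] = du[keep]
        if variant == "bionj":
            v_new = np.zeros((n - 1, n - 1))
            v_new[: n - 2, : n - 2] = v[np.ix_(keep, keep)]
            v_new[-1, : n - 2] = v_new[: n - 2, -1] = vu[keep]
            v = v_new
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    root = _finish_three(nodes, reps, d)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids=labels, matrix=m, model="patristic")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    t = tree.clone(depth=1)
    lengths = [e.length or 0.0 for e in t.edges()]
    if sum(lengths) <= 0:
        raise ValueError("all branch lengths zero: midpoint root is ambiguous")
    t.reroot_at_midpoint(update_bipartitions=True)
    t.is_rooted = True
    return t


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as canonical frozensets of tip labels.

    The canonical side is the one *not* containing the lexicographically
    smallest label, so rooted and unrooted encodings agree.
    """
    labels = set(tip_labels(tree))
    ref = min(labels)
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds: count of splits present in exactly one tree."""
    if set(tip_labels(t1)) != set(tip_labels(t2)):
        raise ValueError("trees must share the same tip set")
    return len(bipartitions(t1) ^ bipartitions(t2))


def is_monophyletic(tree: dendropy.Tree, tips) -> bool:
    """Whether ``tips`` form a clade (unrooted split semantics)."""
    tips = frozenset(tips)
    labels = set(tip_labels(tree))
    unknown = tips - labels
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(tips) in (1, len(labels)):
        return True
    ref = min(labels)
    side = tips if ref not in tips else frozenset(labels - tips)
    if len(side) < 2 or len(side) > len(labels) - 2:
        # splits of size 1 / n-1 are present in every binary tree
        return True
    return side in bipartitions(tree)


def sister_group(tree: dendropy.Tree, clade) -> frozenset:
    """Tip labels of the sibling subtree of the (rooted) clade ``clade``."""
    clade = frozenset(clade)
    labels = set(tip_labels(tree))
    if clade - labels:
        raise ValueError(f"unknown tips: {sorted(clade - labels)}")
    if clade == labels:
        raise UndefinedSisterError("sister of the full tip set is undefined")
    for node in tree.preorder_node_iter():
        leaves = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if leaves == clade:
            parent = node.parent_node
            if parent is None:
                raise UndefinedSisterError("clade is the root")
            return frozenset(
                leaf.taxon.label
                for sib in parent.child_nodes()
                if sib is not node
                for leaf in sib.leaf_iter()
            )
    raise ValueError("tip set is not a clade of this tree")


def bootstrap_support(
    msa: dict[str, str],
    n: int = 100,
    seed: int = 0,
    variant: str = "classic",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from ``n`` column-resampled replicates.

    Support is the percentage of usable replicate trees containing each split
    of the full-alignment tree, attached as internal-node labels.  Replicates
    whose resampled distance matrix contains a saturated pair are discarded.
    Column indices alone are drawn from the seeded RNG, so supports do not
    depend on taxon input order.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    ids, arr = _codes_matrix(msa)
    L = arr.shape[1]
    base = nj_tree(distance_matrix(msa), variant=variant)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(base)}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(n):
        cols = rng.integers(0, L, size=L)
        m = _k2p_matrix(arr[:, cols])
        if np.isnan(m).any():
            continue
        used += 1
        dm = DistanceMatrix(ids=ids, matrix=m, model="K2P")
        for bp in bipartitions(nj_tree(dm, variant=variant)):
            if bp in counts:
                counts[bp] += 1
    denom = max(used, 1)
    labels = set(tip_labels(base))
    ref = min(labels)
    for node in base.preorder_internal_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if side in counts:
            node.label = str(int(round(100.0 * counts[side] / denom)))
    return base


def _node_support(node: dendropy.Node) -> float | None:
    try:
        return float(node.label) if node.label is not None else None
    except (TypeError, ValueError):
        return None


def _species_clade_sister(host_tree: dendropy.Tree, species: str, host_species_of) -> frozenset:
    """Species in the sibling of the (maximal) clade of ``species`` tips."""
    tips = [t for t in tip_labels(host_tree) if host_species_of(t) == species]
    if not tips:
        return frozenset()
    try:
        sis = sister_group(host_tree, tips)
    except (ValueError, UndefinedSisterError):
        # species not monophyletic in host tree: use sister of its MRCA
        mrca = host_tree.mrca(taxon_labels=tips)
        if mrca is None or mrca.parent_node is None:
            return frozenset()
        sis = frozenset(
            leaf.taxon.label
            for sib in mrca.parent_node.child_nodes()
            if sib is not mrca
            for leaf in sib.leaf_iter()
        )
    return frozenset(host_species_of(t) for t in sis)


def htt_flag(
    te_tree: dendropy.Tree,
    host_tree: dendropy.Tree,
    species_of: dict[str, str],
    presence_table=None,
    min_support: float = 70,
    similarity_ratio: float = 0.5,
    host_species_of: dict[str, str] | None = None,
    patchy_min_absent: int = 2,
    incongruence_ratio: float = 0.5,
) -> list[HTTFlag]:
    """Flag TE clades whose placement is inconsistent with vertical descent.

    ``species_of`` maps TE-tree tip labels to host species; ``host_species_of``
    maps host-tree tip labels to species (defaults to identity).
    ``presence_table`` is an optional mapping/DataFrame of host tip ->
    {subfamily: bool} used for the patchy-distribution test.
    """
    te_tips = set(tip_labels(te_tree))
    unmapped = te_tips - set(species_of)
    if unmapped:
        raise ValueError(f"TE tips without species mapping: {sorted(unmapped)[:5]}")
    hso = (lambda t: host_species_of.get(t, t)) if host_species_of else (lambda t: t)
    host_species = {hso(t) for t in tip_labels(host_tree)}
    missing = set(species_of.values()) - host_species
    if missing:
        raise ValueError(f"TE tip species absent from host tree: {sorted(missing)}")

    flags: list[HTTFlag] = []
    te_pd = patristic_distances(te_tree)
    host_pd = patristic_distances(host_tree)
    te_idx = {t: k for k, t in enumerate(te_pd.ids)}

    def host_div(sa: str, sb: str) -> float:
        """Species-level host divergence: mean over strain pairs."""
        ia = [k for k, t in enumerate(host_pd.ids) if hso(t) == sa]
        ib = [k for k, t in enumerate(host_pd.ids) if hso(t) == sb]
        return float(np.mean([host_pd.matrix[x, y] for x in ia for y in ib]))

    # (a) incongruence: a maximal single-species group nested, with support,
    # inside the diversity of a species that is not the host-tree sister of
    # its own.  The placement is read from the smallest well-supported split
    # side enclosing the group, so an unstable attachment *within* the other
    # species' clade (low support for which exact element is closest) does
    # not mask a certain nesting one level up.
    sides: list[tuple[frozenset, float | None]] = []
    for node in te_tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sup = _node_support(node)
        sides.append((leaves, sup))
        sides.append((frozenset(te_tips - leaves), sup))
    groups: list[frozenset] = []
    for node in te_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len({species_of[t] for t in leaves}) != 1:
            continue
        parent_leaves = frozenset(
            leaf.taxon.label for leaf in node.parent_node.leaf_iter())
        if len({species_of[t] for t in parent_leaves}) == 1:
            continue  # not maximal
        groups.append(leaves)
    host_sister_cache: dict[str, frozenset] = {}
    for group in groups:
        sp = species_of[next(iter(group))]
        enclosing = sorted(
            (s for s in sides if group < s[0] and s[0] != te_tips),
            key=lambda s: len(s[0]))
        for side, sup in enclosing:
            if sup is not None and sup < min_support:
                continue
            others = {species_of[t] for t in side - group} - {sp}
            if not others:
                continue  # still a pure own-species context, keep widening
            if len(others) > 1:
                break  # mixed context: no single-donor statement possible
            (sis_sp,) = others
            # nesting requires the other species on both sides of the split
            y_in = [t for t in side if species_of[t] == sis_sp]
            y_out = any(species_of[t] == sis_sp for t in te_tips - side)
            if not y_out:
                break  # clean sister placement: vertical-compatible
            # transfer attaches the group far below the host divergence; an
            # arbitrary (if well-resampled) resolution of a deep polytomy
            # does not
            attach = min(te_pd.matrix[te_idx[a], te_idx[b]]
                         for a in group for b in y_in)
            if attach >= incongruence_ratio * host_div(sp, sis_sp):
                break
            if sp not in host_sister_cache:
                host_sister_cache[sp] = _species_clade_sister(host_tree, sp, hso)
            if sis_sp not in host_sister_cache[sp]:
                flags.append(
                    HTTFlag(
                        clade=group,
                        evidence="incongruence",
                        details={
                            "species": sp,
                            "te_sister_species": sis_sp,
                            "host_sister_species": sorted(host_sister_cache[sp]),
                            "support": sup if sup is not None else 100.0,
                            "attach_distance": attach,
                        },
                    )
                )
            break

    # (b) excess similarity: cross-species TE distance far below the
    # within-species scale, for hosts more divergent than that distance.
    within: list[float] = []
    n = len(te_pd.ids)
    for i, j in itertools.combinations(range(n), 2):
        if species_of[te_pd.ids[i]] == species_of[te_pd.ids[j]]:
            within.append(te_pd.matrix[i, j])
    if within:
        med_within = float(np.median(within))
        seen_pairs = set()
        for i, j in itertools.combinations(range(n), 2):
            sa, sb = species_of[te_pd.ids[i]], species_of[te_pd.ids[j]]
            if sa == sb or frozenset((sa, sb)) in seen_pairs:
                continue
            ia = [k for k in range(n) if species_of[te_pd.ids[k]] == sa]
            ib = [k for k in range(n) if species_of[te_pd.ids[k]] == sb]
            dmin = min(te_pd.matrix[x, y] for x in ia for y in ib)
            seen_pairs.add(frozenset((sa, sb)))
            # under vertical descent the closest cross-species TE pair is at
            # least as divergent as the hosts; HTT collapses it far below that
            if (dmin < similarity_ratio * med_within
                    and dmin < similarity_ratio * host_div(sa, sb)):
                flags.append(
                    HTTFlag(
                        clade=frozenset(
                            te_pd.ids[k] for k in ia + ib
                        ),
                        evidence="excess_similarity",
                        details={
                            "species_pair": sorted((sa, sb)),
                            "min_cross_distance": dmin,
                            "median_within_distance": med_within,
                            "ratio": dmin / med_within if med_within > 0 else 0.0,
                        },
                    )
                )

    # (c) patchy distribution: subfamily present in a non-monophyletic
    # subset of host lineages.
    if presence_table is not None:
        table = {t: dict(row) for t, row in _iter_presence(presence_table)}
        host_tips = set(tip_labels(host_tree))
        subfams = sorted({sf for row in table.values() for sf in row})
        # rooted-clade semantics: a presence pattern is patchy when the
        # present tips do not form a clade of the (rooted) host tree
        clades = {frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                  for node in host_tree.preorder_node_iter()}
        for sf in subfams:
            present = frozenset(t for t in host_tips if table.get(t, {}).get(sf))
            absent = host_tips - present
            # a single absent tip is parsimoniously one loss event, not a
            # patchy distribution
            if present and len(absent) >= patchy_min_absent and present not in clades:
                flags.append(
                    HTTFlag(
                        clade=present,
                        evidence="patchy_distribution",
                        details={"subfamily": sf, "n_present": len(present),
                                 "n_absent": len(absent)},
                    )
                )
    return flags


def _iter_presence(table):
    """Yield (tip, {subfamily: bool}) from a DataFrame or mapping."""
    if hasattr(table, "iterrows"):  # pandas DataFrame, strains indexed
        for tip, row in table.iterrows():
            yield str(tip), {str(k): bool(v) for k, v in row.items()}
    else:
        for tip, row in table.items():
            yield str(tip), {str(k): bool(v) for k, v in row.items()}
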