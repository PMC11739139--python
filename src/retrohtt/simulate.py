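"""Forward simulator of LTR-retrotransposon family evolution along a host tree.

The simulator evolves a family of Ty1/copia-like elements (5'LTR - internal
gag/pol region - 3'LTR) along a rooted host strain tree under a Kimura
2-parameter substitution process, with per-element stochastic events:

* transposition      — a new copy is created from an existing element;
* solo-LTR formation — intra-element recombination between the two LTRs
                       excises the internal region, leaving a single LTR;
* truncation         — a contiguous terminal portion of the element is lost;
* loss               — the whole copy is deleted;
* HTT                — an element state is copied from a donor branch into a
                       recipient branch at a stated time (horizontal transfer);
* recombination      — a chimeric element is formed from two co-occurring
                       subfamilies with stated internal breakpoints.

Substitution is gap-free (no indels), so the true homology alignment of all
internal regions is simply the column-wise stack of their full-length
internal sequences (with 'N' padding over truncated portions).  Every event
is recorded in an :class:`EventLog` and the tip states form a
:class:`TruthSet` against which every downstream stage can be scored.
"""
from __future__ import annotations

import copy
import graphlib
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .models import DepthProfile, TEQueryModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes.astype(np.int64)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=length))


def k2p_substitution_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P, Q): per-site transition / transversion substitution probabilities
    after branch length ``t`` (expected substitutions/site), given the
    transition/transversion rate ratio ``kappa``.  Rates are normalized so
    that ``alpha + 2*beta = 1``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_bb = np.exp(-4.0 * beta * t)
    e_ab = np.exp(-2.0 * (alpha + beta) * t)
    P = 0.25 + 0.25 * e_bb - 0.5 * e_ab
    Q = 0.5 - 0.5 * e_bb
    return float(P), float(Q)


def evolve_sequence(seq: str, t: float, kappa: float = 2.0, seed=None) -> str:
    """Evolve ``seq`` for branch length ``t`` under the K2P model.

    ``seed`` may be an integer or a live ``numpy`` Generator.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _encode(seq)
    if t == 0:
        return _decode(codes)
    P, Q = k2p_substitution_probs(t, kappa)
    u = rng.random(len(codes))
    ts_mask = u < P
    tv_mask = (u >= P) & (u < P + Q)
    out = codes.copy()
    out[ts_mask] = _TRANSITION[codes[ts_mask]]
    if tv_mask.any():
        which = rng.integers(0, 2, size=int(tv_mask.sum()))
        out[tv_mask] = _TRANSVERSION[codes[tv_mask], which]
    return _decode(out)


def make_query_model(
    query_id: str,
    ltr_len: int = 300,
    internal_len: int = 4000,
    seed: int = 0,
    tsd_motif: str = "tgca",
) -> TEQueryModel:
    """Random full-length element model with identical LTRs and terminal motif."""
    rng = np.random.default_rng(seed)
    ltr = random_sequence(ltr_len, rng)
    motif = tsd_motif.upper()
    # canonical LTR termini: element starts TG... ends ...CA
    ltr = motif[:2] + ltr[2:-2] + motif[2:]
    internal = random_sequence(internal_len, rng)
    seq = ltr + internal + ltr
    return TEQueryModel(
        query_id=query_id,
        sequence=seq,
        regions={
            "ltr5": (0, ltr_len),
            "internal": (ltr_len, ltr_len + internal_len),
            "ltr3": (ltr_len + internal_len, 2 * ltr_len + internal_len),
        },
    )


def diverged_subfamily(
    model: TEQueryModel, query_id: str, divergence: float, kappa: float = 2.0, seed: int = 1
) -> TEQueryModel:
    """A sister subfamily: same region structure, sequence evolved by
    ``divergence`` expected substitutions/site from ``model``."""
    seq = evolve_sequence(model.sequence, divergence, kappa, seed)
    return TEQueryModel(query_id=query_id, sequence=seq, regions=dict(model.regions))


# ---------------------------------------------------------------------------
# host tree


@dataclass
class StrainTree:
    tree: dendropy.Tree  # rooted, binary, branch lengths in subs/site
    lineage_labels: dict[str, str] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_host_tree(
    n_strains: int, depth_scale: float, seed: int, n_lineages: int = 1
) -> StrainTree:
    """Random rooted binary strain tree by sequential random coalescence.

    Branch lengths are exponential with mean ``depth_scale`` (expected
    substitutions/site).  With ``n_lineages == 2``, tips are labeled by the
    root-split subtree they fall in (``L1``/``L2``) and the root edges are
    stretched so the two lineages are well separated.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()

    def _coalesce(tips: list[str]) -> dendropy.Node:
        nodes = []
        for name in tips:
            taxon = tns.new_taxon(label=name)
            node = dendropy.Node(taxon=taxon)
            node.edge.length = float(rng.exponential(depth_scale))
            nodes.append(node)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            parent.edge.length = float(rng.exponential(depth_scale))
            parent.add_child(nodes[i])
            parent.add_child(nodes[j])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        return nodes[0]

    labels: dict[str, str] = {}
    if n_lineages > 1 and n_strains >= 2 * n_lineages:
        # balanced lineage subtrees joined by a caterpillar of deep branches
        sizes = [n_strains // n_lineages] * n_lineages
        for i in range(n_strains % n_lineages):
            sizes[i] += 1
        start = 0
        subroots = []
        for li, size in enumerate(sizes, start=1):
            tips = [f"s{i:02d}" for i in range(start, start + size)]
            start += size
            sub = _coalesce(tips)
            sub.edge.length += 2.0 * depth_scale
            subroots.append(sub)
            labels |= {t: f"L{li}" for t in tips}
        root = subroots[0]
        for sub in subroots[1:]:
            new = dendropy.Node()
            new.add_child(root)
            new.add_child(sub)
            root.edge.length = float(rng.exponential(depth_scale)) + 2.0 * depth_scale
            root = new
    else:
        root = _coalesce([f"s{i:02d}" for i in range(n_strains)])
        labels = {f"s{i:02d}": "L1" for i in range(n_strains)}
    root.edge.length = 0.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    # deterministic internal-node labels for addressing branches
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None:
            node.label = f"n{k}"
            k += 1
    return StrainTree(tree=tree, lineage_labels=labels)


# ---------------------------------------------------------------------------
# family history


@dataclass
class EvolutionParams:
    kappa: float = 2.0
    sub_rate: float = 1.0  # substitutions/site per branch-length unit
    transposition_rate: float = 0.0  # events per element per branch-length unit
    solo_ltr_rate: float = 0.0
    truncation_rate: float = 0.0
    loss_rate: float = 0.0
    htt_events: list[dict] = field(default_factory=list)
    # each: {donor: branch, recipient: branch, time: fraction, subfamily: optional}
    recomb_events: list[dict] = field(default_factory=list)
    # each: {branch, time, subfamily_a, subfamily_b, breakpoints: [...], subfamily_out}
    subfamily_loss_events: list[dict] = field(default_factory=list)
    # each: {branch, subfamily, time}: lineage-specific subfamily extinction
    seed: int = 0

    def validate(self, branch_ids: set[str]) -> None:
        for name in ("sub_rate", "transposition_rate", "solo_ltr_rate",
                     "truncation_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for ev in self.htt_events:
            for key in ("donor", "recipient"):
                if ev[key] not in branch_ids:
                    raise ValueError(f"htt event references unknown branch {ev[key]!r}")
            if not (0.0 <= ev.get("time", 0.5) <= 1.0):
                raise ValueError("htt time must be a fraction of the branch")
        for ev in self.recomb_events:
            if ev["branch"] not in branch_ids:
                raise ValueError(f"recomb event references unknown branch {ev['branch']!r}")
            bps = list(ev["breakpoints"])
            if not bps or any(b >= c for b, c in zip(bps, bps[1:])):
                raise ValueError("breakpoints must be non-empty and strictly increasing")
        for ev in self.subfamily_loss_events:
            if ev["branch"] not in branch_ids:
                raise ValueError(f"loss event references unknown branch {ev['branch']!r}")


@dataclass
class Event:
    kind: str  # transposition | solo_ltr | truncation | loss | htt | recombination
    branch: str
    time: float  # fraction along the branch
    element_ids: list[str]
    breakpoints: list[int] = field(default_factory=list)


@dataclass
class SimElement:
    """One element copy during simulation.  Sequences are kept full-length
    (coordinates anchored to the subfamily reference); ``retained`` records
    which region-local interval survives truncation / solo-LTR formation."""

    element_id: str
    subfamily: str
    seqs: dict[str, str]  # ltr5 / internal / ltr3, full-length
    retained: dict[str, tuple[int, int]]
    source: str = "vertical"  # vertical | htt | recomb
    breakpoints: list[int] = field(default_factory=list)

    def region_len(self, region: str) -> int:
        return len(self.seqs[region])

    def retained_frac(self, region: str) -> float:
        a, b = self.retained[region]
        return (b - a) / self.region_len(region)

    @property
    def element_class(self) -> str:
        f5, fi, f3 = (self.retained_frac(r) for r in ("ltr5", "internal", "ltr3"))
        n_full_ltr = (f5 >= 0.999) + (f3 >= 0.999)
        if fi >= 0.999 and n_full_ltr == 2:
            return "FLE"
        if fi <= 0.001 and ((f5 >= 0.999 and f3 <= 0.001) or (f3 >= 0.999 and f5 <= 0.001)):
            return "solo_LTR"
        return "truncated"

    def retained_sequence(self) -> str:
        parts = []
        for region in ("ltr5", "internal", "ltr3"):
            a, b = self.retained[region]
            parts.append(self.seqs[region][a:b])
        return "".join(parts)

    def total_retained_len(self) -> int:
        return sum(b - a for a, b in self.retained.values())


def solo_ltr_element(el: SimElement) -> None:
    """Intra-element LTR-LTR recombination: excise internal + 3'LTR in place."""
    el.retained["internal"] = (0, 0)
    el.retained["ltr3"] = (0, 0)
    el.retained["ltr5"] = (0, el.region_len("ltr5"))


def truncate_element(el: SimElement, frac: float, five_prime: bool) -> None:
    """Remove the terminal ``frac`` of the element from the stated end."""
    total = sum(el.region_len(r) for r in ("ltr5", "internal", "ltr3"))
    cut = int(frac * total)
    offsets = {"ltr5": 0, "internal": el.region_len("ltr5"),
               "ltr3": el.region_len("ltr5") + el.region_len("internal")}
    if five_prime:
        pos = cut
        for region in ("ltr5", "internal", "ltr3"):
            a, b = el.retained[region]
            el.retained[region] = (max(a, min(b, pos - offsets[region])), b)
    else:
        pos = total - cut
        for region in ("ltr5", "internal", "ltr3"):
            a, b = el.retained[region]
            el.retained[region] = (a, min(b, max(a, pos - offsets[region])))


def _full_element(model: TEQueryModel, element_id: str) -> SimElement:
    return SimElement(
        element_id=element_id,
        subfamily=model.query_id,
        seqs={r: model.region_seq(r) for r in ("ltr5", "internal", "ltr3")},
        retained={r: (0, len(model.region_seq(r))) for r in ("ltr5", "internal", "ltr3")},
    )


@dataclass
class TruthSet:
    query_models: dict[str, TEQueryModel]
    host: StrainTree
    elements: dict[str, list[SimElement]]  # strain -> inventory

    def copy_number(self, strain: str, subfamily: str) -> tuple[float, float]:
        """(cn_ltr, cn_internal): expected depth-ratio copy numbers, i.e. the
        summed retained fraction of the LTR union / internal region."""
        model = self.query_models[subfamily]
        ltr_total = sum(
            model.regions[r][1] - model.regions[r][0] for r in ("ltr5", "ltr3")
        )
        cn_ltr = cn_int = 0.0
        for el in self.elements[strain]:
            if el.subfamily != subfamily:
                continue
            ltr_kept = sum(b - a for r in ("ltr5", "ltr3") for a, b in [el.retained[r]])
            cn_ltr += ltr_kept / ltr_total
            cn_int += el.retained_frac("internal")
        return cn_ltr, cn_int

    def class_counts(self, strain: str, subfamily: str | None = None) -> dict[str, int]:
        counts = {"FLE": 0, "truncated": 0, "solo_LTR": 0}
        for el in self.elements[strain]:
            if subfamily is None or el.subfamily == subfamily:
                counts[el.element_class] += 1
        return counts

    def internal_alignment(self, subfamilies=None, min_frac: float = 0.0) -> dict[str, str]:
        """Gap-free truth alignment of internal regions ('N' over truncated
        spans), keyed ``strain|element_id``.  Requires equal internal lengths
        across the included subfamilies."""
        rows: dict[str, str] = {}
        lengths = set()
        for strain, inv in self.elements.items():
            for el in inv:
                if subfamilies is not None and el.subfamily not in subfamilies:
                    continue
                if el.retained_frac("internal") <= min_frac:
                    continue
                a, b = el.retained["internal"]
                seq = "N" * a + el.seqs["internal"][a:b] + "N" * (len(el.seqs["internal"]) - b)
                rows[f"{strain}|{el.element_id}"] = seq
                lengths.add(len(seq))
        if len(lengths) > 1:
            raise ValueError("internal regions of requested subfamilies differ in length")
        return rows


def lineage_root_branch(host: StrainTree, lineage: str) -> str:
    """Branch id (node label) of the smallest clade holding all of a lineage's tips."""
    tips = {t for t, l in host.lineage_labels.items() if l == lineage}
    if not tips:
        raise ValueError(f"unknown lineage {lineage!r}")
    mrca = host.tree.mrca(taxon_labels=tips)
    return mrca.taxon.label if mrca.taxon is not None else mrca.label


def _branch_ids(host: StrainTree) -> dict[str, dendropy.Node]:
    out = {}
    for node in host.tree.preorder_node_iter():
        key = node.taxon.label if node.taxon is not None else node.label
        out[key] = node
    return out


def simulate_family_history(
    host: StrainTree,
    params: EvolutionParams,
    root_elements: list[TEQueryModel],
) -> tuple[TruthSet, list[Event]]:
    """Evolve the root element inventory down the host tree.

    Returns the tip-state :class:`TruthSet` and the ordered :class:`Event`
    log.  Branches are addressed by the label of the node below them (tip
    name or ``n<k>`` internal label); HTT donor branches are always processed
    before their recipients, so a transfer copies the donor's element state
    at the stated time fraction of the donor branch.
    """
    if not root_elements:
        raise ValueError("root_elements must be non-empty")
    nodes = _branch_ids(host)
    params.validate(set(nodes))
    rng = np.random.default_rng(params.seed)
    counter = itertools.count()

    def new_id() -> str:
        return f"e{next(counter):04d}"

    models = {m.query_id: m for m in root_elements}
    root_inv = [_full_element(m, new_id()) for m in root_elements]

    # processing order: parents before children, donors before recipients
    order_edges: dict[str, set[str]] = {k: set() for k in nodes}
    for key, node in nodes.items():
        for child in node.child_nodes():
            ck = child.taxon.label if child.taxon is not None else child.label
            order_edges[ck].add(key)
    for ev in params.htt_events:
        order_edges[ev["recipient"]].add(ev["donor"])
    try:
        topo = list(graphlib.TopologicalSorter(order_edges).static_order())
    except graphlib.CycleError as exc:
        raise ValueError("cyclic HTT donor/recipient dependencies") from exc

    htt_by_donor: dict[str, list[tuple[int, dict]]] = {}
    htt_by_recipient: dict[str, list[tuple[int, dict]]] = {}
    for idx, ev in enumerate(params.htt_events):
        htt_by_donor.setdefault(ev["donor"], []).append((idx, ev))
        htt_by_recipient.setdefault(ev["recipient"], []).append((idx, ev))
    recomb_by_branch: dict[str, list[dict]] = {}
    for ev in params.recomb_events:
        recomb_by_branch.setdefault(ev["branch"], []).append(ev)
    subloss_by_branch: dict[str, list[dict]] = {}
    for ev in params.subfamily_loss_events:
        subloss_by_branch.setdefault(ev["branch"], []).append(ev)

    snapshots: dict[int, SimElement] = {}
    inventories: dict[str, list[SimElement]] = {}
    parent_key = {}
    for key, node in nodes.items():
        p = node.parent_node
        parent_key[key] = None if p is None else (
            p.taxon.label if p.taxon is not None else p.label
        )
    log: list[Event] = []

    def _evolve_inventory(inv: list[SimElement], dt: float) -> None:
        if dt <= 0:
            return
        t = dt * params.sub_rate
        for el in inv:
            for region in el.seqs:
                el.seqs[region] = evolve_sequence(el.seqs[region], t, params.kappa, rng)

    def _apply_stochastic(el: SimElement, kind: str, inv: list[SimElement],
                          branch: str, time: float) -> None:
        if kind == "transposition":
            if el.retained_frac("internal") < 0.999:
                return  # only intact internal regions encode transposition machinery
            child = copy.deepcopy(el)
            child.element_id = new_id()
            child.source = el.source
            inv.append(child)
            log.append(Event("transposition", branch, time, [el.element_id, child.element_id]))
        elif kind == "solo_ltr":
            if el.retained_frac("ltr5") < 0.999 or el.retained_frac("ltr3") < 0.999:
                return  # needs both LTRs to recombine
            solo_ltr_element(el)
            log.append(Event("solo_ltr", branch, time, [el.element_id]))
        elif kind == "truncation":
            if el.element_class == "solo_LTR":
                return
            truncate_element(el, float(rng.uniform(0.2, 0.7)), rng.random() < 0.5)
            log.append(Event("truncation", branch, time, [el.element_id]))
        elif kind == "loss":
            inv.remove(el)
            log.append(Event("loss", branch, time, [el.element_id]))

    for key in topo:
        node = nodes[key]
        pk = parent_key[key]
        inv = copy.deepcopy(root_inv if pk is None else inventories[pk])
        blen = float(node.edge.length or 0.0)
        branch = key

        timeline: list[tuple[float, str, object]] = []
        if blen > 0:
            rates = {
                "transposition": params.transposition_rate,
                "solo_ltr": params.solo_ltr_rate,
                "truncation": params.truncation_rate,
                "loss": params.loss_rate,
            }
            for el in inv:
                for kind, rate in rates.items():
                    if rate <= 0:
                        continue
                    for _ in range(rng.poisson(rate * blen)):
                        timeline.append((float(rng.uniform(0, 1)), kind, el.element_id))
        for idx, ev in htt_by_donor.get(key, []):
            timeline.append((float(ev.get("time", 0.5)), "htt_out", idx))
        for idx, ev in htt_by_recipient.get(key, []):
            timeline.append((float(ev.get("time", 0.5)), "htt_in", idx))
        for ev in recomb_by_branch.get(key, []):
            timeline.append((float(ev.get("time", 0.5)), "recombination", ev))
        for ev in subloss_by_branch.get(key, []):
            timeline.append((float(ev.get("time", 0.1)), "subfamily_loss", ev))
        timeline.sort(key=lambda x: (x[0], str(x[1])))

        t_prev = 0.0
        for t_frac, kind, payload in timeline:
            _evolve_inventory(inv, (t_frac - t_prev) * blen)
            t_prev = t_frac
            if kind in ("transposition", "solo_ltr", "truncation", "loss"):
                el = next((e for e in inv if e.element_id == payload), None)
                if el is not None:
                    _apply_stochastic(el, kind, inv, branch, t_frac)
            elif kind == "subfamily_loss":
                gone = [e for e in inv if e.subfamily == payload["subfamily"]]
                for e in gone:
                    inv.remove(e)
                if gone:
                    log.append(Event("loss", branch, t_frac,
                                     [e.element_id for e in gone]))
            elif kind == "htt_out":
                ev = params.htt_events[payload]
                wanted = ev.get("subfamily")
                pool = [e for e in inv
                        if (wanted is None or e.subfamily == wanted)
                        and e.element_class == "FLE"]
                if not pool:
                    pool = [e for e in inv if wanted is None or e.subfamily == wanted]
                if not pool:
                    raise ValueError(
                        f"htt event {payload}: no element of subfamily {wanted!r} "
                        f"on donor branch {branch!r}"
                    )
                snapshots[payload] = copy.deepcopy(pool[int(rng.integers(len(pool)))])
            elif kind == "htt_in":
                src = snapshots[payload]
                el = copy.deepcopy(src)
                el.element_id = new_id()
                el.source = "htt"
                inv.append(el)
                log.append(Event("htt", branch, t_frac, [src.element_id, el.element_id]))
            elif kind == "recombination":
                ev = payload
                def _parent_pool(subfam: str) -> list[SimElement]:
                    full = [e for e in inv if e.subfamily == subfam
                            and e.retained_frac("internal") >= 0.999]
                    # sequences are tracked full-length even for truncated
                    # copies, so any surviving copy can donate its subfamily's
                    # internal state when no intact element remains
                    return full or [e for e in inv if e.subfamily == subfam]

                pa = _parent_pool(ev["subfamily_a"])
                pb = _parent_pool(ev["subfamily_b"])
                if not pa or not pb:
                    raise ValueError(
                        f"recombination on branch {branch!r}: parent subfamilies "
                        f"{ev['subfamily_a']!r}/{ev['subfamily_b']!r} not both present"
                    )
                a = pa[int(rng.integers(len(pa)))]
                b = pb[int(rng.integers(len(pb)))]
                bps = [int(x) for x in ev["breakpoints"]]
                int_len = a.region_len("internal")
                if b.region_len("internal") != int_len:
                    raise ValueError("recombining subfamilies must share internal length")
                if bps[0] <= 0 or bps[-1] >= int_len:
                    raise ValueError("breakpoints must lie strictly inside the internal region")
                bounds = [0] + bps + [int_len]
                parts = []
                for i in range(len(bounds) - 1):
                    donor = a if i % 2 == 0 else b
                    parts.append(donor.seqs["internal"][bounds[i]:bounds[i + 1]])
                chimera = copy.deepcopy(a)
                chimera.element_id = new_id()
                chimera.subfamily = ev.get("subfamily_out", f"{a.subfamily}x{b.subfamily}")
                chimera.seqs["internal"] = "".join(parts)
                chimera.retained = {r: (0, chimera.region_len(r))
                                    for r in ("ltr5", "internal", "ltr3")}
                chimera.source = "recomb"
                chimera.breakpoints = bps
                inv.append(chimera)
                log.append(Event("recombination", branch, t_frac,
                                 [a.element_id, b.element_id, chimera.element_id], bps))
        _evolve_inventory(inv, (1.0 - t_prev) * blen)
        inventories[key] = inv

    tip_inventories = {s: inventories[s] for s in host.strains}
    # chimeras inherit region structure from parent A; register their model so
    # downstream stages can resolve coordinates
    for inv in tip_inventories.values():
        for el in inv:
            if el.subfamily not in models:
                base = next(iter(models.values()))
                models[el.subfamily] = TEQueryModel(
                    query_id=el.subfamily,
                    sequence=el.seqs["ltr5"] + el.seqs["internal"] + el.seqs["ltr3"],
                    regions=dict(base.regions),
                )
    truth = TruthSet(query_models=models, host=host, elements=tip_inventories)
    return truth, log


# ---------------------------------------------------------------------------
# genome / depth / hit-table emission


@dataclass
class PlacedElement:
    element: SimElement
    start: int  # genome coords, 0-based half-open
    end: int
    strand: str
    query_span: tuple[int, int]  # interval on the subfamily query covered

    def bed_row(self, strain: str) -> tuple:
        return (strain, self.start, self.end,
                f"{self.element.element_id}|{self.element.subfamily}|{self.element.element_class}",
                0, self.strand)


@dataclass
class StrainGenome:
    strain_id: str
    sequence: str
    placements: list[PlacedElement]


def _query_span(el: SimElement, model: TEQueryModel) -> tuple[int, int]:
    """Query interval covered by the retained (contiguous) element span."""
    offsets = {"ltr5": model.regions["ltr5"][0],
               "internal": model.regions["internal"][0],
               "ltr3": model.regions["ltr3"][0]}
    starts, ends = [], []
    for region in ("ltr5", "internal", "ltr3"):
        a, b = el.retained[region]
        if b > a:
            starts.append(offsets[region] + a)
            ends.append(offsets[region] + b)
    return (min(starts), max(ends)) if starts else (0, 0)


def emit_genome(
    strain_id: str,
    inventory: list[SimElement],
    models: dict[str, TEQueryModel],
    background_length: int,
    seed: int,
    margin: int = 300,
) -> StrainGenome:
    """Embed each element at a unique random locus in i.i.d. background
    sequence; minus-strand elements are inserted as reverse complements."""
    rng = np.random.default_rng(seed)
    total_el = sum(el.total_retained_len() for el in inventory)
    if background_length <= total_el + margin * (len(inventory) + 1):
        raise ValueError("background_length too small for the element inventory")
    background = random_sequence(background_length, rng)
    # choose insertion points with a minimum background separation
    n = len(inventory)
    points: list[int] = []
    for _ in range(100):
        points = sorted(int(p) for p in rng.choice(
            np.arange(margin, background_length - margin), size=n, replace=False))
        if all(b - a >= margin for a, b in zip(points, points[1:])):
            break
    else:
        raise ValueError("could not place elements without overlap; "
                         "increase background_length")
    pieces, placements = [], []
    cursor = 0
    genome_pos = 0
    for el, point in zip(inventory, points):
        pieces.append(background[cursor:point])
        genome_pos += point - cursor
        seq = el.retained_sequence()
        strand = "+" if rng.random() < 0.5 else "-"
        ins = seq if strand == "+" else reverse_complement(seq)
        placements.append(PlacedElement(
            element=el, start=genome_pos, end=genome_pos + len(ins), strand=strand,
            query_span=_query_span(el, models[el.subfamily]),
        ))
        pieces.append(ins)
        genome_pos += len(ins)
        cursor = point
    pieces.append(background[cursor:])
    return StrainGenome(strain_id=strain_id, sequence="".join(pieces),
                        placements=placements)


def simulate_depth(
    genome: StrainGenome,
    query: TEQueryModel,
    fold_coverage: float,
    read_len: int = 100,
    err: float = 0.0,
    seed: int = 0,
) -> tuple[DepthProfile, np.ndarray]:
    """Sample uniform-start reads and project depth onto query coordinates.

    Reads are not aligned: placement uses the truth homology map (each
    element copy's genome span maps linearly onto its query span).  Returns
    the :class:`DepthProfile` (baseline = mean depth over single-copy
    background) and an ``(L, 4)`` A/C/G/T base-count matrix for consensus
    building, with symmetric read errors at rate ``err``.
    """
    if fold_coverage <= 0:
        raise ValueError("fold_coverage must be positive")
    if not (0 <= err < 0.5):
        raise ValueError("err must be in [0, 0.5)")
    G = len(genome.sequence)
    if read_len >= G:
        raise ValueError("read_len must be shorter than the genome")
    rng = np.random.default_rng(seed)
    n_reads = int(round(fold_coverage * G / read_len))
    starts = rng.integers(0, G - read_len + 1, size=n_reads)
    cov_diff = np.zeros(G + 1, dtype=np.int64)
    np.add.at(cov_diff, starts, 1)
    np.add.at(cov_diff, starts + read_len, -1)
    cov = np.cumsum(cov_diff[:-1])

    is_te = np.zeros(G, dtype=bool)
    for pl in genome.placements:
        is_te[pl.start:pl.end] = True
    background_cov = cov[~is_te]
    baseline = float(background_cov.mean()) if background_cov.size else float(cov.mean())

    L = query.length
    depth = np.zeros(L, dtype=np.int64)
    counts = np.zeros((L, 4), dtype=np.int64)
    for pl in genome.placements:
        if pl.element.subfamily != query.query_id:
            continue
        qa, qb = pl.query_span
        span = pl.end - pl.start
        if span != qb - qa or span == 0:
            continue
        seg = cov[pl.start:pl.end]
        if pl.strand == "-":
            seg = seg[::-1]
        depth[qa:qb] += seg
        # true bases of this copy over its query span (plus-strand frame)
        el_seq = pl.element.retained_sequence()
        codes = _encode(el_seq)
        if err > 0:
            flip = rng.random(span) < err
            if flip.any():
                shift = rng.integers(1, 4, size=int(flip.sum()))
                codes[flip] = (codes[flip] + shift) % 4
        np.add.at(counts, (np.arange(qa, qb), codes), seg)
    profile = DepthProfile(query_id=query.query_id, depth=depth,
                           baseline_depth=max(baseline, 1e-9),
                           fold_coverage_original=fold_coverage)
    return profile, counts


def emit_hit_table(
    genome: StrainGenome,
    models: dict[str, TEQueryModel],
    frag_prob: float = 0.0,
    seed: int = 0,
):
    """Homology-hit rows for each placed element (emulating the output of a
    repeat-annotation search).  With probability ``frag_prob`` an element's
    hit is split into two collinear rows separated by a gap, exercising
    downstream defragmentation.  Returns a pandas DataFrame with columns
    (target_seq, t_start, t_end, strand, query_id, q_start, q_end, pct_div).
    """
    import pandas as pd

    if not (0.0 <= frag_prob <= 1.0):
        raise ValueError("frag_prob must be a probability")
    rng = np.random.default_rng(seed)
    rows = []
    for pl in genome.placements:
        el = pl.element
        model = models[el.subfamily]
        qa, qb = pl.query_span
        span = pl.end - pl.start
        if span == 0:
            continue
        el_seq = pl.element.retained_sequence()
        ref_seq = model.sequence[qa:qb]
        mism = sum(1 for x, y in zip(el_seq, ref_seq) if x != y)
        pct_div = round(100.0 * mism / max(len(ref_seq), 1), 2)
        split = rng.random() < frag_prob and span > 400
        if split:
            cut = int(rng.integers(int(span * 0.3), int(span * 0.7)))
            gap = int(rng.integers(30, 120))
            gap = min(gap, span - cut - 1)
            segments = [(0, cut), (cut + gap, span)]
        else:
            segments = [(0, span)]
        for a, b in segments:
            if pl.strand == "+":
                q0, q1 = qa + a, qa + b
            else:
                q0, q1 = qa + (span - b), qa + (span - a)
            rows.append({
                "target_seq": genome.strain_id,
                "t_start": pl.start + a,
                "t_end": pl.start + b,
                "strand": pl.strand,
                "query_id": el.subfamily,
                "q_start": q0,
                "q_end": q1,
                "pct_div": pct_div,
            })
    return pd.DataFrame(rows, columns=["target_seq", "t_start", "t_end", "strand",
                                       "query_id", "q_start", "q_end", "pct_div"])
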