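"""Truth-scored evaluation experiments over the simulator.

Each function runs one calibration/validation experiment end to end —
generating synthetic data with known ground truth, running the relevant
analysis stage, and scoring the result against that truth — and returns a
dict of summary metrics.  These experiments back both the test suite and
the reproduction script; problem sizes are chosen so the full battery runs
in a few minutes on one CPU.
"""
from __future__ import annotations

import copy as _copy
import math

import numpy as np

from . import annotate, consensus, coverage, divergence, phylo, pipeline, simulate


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31 - 1)
            for s in np.random.SeedSequence(seed).generate_state(n).tolist()]


# ---------------------------------------------------------------------------
# K2P engine


def k2p_worked_example() -> dict:
    """Distance for the textbook pair P=0.1, Q=0.05 (20 sites: 2 transitions,
    1 transversion) against the closed form."""
    a = "ACGT" * 5
    b = "GTT" + a[3:]  # A->G, C->T transitions; G->T transversion
    res = divergence.k2p(a, b)
    expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
    return {
        "P": res.P, "Q": res.Q, "d": res.d,
        "expected_d": expected,
        "abs_error": abs(res.d - expected),
        "n": res.n_sites,
    }


def k2p_symmetry_check(n_pairs: int = 100, length: int = 500, seed: int = 0) -> dict:
    """Max |d(a,b) - d(b,a)| and max pairwise-deletion shift over random pairs."""
    rng = np.random.default_rng(seed)
    max_asym = 0.0
    max_del_shift = 0.0
    for _ in range(n_pairs):
        a = simulate.random_sequence(length, rng)
        b = simulate.evolve_sequence(a, float(rng.uniform(0.01, 0.3)), 2.0, rng)
        dab = divergence.k2p(a, b).d
        dba = divergence.k2p(b, a).d
        max_asym = max(max_asym, abs(dab - dba))
        # appending N columns must not change the distance
        d_pad = divergence.k2p(a + "N" * 10, b + "N" * 10).d
        max_del_shift = max(max_del_shift, abs(dab - d_pad))
    return {"max_asymmetry": max_asym, "max_pairwise_deletion_shift": max_del_shift,
            "n": n_pairs}


# ---------------------------------------------------------------------------
# NJ / BIONJ


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary topology with branch lengths; returns (tree, ids, matrix)."""
    import dendropy

    ids = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in ids]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pd = phylo.patristic_distances(tree)
    return tree, pd.ids, pd.matrix


def nj_additive_recovery(n_trees: int = 50, n_taxa: int = 6, seed: int = 0,
                         variant: str = "classic") -> dict:
    """Fraction of random additive matrices whose generating tree NJ recovers
    exactly (topology via RF = 0, path lengths to 1e-9)."""
    rng = np.random.default_rng(seed)
    exact = 0
    max_len_err = 0.0
    for _ in range(n_trees):
        true_tree, ids, matrix = random_additive_tree(n_taxa, rng)
        est = phylo.nj_tree(phylo.DistanceMatrix(ids=ids, matrix=matrix),
                            variant=variant)
        rf = phylo.rf_distance(true_tree, est)
        est_pd = phylo.patristic_distances(est)
        err = float(np.max(np.abs(est_pd.matrix - matrix)))
        max_len_err = max(max_len_err, err)
        exact += (rf == 0 and err < 1e-9)
    return {"exact_fraction": exact / n_trees, "max_path_length_error": max_len_err,
            "n": n_trees}


# ---------------------------------------------------------------------------
# copy number


def copy_number_recovery(
    k_values: tuple[int, ...] = (0, 1, 5, 20),
    n_rep: int = 20,
    fold_coverage: float = 30.0,
    seed: int = 0,
    ltr_len: int = 100,
    internal_len: int = 1000,
) -> dict:
    """Depth-ratio copy-number recovery over a ladder of true copy counts.

    Each replicate embeds ``k`` copies of an element (each ~5% diverged from
    the query) in random background, samples reads and scores the normalized
    depth estimate and the derived presence call against truth.
    """
    seeds = iter(_spawn_seeds(seed, len(k_values) * n_rep * 4 + 8))
    model = simulate.make_query_model("Q", ltr_len, internal_len, seed=next(seeds))
    rel_errors: dict[int, list[float]] = {k: [] for k in k_values}
    zero_estimates: list[float] = []
    presence_ok = presence_total = 0
    monotone_ok = 0
    for rep in range(n_rep):
        ladder = []
        for k in k_values:
            rng = np.random.default_rng(next(seeds))
            inventory = []
            for c in range(k):
                el = simulate._full_element(model, f"e{rep}_{k}_{c}")
                t = float(rng.uniform(0.02, 0.08))
                for region in el.seqs:
                    el.seqs[region] = simulate.evolve_sequence(
                        el.seqs[region], t, 2.0, rng)
                inventory.append(el)
            genome = simulate.emit_genome(
                f"s{rep}", inventory, {"Q": model},
                background_length=60_000 + k * 2 * model.length,
                seed=next(seeds))
            profile, _ = simulate.simulate_depth(
                genome, model, fold_coverage, read_len=100, err=0.0,
                seed=next(seeds))
            est = coverage.estimate_strain(f"s{rep}", profile, model.regions)
            ladder.append(est.cn_internal)
            if k == 0:
                zero_estimates.append(est.cn_internal)
            else:
                rel_errors[k].append(abs(est.cn_internal - k) / k)
            presence_total += 1
            presence_ok += ((est.presence_ltr or est.presence_internal) == (k >= 1))
        monotone_ok += all(a <= b + 0.25 for a, b in zip(ladder, ladder[1:]))
    return {
        "median_rel_error": {
            k: float(np.median(v)) for k, v in rel_errors.items() if v},
        "max_zero_estimate": float(max(zero_estimates)) if zero_estimates else 0.0,
        "presence_accuracy": presence_ok / presence_total,
        "monotone_fraction": monotone_ok / n_rep,
        "n": presence_total,
    }


# ---------------------------------------------------------------------------
# annotation


def classification_accuracy(
    n_elements: int = 210,
    n_strains: int = 6,
    max_divergence: float = 0.15,
    frag_prob: float = 0.5,
    seed: int = 0,
    ltr_len: int = 200,
    internal_len: int = 2000,
) -> dict:
    """Element-class recovery (FLE / truncated / solo_LTR) on simulated
    genomes with fragmented hits, scored against truth by locus overlap."""
    seeds = iter(_spawn_seeds(seed, n_strains * 3 + 8))
    model = simulate.make_query_model("Q", ltr_len, internal_len, seed=next(seeds))
    rng = np.random.default_rng(next(seeds))
    correct = total = 0
    counts = {"FLE": 0, "truncated": 0, "solo_LTR": 0}
    per_strain = max(1, n_elements // n_strains)
    for s in range(n_strains):
        inventory = []
        for c in range(per_strain):
            el = simulate._full_element(model, f"e{s}_{c}")
            t = float(rng.uniform(0.01, max_divergence))
            for region in el.seqs:
                el.seqs[region] = simulate.evolve_sequence(el.seqs[region], t, 2.0, rng)
            u = rng.random()
            if u < 0.25:
                simulate.solo_ltr_element(el)
            elif u < 0.5:
                simulate.truncate_element(el, float(rng.uniform(0.2, 0.7)),
                                          bool(rng.random() < 0.5))
            inventory.append(el)
            counts[el.element_class] += 1
        genome = simulate.emit_genome(
            f"s{s}", inventory, {"Q": model},
            background_length=40_000 + 2 * sum(e.total_retained_len()
                                               for e in inventory),
            seed=next(seeds))
        hit_df = simulate.emit_hit_table(genome, {"Q": model}, frag_prob,
                                         seed=next(seeds))
        hits = annotate.parse_hits(hit_df.to_csv(sep="\t", index=False))
        records = annotate.annotate_elements(hits, {"Q": model})
        for rec in records:
            matched = pipeline._match_truth(rec, genome.placements)
            if matched is None:
                continue
            total += 1
            correct += (rec.element_class == matched.element.element_class)
    return {"accuracy": correct / total if total else 0.0, "n": total,
            "true_class_counts": counts}


def ltr_detector_check(
    n_planted: int = 10,
    random_length: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Planted-pair recall and the false-positive count on random sequence.

    Each planted instance is a compliant LTR pair: identical 300-bp repeats
    with tg..ca termini, 5 kb apart, flanked by a 5-bp target-site
    duplication.
    """
    seeds = _spawn_seeds(seed, 4)
    rng = np.random.default_rng(seeds[0])
    pieces, truth_spans = [], []
    cursor = 0
    for _ in range(n_planted):
        gap = int(rng.integers(2_000, 4_000))
        pieces.append(simulate.random_sequence(gap, rng))
        cursor += gap
        ltr = "TG" + simulate.random_sequence(296, rng) + "CA"
        tsd = simulate.random_sequence(5, rng)
        inner = simulate.random_sequence(4_400, rng)
        element = tsd + ltr + inner + ltr + tsd
        truth_spans.append((cursor + 5, cursor + 5 + 300 + 4_400 + 300))
        pieces.append(element)
        cursor += len(element)
    pieces.append(simulate.random_sequence(2_000, rng))
    planted_genome = "".join(pieces)
    cands = annotate.detect_ltr_pairs(planted_genome)
    recall = 0
    for span in truth_spans:
        recall += any(abs(c.full_span[0] - span[0]) <= 5
                      and abs(c.full_span[1] - span[1]) <= 5 for c in cands)
    rng2 = np.random.default_rng(seeds[1])
    random_genome = simulate.random_sequence(random_length, rng2)
    fp = annotate.detect_ltr_pairs(random_genome)
    return {"planted_recall": recall / n_planted, "n_planted": n_planted,
            "n_candidates_planted": len(cands),
            "false_positives_random": len(fp), "random_length": random_length}


# ---------------------------------------------------------------------------
# consensus


def consensus_fidelity(
    fold_coverage: float = 30.0,
    read_error: float = 0.01,
    n_copies: int = 3,
    seed: int = 0,
    ltr_len: int = 200,
    internal_len: int = 2000,
) -> dict:
    """Consensus accuracy for a strain without within-strain variation.

    With error-free reads the consensus must equal the true internal
    sequence at every covered site; with read errors identity should stay
    above 99.9%.  A strain with zero copies must fail the depth/breadth QC.
    """
    seeds = iter(_spawn_seeds(seed, 8))
    model = simulate.make_query_model("Q", ltr_len, internal_len, seed=next(seeds))
    truth_el = simulate._full_element(model, "e0")
    t_seed = next(seeds)
    for region in truth_el.seqs:
        truth_el.seqs[region] = simulate.evolve_sequence(
            truth_el.seqs[region], 0.05, 2.0, np.random.default_rng(t_seed))
    inventory = [_copy.deepcopy(truth_el) for _ in range(n_copies)]
    genome = simulate.emit_genome("s0", inventory, {"Q": model}, 60_000,
                                  seed=next(seeds))
    ia, ib = model.regions["internal"]
    out = {}
    for label, err in (("error_free", 0.0), ("with_error", read_error)):
        profile, base_counts = simulate.simulate_depth(
            genome, model, fold_coverage, read_len=100, err=err, seed=next(seeds))
        pile = consensus.Pileup(query_id="Q", counts=base_counts[ia:ib])
        seq = consensus.majority_consensus(pile)
        truth_seq = truth_el.seqs["internal"]
        covered = [i for i, c in enumerate(seq) if c != "N"]
        matches = sum(seq[i] == truth_seq[i] for i in covered)
        out[label] = {
            "identity": matches / len(covered) if covered else 0.0,
            "covered_fraction": len(covered) / len(seq),
        }
        cn_int = coverage.normalize_copy_number(profile, model.regions["internal"])
        breadth = coverage.compute_breadth(profile, model.regions["internal"])
        out[label]["qc_pass"] = consensus.qc_strain(cn_int, breadth)
    # absence control: genome without any copy
    empty = simulate.emit_genome("s1", [], {"Q": model}, 60_000, seed=next(seeds))
    profile, _ = simulate.simulate_depth(empty, model, fold_coverage,
                                         read_len=100, seed=next(seeds))
    cn_int = coverage.normalize_copy_number(profile, model.regions["internal"])
    breadth = coverage.compute_breadth(profile, model.regions["internal"])
    out["absent_strain_qc_pass"] = consensus.qc_strain(cn_int, breadth)
    out["n"] = internal_len
    return out


# ---------------------------------------------------------------------------
# breakpoints


def breakpoint_recovery(
    n_seeds: int = 20,
    internal_len: int = 4000,
    window: int = 50,
    step: int = 10,
    min_seg: int = 3,
    seed: int = 0,
) -> dict:
    """Planted single- and double-breakpoint chimera recovery.

    Parents are 5-15% diverged sequence pairs; a call within +-``window``
    columns of the planted coordinate counts as recovered.  Pure (non-
    chimeric) candidates must yield zero calls.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    recovered = planted = 0
    false_calls = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        anc = simulate.random_sequence(internal_len, rng)
        div = float(rng.uniform(0.05, 0.15))
        pa = simulate.evolve_sequence(anc, div / 2, 2.0, rng)
        pb = simulate.evolve_sequence(anc, div / 2, 2.0, rng)
        parents = {"A": pa, "B": pb}
        # single breakpoint
        b1 = int(rng.integers(800, internal_len - 800))
        chim1 = pa[:b1] + pb[b1:]
        # double breakpoint bounding a ~2 kb middle segment
        left = int(rng.integers(400, internal_len - 2400))
        b2a, b2b = left, left + 2000
        chim2 = pa[:b2a] + pb[b2a:b2b] + pa[b2b:]
        for chim, truths in ((chim1, [b1]), (chim2, [b2a, b2b])):
            profile = divergence.sliding_window_divergence(chim, parents, window, step)
            call = divergence.infer_breakpoints(profile, min_seg)
            planted += len(truths)
            for t in truths:
                recovered += any(abs(p - t) <= window for p in call.positions)
        # pure candidate: an evolved copy of parent A must produce no call
        pure = simulate.evolve_sequence(pa, 0.01, 2.0, rng)
        profile = divergence.sliding_window_divergence(pure, parents, window, step)
        call = divergence.infer_breakpoints(profile, min_seg)
        false_calls += len(call.positions)
    return {"recovery_rate": recovered / planted, "n": planted,
            "false_calls_on_pure": false_calls, "n_pure": len(seeds)}


# ---------------------------------------------------------------------------
# HTT flagging and partition discordance


def htt_factorial(n_seeds: int = 5, seed: int = 0, config: dict | None = None) -> dict:
    """Factorial flag scan: HTT present/absent x recombination present/absent.

    Sensitivity = fraction of HTT-present runs with any flag; false-flag
    rate = fraction of HTT-absent runs with any flag.
    """
    base = dict(config or {})
    cells = {
        ("htt", "recomb"): "htt_plus_recombinant",
        ("htt", "no_recomb"): "htt_single",
        ("no_htt", "recomb"): "recombinant_only",
        ("no_htt", "no_recomb"): "vertical_only",
    }
    seeds = _spawn_seeds(seed, n_seeds)
    flagged: dict[str, int] = {}
    htt_hits = htt_total = vert_hits = vert_total = 0
    for (htt_state, _), scenario in cells.items():
        count = 0
        for s in seeds:
            cfg = dict(base)
            cfg["scenario"] = scenario
            cfg["seed"] = s
            report = pipeline.run_end_to_end(cfg)
            has_flag = len(report.htt_flags) > 0
            count += has_flag
            if htt_state == "htt":
                htt_total += 1
                htt_hits += has_flag
            else:
                vert_total += 1
                vert_hits += has_flag
        flagged[scenario] = count
    return {
        "sensitivity": htt_hits / htt_total,
        "false_flag_rate": vert_hits / vert_total,
        "flagged_by_scenario": flagged,
        "n": htt_total + vert_total,
    }


def _split_support(tree, side: frozenset) -> float | None:
    """Bootstrap support of the split separating ``side`` from the rest,
    or None when the tree does not contain that split."""
    labels = frozenset(phylo.tip_labels(tree))
    other = labels - side
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if leaves == side or leaves == other:
            sup = phylo._node_support(node)
            return sup if sup is not None else 100.0
    return None


def partition_discordance(
    n_rep: int = 5,
    seed: int = 0,
    min_support: float = 70,
    config: dict | None = None,
) -> dict:
    """Partitioned-tree placement of a single-breakpoint chimera.

    For each replicate, a chimera whose 5' side derives from the Ty4-like
    subfamily and 3' side from the transferred Tsu4-like subfamily is
    analyzed: the alignment is split at the breakpoint and NJ trees with
    bootstrap supports are built per partition.  Success means each
    partition's tree contains a well-supported split placing the chimera on
    the expected parent subfamily's side: with the Ty4-like elements in the
    5' tree and with the Tsu4-like elements in the 3' tree.
    """
    base = dict(config or {})
    base["scenario"] = "htt_plus_recombinant"
    sim_over = dict(base.get("simulate", {}))
    internal_len = sim_over.get(
        "internal_len", pipeline.DEFAULT_CONFIG["simulate"]["internal_len"])
    sim_over["recomb_breakpoints"] = [internal_len // 2]
    base["simulate"] = sim_over
    seeds = _spawn_seeds(seed, 2 * n_rep)
    success = 0
    details = []
    for i in range(n_rep):
        cfg = dict(base)
        cfg["seed"] = seeds[i]
        artifacts = pipeline.run_with_artifacts(cfg)
        truth = artifacts["truth"]
        aln = truth.internal_alignment(min_frac=0.999)
        subfam_of = {f"{s}|{el.element_id}": el.subfamily
                     for s, inv in truth.elements.items() for el in inv}
        chimera_tips = [t for t, sf in subfam_of.items()
                        if sf == "recombinant" and t in aln]
        if not chimera_tips:
            details.append("no chimera with full internal region")
            continue
        tip = chimera_tips[0]
        keep = {t: seq for t, seq in aln.items()
                if subfam_of[t] in ("Ty4L", "Tsu4L") or t == tip}
        bp = internal_len // 2
        spec = divergence.PartitionSpec(intervals={
            "five_prime": (0, bp), "three_prime": (bp, internal_len)})
        parts = divergence.partition_alignment(keep, spec)
        ok = {}
        for name, expected_parent in (("five_prime", "Ty4L"), ("three_prime", "Tsu4L")):
            tree = phylo.bootstrap_support(parts[name], n=100,
                                           seed=seeds[n_rep + i])
            side = frozenset(t for t in keep
                             if subfam_of[t] == expected_parent) | {tip}
            sup = _split_support(tree, frozenset(side))
            ok[name] = sup is not None and sup >= min_support
        success += ok["five_prime"] and ok["three_prime"]
        details.append(ok)
    return {"success_fraction": success / n_rep, "n": n_rep, "details": details}
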