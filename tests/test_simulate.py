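import math

import numpy as np
import pytest

from retrohtt import simulate
from retrohtt.divergence import k2p
from retrohtt.simulate import (
    EvolutionParams,
    emit_genome,
    emit_hit_table,
    evolve_sequence,
    k2p_substitution_probs,
    lineage_root_branch,
    make_query_model,
    reverse_complement,
    simulate_depth,
    simulate_family_history,
    simulate_host_tree,
)


class TestHostTree:
    def test_two_tip_tree_has_positive_branches(self):
        host = simulate_host_tree(2, 0.1, seed=1)
        assert len(host.strains) == 2
        lengths = [leaf.edge.length for leaf in host.tree.leaf_node_iter()]
        assert all(l > 0 for l in lengths)

    def test_deterministic_given_seed(self):
        a = simulate_host_tree(8, 0.1, seed=42).newick()
        b = simulate_host_tree(8, 0.1, seed=42).newick()
        assert a == b

    def test_different_seed_changes_tree(self):
        a = simulate_host_tree(8, 0.1, seed=42).newick()
        b = simulate_host_tree(8, 0.1, seed=43).newick()
        assert a != b

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            simulate_host_tree(1, 0.1, seed=0)

    def test_lineage_labels_partition_tips(self):
        host = simulate_host_tree(9, 0.01, seed=5, n_lineages=3)
        assert set(host.lineage_labels.values()) == {"L1", "L2", "L3"}
        for lineage in ("L1", "L2", "L3"):
            branch = lineage_root_branch(host, lineage)
            tips = {t for t, l in host.lineage_labels.items() if l == lineage}
            mrca = host.tree.mrca(taxon_labels=tips)
            got = {l.taxon.label for l in mrca.leaf_iter()}
            assert got == tips, branch


class TestEvolveSequence:
    def test_zero_branch_length_is_identity(self):
        seq = "ACGTACGTAC"
        assert evolve_sequence(seq, 0.0, 2.0, seed=3) == seq

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGN", 0.1, 2.0, seed=0)

    def test_realized_k2p_distance_within_monte_carlo_error(self, rng):
        # 10 kb at t = 0.10: realized K2P distance within 3 SD of 0.10,
        # with the sampling SD from the K2P large-sample variance formula
        n = 10_000
        seq = simulate.random_sequence(n, rng)
        out = evolve_sequence(seq, 0.10, 2.0, seed=7)
        res = k2p(seq, out)
        c1 = 1.0 / (1.0 - 2.0 * res.P - res.Q)
        c2 = 1.0 / (1.0 - 2.0 * res.Q)
        c3 = 0.5 * (c1 + c2)
        var = (c1 ** 2 * res.P + c3 ** 2 * res.Q
               - (c1 * res.P + c3 * res.Q) ** 2) / n
        assert abs(res.d - 0.10) < 3.0 * math.sqrt(var)

    def test_ts_tv_ratio_matches_k2p_expectation(self, rng):
        # kappa = 2: expected observed transition/transversion proportion
        # ratio follows the closed-form P(t)/Q(t)
        n = 10_000
        t, kappa = 0.1, 2.0
        seq = simulate.random_sequence(n, rng)
        out = evolve_sequence(seq, t, kappa, seed=11)
        res = k2p(seq, out)
        P_exp, Q_exp = k2p_substitution_probs(t, kappa)
        assert res.P / res.Q == pytest.approx(P_exp / Q_exp, rel=0.25)
        # at small t the observed ratio approaches kappa/2
        assert P_exp / Q_exp == pytest.approx(kappa / 2, rel=0.1)

    def test_substitution_probabilities_have_k2p_limits(self):
        P, Q = k2p_substitution_probs(1e3, 2.0)
        assert P == pytest.approx(0.25, abs=1e-6)
        assert Q == pytest.approx(0.5, abs=1e-6)


class TestFamilyHistory:
    def test_null_process_preserves_inventories(self, query_model):
        host = simulate_host_tree(4, 0.02, seed=2)
        params = EvolutionParams(seed=5)
        truth, log = simulate_family_history(host, params, [query_model])
        assert all(e.kind in () for e in log)  # no events at all
        for strain in host.strains:
            inv = truth.elements[strain]
            assert len(inv) == 1
            assert inv[0].element_class == "FLE"

    def test_htt_recipient_closer_to_donor_than_vertical(self, query_model):
        host = simulate_host_tree(9, 0.02, seed=3, n_lineages=3)
        recipient = min(t for t, l in host.lineage_labels.items() if l == "L1")
        params = EvolutionParams(
            seed=5,
            htt_events=[{"donor": lineage_root_branch(host, "L3"),
                         "recipient": recipient, "time": 0.5}],
        )
        truth, log = simulate_family_history(host, params, [query_model])
        htt_events = [e for e in log if e.kind == "htt"]
        assert len(htt_events) == 1
        transferred_id = htt_events[0].element_ids[1]
        aln = truth.internal_alignment()
        t_key = next(k for k in aln if k.endswith(transferred_id))
        donor_keys = [k for k in aln
                      if host.lineage_labels[k.split("|")[0]] == "L3"]
        vertical_keys = [
            k for k in aln
            if host.lineage_labels[k.split("|")[0]] == "L1" and k != t_key]
        d_donor = min(k2p(aln[t_key], aln[k]).d for k in donor_keys)
        d_vert = min(k2p(aln[t_key], aln[k]).d for k in vertical_keys)
        assert d_donor < d_vert

    def test_recombination_creates_exact_chimera_without_substitution(
            self, query_model, sister_model):
        host = simulate_host_tree(4, 0.02, seed=4)
        strain = host.strains[0]
        params = EvolutionParams(
            seed=6, sub_rate=0.0,
            recomb_events=[{"branch": strain, "time": 0.5,
                            "subfamily_a": "Ty4L", "subfamily_b": "Tsu4L",
                            "breakpoints": [700], "subfamily_out": "chimera"}],
        )
        truth, log = simulate_family_history(
            host, params, [query_model, sister_model])
        chim = next(e for e in truth.elements[strain] if e.subfamily == "chimera")
        expected = (query_model.region_seq("internal")[:700]
                    + sister_model.region_seq("internal")[700:])
        assert chim.seqs["internal"] == expected
        assert chim.breakpoints == [700]

    def test_solo_ltr_event_leaves_single_ltr_record(self, query_model):
        host = simulate_host_tree(3, 0.05, seed=8)
        params = EvolutionParams(seed=9, solo_ltr_rate=30.0)
        truth, log = simulate_family_history(host, params, [query_model])
        assert any(e.kind == "solo_ltr" for e in log)
        solos = [el for inv in truth.elements.values() for el in inv
                 if el.element_class == "solo_LTR"]
        assert solos
        for el in solos:
            assert el.retained["internal"] == (0, 0)
            assert el.retained_frac("ltr5") + el.retained_frac("ltr3") == 1.0

    def test_unknown_branch_in_htt_event_rejected(self, query_model):
        host = simulate_host_tree(4, 0.02, seed=2)
        params = EvolutionParams(
            htt_events=[{"donor": "nope", "recipient": host.strains[0]}])
        with pytest.raises(ValueError, match="unknown branch"):
            simulate_family_history(host, params, [query_model])

    def test_ltr_conservation_invariant(self, query_model):
        host = simulate_host_tree(6, 0.03, seed=10)
        params = EvolutionParams(seed=11, transposition_rate=5.0,
                                 solo_ltr_rate=3.0)
        truth, _ = simulate_family_history(host, params, [query_model])
        for strain in host.strains:
            full_ltrs = sum(
                (el.retained_frac("ltr5") >= 0.999)
                + (el.retained_frac("ltr3") >= 0.999)
                for el in truth.elements[strain]
                if el.element_class != "solo_LTR")
            solos = truth.class_counts(strain)["solo_LTR"]
            cn_ltr, _ = truth.copy_number(strain, "Ty4L")
            # every retained LTR contributes half an LTR-pair equivalent
            assert cn_ltr == pytest.approx((full_ltrs + solos) / 2, abs=0.2)

    def test_replay_determinism(self, query_model):
        host = simulate_host_tree(5, 0.02, seed=12)
        params = EvolutionParams(seed=13, transposition_rate=3.0,
                                 truncation_rate=1.0)
        t1, l1 = simulate_family_history(host, params, [query_model])
        t2, l2 = simulate_family_history(host, params, [query_model])
        assert [(e.kind, e.branch, e.element_ids) for e in l1] == \
            [(e.kind, e.branch, e.element_ids) for e in l2]
        for strain in host.strains:
            s1 = [(e.element_id, e.retained_sequence()) for e in t1.elements[strain]]
            s2 = [(e.element_id, e.retained_sequence()) for e in t2.elements[strain]]
            assert s1 == s2


class TestEmitGenome:
    def test_single_insertion_exact_substring_with_bed(self, query_model):
        el = simulate._full_element(query_model, "e0")
        genome = emit_genome("s0", [el], {"Ty4L": query_model}, 20_000, seed=1)
        assert len(genome.placements) == 1
        pl = genome.placements[0]
        embedded = genome.sequence[pl.start:pl.end]
        if pl.strand == "+":
            assert embedded == el.retained_sequence()
        else:
            assert embedded == reverse_complement(el.retained_sequence())

    def test_minus_strand_occurs_and_is_reverse_complement(self, query_model):
        seen = set()
        for seed in range(6):
            el = simulate._full_element(query_model, "e0")
            genome = emit_genome("s0", [el], {"Ty4L": query_model}, 20_000,
                                 seed=seed)
            pl = genome.placements[0]
            seen.add(pl.strand)
            expected = (el.retained_sequence() if pl.strand == "+"
                        else reverse_complement(el.retained_sequence()))
            assert genome.sequence[pl.start:pl.end] == expected
        assert seen == {"+", "-"}

    def test_twenty_elements_non_overlapping(self, query_model):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(20)]
        genome = emit_genome("s0", inventory, {"Ty4L": query_model},
                             200_000, seed=3)
        spans = sorted((pl.start, pl.end) for pl in genome.placements)
        assert len(spans) == 20
        assert all(a2 >= b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_insufficient_background_rejected(self, query_model):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(5)]
        with pytest.raises(ValueError):
            emit_genome("s0", inventory, {"Ty4L": query_model}, 5_000, seed=1)


class TestSimulateDepth:
    def test_zero_copies_gives_zero_depth_and_coverage_baseline(self, query_model):
        genome = emit_genome("s0", [], {"Ty4L": query_model}, 50_000, seed=1)
        profile, counts = simulate_depth(genome, query_model, 30.0, seed=2)
        assert profile.depth.sum() == 0
        assert counts.sum() == 0
        assert profile.baseline_depth == pytest.approx(30.0, rel=0.05)

    @pytest.mark.parametrize("k,lo,hi", [(1, 0.85, 1.15), (10, 8.5, 11.5)])
    def test_copy_number_ratio_tracks_truth(self, query_model, k, lo, hi):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(k)]
        genome = emit_genome("s0", inventory, {"Ty4L": query_model},
                             60_000 + k * 6_000, seed=k)
        profile, _ = simulate_depth(genome, query_model, 30.0, seed=k + 1)
        a, b = query_model.regions["internal"]
        ratio = profile.depth[a:b].mean() / profile.baseline_depth
        assert lo <= ratio <= hi

    def test_invalid_fold_coverage_rejected(self, query_model):
        genome = emit_genome("s0", [], {"Ty4L": query_model}, 20_000, seed=1)
        with pytest.raises(ValueError):
            simulate_depth(genome, query_model, 0.0)


class TestHitTable:
    def test_frag_prob_zero_gives_one_row_per_element(self, query_model):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(10)]
        genome = emit_genome("s0", inventory, {"Ty4L": query_model},
                             120_000, seed=4)
        df = emit_hit_table(genome, {"Ty4L": query_model}, frag_prob=0.0, seed=5)
        assert len(df) == 10

    def test_frag_prob_one_splits_every_element(self, query_model):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(10)]
        genome = emit_genome("s0", inventory, {"Ty4L": query_model},
                             120_000, seed=4)
        df = emit_hit_table(genome, {"Ty4L": query_model}, frag_prob=1.0, seed=5)
        assert len(df) >= 20

    def test_rows_stay_within_genome_and_query_bounds(self, query_model):
        inventory = [simulate._full_element(query_model, f"e{i}")
                     for i in range(8)]
        genome = emit_genome("s0", inventory, {"Ty4L": query_model},
                             100_000, seed=6)
        df = emit_hit_table(genome, {"Ty4L": query_model}, frag_prob=0.5, seed=7)
        assert (df.t_start >= 0).all() and (df.t_end <= len(genome.sequence)).all()
        assert (df.q_start >= 0).all() and (df.q_end <= query_model.length).all()
        assert (df.t_start < df.t_end).all() and (df.q_start < df.q_end).all()
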