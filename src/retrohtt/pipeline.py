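"""End-to-end synthetic-mode orchestration.

A run simulates a TE family along a host strain tree under a bundled
scenario, then pushes the simulated data through every analysis stage —
copy number & presence, element annotation, strain consensus, sliding-window
recombination mapping, tree building, and HTT flagging — writing every
intermediate to a run directory plus a machine-readable report.

Bundled scenarios:

* ``vertical_only``          — both subfamilies inherited vertically, no
                               transfer, no recombination;
* ``htt_single``             — the Tsu4-like subfamily is restricted to one
                               lineage and horizontally transferred into a
                               strain of a non-sister lineage;
* ``htt_plus_recombinant``   — as above, plus an inter-subfamily chimera
                               created in the recipient genome with two
                               internal breakpoints bounding a ~2 kb segment.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate, consensus, coverage, divergence, phylo, runio, simulate

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "scenario": "htt_plus_recombinant",
    "simulate": {
        "n_strains": 9,
        "n_lineages": 3,
        "root_copies": 2,
        "depth_scale": 0.01,
        "ltr_len": 300,
        "internal_len": 4000,
        "subfamily_divergence": 0.25,
        "kappa": 2.0,
        "transposition_rate": 2.0,
        "solo_ltr_rate": 0.5,
        "truncation_rate": 0.5,
        "loss_rate": 0.0,
        "background_length": 150_000,
        "fold_coverage": 30.0,
        "read_len": 100,
        "read_error": 0.01,
        "frag_prob": 0.3,
        "htt_time": 0.3,
        "recomb_time": 0.7,
        "recomb_breakpoints": [1300, 3300],
    },
    "coverage": {
        "ltr_threshold": 1.0,
        "internal_threshold": 0.5,
        "cap": 100.0,
        "min_depth": 1,
    },
    "annotate": {
        "max_gap": 250,
        "min_full_frac": 0.9,
        "ltr_only_frac": 0.8,
    },
    "consensus": {
        "min_mapq": 20,
        "min_baseq": 20,
        "min_depth": 1,
        "depth_min": 0.75,
        "breadth_min": 0.9,
    },
    "recomb": {
        "window": 50,
        "step": 10,
        "min_seg": 3,
        "min_delta_ratio": 0.5,
    },
    "phylo": {
        "variant": "classic",
        "bootstrap": 100,
        "min_support": 70,
        "similarity_ratio": 0.5,
        "patchy_min_absent": 2,
    },
}

SCENARIOS = ("vertical_only", "recombinant_only", "htt_single",
             "htt_plus_recombinant")

_RANGES = {
    ("coverage", "ltr_threshold"): (0.0, None),
    ("coverage", "internal_threshold"): (0.0, None),
    ("coverage", "cap"): (1e-9, None),
    ("annotate", "min_full_frac"): (0.0, 1.0),
    ("annotate", "ltr_only_frac"): (0.0, 1.0),
    ("consensus", "depth_min"): (0.0, None),
    ("consensus", "breadth_min"): (0.0, 1.0),
    ("recomb", "window"): (1, None),
    ("recomb", "step"): (1, None),
    ("recomb", "min_seg"): (1, None),
    ("recomb", "min_delta_ratio"): (0.0, 1.0),
    ("phylo", "bootstrap"): (1, None),
    ("phylo", "min_support"): (0, 100),
    ("simulate", "n_strains"): (2, None),
    ("simulate", "subfamily_divergence"): (0.0, None),
    ("simulate", "fold_coverage"): (1e-9, None),
    ("simulate", "read_error"): (0.0, 0.4999),
    ("simulate", "frag_prob"): (0.0, 1.0),
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(config: dict | None) -> tuple[dict, list[str]]:
    """Fill defaults and validate; returns (normalized config, warnings).

    All violations are aggregated into a single :class:`ConfigError`;
    unknown keys produce warnings (forward compatibility), never errors.
    """
    config = config or {}
    out = copy.deepcopy(DEFAULT_CONFIG)
    errors: list[str] = []
    warnings: list[str] = []

    def merge(dst: dict, src: dict, path: str) -> None:
        for key, val in src.items():
            here = f"{path}.{key}" if path else str(key)
            if key not in dst:
                warnings.append(f"unknown config key {here!r} (ignored)")
                continue
            if isinstance(dst[key], dict) and isinstance(val, dict):
                merge(dst[key], val, here)
            else:
                dst[key] = val

    merge(out, config, "")
    if out["scenario"] not in SCENARIOS:
        errors.append(f"scenario: {out['scenario']!r} not one of {SCENARIOS}")
    for (section, key), (lo, hi) in _RANGES.items():
        val = out[section][key]
        if not isinstance(val, (int, float)):
            errors.append(f"{section}.{key}: expected a number, got {val!r}")
            continue
        if (lo is not None and val < lo) or (hi is not None and val > hi):
            errors.append(f"{section}.{key}: {val} outside [{lo}, {hi}]")
    bps = out["simulate"]["recomb_breakpoints"]
    if (not isinstance(bps, (list, tuple)) or not bps
            or any(b >= c for b, c in zip(bps, bps[1:]))):
        errors.append("simulate.recomb_breakpoints: must be strictly increasing and non-empty")
    elif bps[0] <= 0 or bps[-1] >= out["simulate"]["internal_len"]:
        errors.append("simulate.recomb_breakpoints: must lie inside the internal region")
    if errors:
        raise ConfigError(errors)
    return out, warnings


def scenario_params(
    config: dict, host: simulate.StrainTree
) -> simulate.EvolutionParams:
    """Evolution parameters for the configured bundled scenario."""
    sim = config["simulate"]
    scenario = config["scenario"]
    params = simulate.EvolutionParams(
        kappa=sim["kappa"],
        transposition_rate=sim["transposition_rate"],
        solo_ltr_rate=sim["solo_ltr_rate"],
        truncation_rate=sim["truncation_rate"],
        loss_rate=sim["loss_rate"],
        seed=config["seed"],
    )
    if scenario == "vertical_only":
        return params
    if scenario == "recombinant_only":
        # both subfamilies co-exist vertically; a chimera forms in one strain
        params.recomb_events.append({
            "branch": min(host.strains),
            "time": sim["recomb_time"],
            "subfamily_a": "Ty4L",
            "subfamily_b": "Tsu4L",
            "breakpoints": list(sim["recomb_breakpoints"]),
            "subfamily_out": "recombinant",
        })
        return params
    lineages = sorted(set(host.lineage_labels.values()))
    if len(lineages) < 3:
        raise ConfigError(["htt scenarios need >= 3 lineages (simulate.n_lineages)"])
    donor_lineage, recipient_lineage = lineages[-1], lineages[0]
    recipient_tip = min(t for t, l in host.lineage_labels.items()
                        if l == recipient_lineage)
    # restrict the donor subfamily to the donor lineage: extinction on the
    # other lineage stems
    for lin in lineages[:-1]:
        params.subfamily_loss_events.append({
            "branch": simulate.lineage_root_branch(host, lin),
            "subfamily": "Tsu4L",
            "time": 0.05,
        })
    # recent transfer from within the donor lineage's extant diversity: the
    # donor is a tip branch, so the transferred copy nests inside the donor
    # clade with high sequence similarity
    donor_tip = min(t for t, l in host.lineage_labels.items()
                    if l == donor_lineage)
    params.htt_events.append({
        "donor": donor_tip,
        "recipient": recipient_tip,
        "time": sim["htt_time"],
        "subfamily": "Tsu4L",
    })
    if scenario == "htt_plus_recombinant":
        params.recomb_events.append({
            "branch": recipient_tip,
            "time": sim["recomb_time"],
            "subfamily_a": "Ty4L",
            "subfamily_b": "Tsu4L",
            "breakpoints": list(sim["recomb_breakpoints"]),
            "subfamily_out": "recombinant",
        })
    return params


@dataclass
class RunReport:
    config: dict
    scenario: str
    copy_number: list[dict]
    class_counts: dict[str, dict[str, int]]
    classification_accuracy: float | None
    consensus_qc: list[dict]
    breakpoint_calls: list[dict]
    htt_flags: list[dict]
    presence_agreement: float
    config_fingerprint: str
    files: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "copy_number": self.copy_number,
            "class_counts": self.class_counts,
            "classification_accuracy": self.classification_accuracy,
            "consensus_qc": self.consensus_qc,
            "breakpoint_calls": self.breakpoint_calls,
            "htt_flags": self.htt_flags,
            "presence_agreement": self.presence_agreement,
            "config_fingerprint": self.config_fingerprint,
            "files": self.files,
            "config": self.config,
        }


def _fingerprint(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _match_truth(record, placements) -> object | None:
    """Truth element whose locus best overlaps an annotated record."""
    best, best_ov = None, 0
    for pl in placements:
        ov = max(0, min(record.end, pl.end) - max(record.start, pl.start))
        if ov > best_ov:
            best, best_ov = pl, ov
    return best


def run_end_to_end(config: dict | None = None, outdir: str | Path | None = None) -> RunReport:
    """Run the full synthetic pipeline; write artifacts when ``outdir`` given."""
    return run_with_artifacts(config, outdir)["report"]


def run_with_artifacts(
    config: dict | None = None, outdir: str | Path | None = None
) -> dict:
    """As :func:`run_end_to_end`, but also return in-memory intermediates
    (truth set, host tree, genomes, TE tree) for downstream scoring."""
    config, _ = validate_config(config)
    sim_cfg = config["simulate"]
    seed = int(config["seed"])
    root_seq = np.random.SeedSequence(seed)
    seeds = iter(root_seq.generate_state(200).tolist())

    def next_seed() -> int:
        return int(next(seeds)) % (2**31 - 1)

    # --- simulate ---------------------------------------------------------
    host = simulate.simulate_host_tree(
        sim_cfg["n_strains"], sim_cfg["depth_scale"], next_seed(),
        n_lineages=sim_cfg["n_lineages"],
    )
    ty4 = simulate.make_query_model(
        "Ty4L", sim_cfg["ltr_len"], sim_cfg["internal_len"], seed=next_seed())
    tsu4 = simulate.diverged_subfamily(
        ty4, "Tsu4L", sim_cfg["subfamily_divergence"],
        kappa=sim_cfg["kappa"], seed=next_seed())
    params = scenario_params(config, host)
    params.seed = next_seed()
    n_root = max(1, int(sim_cfg["root_copies"]))
    truth, event_log = simulate.simulate_family_history(
        host, params, [ty4, tsu4] * n_root)
    root_models = {"Ty4L": ty4, "Tsu4L": tsu4}

    # --- per-strain genomes, depth, copy number, annotation ---------------
    cov_cfg, ann_cfg = config["coverage"], config["annotate"]
    cn_rows: list[dict] = []
    class_counts: dict[str, dict[str, int]] = {}
    presence_table: dict[str, dict[str, bool]] = {}
    genomes: dict[str, simulate.StrainGenome] = {}
    pileups: dict[str, np.ndarray] = {}  # Tsu4L base counts per strain
    profiles: dict[tuple[str, str], object] = {}
    n_class_correct = n_class_total = 0
    n_presence_ok = n_presence_total = 0

    for strain in host.strains:
        genome = simulate.emit_genome(
            strain, truth.elements[strain], truth.query_models,
            sim_cfg["background_length"], seed=next_seed())
        genomes[strain] = genome
        presence_table[strain] = {}
        for model in (ty4, tsu4):
            profile, counts = simulate.simulate_depth(
                genome, model, sim_cfg["fold_coverage"], sim_cfg["read_len"],
                err=sim_cfg["read_error"], seed=next_seed())
            profile = coverage.downsample_depth(profile, cov_cfg["cap"], seed=next_seed())
            est = coverage.estimate_strain(
                strain, profile, model.regions,
                cov_cfg["ltr_threshold"], cov_cfg["internal_threshold"],
                cov_cfg["min_depth"])
            profiles[(strain, model.query_id)] = profile
            if model.query_id == "Tsu4L":
                ia, ib = model.regions["internal"]
                pileups[strain] = counts[ia:ib]
            n_fle = truth.class_counts(strain, model.query_id)["FLE"]
            cn_rows.append({
                "strain": strain, "subfamily": model.query_id,
                "cn_ltr": round(est.cn_ltr, 4), "cn_internal": round(est.cn_internal, 4),
                "breadth_internal": round(est.breadth_internal, 4),
                "presence_ltr": est.presence_ltr, "presence_internal": est.presence_internal,
                "activity": coverage.interpret_activity(
                    est.presence_ltr, est.presence_internal, n_fle),
            })
            presence_table[strain][model.query_id] = (
                est.presence_ltr or est.presence_internal)
            # cross-consistency: presence call vs inventory-derived truth
            t_ltr, t_int = truth.copy_number(strain, model.query_id)
            n_presence_total += 1
            n_presence_ok += (est.presence_internal == (t_int > cov_cfg["internal_threshold"]))

        hit_df = simulate.emit_hit_table(
            genome, truth.query_models, sim_cfg["frag_prob"], seed=next_seed())
        hits = annotate.parse_hits(hit_df.to_csv(sep="\t", index=False))
        records = annotate.annotate_elements(
            hits, truth.query_models, ann_cfg["max_gap"],
            ann_cfg["min_full_frac"], ann_cfg["ltr_only_frac"])
        counts_by_class = {"FLE": 0, "truncated": 0, "solo_LTR": 0}
        for rec in records:
            counts_by_class[rec.element_class] += 1
            matched = _match_truth(rec, genome.placements)
            if matched is not None:
                n_class_total += 1
                n_class_correct += (rec.element_class == matched.element.element_class)
        class_counts[strain] = counts_by_class

    # --- consensus --------------------------------------------------------
    con_cfg = config["consensus"]
    consensus_rows: list[dict] = []
    consensi: dict[str, str] = {}
    for strain in host.strains:
        profile = profiles[(strain, "Tsu4L")]
        cn_int = coverage.normalize_copy_number(profile, tsu4.regions["internal"])
        breadth = coverage.compute_breadth(profile, tsu4.regions["internal"])
        pile = consensus.Pileup(query_id="Tsu4L", counts=pileups[strain])
        result = consensus.build_consensus(
            strain, pile, cn_int, breadth, con_cfg["min_depth"],
            con_cfg["depth_min"], con_cfg["breadth_min"])
        consensus_rows.append({
            "strain": strain, "cn_internal": round(cn_int, 4),
            "breadth": round(breadth, 4), "qc_pass": result.qc_pass,
        })
        if result.qc_pass:
            consensi[f"{strain}|Tsu4L"] = result.sequence

    # --- recombination scan ----------------------------------------------
    rec_cfg = config["recomb"]
    aln = truth.internal_alignment(min_frac=0.999)
    parent_refs = {"Ty4L": ty4.region_seq("internal"), "Tsu4L": tsu4.region_seq("internal")}
    breakpoint_calls: list[dict] = []
    for tip, seq in aln.items():
        profile = divergence.sliding_window_divergence(
            seq, parent_refs, rec_cfg["window"], rec_cfg["step"])
        try:
            call = divergence.infer_breakpoints(
                profile, rec_cfg["min_seg"], rec_cfg["min_delta_ratio"])
        except ValueError:
            continue
        if call.positions:
            breakpoint_calls.append({
                "element": tip,
                "breakpoints": [round(p, 1) for p in call.positions],
                "segment_parents": call.segment_parents,
                "confidence": [round(c, 4) for c in call.confidence],
            })

    # --- trees and HTT flags ----------------------------------------------
    phy_cfg = config["phylo"]
    # flags are evaluated per subfamily (chimeras excluded): mixing the two
    # subfamilies in one tree lets differential solo-LTR loss masquerade as
    # discordance
    subfam_of = {f"{s}|{el.element_id}": el.subfamily
                 for s, inv in truth.elements.items() for el in inv}
    te_trees: dict[str, object] = {}
    flags: list[phylo.HTTFlag] = []
    presence_used = False
    for subfam in root_models:
        sub_aln = {tip: seq for tip, seq in aln.items()
                   if subfam_of.get(tip) == subfam}
        if len(sub_aln) < 4:
            continue
        tree = phylo.bootstrap_support(
            sub_aln, n=phy_cfg["bootstrap"], seed=next_seed(),
            variant=phy_cfg["variant"])
        te_trees[subfam] = tree
        species_of = {tip: host.lineage_labels[tip.split("|")[0]]
                      for tip in sub_aln}
        flags.extend(phylo.htt_flag(
            tree, host.tree, species_of,
            presence_table=(None if presence_used
                            else _presence_by_tip(presence_table)),
            min_support=phy_cfg["min_support"],
            similarity_ratio=phy_cfg["similarity_ratio"],
            host_species_of=host.lineage_labels,
            patchy_min_absent=phy_cfg["patchy_min_absent"],
        ))
        presence_used = True

    report = RunReport(
        config=config,
        scenario=config["scenario"],
        copy_number=cn_rows,
        class_counts=class_counts,
        classification_accuracy=(n_class_correct / n_class_total
                                 if n_class_total else None),
        consensus_qc=consensus_rows,
        breakpoint_calls=breakpoint_calls,
        htt_flags=[{"evidence": f.evidence, "clade": sorted(f.clade)[:10],
                    "details": f.details} for f in flags],
        presence_agreement=(n_presence_ok / n_presence_total
                            if n_presence_total else 1.0),
        config_fingerprint=_fingerprint(config),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_artifacts(outdir, report, host, truth, event_log, genomes,
                         profiles, consensi, te_trees, root_models)
    return {
        "report": report,
        "truth": truth,
        "host": host,
        "event_log": event_log,
        "genomes": genomes,
        "profiles": profiles,
        "consensi": consensi,
        "te_trees": te_trees,
        "models": root_models,
    }


def _subfamily_index(truth, root_models) -> set[str]:
    """Element ids belonging to the root (non-chimeric) subfamilies."""
    keep = set()
    for inv in truth.elements.values():
        for el in inv:
            if el.subfamily in root_models:
                keep.add(el.element_id)
    return keep


def _presence_by_tip(presence_table: dict[str, dict[str, bool]]) -> dict:
    return presence_table


def _write_artifacts(outdir, report, host, truth, event_log, genomes,
                     profiles, consensi, te_trees, root_models) -> None:
    files: dict[str, str] = {}

    def register(name: str, path: Path) -> Path:
        files[name] = path.name
        return path

    runio.write_fasta(register("queries_fasta", outdir / "queries.fasta"),
                      {m.query_id: m.sequence for m in root_models.values()})
    runio.write_bed(register("query_regions_bed", outdir / "query_regions.bed"),
                    [(qid, a, b, region, 0, "+")
                     for qid, m in root_models.items()
                     for region, (a, b) in m.regions.items()])
    (outdir / "host.nwk").write_text(host.newick() + "\n")
    files["host_tree"] = "host.nwk"
    for subfam, tree in te_trees.items():
        name = f"te_tree_{subfam}.nwk"
        (outdir / name).write_text(tree.as_string(schema="newick").strip() + "\n")
        files[f"te_tree_{subfam}"] = name
    for strain, genome in genomes.items():
        runio.write_fasta(outdir / f"genome_{strain}.fasta", {strain: genome.sequence})
        runio.write_bed(outdir / f"truth_{strain}.bed",
                        [pl.bed_row(strain) for pl in genome.placements])
    for (strain, qid), profile in profiles.items():
        runio.write_depth_tsv(outdir / f"depth_{strain}_{qid}.tsv", profile)
    if consensi:
        runio.write_fasta(register("consensus_fasta", outdir / "consensus.fasta"),
                          consensi)
    with open(register("event_log", outdir / "events.tsv"), "w") as fh:
        fh.write("kind\tbranch\ttime\telements\tbreakpoints\n")
        for ev in event_log:
            fh.write(f"{ev.kind}\t{ev.branch}\t{ev.time:.4f}\t"
                     f"{','.join(ev.element_ids)}\t"
                     f"{','.join(map(str, ev.breakpoints))}\n")
    runio.write_json(register("truth_copy_numbers", outdir / "truth_cn.json"), {
        strain: {qid: truth.copy_number(strain, qid) for qid in root_models}
        for strain in host.strains
    })
    report.files = files
    runio.write_json(register("report", outdir / "report.json"), report.to_dict())
    runio.write_json(outdir / "manifest.json", {
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "config_fingerprint": report.config_fingerprint,
    })
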