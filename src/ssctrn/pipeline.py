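"""End-to-end orchestration of the staged-reprogramming analysis.

``run_pipeline`` executes the stages in dependency order — simulate (or load
inputs) → quantile normalization → expressed-gene detection → differential
expression → temporal grouping → NMF signatures → TF enrichment and overlap
testing → TRN assembly — writing every stage's output files plus a
machine-readable ``summary.json`` into a run directory. A single master seed
deterministically derives per-stage substreams, so a fixed configuration is
byte-reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg, enrich, io, metrics, nmf, patterns, preprocess, simulate, trn

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "signatures": True,
        "enrich": True,
        "overlap": True,
        "trn": True,
    },
    "inputs": {  # used when stages.simulate is false
        "expression": None,
        "stage_map": None,
        "timecourses": [],
        "tf_gmt": None,
        "term_gmt": None,
        "ppi": None,
    },
    "simulate": {
        "n_genes": 2000,
        "replicates_per_stage": [3, 2, 3],
        "group_fractions": {1: 0.1, 3: 0.1, 7: 0.1, 9: 0.1},
        "effect_size": 1.5,
        "noise_sd": 0.3,
        "baseline_mean": 6.0,
        "expressed_mean": 10.0,
        "unexpressed_fraction": 0.3,
        "timecourse": {
            "n_lines": 3,
            "timepoints": 10,
            "terminal_log2fc": 2.0,
            "noise_sd": 0.3,
            "plant_from_groups": True,  # pluripotency <- up-groups, differentiation <- down-groups
        },
        "tf_network": {
            "n_tfs": 20,
            "targets_per_tf": 20,
            "planted_groups": [1, 3, 7, 9],
            "per_group": 2,
            "fraction": 0.8,
            "name_tfs_after_genes": True,
        },
    },
    "deg": {"alpha": 0.05, "fc_threshold": 0.58, "n_perm": 10000},
    "groups": {"k": 12},
    "signatures": {"rank": 40, "alpha": 0.05, "fc_min": 1.5, "n_perm": 99},
    "enrich": {"alpha": 0.05, "min_count": 5, "max_group_fraction": 0.8,
               "universe": "annotated"},
    "overlap": {"n_samples": 10000},
    "trn": {"groups": None, "process": None, "min_count": 5, "alpha": 0.05},
}

#: up-pattern and down-pattern planted group ids (see simulate.GROUP_STAGE_OFFSETS)
_UP_GROUPS = {1, 2, 3}
_DOWN_GROUPS = {7, 8, 9}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults.

    ``group_fractions`` keys are normalized to int (YAML/JSON configs carry
    them as strings); an override of that mapping replaces the default
    planting wholesale rather than merging into it.
    """

    def _merge(base: dict, over: dict) -> dict:
        out = copy.deepcopy(base)
        for key, val in over.items():
            if key == "group_fractions" and isinstance(val, dict):
                out[key] = {int(k): float(v) for k, v in val.items()}
            elif isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = _merge(out[key], val)
            else:
                out[key] = copy.deepcopy(val)
        return out

    return _merge(DEFAULT_CONFIG, overrides or {})


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["sim_expr", "sim_tc", "sim_tf", "expressed", "deg", "signatures", "overlap"]
    seqs = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, seqs)}


def _simulate_inputs(cfg: dict, seeds: dict[str, int], outdir: Path):
    sim = cfg["simulate"]
    config = simulate.SimulationConfig(
        n_genes=sim["n_genes"],
        replicates_per_stage=tuple(sim["replicates_per_stage"]),
        group_fractions={int(k): v for k, v in sim["group_fractions"].items()},
        effect_size=sim["effect_size"],
        noise_sd=sim["noise_sd"],
        baseline_mean=sim["baseline_mean"],
        expressed_mean=sim["expressed_mean"],
        unexpressed_fraction=sim["unexpressed_fraction"],
        seed=seeds["sim_expr"],
    )
    matrix, stage_map, truth = simulate.simulate_expression(config)
    io.write_expression_tsv(matrix, outdir / "expression.tsv")
    io.write_stage_map(stage_map, outdir / "stage_map.tsv")

    tc = sim["timecourse"]
    planted_down = planted_up = None
    if tc.get("plant_from_groups", True):
        planted_down = sorted(
            g for g, grp in truth.group_of_gene.items() if grp in _UP_GROUPS
        )
        planted_up = sorted(
            g for g, grp in truth.group_of_gene.items() if grp in _DOWN_GROUPS
        )
    courses, tc_truth = simulate.simulate_timecourses(
        n_genes=sim["n_genes"],
        n_lines=tc["n_lines"],
        timepoints=tc["timepoints"],
        signature_spec=simulate.SignatureSpec(terminal_log2fc=tc["terminal_log2fc"]),
        noise_sd=tc["noise_sd"],
        seed=seeds["sim_tc"],
        pluripotency_genes=planted_down,
        differentiation_genes=planted_up,
    )
    for i, course in enumerate(courses):
        io.write_expression_tsv(course, outdir / f"timecourse_line{i+1}.tsv")
    truth.signature_of_gene = tc_truth.signature_of_gene

    tf = sim["tf_network"]
    group_members = {
        grp: truth.planted_genes(grp)
        for grp in {int(g) for g in tf["planted_groups"]}
    }
    planted: dict[str, tuple[int, float]] = {}
    rng_names = np.random.default_rng(np.random.SeedSequence(seeds["sim_tf"]).spawn(1)[0])
    n_planted = len(tf["planted_groups"]) * tf["per_group"]
    if tf.get("name_tfs_after_genes", True):
        taken: set[str] = set()
        names = []
        for grp in tf["planted_groups"]:
            pool = [g for g in group_members[int(grp)] if g not in taken]
            for g in rng_names.choice(pool, size=tf["per_group"], replace=False):
                names.append(str(g))
                taken.add(str(g))
        null_pool = [
            g for g, grp in sorted(truth.group_of_gene.items())
            if grp == 0 and truth.expressed.get(g, False) and g not in taken
        ]
        names += [
            str(g)
            for g in rng_names.choice(null_pool, size=tf["n_tfs"] - n_planted, replace=False)
        ]
        tf_names = names
    else:
        tf_names = None
    planted_order = [
        (tf_names[i] if tf_names else None, int(grp))
        for i, grp in enumerate(
            [g for g in tf["planted_groups"] for _ in range(tf["per_group"])]
        )
    ]
    if tf_names is None:
        width = max(2, len(str(tf["n_tfs"])))
        default_names = [f"TF{i:0{width}d}" for i in range(1, tf["n_tfs"] + 1)]
        planted_order = [
            (default_names[i], grp) for i, (_n, grp) in enumerate(planted_order)
        ]
    for name, grp in planted_order:
        planted[name] = (grp, tf["fraction"])
    collection, tf_truth = simulate.simulate_tf_network(
        n_tfs=tf["n_tfs"],
        targets_per_tf=tf["targets_per_tf"],
        planted_enrichment=planted,
        universe=sorted(matrix.index),
        group_members=group_members,
        seed=seeds["sim_tf"],
        tf_names=tf_names,
    )
    truth.tf_targets = tf_truth.tf_targets
    truth.planted_tfs = tf_truth.planted_tfs
    pd.DataFrame(
        {
            "tf": sorted(collection.sets),
            "planted_group": [
                planted.get(name, (0, 0.0))[0] for name in sorted(collection.sets)
            ],
        }
    ).to_csv(outdir / "tf_truth.tsv", sep="\t", index=False)
    io.write_gmt(collection.sets, outdir / "tf_targets.gmt", "simulated")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return matrix, stage_map, courses, collection, truth


def _load_inputs(cfg: dict):
    inp = cfg["inputs"]
    if not inp["expression"] or not inp["stage_map"]:
        raise ValueError("stages.simulate is off: inputs.expression and inputs.stage_map are required")
    matrix = io.read_expression_tsv(inp["expression"])
    stage_map = io.read_stage_map(inp["stage_map"])
    courses = [io.read_expression_tsv(p) for p in inp["timecourses"] or []]
    collection = None
    if inp["tf_gmt"]:
        collection = enrich.GeneSetCollection(io.read_gmt(inp["tf_gmt"]), inp["tf_gmt"])
    return matrix, stage_map, courses, collection, None


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run all enabled stages; returns (and writes) the summary dict."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    stages = cfg["stages"]
    summary: dict = {"parameters": copy.deepcopy(cfg), "counts": {}}

    if stages["simulate"]:
        matrix, stage_map, courses, tf_collection, truth = _simulate_inputs(
            cfg, seeds, outdir
        )
    else:
        matrix, stage_map, courses, tf_collection, truth = _load_inputs(cfg)

    normalized = preprocess.quantile_normalize(matrix)
    io.write_expression_tsv(normalized, outdir / "normalized.tsv")

    expressed = preprocess.detect_expressed(normalized, seed=seeds["expressed"])
    pd.DataFrame(
        {
            "gene": normalized.index,
            "posterior_expressed": expressed.posterior.loc[normalized.index],
            "expressed": [int(g in set(expressed.members)) for g in normalized.index],
        }
    ).to_csv(outdir / "expressed.tsv", sep="\t", index=False)
    summary["counts"]["expressed_genes"] = len(expressed.members)

    results = deg.run_comparisons(
        normalized,
        stage_map,
        expressed,
        alpha=cfg["deg"]["alpha"],
        fc_threshold=cfg["deg"]["fc_threshold"],
        n_perm=cfg["deg"]["n_perm"],
        seed=seeds["deg"],
    )
    results.to_csv(outdir / "deg_results.tsv", sep="\t", index=False)
    summary["counts"]["degs_per_comparison"] = {
        name: int((results.loc[results["comparison"] == name, "call"] != 0).sum())
        for name in results["comparison"].unique()
    }
    union = deg.deg_union(results)
    summary["counts"]["deg_union"] = len(union)

    groups = patterns.group_degs(
        normalized, results, k=cfg["groups"]["k"], stage_of_sample=stage_map
    )
    io.write_gmt(groups.as_gene_sets(), outdir / "groups.gmt", "temporal group")
    groups.mean_profiles.to_csv(outdir / "group_profiles.tsv", sep="\t")
    summary["counts"]["group_sizes"] = {str(g): n for g, n in groups.sizes().items()}

    signatures = None
    if stages["signatures"] and len(courses) >= 2:
        sig_cfg = cfg["signatures"]
        signatures, model, _clusters = nmf.extract_signatures(
            courses,
            k=sig_cfg["rank"],
            alpha=sig_cfg["alpha"],
            fc_min=sig_cfg["fc_min"],
            n_perm=sig_cfg["n_perm"],
            seed=seeds["signatures"],
        )
        io.write_gmt(signatures.as_gene_sets(), outdir / "signatures.gmt", "NMF signature")
        summary["counts"]["signature_sizes"] = {
            "pluripotency": len(signatures.pluripotency),
            "differentiation": len(signatures.differentiation),
        }
        summary["counts"]["nmf_reconstruction_error"] = round(
            model.reconstruction_error, 6
        )

    catalog = None
    major_per_group: dict[int, list[str]] = {}
    if stages["enrich"] and tf_collection is not None:
        en = cfg["enrich"]
        if en["universe"] == "annotated":
            universe = sorted(
                set(expressed.members) & tf_collection.annotated_genes()
                | (set(expressed.members) & set(tf_collection.names()))
            )
        else:
            universe = sorted(expressed.members)
        group_members = {g: groups.members(g) for g in groups.groups}
        major_per_group, rows = enrich.major_tfs(
            group_members,
            tf_collection,
            universe,
            alpha=en["alpha"],
            min_count=en["min_count"],
            max_group_fraction=en["max_group_fraction"],
        )
        rows.to_csv(outdir / "tf_enrichment.tsv", sep="\t", index=False)
        major_union = sorted({t for ts in major_per_group.values() for t in ts})
        catalog = enrich.categorize_tfs(major_union, union, tf_collection.names())
        summary["counts"]["major_tfs"] = len(major_union)
        summary["counts"]["major_tfs_per_group"] = {
            str(g): len(ts) for g, ts in major_per_group.items()
        }
        summary["counts"]["tf_catalog"] = catalog.counts()

    if stages["overlap"] and signatures is not None:
        shared = sorted(set(normalized.index) & set(courses[0].index))
        universe_ov = sorted(set(expressed.members) & set(shared))
        overlap_rows = []
        for grp in groups.groups:
            query = sorted(set(groups.members(grp)) & set(universe_ov))
            for name, sig in signatures.as_gene_sets().items():
                sig_in = sorted(set(sig) & set(universe_ov))
                if not query or not sig_in:
                    continue
                p = enrich.overlap_permutation_p(
                    query, sig_in, universe_ov,
                    n_samples=cfg["overlap"]["n_samples"],
                    seed=seeds["overlap"],
                )
                overlap_rows.append(
                    {"group": grp, "signature": name,
                     "overlap": len(set(query) & set(sig_in)), "p": p}
                )
        pd.DataFrame(overlap_rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
        summary["counts"]["overlap_tests"] = len(overlap_rows)

    if stages["trn"] and tf_collection is not None and catalog is not None:
        trn_cfg = cfg["trn"]
        selected = catalog.de_mtf or sorted(
            {t for ts in major_per_group.values() for t in ts}
        )
        allowed = (
            set(int(g) for g in trn_cfg["groups"])
            if trn_cfg["groups"]
            else set(groups.groups)
        )
        process_genes = None
        if trn_cfg["process"] and cfg["inputs"].get("term_gmt"):
            terms = io.read_gmt(cfg["inputs"]["term_gmt"])
            process_genes = set(terms[trn_cfg["process"]])
        ppi = (
            io.read_ppi_edges(cfg["inputs"]["ppi"]) if cfg["inputs"].get("ppi") else None
        )
        graph = trn.build_trn(
            selected,
            dict(groups.group_of_gene),
            allowed,
            process_genes,
            tf_collection,
            ppi,
        )
        trn.export_network(graph, "sif", outdir / "trn.sif")
        trn.export_network(graph, "graphml", outdir / "trn.graphml")
        trn.export_network(graph, "tsv", outdir / "trn_nodes.tsv")
        summary["counts"]["trn_nodes"] = graph.n_nodes
        summary["counts"]["trn_edges"] = graph.n_edges

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def recovery_report(outdir: str | Path, truth: simulate.SimulationTruth) -> dict:
    """Planted-vs-recovered metrics for a finished simulated run."""
    outdir = Path(outdir)
    group_sets = io.read_gmt(outdir / "groups.gmt")
    recovered = pd.Series(
        {g: int(name.split("_")[1]) for name, genes in group_sets.items() for g in genes}
    )
    _mapping, rate = metrics.match_groups(truth.group_of_gene, recovered)
    return {"group_recovery_rate": rate}
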