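"""End-to-end orchestration: inputs -> scores -> phylogeny -> profiles ->
clustering -> formula synergy -> structured report.

The report is a plain dict (serialized as JSON) whose every number is
recomputable from the stage TSVs written alongside it.  All randomness
derives from one master seed split per stage; reruns with the same config
are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .catalog import (
    read_formulas,
    read_interaction_table,
    read_medicinal_catalog,
    read_modification_catalog,
    read_tree,
    validate_tree_against_catalog,
)
from .cluster import export_clustered_matrix, hierarchical_cluster, potency_matrix
from .formulas import run_synergy_analysis
from .phylo import morans_i_for_tree
from .profiling import (
    build_potency_profiles,
    chromatin_call,
    correlation_screen,
    is_histone_modifying,
    materia_medica_summary,
    profiles_to_tsv,
)
from .scoring import score_catalog
from .simulate import GeneratorConfig, generate_bundle

logger = logging.getLogger(__name__)

SCORE_MODES = ("nature_only", "full", "flavor_only")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_inputs(config: dict):
    if "synthetic" in config:
        syn = dict(config["synthetic"])
        syn.setdefault("seed", config.get("seed", 0))
        for key in ("n_chemicals_per_medicinal", "n_enzymes_per_attribute",
                    "n_flavors", "formula_size_range", "action_mix"):
            if key in syn:
                syn[key] = tuple(syn[key])
        if "planted_associations" in syn:
            syn["planted_associations"] = tuple(
                tuple(x) for x in syn["planted_associations"])
        bundle = generate_bundle(GeneratorConfig(**syn))
        return (bundle.catalog, bundle.interactions, bundle.modcat,
                bundle.formulas, bundle.tree, {"synthetic": syn})
    inputs = config["inputs"]
    catalog = read_medicinal_catalog(inputs["medicinals"],
                                     strict=config.get("strict", True))
    interactions = read_interaction_table(inputs["interactions"])
    modcat = read_modification_catalog(inputs["modifications"])
    formulas = (read_formulas(inputs["formulas"], catalog)
                if "formulas" in inputs else [])
    tree = read_tree(inputs["tree"]) if "tree" in inputs else None
    if tree is not None:
        validate_tree_against_catalog(tree, catalog)
    checksums = {k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
                 for k, v in inputs.items()}
    return catalog, interactions, modcat, formulas, tree, {"inputs": checksums}


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every enabled stage and return the analysis report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    seed = int(config.get("seed", 0))
    rng_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in np.random.SeedSequence(seed).spawn(4)]
    report: dict = {"provenance": {
        "config_hash": _config_hash(config), "seed": seed,
        "version": __version__,
    }}

    t0 = time.perf_counter()
    catalog, interactions, modcat, formulas, tree, prov = _load_inputs(config)
    report["provenance"].update(prov)
    logger.info("stage=load n_medicinals=%d n_interactions=%d n_formulas=%d "
                "elapsed=%.2fs", len(catalog), len(interactions),
                len(formulas), time.perf_counter() - t0)

    scores = score_catalog(catalog)
    scores.to_tsv(out / "scores.tsv")
    report["scores"] = {
        "n_medicinals": len(catalog),
        "n_na_nature": int(scores.table["cold_hot"].isna().sum()),
        "n_na_flavor": int(scores.table["flavor"].isna().sum()),
    }

    if stages.get("phylo", True) and tree is not None:
        t0 = time.perf_counter()
        phylo = {}
        for mode in SCORE_MODES:
            res = morans_i_for_tree(
                tree, scores.scores(mode), method=config.get(
                    "moran_method", "analytic"),
                n_permutations=config.get("n_permutations", 999),
                seed=rng_seeds[0],
                row_standardize=config.get("moran_row_standardize", True))
            phylo[mode] = res.to_dict()
        report["phylogenetic"] = phylo
        (out / "moran.json").write_text(json.dumps(phylo, indent=2) + "\n")
        logger.info("stage=phylo elapsed=%.2fs", time.perf_counter() - t0)
    else:
        report["phylogenetic"] = {"skipped": "no tree supplied or stage off"}

    t0 = time.perf_counter()
    profiles = build_potency_profiles(catalog, interactions, modcat)
    calls = [chromatin_call(p, modcat) for p in profiles]
    profiles_to_tsv(profiles, out / "profiles.tsv", calls)
    report["materia_medica"] = materia_medica_summary(calls)
    corr_frames = []
    for mode in SCORE_MODES:
        corr_frames.append(correlation_screen(scores, profiles, mode))
    import pandas as pd

    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    report["correlations"] = {
        "alpha": 0.05,
        "multiple_testing_correction": "none (per-attribute screen)",
        "significant": corr[corr["significant"]].loc[
            :, ["attribute_code", "score_mode", "r", "p", "n"]
        ].to_dict(orient="records"),
    }
    logger.info("stage=profile n_modifying=%d elapsed=%.2fs",
                report["materia_medica"]["n_modifying"],
                time.perf_counter() - t0)

    if stages.get("cluster", True):
        t0 = time.perf_counter()
        modifying = [p for p in profiles if is_histone_modifying(p)]
        cluster_files = {}
        if len(modifying) >= 2:
            mat = potency_matrix(modifying)
            rows = hierarchical_cluster(mat, axis="rows",
                                        linkage=config.get("linkage", "complete"))
            cols = hierarchical_cluster(mat, axis="columns",
                                        linkage=config.get("linkage", "complete"))
            cluster_files = export_clustered_matrix(
                mat, rows, cols, str(out / "medicinal_cluster"),
                image=config.get("images", False))
        report["clustering"] = {"n_clustered": len(modifying),
                                "files": {k: Path(v).name
                                          for k, v in cluster_files.items()}}
        logger.info("stage=cluster n=%d elapsed=%.2fs", len(modifying),
                    time.perf_counter() - t0)
    else:
        report["clustering"] = {"skipped": "stage off"}

    if stages.get("formulas", True) and formulas:
        t0 = time.perf_counter()
        member_profiles = {p.entity_id: p for p in profiles}
        member_calls = {c.entity_id: c for c in calls}
        from .formulas import formula_is_histone_modifying

        n_modifying = sum(formula_is_histone_modifying(f, member_calls)
                          for f in formulas)
        synergy = run_synergy_analysis(
            formulas, member_profiles, member_calls, modcat,
            n_controls=config.get("n_controls", 199), seed=rng_seeds[1])
        report["formulas"] = {
            "n_formulas": len(formulas),
            "n_modifying": n_modifying,
            "synergy": {"summary": synergy.summary,
                        "n_controls": synergy.n_controls,
                        "median_size": synergy.median_size,
                        "median_modifying": synergy.median_modifying},
        }
        (out / "synergy.json").write_text(
            json.dumps(synergy.to_dict(), indent=2) + "\n")
        logger.info("stage=formulas n_modifying=%d elapsed=%.2fs",
                    n_modifying, time.perf_counter() - t0)
    else:
        report["formulas"] = {"skipped": "no formulas supplied or stage off"}

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
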