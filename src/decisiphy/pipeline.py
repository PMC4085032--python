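"""End-to-end orchestration: inputs (synthetic or on-disk) -> coverage ->
decisiveness -> quartet jackknife -> ICA -> regression -> monophyly ->
annotated trees -> machine-readable report.

All randomness flows from one master seed; per-stage and per-branch streams
are derived from it, so reruns (and any `workers` setting) give byte-identical
outputs. No output file embeds a timestamp for the same reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import annotation, coverage_decisiveness as cd, ica_stats, quartet_support as qs
from .synthetic_data import PRESETS, simulate_bundle, write_bundle
from .trees_io import (
    ValidationError,
    read_alignment,
    read_partition_map,
    read_record_metadata,
    read_taxonomy,
    read_tree,
    write_figtree_annotations,
)

log = logging.getLogger("decisiphy")

DEFAULTS = {
    "seed": 0,
    "reps": 500,
    "model": "jc",
    "min_sites": 1,
    "workers": 1,
    "n_trees": 500,
    "reg_lower": 5,
    "reg_upper": 25,
    "count_thresholds": [4, 15],
    "alignment_format": "fasta",
    "palette_counts": "RdYlBu",
    "palette_ica": "RdYlBu",
}

_INPUT_KEYS = ("tree", "alignment", "partitions", "taxonomy", "records")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a flat key: value mapping")
    return cfg


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _check_tip_match(tree_tips, other, what):
    missing = set(tree_tips) - set(other)
    extra = set(other) - set(tree_tips)
    if missing:
        raise ValidationError(
            f"tips in tree but not in {what}: {sorted(missing)[:10]}"
            + (f" (+{len(missing) - 10} more)" if len(missing) > 10 else "")
        )
    if extra:
        log.info("%d taxa in %s not present in tree (ignored)", len(extra), what)


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis described by a flat config mapping (or a YAML
    file path). Returns a dict with the summary and all output paths."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULTS, **config}
    out_dir = out_dir or cfg.get("out_dir")
    if not out_dir:
        raise ValidationError("config needs an out_dir")
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    hashed = {k: v for k, v in cfg.items() if k != "workers"}  # scheduling only
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    log.info("config hash %s, master seed %d", cfg_hash, seed)

    taxonomy = records = truth = None
    if cfg.get("preset"):
        preset = cfg["preset"]
        if preset not in PRESETS:
            raise ValidationError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        bundle = simulate_bundle(PRESETS[preset](seed))
        write_bundle(bundle, os.path.join(out_dir, "inputs"))
        tree = bundle.tree
        alignment, partitions = bundle.alignment, bundle.partitions
        taxonomy, records, truth = bundle.taxonomy, bundle.records, bundle.truth
        log.info("simulated preset %r: %d tips, %d loci, realized missingness %.2f%%",
                 preset, tree.n_tips, len(partitions.loci),
                 bundle.missingness_report["realized_cellwise_missing_pct"])
    else:
        missing = [k for k in ("tree", "alignment", "partitions") if not cfg.get(k)]
        if missing:
            raise ValidationError(f"config needs a preset or input paths; missing {missing}")
        tree = read_tree(cfg["tree"])
        alignment = read_alignment(cfg["alignment"], cfg["alignment_format"])
        partitions = read_partition_map(cfg["partitions"])
        if cfg.get("taxonomy"):
            taxonomy = read_taxonomy(cfg["taxonomy"])
        if cfg.get("records"):
            records = read_record_metadata(cfg["records"])
    _check_tip_match(tree.tip_labels, alignment.taxa, "alignment")

    paths = {}

    # --- coverage & missingness ------------------------------------------
    coverage = cd.build_coverage(alignment, partitions)
    summary_stats = cd.missingness_summary(alignment, partitions)
    empty = coverage.empty_taxa()
    if empty:
        log.warning("%d taxa have no data at any locus", len(empty))

    # --- decisiveness -----------------------------------------------------
    counts = cd.branchwise_decisive_counts(tree, coverage)
    estimate = cd.estimate_partial_decisiveness(
        coverage, n_trees=int(cfg["n_trees"]), seed=seed
    )
    paths["decisiveness"] = os.path.join(out_dir, "decisiveness.json")
    _json_dump(asdict(estimate), paths["decisiveness"])

    max_count = max(counts.values()) if counts else 0
    count_values = np.array(sorted(counts.values()))
    cumulative = pd.DataFrame(
        {
            "n_loci": np.arange(max_count + 1),
            "cumulative_fraction": [
                float((count_values <= k).mean()) for k in range(max_count + 1)
            ],
        }
    )
    paths["cumulative_counts"] = os.path.join(out_dir, "branch_count_cumulative.csv")
    cumulative.to_csv(paths["cumulative_counts"], index=False)

    # --- quartet jackknife + ICA -----------------------------------------
    model = None if cfg["model"] in ("jc", "jc69", "JC69") else qs.SubstitutionModel(
        "GTR", rates=cfg.get("gtr_rates"), freqs=cfg.get("gtr_freqs")
    )
    tallies = qs.quartet_jackknife_tree(
        tree,
        alignment,
        n_reps=int(cfg["reps"]),
        model=model,
        seed=seed,
        workers=int(cfg["workers"]),
        min_sites=int(cfg["min_sites"]),
    )
    ica_results = {key: ica_stats.ica_from_tally(t) for key, t in tallies.items()}

    # --- oldest exemplar ages --------------------------------------------
    edge_years = {}
    if records is not None and len(records):
        exemplars = annotation.select_exemplars(records)
        _, edge_years = annotation.oldest_exemplar_age(tree, records, exemplars)

    branch_rows = []
    for key in sorted(counts):
        tally = tallies.get(key)
        res = ica_results.get(key)
        branch_rows.append(
            {
                "branch": key,
                "decisive_count": counts[key],
                "c_focal": tally.counts[0] if tally else np.nan,
                "c_alt1": tally.counts[1] if tally else np.nan,
                "c_alt2": tally.counts[2] if tally else np.nan,
                "n_uninformative": tally.n_uninformative if tally else np.nan,
                "ica": res.ica if res else np.nan,
                "sign_basis": res.sign_basis if res else "",
                "oldest_year": edge_years.get(key, np.nan),
            }
        )
    branches = pd.DataFrame(branch_rows)
    paths["branches"] = os.path.join(out_dir, "branches.csv")
    branches.to_csv(paths["branches"], index=False)

    # --- regression -------------------------------------------------------
    points = list(zip(branches["decisive_count"], branches["ica"]))
    regressions = {}
    for name, lo, hi in (
        ("all", None, None),
        ("bounded", float(cfg["reg_lower"]), float(cfg["reg_upper"])),
    ):
        try:
            fit = ica_stats.regress_support_vs_depth(points, lo, hi)
            regressions[name] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.r,
                "r2": fit.r2,
                "pvalue": fit.pvalue,
                "n": fit.n,
                "lower_excl": lo,
                "upper_excl": hi,
            }
        except ValueError as exc:
            regressions[name] = {"error": str(exc)}
    paths["regression"] = os.path.join(out_dir, "regression.json")
    _json_dump(regressions, paths["regression"])

    # --- monophyly --------------------------------------------------------
    pct_not_rejected = None
    if taxonomy is not None:
        report = annotation.test_family_monophyly(tree, taxonomy)
        paths["monophyly"] = os.path.join(out_dir, "monophyly.csv")
        report.statuses.to_csv(paths["monophyly"], index=False)
        pct_not_rejected = report.pct_not_rejected
        if truth is not None:
            merged = report.statuses.merge(truth, on="family")
            mismatch = merged[
                (merged["status"] == "not_rejected") != merged["monophyletic_truth"]
            ]
            if len(mismatch):
                log.warning("%d families disagree with construction truth", len(mismatch))

    # --- annotated trees --------------------------------------------------
    paths["tree_counts"] = os.path.join(out_dir, "tree_decisive_counts.nex")
    with open(paths["tree_counts"], "w") as fh:
        fh.write(
            write_figtree_annotations(
                tree, {k: float(v) for k, v in counts.items()}, cfg["palette_counts"]
            )
        )
    ica_values = {k: r.ica for k, r in ica_results.items()}
    paths["tree_ica"] = os.path.join(out_dir, "tree_ica.nex")
    with open(paths["tree_ica"], "w") as fh:
        fh.write(write_figtree_annotations(tree, ica_values, cfg["palette_ica"]))

    # --- summary ----------------------------------------------------------
    thresholds = {
        f"pct_branches_lt_{k}_loci": 100.0 * float((count_values < k).mean())
        for k in cfg["count_thresholds"]
    }
    summary = {
        "config_hash": cfg_hash,
        "seed": seed,
        "n_tips": tree.n_tips,
        "n_loci": len(partitions.loci),
        "n_internal_branches": len(counts),
        **summary_stats,
        "d_hat": estimate.d_hat,
        "d_se": estimate.se,
        "n_trees_sampled": estimate.n_trees,
        **thresholds,
        "pct_families_not_rejected": pct_not_rejected,
        "mean_ica": float(np.nanmean(branches["ica"])) if len(branches) else None,
        "pct_branches_positive_ica": (
            100.0 * float((branches["ica"] > 0).mean()) if len(branches) else None
        ),
    }
    paths["summary"] = os.path.join(out_dir, "summary.json")
    _json_dump(summary, paths["summary"])
    return {"summary": summary, "paths": paths}
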