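"""End-to-end orchestration: simulate -> merge -> normalize/DE -> cluster ->
enrich -> screen, with plain-TSV/JSON stage outputs and a machine-readable
run report whose counts are checked for internal arithmetic consistency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .cluster import center_profiles, cluster_pattern_stats, kmeans_pearson, pca_samples
from .de import SignificanceThresholds, adjust_and_call, fit_moderated, summarize_de
from .enrichment import enrich_sets
from .errors import LabyprotError
from .merge import build_nonredundant, map_detected, reciprocal_best_hits, write_merge_map
from .normalize import batch_correct, glog_normalize
from .screen import (ScreenConfig, bin_deltas, classify_lineage, combine_candidates,
                     concordance_crosstab, orthogroup_filter, select_top_hits)
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    k: int = 4
    n_restarts: int = 25


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_all(config: RunConfig) -> dict:
    """Run every stage on a fresh simulation; returns the run report dict.

    All randomness derives from ``config.seed``; repeated runs write
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})

    report: dict = {"seed": config.seed, "stages": {}}

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        matrix, truth, hits, orthogroups, lineages, annotations = simulate_all(sim)
        lio.write_intensity_table(matrix, out / "intensity.tsv", out / "design.tsv")
        lio.write_hit_table(hits.screen_hits, out / "screen_hits.tsv")
        lio.write_hit_table(hits.hits_ab, out / "hits_ab.tsv")
        lio.write_hit_table(hits.hits_ba, out / "hits_ba.tsv")
        lio.write_orthogroups(orthogroups, out / "orthogroups.tsv")
        lio.write_annotation_map(annotations, out / "annotations.tsv")
        truth.write(out / "truth.tsv")
        pd.Series(hits.taxon_map, name="taxon_class").rename_axis("subject") \
            .to_frame().to_csv(out / "taxon_map.tsv", sep="\t")
        report["stages"][stage] = {"n_proteins": matrix.n_proteins,
                                   "n_samples": len(matrix.values.columns)}

        # --- merge ----------------------------------------------------------
        stage = "merge"
        pairs = reciprocal_best_hits(hits.hits_ab, hits.hits_ba)
        merge = build_nonredundant(matrix.protein_ids, hits.ids_b, pairs,
                                   hits.hits_ab, hits.hits_ba)
        detected_a = set(matrix.values.index[matrix.values.notna().any(axis=1)])
        detected = map_detected(detected_a, set(), merge)
        write_merge_map(merge, out / "merge_map.tsv")
        report["stages"][stage] = {**merge.counts(), "n_detected": len(detected)}

        # --- normalize + DE -------------------------------------------------
        stage = "de"
        normalized = batch_correct(glog_normalize(matrix))
        params, table = fit_moderated(normalized)
        calls = adjust_and_call(table, config.thresholds)
        summary = summarize_de(calls)
        calls.to_csv(out / "contrasts.tsv", sep="\t", index=False, float_format="%.8g")
        de_counts = {
            "n_up": summary.n_up, "n_down": summary.n_down,
            "n_unique_de": summary.n_unique_de,
            "n_both_directions": summary.n_both_directions,
            "per_timepoint_up": summary.per_timepoint_up,
            "per_timepoint_down": summary.per_timepoint_down,
            "exclusively_up_at": summary.exclusively_up_at,
            "down_at_all": summary.down_at_all,
            "prior_df": params.d0, "prior_var": params.s0_sq,
        }
        _write_json(de_counts, out / "summary.json")
        report["stages"][stage] = de_counts

        # --- cluster --------------------------------------------------------
        stage = "cluster"
        de_ids = sorted(set(summary.up_timepoints) | set(summary.down_timepoints))
        profiles_all = center_profiles(normalized).loc[de_ids]
        profiles = profiles_all.dropna(axis=0)
        n_incomplete = len(profiles_all) - len(profiles)
        model = kmeans_pearson(profiles, normalized.design, k=config.k,
                               seed=config.seed, n_restarts=config.n_restarts)
        pca = pca_samples(normalized)
        model.assignments.rename("cluster").rename_axis("protein_id") \
            .to_frame().to_csv(out / "assignments.tsv", sep="\t")
        model.centroids.to_csv(out / "centroids.tsv", sep="\t", float_format="%.8g")
        pca.sample_scores.round(8).to_csv(out / "pca.tsv", sep="\t")
        pattern = cluster_pattern_stats(model, calls)
        pattern.to_csv(out / "cluster_patterns.tsv", sep="\t", float_format="%.8g")
        report["stages"][stage] = {
            "cluster_sizes": model.sizes(),
            "n_excluded_profiles": len(model.excluded),
            "n_incomplete_profiles": n_incomplete,
            "pc1_variance_fraction": float(pca.variance_fraction[0]),
            "pc2_variance_fraction": float(pca.variance_fraction[1]),
            "inertia": model.inertia,
        }

        # --- enrichment -----------------------------------------------------
        stage = "enrich"
        background = set(detected) & set(matrix.protein_ids)
        foregrounds = {name: set(model.members(name)) & background
                       for name in model.centroids.index}
        foregrounds["up"] = set(summary.up_timepoints) & background
        foregrounds["down"] = set(summary.down_timepoints) & background
        enr = enrich_sets(annotations, foregrounds, background)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.8g")
        report["stages"][stage] = {
            "n_tests": int(len(enr)),
            "n_over_flagged": int(enr["over_flag"].sum()) if len(enr) else 0,
            "n_under_flagged": int(enr["under_flag"].sum()) if len(enr) else 0,
        }

        # --- lineage screen -------------------------------------------------
        stage = "screen"
        screen_hits = hits.screen_hits.copy()
        screen_hits["taxon_class"] = screen_hits["subject"].map(hits.taxon_map)
        top = select_top_hits(screen_hits, config.screen.top_n)
        lineage_calls = bin_deltas(classify_lineage(top, matrix.protein_ids,
                                                    config.screen.top_n))
        og_flags = orthogroup_filter(orthogroups, summary, config.screen,
                                     matrix.protein_ids)
        candidates = combine_candidates(lineage_calls, og_flags, summary, config.screen)
        pd.DataFrame([{
            "protein_id": r.protein_id, "passed_blast": r.passed_blast,
            "passed_orthogroup": r.passed_orthogroup, "group": r.group,
            "quantile_bin": r.quantile_bin,
            "upregulated_at": ",".join(sorted(r.upregulated_at)),
        } for r in candidates]).to_csv(out / "candidates.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "query": c.query, "group": c.group, "delta_bitscore": c.delta_bitscore,
            "delta_log10_evalue": c.delta_log10_evalue, "delta_pident": c.delta_pident,
            "quantile_bin": c.quantile_bin,
        } for c in lineage_calls]).to_csv(out / "lineage_calls.tsv", sep="\t",
                                          index=False, float_format="%.8g")
        group_counts = pd.Series([c.group for c in lineage_calls]).value_counts().to_dict()
        report["stages"][stage] = {
            "n_candidates": len(candidates),
            "n_blast_route": sum(r.passed_blast for r in candidates),
            "n_orthogroup_route": sum(r.passed_orthogroup for r in candidates),
            "group_counts": group_counts,
        }

        # --- concordance with planted truth ---------------------------------
        stage = "concordance"
        protein_calls = {p: "up" for p in summary.up_timepoints}
        protein_calls.update({p: "down" for p in summary.down_timepoints
                              if p not in protein_calls})
        truth_calls = {}
        for pid, arch in truth.frame["archetype"].items():
            if arch in ("C3", "C4"):
                truth_calls[pid] = "up"
            elif arch in ("C1", "C2"):
                truth_calls[pid] = "down"
        crosstab = concordance_crosstab(protein_calls, truth_calls)
        crosstab.to_csv(out / "crosstab.tsv", sep="\t")
        report["stages"][stage] = {
            "n_shared": int(crosstab.to_numpy().sum()),
            "n_concordant": int(np.diag(crosstab.to_numpy()).sum()),
            "n_discordant": int(crosstab.to_numpy().sum()
                                - np.diag(crosstab.to_numpy()).sum()),
        }
    except LabyprotError as exc:
        raise LabyprotError(f"stage {stage!r} failed: {exc}") from exc

    # --- arithmetic identities --------------------------------------------
    d = report["stages"]
    identities = {
        "merge_conservation": (
            d["merge"]["rbh_pairs"] * 2 + d["merge"]["unpaired_a"]
            + d["merge"]["unpaired_b"] + d["merge"]["dropped"]
            == d["simulate"]["n_proteins"] + len(hits.ids_b)
        ),
        "de_uniqueness": (
            d["de"]["n_up"] + d["de"]["n_down"] - d["de"]["n_both_directions"]
            == d["de"]["n_unique_de"]
        ),
        "cluster_cover": (
            sum(d["cluster"]["cluster_sizes"].values())
            + d["cluster"]["n_excluded_profiles"]
            + d["cluster"]["n_incomplete_profiles"] == d["de"]["n_unique_de"]
        ),
        "candidate_union": (
            d["screen"]["n_candidates"]
            <= d["screen"]["n_blast_route"] + d["screen"]["n_orthogroup_route"]
        ),
    }
    report["identities"] = identities
    if not all(identities.values()):
        logger.warning("report identities violated: %s",
                       [k for k, v in identities.items() if not v])
    _write_json(report, out / "report.json")
    return report
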