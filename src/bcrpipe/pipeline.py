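"""End-to-end cohort analysis: QC -> diversity -> clonotypes -> features -> stats.

`run_pipeline` drives the full analysis on a list of repertoires (simulated
or read from AIRR files) and writes every per-stage output under one
directory.  Stages mirror the study's analysis plan: depth QC, rarefied
diversity and composition bins, cross-subject clonotype clustering, gene
usage with targeted six-feature testing, SHM / N-glycosylation / isotype
summaries, the case/control classifier, and the high-IGHV3-30 subset
network comparison.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clonotyping, diversity, features, stats
from .io import (
    Repertoire,
    apply_depth_threshold,
    filter_productive,
    flag_aberrant_repertoires,
    qc_report,
    read_airr,
    read_metadata,
    split_repertoires,
)

SIX_FEATURES = stats.DEFAULT_CLASSIFIER_FEATURES


def run_pipeline(
    repertoires: Sequence[Repertoire],
    outdir: str | Path,
    seed: int = 0,
    min_umis: int = 1500,
    diversity_subsample: int = 1000,
    diversity_iterations: int = 1000,
    clonotype_threshold: float = 0.15,
    subset_gene: str = "IGHV3-30",
    subset_subjects: int = 10,
    subset_umis: int = 5000,
) -> dict:
    """Run every analysis stage and return a summary dictionary.

    Deterministic for a fixed seed.  Writes per-stage CSV/TSV/GraphML
    outputs under ``outdir`` and a ``summary.json`` of the headline numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- QC ---------------------------------------------------------------
    included, excluded = apply_depth_threshold(list(repertoires), min_umis=min_umis)
    qc = qc_report(list(repertoires))
    qc.to_csv(outdir / "qc_report.csv", index=False)
    flag_aberrant_repertoires(included).to_csv(outdir / "aberrant_report.csv", index=False)
    groups = pd.Series({r.subject_id: r.group for r in included})

    # --- diversity --------------------------------------------------------
    div_rows = []
    for rep in included:
        result = diversity.resampled_diversity(
            rep,
            unit="cdr3",
            subsample_size=diversity_subsample,
            iterations=diversity_iterations,
            rng=rng,
        )
        bins = diversity.composition_bins(rep)
        div_rows.append(
            {
                "subject_id": rep.subject_id,
                "group": rep.group,
                "shannon": result.shannon,
                "gini": result.gini,
                "unit": result.unit,
                "subsample": result.subsample_size,
                "iterations": result.iterations,
                **bins,
            }
        )
    div_table = pd.DataFrame(div_rows)
    div_table.to_csv(outdir / "diversity.csv", index=False)

    # --- clonotyping ------------------------------------------------------
    pooled = pd.concat(
        [filter_productive(rep.records) for rep in included], ignore_index=True
    )
    assignment = clonotyping.cluster_clonotypes(pooled, threshold=clonotype_threshold)
    ct_table = clonotyping.clonotype_table(pooled, assignment)
    ct_table.to_csv(outdir / "clonotypes.csv", index=False)

    # --- features ---------------------------------------------------------
    usage_v = features.gene_usage_matrix(included, "v")
    usage_d = features.gene_usage_matrix(included, "d")
    usage_j = features.gene_usage_matrix(included, "j")
    usage_v.to_csv(outdir / "usage_v.csv")
    usage_d.to_csv(outdir / "usage_d.csv")
    usage_j.to_csv(outdir / "usage_j.csv")
    usage_all = pd.concat([usage_v, usage_d, usage_j], axis=1)

    shm = features.shm_summary(included)
    shm.to_csv(outdir / "shm_summary.csv", index=False)
    isotypes = pd.DataFrame(
        {rep.subject_id: features.isotype_proportions(rep) for rep in included}
    ).T
    isotypes.index.name = "subject_id"
    isotypes["group"] = groups
    isotypes.to_csv(outdir / "isotype_proportions.csv")

    # --- group statistics -------------------------------------------------
    present_groups = sorted(groups.unique())
    comparisons = [
        (case, "HC") for case in ("ME_mm", "ME_sa") if case in present_groups
    ] if "HC" in present_groups else []
    summary: dict = {
        "n_subjects_input": len(list(repertoires)),
        "n_subjects_included": len(included),
        "n_subjects_excluded": len(excluded),
        "n_clonotypes": int(len(ct_table)),
        "median_shannon": float(div_table["shannon"].median()),
        "median_gini": float(div_table["gini"].median()),
        "seed": seed,
    }

    if comparisons:
        targeted = [g for g in SIX_FEATURES if g in usage_all.columns]
        six_tests = stats.mannwhitney_usage(
            usage_all, groups, comparisons, genes=targeted, m_tests=2
        )
        six_tests.to_csv(outdir / "six_feature_tests.csv", index=False)
        all_v_tests = stats.mannwhitney_usage(usage_v, groups, comparisons)
        all_v_tests.to_csv(outdir / "v_usage_tests.csv", index=False)
        if "IGHV3-30" in usage_v.columns and "ME_mm" in present_groups:
            case = usage_v.loc[groups[groups == "ME_mm"].index, "IGHV3-30"]
            control = usage_v.loc[groups[groups == "HC"].index, "IGHV3-30"]
            summary["ighv3_30_cohens_d_memm_vs_hc"] = stats.cohens_d(case, control)
            row = six_tests.query("feature == 'IGHV3-30' and comparison == 'ME_mm_vs_HC'")
            if len(row):
                summary["ighv3_30_p_adjusted_memm_vs_hc"] = float(row["p_adjusted"].iloc[0])
        correlations = {
            f"{a}_vs_HC": stats.median_usage_correlation(usage_v, groups, a, "HC")
            for a in present_groups
            if a != "HC"
        }
        summary["median_usage_r2"] = correlations

    if len(present_groups) >= 3:
        shannon_by_group = {
            g: div_table.loc[div_table["group"] == g, "shannon"].to_numpy()
            for g in present_groups
        }
        omnibus, dunn = stats.kruskal_dunn(shannon_by_group)
        dunn.to_csv(outdir / "shannon_dunn.csv", index=False)
        summary["shannon_kruskal_p"] = omnibus.p_raw
        igm_by_group = {
            g: isotypes.loc[isotypes["group"] == g, "IgM"].to_numpy() for g in present_groups
        }
        igm_omnibus, igm_dunn = stats.kruskal_dunn(igm_by_group)
        igm_dunn.to_csv(outdir / "igm_dunn.csv", index=False)
        summary["igm_kruskal_p"] = igm_omnibus.p_raw

    classifier_reports = {}
    for case in ("ME_mm", "ME_sa"):
        if case in present_groups and "HC" in present_groups:
            report = stats.run_classifier_experiment(
                usage_all, groups, case_group=case, control_group="HC",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            classifier_reports[case] = report
            summary[f"classifier_{case}_auc_train"] = report.auc_train
            summary[f"classifier_{case}_auc_test"] = report.auc_test
            report.roc_test.to_csv(outdir / f"roc_test_{case}.csv", index=False)
    if classifier_reports:
        with open(outdir / "classifier_reports.json", "w") as fh:
            json.dump(
                {
                    case: {
                        "features": list(r.features),
                        "coefficients": [float(c) for c in r.coefficients],
                        "used_ridge": r.used_ridge,
                        "train_subjects": r.train_subjects,
                        "test_subjects": r.test_subjects,
                        "auc_train": r.auc_train,
                        "auc_test": r.auc_test,
                        "seed": r.seed,
                    }
                    for case, r in classifier_reports.items()
                },
                fh,
                indent=2,
            )

    # PCA of the six features over case/control groups
    if comparisons and all(g in usage_all.columns for g in SIX_FEATURES):
        scores, explained, _ = stats.pca_features(usage_all[list(SIX_FEATURES)])
        scores.assign(group=groups).to_csv(outdir / "pca_scores.csv")
        summary["pca_explained_variance"] = [float(x) for x in explained]

    # --- high-usage subset networks ----------------------------------------
    subset_summary = _subset_network_analysis(
        included,
        usage_v,
        groups,
        outdir,
        rng,
        gene=subset_gene,
        n_subjects=subset_subjects,
        total_umis=subset_umis,
        threshold=clonotype_threshold,
        subsample=diversity_subsample,
        iterations=min(diversity_iterations, 200),
    )
    if subset_summary:
        summary["subset_analysis"] = subset_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _subset_network_analysis(
    included: Sequence[Repertoire],
    usage_v: pd.DataFrame,
    groups: pd.Series,
    outdir: Path,
    rng: np.random.Generator,
    gene: str,
    n_subjects: int,
    total_umis: int,
    threshold: float,
    subsample: int,
    iterations: int,
    k: float = 1.0,
) -> dict | None:
    """Network comparison of high-usage case subjects vs random controls.

    Selects case subjects whose usage of ``gene`` exceeds the control mean
    by one control SD, samples the same number of controls at random,
    subsets both groups to the gene's records at matched depth, clusters
    clonotypes, and reports per-group Shannon entropy (on clonotypes), IgM
    fraction and mean mutation frequency alongside the exported networks.
    """
    if gene not in usage_v.columns or "ME_mm" not in set(groups) or "HC" not in set(groups):
        return None
    high = clonotyping.select_high_usage_subjects(
        usage_v, groups, gene, case_group="ME_mm", reference_group="HC", k=k
    )
    if not high:
        return None
    usage_high = usage_v.loc[high, gene].sort_values(ascending=False)
    case_subjects = list(usage_high.index[:n_subjects])
    hc_members = sorted(groups.index[groups == "HC"])
    control_subjects = sorted(
        rng.choice(hc_members, size=min(len(case_subjects), len(hc_members)), replace=False)
    )

    by_subject = {rep.subject_id: rep for rep in included}
    chosen = case_subjects + control_subjects
    pooled = pd.concat(
        [filter_productive(by_subject[s].records) for s in chosen], ignore_index=True
    )
    from .io import strip_allele_series

    pooled = pooled[strip_allele_series(pooled["v_call"]) == gene].reset_index(drop=True)
    if len(pooled) == 0:
        return None
    subset_groups = pd.Series(
        {s: ("case" if s in case_subjects else "control") for s in chosen}
    )
    total = min(
        total_umis,
        int(pooled.groupby(subset_groups.reindex(pooled["subject_id"]).to_numpy())
            ["duplicate_count"].sum().min()),
    )
    matched = clonotyping.subsample_matched(
        pooled,
        subset_groups,
        n_subjects=len(case_subjects),
        total_umis=total,
        rng=rng,
        subjects_by_group={"case": case_subjects, "control": control_subjects},
    )
    assignment = clonotyping.cluster_clonotypes(matched, threshold=threshold)
    feats = features.record_features(matched)
    mut_freq = pd.Series(feats["mutation_frequency"].to_numpy(), index=matched.index)
    network = clonotyping.build_network(matched, assignment, mutation_frequency=mut_freq)
    network.write_graphml(outdir / f"network_{gene}.graphml")
    network.write_edge_list(outdir / f"network_{gene}_edges.tsv")

    result: dict = {
        "gene": gene,
        "case_subjects": case_subjects,
        "control_subjects": [str(s) for s in control_subjects],
        "umis_per_group": total,
    }
    for label in ("case", "control"):
        side_subjects = case_subjects if label == "case" else control_subjects
        side = matched[matched["subject_id"].isin(side_subjects)].reset_index(drop=True)
        side = side.assign(
            clonotype_id=assignment.loc[
                matched.index[matched["subject_id"].isin(side_subjects)]
            ].to_numpy()
        )
        depth = int(side["duplicate_count"].sum())
        sub = min(subsample, depth)
        div = diversity.resampled_diversity(
            side, unit="clonotype", subsample_size=sub, iterations=iterations, rng=rng
        )
        side_feats = features.record_features(side)
        w = side_feats["duplicate_count"].to_numpy(dtype=float)
        result[label] = {
            "shannon_clonotype": div.shannon,
            "igm_fraction": features.isotype_proportions(side)["IgM"],
            "mean_mutation_frequency": float(
                np.average(side_feats["mutation_frequency"], weights=w)
            ),
        }
    return result


def run_pipeline_from_files(
    airr_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    **kwargs,
) -> dict:
    """Read an AIRR TSV + metadata TSV and run the full pipeline."""
    records = read_airr(airr_path)
    metadata = read_metadata(metadata_path)
    repertoires = split_repertoires(records, metadata)
    return run_pipeline(repertoires, outdir, **kwargs)
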