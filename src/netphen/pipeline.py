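"""End-to-end runner tying the stages into one analysis graph:

QC (edge outliers, subject exclusion) -> residualization -> univariate
comparisons with FDR and interval-null BF/PPA evidence -> NBS -> density-
curve graph metrics and block-level FC means -> evidence.

Every random stage consumes a named child seed spawned from the config
seed; reruns with an identical config are bit-identical. The manifest
records the config (and its hash), seeds, exclusions and software
version, which is enough to reproduce any number in the reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GROUP_CASE, Cohort
from .compare import GroupComparison, adjust_family
from .evidence import evaluate_evidence
from .graphs import (
    GLOBAL_METRICS,
    CurveComparison,
    DensityGrid,
    block_means,
    density_upper_bound,
    metric_curves,
    modularity_participation_curves,
)
from .io import RunConfig, read_cohort, write_cohort
from .nbs import NetworkBasedStatistic
from .preprocess import (
    build_design,
    detect_edge_outliers,
    general_factor,
    residualize,
)

log = logging.getLogger("netphen")

_STAGE_SEEDS = ("nbs", "curves", "curve_perm")


def _named_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_SEEDS))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(_STAGE_SEEDS, children)
    }


def _family_prior(config: RunConfig, family: str, n_tests: int) -> float:
    if family in config.family_priors:
        return float(config.family_priors[family])
    # hypothesis-driven default for small families, 1/m for exploratory ones
    return 0.1 if n_tests <= 10 else 1.0 / n_tests


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run the full analysis; writes the report bundle to
    ``config.output_dir`` and returns it as a dict."""
    if cohort is None:
        cohort, load_report = read_cohort(config.data_dir)
    else:
        load_report = {"subjects_without_matrix": [], "orphan_matrices": []}
    config.validate_columns(cohort.phenotypes)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _named_seeds(config.seed)
    log.info("load: %d subjects, %d with matrices",
             len(cohort.phenotypes), len(cohort.matrices))

    bundle: dict = {"exclusions": {}, "seeds": seeds}

    # ---- QC ---------------------------------------------------------------
    excluded: list[str] = []
    if cohort.matrices:
        qc = detect_edge_outliers(
            cohort.matrices, sd_cut=config.sd_cut, subject_cut=config.subject_cut
        )
        excluded = qc.excluded_subject_ids
        bundle["exclusions"]["outlier_subjects"] = excluded
        qc.per_subject_count.to_csv(out / "qc_outlier_counts.csv")
        log.info("qc: %d subjects flagged (> %d outlier edges)",
                 len(excluded), qc.subject_cut)

    # ---- residualized measures + comparisons ------------------------------
    design = build_design(cohort.phenotypes, confounders=config.confounders)
    measures = {}
    scores = cohort.phenotypes[list(config.measures)] if config.measures else None
    if scores is not None and scores.shape[1] >= 2:
        gf = general_factor(scores, anchor=config.anchor_test)
        measures["g"] = pd.Series(gf.scores, name="g")
    if scores is not None:
        for col in scores.columns:
            measures[col] = scores[col]

    comparisons, evid = [], []
    for name, values in measures.items():
        rm = residualize(
            values, design, transform=config.transforms.get(name, "none"), name=name
        )
        res = GroupComparison(rm.values, cohort.groups, name=name).fit()
        comparisons.append(res)
    if comparisons:
        adjust_family(comparisons, "cognition")
        prior = _family_prior(config, "cognition", len(comparisons))
        for res in comparisons:
            evid.append(
                evaluate_evidence(
                    res.measure, res.statistic, res.n_case, res.n_control, prior
                ).to_row()
            )
        pd.DataFrame([r.to_row() for r in comparisons]).to_csv(
            out / "comparisons.csv", index=False
        )
        log.info("compare: %d measures in family 'cognition'", len(comparisons))

    # ---- imaging subset ----------------------------------------------------
    nbs_report: list[dict] = []
    curve_rows: list[pd.DataFrame] = []
    block_rows: list[dict] = []
    imaging = cohort.imaging_subset()
    keep = [s for s in imaging.subject_ids if s not in excluded]
    if len(keep) >= 8:
        img = Cohort(
            phenotypes=imaging.phenotypes.loc[keep],
            matrices={s: imaging.matrices[s] for s in keep},
            parcels=imaging.parcels,
            seed=imaging.seed,
        )
        ids, stack = img.connectome_stack()
        img_design = design.loc[ids].to_numpy(float)
        groups = img.groups.loc[ids].to_numpy()
        case_mask = groups == GROUP_CASE
        n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
        labels = (
            list(img.parcels["label"]) if img.parcels is not None else None
        )

        # ---- NBS -----------------------------------------------------------
        model = NetworkBasedStatistic(stack, groups, design=img_design,
                                      node_labels=labels)
        for thr in config.nbs_thresholds:
            fit = model.fit(
                thr,
                statistic=config.nbs_statistic,
                n_perm=config.nbs_n_perm,
                seed=seeds["nbs"],
            )
            for comp in fit.components:
                nbs_report.append(
                    {
                        "threshold": thr,
                        "statistic": config.nbs_statistic,
                        "extent": comp.extent,
                        "intensity": comp.intensity,
                        "p_extent": comp.p_extent,
                        "p_intensity": comp.p_intensity,
                        "exhaustive": fit.exhaustive,
                        "edges": comp.edge_labels(model.node_labels),
                    }
                )
            log.info("nbs: threshold %.3g -> %d components", thr, len(fit.components))
        with open(out / "nbs_components.json", "w") as fh:
            json.dump(nbs_report, fh, indent=1, sort_keys=True)

        # ---- graph metric curves -------------------------------------------
        if config.run_graph_metrics:
            bound = min(config.density_max,
                        density_upper_bound(list(img.matrices.values()), "union"))
            n_possible = img.n_nodes * (img.n_nodes - 1) // 2
            lowest = max(1, int(np.ceil(100 / n_possible)))  # first density with >=1 edge
            grid = DensityGrid(percents=tuple(range(lowest, bound + 1)), sign="positive")
            shared = {}
            if {"modularity", "participation"} <= set(config.graph_metrics):
                mod_c, part_c = modularity_participation_curves(
                    stack, grid,
                    seed=seeds["curves"], n_restarts=config.louvain_restarts,
                )
                shared = {"modularity": mod_c, "participation": part_c}
            for metric in config.graph_metrics:
                if metric in shared:
                    curves = shared[metric]
                else:
                    curves = metric_curves(
                        stack, grid, metric,
                        seed=seeds["curves"], n_restarts=config.louvain_restarts,
                    )
                cc = CurveComparison(
                    curves[case_mask], curves[~case_mask], metric=metric,
                    node_labels=labels,
                )
                res = cc.fit(n_perm=config.curve_n_perm, seed=seeds["curve_perm"])
                df = res.summary()
                if metric in GLOBAL_METRICS:
                    prior = _family_prior(config, "graph_global", len(GLOBAL_METRICS))
                    avg = curves.mean(axis=-1)
                    t = GroupComparison(
                        pd.Series(avg, index=ids), img.groups.loc[ids], name=metric
                    ).fit().statistic
                    evid.append(
                        evaluate_evidence(f"graph:{metric}", t, n1, n2, prior).to_row()
                    )
                curve_rows.append(df)
                log.info("graph: %s over 1-%d%% density", metric, bound)
            pd.concat(curve_rows, ignore_index=True).to_csv(
                out / "curve_tests.csv", index=False
            )

        # ---- block-level FC means ------------------------------------------
        if img.parcels is not None:
            per_subj = [block_means(img.matrices[s], img.module_of) for s in ids]
            mods = list(per_subj[0].within.index)
            tables = {"whole": pd.DataFrame({"whole": [b.whole for b in per_subj]},
                                            index=ids)}
            tables["within"] = pd.DataFrame(
                {f"within_{m}": [b.within[m] for b in per_subj] for m in mods},
                index=ids,
            )
            tables["to_rest"] = pd.DataFrame(
                {f"to_rest_{m}": [b.to_rest[m] for b in per_subj] for m in mods},
                index=ids,
            )
            pair_cols = {}
            for a_pos, a in enumerate(mods):
                for b in mods[a_pos + 1:]:
                    pair_cols[f"pair_{a}_{b}"] = [
                        bm.pair.loc[a, b] for bm in per_subj
                    ]
            tables["pair"] = pd.DataFrame(pair_cols, index=ids)
            for fam, table in tables.items():
                fam_results = []
                for col in table.columns:
                    rm = residualize(table[col], design.loc[ids], name=col)
                    fam_results.append(
                        GroupComparison(rm.values, img.groups, name=col).fit()
                    )
                adjust_family(fam_results, f"block_{fam}")
                block_rows.extend(r.to_row() for r in fam_results)
            pd.DataFrame(block_rows).to_csv(out / "block_tests.csv", index=False)
            log.info("blocks: %d block-level comparisons", len(block_rows))

    if evid:
        pd.DataFrame(evid).to_csv(out / "evidence.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "exclusions": bundle["exclusions"],
        "load_report": load_report,
        "n_subjects": len(cohort.phenotypes),
        "n_comparisons": len(comparisons),
        "n_nbs_components": len(nbs_report),
        "n_block_tests": len(block_rows),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle.update(manifest)
    bundle["output_dir"] = str(out)
    return bundle
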