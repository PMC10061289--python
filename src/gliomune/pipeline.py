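"""End-to-end orchestration of the radiogenomic workflow.

The four-stage design: (1) discover immune subtypes on an expression-only
discovery cohort (panel ssGSEA -> min-max normalization -> K selection ->
stabilized K-means); (2) replicate the subtypes in two radiogenomic cohorts
by centroid transfer and quantify replication with per-cluster IGP; (3) build
the radiomic signature on cohort 1 (feature extraction -> ICC filter ->
ComBat -> routed screen -> forest ranking -> top-10 retrain) and validate it
on cohort 2; (4) link the 10 signature features to pathway/cell-type
enrichment scores by BH-adjusted Pearson correlation in both cohorts and keep
the pairs that replicate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .characterize import de_screen, km_logrank, ora_hypergeometric
from .linkage import correlate, replication_check
from .quality import combat, icc_filter, icc_report
from .radiomics import extract_feature_vector
from .scoring import composite_scores, minmax_normalize, ssgsea_scores
from .signature import evaluate, predict, rank_and_select, screen_features, train_signature
from .subtypes import (
    align_labels,
    assign_nearest_centroid,
    compute_igp,
    select_k,
    stabilized_kmeans,
)
from .synthetic import CohortConfig, SyntheticCohort, make_cohort

logger = logging.getLogger("gliomune")

__all__ = ["PipelineConfig", "extract_cohort_features", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Study-level knobs: cohort sizes mirror the intended three-cohort design."""

    n_discovery: int = 210
    n_rg1: int = 130
    n_rg2: int = 55
    k: int | str = "auto"
    n_iterations: int = 1000
    subsample: float = 0.8
    n_repeatability: int = 50
    icc_threshold: float = 0.85
    alpha: float = 0.25
    n_select: int = 10
    seed: int = 0
    cohort: CohortConfig = None  # template; sizes/seeds overridden per cohort

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortConfig()


def extract_cohort_features(
    cohort: SyntheticCohort,
    sample_ids: list[str] | None = None,
    mask_kind: str = "true",
    n_bins: int = 32,
    normalize: bool = False,
) -> pd.DataFrame:
    """Samples x features table from a cohort's volumes and masks."""
    if not cohort.volumes:
        raise ValueError("cohort was generated without images")
    mask_sets = {
        "true": cohort.masks,
        "rater2": cohort.masks_rater2,
        "intra2": cohort.masks_intra2,
    }
    try:
        masks = mask_sets[mask_kind]
    except KeyError:
        raise ValueError(f"unknown mask kind {mask_kind!r}") from None
    ids = sample_ids if sample_ids is not None else cohort.sample_ids
    rows = {}
    for sid in ids:
        rows[sid] = extract_feature_vector(
            cohort.volumes[sid],
            masks[sid],
            spacing=cohort.config.voxel_spacing,
            n_bins=n_bins,
            normalize=normalize,
        )
    return pd.DataFrame(rows).T


def _score_cohort(cohort: SyntheticCohort, alpha: float) -> pd.DataFrame:
    scores = ssgsea_scores(cohort.expression, cohort.panel, alpha=alpha)
    return minmax_normalize(scores)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full workflow on three freshly generated synthetic cohorts.

    Returns a result bundle (also written to ``out_dir`` when given) with the
    cluster model, IGP values, signature evaluation and replicated
    feature-pathway pairs.
    """
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(6)
    ]
    logger.info("pipeline seed=%d derived cohort seeds=%s", config.seed, seeds[:3])

    disc_cfg = replace(
        config.cohort, n_samples=config.n_discovery, with_images=False, seed=seeds[0]
    )
    rg1_cfg = replace(config.cohort, n_samples=config.n_rg1, seed=seeds[1])
    rg2_cfg = replace(config.cohort, n_samples=config.n_rg2, seed=seeds[2])
    discovery = make_cohort(disc_cfg)
    rg1 = make_cohort(rg1_cfg)
    rg2 = make_cohort(rg2_cfg)

    # ---- stage 1: subtype discovery
    disc_scores = _score_cohort(discovery, config.alpha)
    if config.k == "auto":
        k, report = select_k(disc_scores, seed=seeds[3])
    else:
        k, report = int(config.k), None
    model, disc_labels = stabilized_kmeans(
        disc_scores,
        k,
        n_iterations=config.n_iterations,
        subsample=config.subsample,
        seed=seeds[3],
    )
    composites = composite_scores(disc_scores, discovery.role_map)

    # ---- stage 2: replication by centroid transfer + IGP
    igp: dict[str, dict[str, float]] = {}
    transferred: dict[str, pd.Series] = {}
    for name, cohort in (("rg1", rg1), ("rg2", rg2)):
        scores = _score_cohort(cohort, config.alpha)
        labels_transfer, _ = assign_nearest_centroid(model, scores)
        _, denovo = stabilized_kmeans(
            scores,
            k,
            n_iterations=config.n_iterations,
            subsample=config.subsample,
            seed=seeds[4],
        )
        aligned, _, _ = align_labels(labels_transfer, denovo)
        igp[name] = compute_igp(aligned, labels_transfer)
        transferred[name] = labels_transfer

    # ---- stage 3: characterization on the discovery cohort
    de_tables = {
        st: de_screen(discovery.expression, disc_labels, st)
        for st in sorted(disc_labels.unique())
    }
    universe = frozenset(discovery.expression.index)
    ora_rows = []
    for st, table in de_tables.items():
        hits = frozenset(table.index[table["differential"]])
        for pw in discovery.pathways.names:
            p, overlap = ora_hypergeometric(hits, discovery.pathways[pw], universe)
            ora_rows.append(
                {"subtype": st, "pathway": pw, "p_value": p, "overlap": overlap}
            )
    ora = pd.DataFrame(ora_rows)
    survival_curves = km_logrank(discovery.clinical, disc_labels)

    # ---- stage 4: radiomic signature on rg1, validation on rg2
    rg1_features = extract_cohort_features(rg1)
    rg2_features = extract_cohort_features(rg2)
    repeat_ids = rg1.sample_ids[: config.n_repeatability]
    base = rg1_features.loc[repeat_ids]
    rater2 = extract_cohort_features(rg1, repeat_ids, mask_kind="rater2")
    intra2 = extract_cohort_features(rg1, repeat_ids, mask_kind="intra2")
    icc = icc_report(base, rater2, intra2, threshold=config.icc_threshold)
    rg1_qc = icc_filter(rg1_features, icc)
    rg2_qc = rg2_features[rg1_qc.columns]
    rg1_harm, _ = combat(rg1_qc, rg1.batch)
    rg2_harm, _ = combat(rg2_qc, rg2.batch)

    y1, y2 = transferred["rg1"], transferred["rg2"]
    screen = screen_features(rg1_harm, y1)
    survivors = rg1_harm.loc[:, screen.index[screen["keep"]]]
    selected = rank_and_select(survivors, y1, n_select=config.n_select, seed=seeds[5])
    signature = train_signature(rg1_harm, y1, selected, seed=seeds[5])
    train_pred, _ = predict(signature, rg1_harm)
    evaluation = evaluate(signature, rg2_harm, y2, seed=seeds[5])

    # ---- stage 5: radiogenomic linkage + replication
    linkages = {}
    for name, cohort, feats in (
        ("rg1", rg1, rg1_harm),
        ("rg2", rg2, rg2_harm),
    ):
        pw_scores = minmax_normalize(
            ssgsea_scores(cohort.expression, cohort.pathways, alpha=config.alpha)
        )
        til_scores = _score_cohort(cohort, config.alpha)
        all_scores = pd.concat([pw_scores, til_scores])
        linkages[name] = correlate(feats[selected], all_scores, dataset=name)
    replicated = replication_check(linkages["rg1"], linkages["rg2"])

    results = {
        "cohorts": {"discovery": discovery, "rg1": rg1, "rg2": rg2},
        "chosen_k": k,
        "k_report": report,
        "model": model,
        "discovery_labels": disc_labels,
        "composite_scores": composites,
        "igp": igp,
        "de_tables": de_tables,
        "ora": ora,
        "survival": survival_curves,
        "icc_report": icc,
        "selected_features": selected,
        "signature": signature,
        "train_accuracy": float((train_pred == y1).mean()),
        "evaluation": evaluation,
        "linkage": linkages,
        "replicated_pairs": replicated,
    }
    if out_dir is not None:
        _write_bundle(results, Path(out_dir))
    return results


def _write_bundle(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results["model"].to_json(out / "model.json")
    results["discovery_labels"].to_csv(out / "labels_discovery.csv")
    pd.DataFrame(results["igp"]).to_csv(out / "igp.csv")
    for st, table in results["de_tables"].items():
        table.to_csv(out / f"de_{st}.tsv", sep="\t")
    results["ora"].to_csv(out / "ora.tsv", sep="\t", index=False)
    results["icc_report"].to_csv(out / "icc_report.csv")
    results["linkage"]["rg1"].to_csv(out / "linkage_train.csv", index=False)
    results["linkage"]["rg2"].to_csv(out / "linkage_test.csv", index=False)
    results["replicated_pairs"].to_csv(out / "replicated_pairs.csv", index=False)
    summary = {
        "chosen_k": results["chosen_k"],
        "igp": results["igp"],
        "selected_features": results["selected_features"],
        "train_accuracy": results["train_accuracy"],
        "validation": results["evaluation"].summary(),
        "logrank_p": results["survival"].p_value,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
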