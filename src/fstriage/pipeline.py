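"""End-to-end orchestration of the slide-triage pipeline.

simulate → segment (trained U-Net or ground-truth oracle) → stitch heatmaps →
feature bank → two-stage random forest → decision-tree triage → metrics.

The slide classifier is fit on the train+val splits (common subtypes only);
binary performance (AUC) is reported on the common-subtype test series and
triage metrics on the real-world series that adds the rare subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TwoStageRandomForest, auc
from .features import FeatureConfig, Heatmap, feature_vector
from .io import RunConfig
from .segmentation import OracleSegmenter, UNetSegmenter, predict_tiles
from .synthetic import SlideRecord, slides_in_test1, slides_in_test2
from .tiling import assemble_heatmap, build_tile_grid, extract_tiles, tissue_mask

__all__ = [
    "heatmap_from_oracle",
    "heatmap_from_model",
    "cohort_heatmaps",
    "cohort_feature_table",
    "fit_slide_classifier",
    "triage_table",
    "evaluate_cohort",
    "PipelineResult",
]

TRIAGE_COLUMNS = {
    "max_area_mm2": "lesion_area_mm2_max",
    "max_diameter_mm": "lesion_diameter_mm_max",
    "max_perimeter_mm": "lesion_perimeter_mm_max",
}


def heatmap_from_oracle(slide: SlideRecord, oracle: OracleSegmenter) -> Heatmap:
    """Stitch the oracle's probability map through the tile grid (so the
    core-crop path is exercised even without a trained model)."""
    grid = build_tile_grid(slide.image.shape[:2])
    return assemble_heatmap(grid, oracle.tile_probs(grid), slide.mpp, slide.slide_id)


def heatmap_from_model(slide: SlideRecord, model: UNetSegmenter) -> Heatmap:
    grid = build_tile_grid(slide.image.shape[:2])
    tiles = extract_tiles(slide.image, grid, fill=255)
    probs = predict_tiles(model, tiles, tile_size=grid.tile_size)
    return assemble_heatmap(grid, probs, slide.mpp, slide.slide_id)


def _oracle_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, 7, index)).generate_state(1)[0] % 2**31)


def cohort_heatmaps(
    slides: list[SlideRecord],
    seed: int,
    noise_sd: float = 0.1,
    flip_rate: float = 0.05,
    model: UNetSegmenter | None = None,
) -> dict[str, Heatmap]:
    """One heatmap per slide, via the trained model when given, otherwise via
    per-slide oracles seeded from one global seed."""
    out: dict[str, Heatmap] = {}
    for idx, slide in enumerate(slides):
        if model is not None:
            hm = heatmap_from_model(slide, model)
        else:
            oracle = OracleSegmenter(
                slide, noise_sd=noise_sd, flip_rate=flip_rate, seed=_oracle_seed(seed, idx)
            )
            hm = heatmap_from_oracle(slide, oracle)
        out[slide.slide_id] = hm
    return out


def cohort_feature_table(
    slides: list[SlideRecord],
    heatmaps: dict[str, Heatmap],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Named feature bank, one row per slide (index = slide_id)."""
    rows = []
    for slide in slides:
        tissue = tissue_mask(slide.image)
        rows.append(feature_vector(heatmaps[slide.slide_id], tissue, config))
    table = pd.DataFrame(rows)
    table.index.name = "slide_id"
    return table


def fit_slide_classifier(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    n_estimators: int = 500,
    top_k: int = 30,
    random_state: int = 0,
) -> TwoStageRandomForest:
    """Fit the two-stage forest on the train+val slides."""
    fit_ids = manifest.loc[manifest["split"].isin(["train", "val"]), "slide_id"]
    labels = manifest.set_index("slide_id").loc[fit_ids, "binary_label"]
    model = TwoStageRandomForest(
        n_estimators=n_estimators, top_k=top_k, random_state=random_state
    )
    model.fit(features.loc[fit_ids], labels.to_numpy())
    return model


def triage_table(features: pd.DataFrame, model: TwoStageRandomForest) -> pd.DataFrame:
    """Decision-tree inputs per slide: rf probability and lesion maxima."""
    table = pd.DataFrame(index=features.index)
    table["rf_prob"] = model.malignancy_probability(features)
    for out_col, feat_col in TRIAGE_COLUMNS.items():
        table[out_col] = features[feat_col]
    return table


@dataclass
class PipelineResult:
    features: pd.DataFrame
    model: TwoStageRandomForest
    triage_inputs: pd.DataFrame
    triage: pd.DataFrame  # adds category + truth columns on the test2 set
    auc_test1: float
    metrics: "object"  # TriageMetrics over the test2 set


def evaluate_cohort(
    manifest: pd.DataFrame,
    slides: list[SlideRecord],
    config: RunConfig | None = None,
    model: UNetSegmenter | None = None,
) -> PipelineResult:
    """Run segmentation → features → classifier → triage → metrics."""
    from .triage import RelabeledTruth, TriageTree, relabel_ground_truth, triage_metrics

    config = config or RunConfig()
    heatmaps = cohort_heatmaps(
        slides,
        seed=config.seed,
        noise_sd=config.oracle.noise_sd,
        flip_rate=config.oracle.flip_rate,
        model=model,
    )
    fcfg = FeatureConfig(
        threshold=config.binarize_threshold, min_lesion_area_mm2=config.min_lesion_area_mm2
    )
    features = cohort_feature_table(slides, heatmaps, fcfg)
    rf = fit_slide_classifier(
        features,
        manifest,
        n_estimators=config.forest.n_estimators,
        top_k=config.forest.top_k,
        random_state=config.seed,
    )
    inputs = triage_table(features, rf)

    meta = manifest.set_index("slide_id")
    t1 = slides_in_test1(manifest)
    auc_test1 = auc(
        inputs.loc[t1, "rf_prob"].to_numpy(),
        (meta.loc[t1, "binary_label"] == "malignant").astype(int).to_numpy(),
    )

    tree = TriageTree(**config.thresholds.model_dump())
    t2 = slides_in_test2(manifest)
    results = tree.classify(inputs.loc[t2])
    truth = []
    for sid in t2:
        pred = "malignant" if inputs.loc[sid, "rf_prob"] >= config.thresholds.prob_cut else "benign"
        truth.append(
            RelabeledTruth(
                slide_id=sid,
                subtype=str(meta.loc[sid, "subtype"]),
                binary_pred=pred,
                category=relabel_ground_truth(
                    str(meta.loc[sid, "subtype"]), pred, str(meta.loc[sid, "binary_label"])
                ),
            )
        )
    metrics = triage_metrics(results, truth, thresholds=tree.thresholds)

    triage_df = inputs.loc[t2].copy()
    triage_df["category"] = [r.category for r in results]
    triage_df["truth_category"] = [t.category for t in truth]
    triage_df["subtype"] = meta.loc[t2, "subtype"]
    return PipelineResult(
        features=features,
        model=rf,
        triage_inputs=inputs,
        triage=triage_df,
        auc_test1=auc_test1,
        metrics=metrics,
    )
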