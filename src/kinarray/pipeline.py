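"""End-to-end orchestration: ingest → preprocess → test → classify → cluster.

`run_pipeline` composes the library stages in the order the analysis
prescribes and writes every artifact with a JSON provenance sidecar that
records the full configuration, so any output directory can be reproduced
exactly from its own metadata.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import array_io, clustering, diffstats, multivariate, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    signal_path: str
    annotation_path: str
    output_dir: str
    panel_path: str | None = None
    inhibitor: str = "vemurafenib"
    alpha: float = 0.05
    t_variant: str = "pooled"  # or "welch"
    n_components: int = 2
    scale: bool = False
    cluster_distance: str = "one_minus_pearson"
    cluster_linkage: str = "average"
    floor: float = preprocess.DEFAULT_FLOOR
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")
        if self.inhibitor not in ("vemurafenib", "sunitinib"):
            raise ValueError(f"unknown inhibitor {self.inhibitor!r}")
        if self.cluster_distance not in clustering.DISTANCES:
            raise ValueError(f"unknown distance {self.cluster_distance!r}")
        if self.cluster_linkage not in clustering.LINKAGES:
            raise ValueError(f"unknown linkage {self.cluster_linkage!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")
        for p in (self.signal_path, self.annotation_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def braf_groups(annotations: pd.DataFrame, sample_ids) -> dict[str, list[str]]:
    """Partition samples into BRAF wild-type / V600E for the two-group contrast.

    Samples with undetermined BRAF status are excluded (with a log notice),
    as are samples absent from the matrix.
    """
    present = set(sample_ids)
    ann = annotations[
        (annotations["tissue"] == "melanoma")
        & annotations["sample_id"].isin(present)
    ]
    unknown = sorted(ann.loc[ann["braf"] == "unknown", "sample_id"])
    if unknown:
        logger.info("excluding %d sample(s) with unknown BRAF status: %s",
                    len(unknown), unknown)
    return {
        "wild_type": sorted(ann.loc[ann["braf"] == "wild_type", "sample_id"]),
        "V600E": sorted(ann.loc[ann["braf"] == "V600E", "sample_id"]),
    }


def _write_sidecar(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the map of artifact names to paths."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = asdict(config)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    exp = array_io.read_experiment(
        config.signal_path, config.annotation_path, config.panel_path
    )
    logger.info(
        "ingest: %d measurements, %d samples, %d peptides",
        len(exp.measurements), len(exp.sample_ids), len(exp.peptide_panel),
    )

    # basal profiles (series-centered)
    basal = preprocess.basal_profiles(exp, floor=config.floor)
    artifacts["basal_matrix"] = out / "basal_matrix.csv"
    basal.values.to_csv(artifacts["basal_matrix"], float_format="%.10g")
    _write_sidecar(
        out / "basal_matrix.meta.json",
        {"provenance": basal.provenance, "settings": settings},
    )

    # inhibition profiles
    profile = preprocess.compute_lfc(exp, config.inhibitor, floor=config.floor)
    artifacts["lfc_matrix"] = out / "lfc_matrix.csv"
    profile.lfc.to_csv(artifacts["lfc_matrix"], float_format="%.10g")
    _write_sidecar(
        out / "lfc_matrix.meta.json",
        {"inhibitor": profile.inhibitor, "settings": settings},
    )

    # per-peptide differential testing on the inhibition profiles
    groups = braf_groups(exp.annotations, profile.sample_ids)
    results = diffstats.test_all_peptides(
        profile, groups, alpha=config.alpha, variant=config.t_variant
    )
    table = diffstats.results_frame(results).rename(
        columns={"mean_a": "mean_wt", "mean_b": "mean_mut"}
    )
    artifacts["ttest_results"] = out / "ttest_results.csv"
    table.to_csv(artifacts["ttest_results"], index=False, float_format="%.10g")

    signature = diffstats.select_signature(
        results, alpha=config.alpha,
        source=f"BRAF wild-type vs V600E on {config.inhibitor} LFC",
    )
    artifacts["signature"] = out / "signature.txt"
    artifacts["signature"].write_text("\n".join(signature.peptide_ids) + "\n")
    k, m = len(signature), len(results)
    fdr = {
        "n_tested": m,
        "n_significant": k,
        "alpha": config.alpha,
        "plug_in_fdr_all_m": diffstats.plug_in_fdr(m, k, config.alpha) if k else None,
        "plug_in_fdr_m_minus_k": (
            diffstats.plug_in_fdr(m, k, config.alpha, "m_minus_k") if k else None
        ),
    }
    _write_sidecar(out / "signature.meta.json", {**fdr, "settings": settings})
    logger.info("diffstats: %d/%d peptides significant at alpha=%g",
                k, m, config.alpha)

    # PCA of the inhibition profiles
    n_pc = min(3, len(profile.sample_ids) - 1, len(profile.peptide_ids))
    pca = multivariate.pca_fit(profile, n_components=n_pc)
    scores = pd.DataFrame(
        pca.scores,
        index=pca.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_pc)],
    )
    artifacts["pca_scores"] = out / "pca_scores.csv"
    scores.to_csv(artifacts["pca_scores"], float_format="%.10g")
    _write_sidecar(
        out / "pca_scores.meta.json",
        {
            "explained_variance_fraction":
                pca.explained_variance_fraction.tolist(),
            "settings": settings,
        },
    )

    # PLS-DA with LOOCV on BRAF status (unknowns excluded)
    labelled = groups["wild_type"] + groups["V600E"]
    X = profile.lfc.loc[labelled]
    y = ["wild_type"] * len(groups["wild_type"]) + ["V600E"] * len(groups["V600E"])
    cv = multivariate.loocv(
        X, y, n_components=config.n_components, scale=config.scale,
        classes=("wild_type", "V600E"),
    )
    artifacts["loocv_report"] = out / "loocv_report.csv"
    cv.frame().to_csv(artifacts["loocv_report"], index=False, float_format="%.10g")
    _write_sidecar(
        out / "loocv_summary.json",
        {
            "overall_accuracy": cv.overall_accuracy,
            "per_class_accuracy": cv.per_class_accuracy,
            "invalid_folds": cv.invalid_folds,
            "settings": settings,
        },
    )
    logger.info("loocv: overall accuracy %.3f", cv.overall_accuracy)

    # clustering of samples on the signature-restricted inhibition profiles
    if len(signature) >= 1:
        ordered = clustering.signature_heatmap_order(
            profile, signature,
            distance=config.cluster_distance, linkage=config.cluster_linkage,
        )
        artifacts["signature_heatmap"] = out / "signature_heatmap_matrix.csv"
        ordered.to_csv(artifacts["signature_heatmap"], float_format="%.10g")
        artifacts["sample_leaf_order"] = out / "sample_leaf_order.txt"
        artifacts["sample_leaf_order"].write_text(
            "\n".join(map(str, ordered.index)) + "\n"
        )

    _write_sidecar(
        out / "pipeline.json",
        {
            "settings": settings,
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "elapsed_seconds": round(time.perf_counter() - t0, 3),
        },
    )
    return artifacts
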