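"""End-to-end orchestration: simulate/load -> extract -> select -> classify -> stats.

A run takes either a synthetic :class:`~nodetex.synthetic.CohortSpec`
or a directory of NIfTI volume/mask pairs with a labels CSV, and emits
a report directory:

- ``features.csv`` — one row per lesion, one column per feature name;
- ``fisher_ranking.csv`` — Fisher coefficients, ranks, selection flags;
- ``group_comparison.csv`` — per selected feature: group medians/IQR and
  the Mann-Whitney p;
- ``roc_per_feature.csv`` — AUC with CI, Youden index, criterion,
  sensitivity/specificity with CIs per selected feature;
- ``regression.csv`` / ``combined_roc.csv`` — the multivariate block and
  the ROC of its fitted values;
- ``knn_report.csv`` — leave-one-out KNN accuracy;
- ``summary.txt`` and ``run_log.json`` (seed, config hash, versions).

Every stage is a pure function of (inputs, config, seed); report CSVs
are written with a fixed float format so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .modeling import KNNConfig, knn_loo_accuracy, rank_and_select
from .stats import combined_roc, compare_rocs, mann_whitney, multiple_regression, roc_analysis
from .synthetic import CohortSpec, Lesion, generate_cohort
from .texture import FeatureGrid, extract_all, features_table
from .volume_io import load_volume_and_mask, normalize_quantize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_cohort_dir", "extract_features"]

FLOAT_FORMAT = "%.10g"
POSITIVE_CLASS = "malignant"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name (and lesion id if per-lesion)."""

    def __init__(self, stage: str, message: str, lesion_id: str | None = None):
        self.stage = stage
        self.lesion_id = lesion_id
        where = f"stage {stage!r}" + (f", lesion {lesion_id!r}" if lesion_id else "")
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``cohort_spec`` (synthetic mode) or ``input_dir``
    (directory of ``*_vol.nii.gz`` / ``*_mask.nii.gz`` pairs plus
    ``labels.csv``) must be given.
    """

    cohort_spec: CohortSpec | None = None
    input_dir: str | None = None
    bits: int = 6
    grid: FeatureGrid = field(default_factory=FeatureGrid)
    top_k: int = 10
    fisher_cutoff: float = 3.0
    knn: KNNConfig = field(default_factory=KNNConfig)
    out_dir: str = "nodetex_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.input_dir is None):
            raise ValueError("exactly one of cohort_spec or input_dir must be set")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        payload = encode(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort_dir(input_dir: str | Path) -> list[Lesion]:
    """Load lesions from a directory written by :func:`generate_cohort`."""
    root = Path(input_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise PipelineError("load", f"missing labels CSV at {labels_path}")
    table = pd.read_csv(labels_path)
    lesions = []
    for _, row in table.iterrows():
        lesion_id = str(row["lesion_id"])
        vol_path = root / f"{lesion_id}_vol.nii.gz"
        mask_path = root / f"{lesion_id}_mask.nii.gz"
        if not vol_path.exists() or not mask_path.exists():
            raise PipelineError("load", "volume/mask files not found", lesion_id=lesion_id)
        volume, mask = load_volume_and_mask(vol_path, mask_path)
        lesions.append(Lesion(lesion_id, volume, mask, str(row["class"])))
    return lesions


def extract_features(lesions, bits: int, grid: FeatureGrid) -> pd.DataFrame:
    """Quantize every lesion and extract the full feature grid."""
    vectors = []
    labels = {}
    for lesion in lesions:
        try:
            roi = normalize_quantize(lesion.volume, lesion.mask, bits=bits)
            fv = extract_all(roi, grid=grid, lesion_id=lesion.lesion_id)
        except Exception as exc:  # pragma: no cover - defensive per-lesion context
            raise PipelineError("extract", str(exc), lesion_id=lesion.lesion_id) from exc
        if fv.n_missing:
            logger.warning("lesion %s: %d missing features", lesion.lesion_id, fv.n_missing)
        vectors.append(fv)
        labels[lesion.lesion_id] = lesion.label
    return features_table(vectors, labels)


def _roc_row(name: str, roc) -> dict:
    return {
        "feature": name,
        "auc": roc.auc,
        "auc_ci_low": roc.auc_ci[0],
        "auc_ci_high": roc.auc_ci[1],
        "p_vs_0.5": roc.p_auc_vs_half,
        "youden": roc.youden,
        "criterion": roc.criterion,
        "sensitivity_pct": 100 * roc.sensitivity,
        "sens_ci_low_pct": 100 * roc.sensitivity_ci[0],
        "sens_ci_high_pct": 100 * roc.sensitivity_ci[1],
        "specificity_pct": 100 * roc.specificity,
        "spec_ci_low_pct": 100 * roc.specificity_ci[0],
        "spec_ci_high_pct": 100 * roc.specificity_ci[1],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report directory.

    Returns a dict with the in-memory results: the feature table, the
    Fisher ranking, per-feature ROC results, the regression, combined
    ROC, KNN report and the paths written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate / load -------------------------------------------------
    try:
        if config.cohort_spec is not None:
            spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
            lesions = generate_cohort(spec)
        else:
            lesions = load_cohort_dir(config.input_dir)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate/load", str(exc)) from exc

    # --- extract ---------------------------------------------------------
    table = extract_features(lesions, bits=config.bits, grid=config.grid)
    labels = table["class"].to_numpy()
    feats = table.drop(columns=["class"])
    table.to_csv(out / "features.csv", float_format=FLOAT_FORMAT)

    # --- select ----------------------------------------------------------
    try:
        ranking = rank_and_select(
            feats, labels, top_k=config.top_k, cutoff=config.fisher_cutoff
        )
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    ranking.to_csv(out / "fisher_ranking.csv", float_format=FLOAT_FORMAT)
    selected = list(ranking.index[ranking["selected_top_k"]])

    # --- univariate + ROC ------------------------------------------------
    benign_mask = labels != POSITIVE_CLASS
    comparison_rows = []
    roc_rows = []
    rocs = {}
    try:
        for name in selected:
            x = feats[name].to_numpy(dtype=float)
            mw = mann_whitney(x[benign_mask], x[~benign_mask])
            comparison_rows.append(
                {
                    "feature": name,
                    "median_benign": mw.median_a,
                    "iqr_benign_low": mw.iqr_a[0],
                    "iqr_benign_high": mw.iqr_a[1],
                    "median_malignant": mw.median_b,
                    "iqr_malignant_low": mw.iqr_b[0],
                    "iqr_malignant_high": mw.iqr_b[1],
                    "U": mw.U,
                    "p": mw.p,
                }
            )
            roc = roc_analysis(x, labels, positive=POSITIVE_CLASS)
            rocs[name] = roc
            roc_rows.append(_roc_row(name, roc))
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    pd.DataFrame(comparison_rows).to_csv(
        out / "group_comparison.csv", index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(roc_rows).to_csv(
        out / "roc_per_feature.csv", index=False, float_format=FLOAT_FORMAT
    )

    # --- multivariate ----------------------------------------------------
    try:
        outcome = (labels == POSITIVE_CLASS).astype(float)
        regression = multiple_regression(feats[selected], outcome)
        comb = combined_roc(regression, labels, positive=POSITIVE_CLASS)
        top_feature = selected[0]
        comparison = compare_rocs(
            feats[top_feature].to_numpy(dtype=float),
            regression.fitted,
            labels,
            positive=POSITIVE_CLASS,
        )
    except Exception as exc:
        raise PipelineError("regression", str(exc)) from exc
    reg_table = regression.coefficients.copy()
    reg_table.to_csv(out / "regression.csv", float_format=FLOAT_FORMAT)
    pd.DataFrame([_roc_row("combined", comb)]).to_csv(
        out / "combined_roc.csv", index=False, float_format=FLOAT_FORMAT
    )

    # --- classify --------------------------------------------------------
    try:
        knn = knn_loo_accuracy(feats[selected], labels, config=config.knn)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    knn_df = pd.DataFrame(
        [
            {
                "k": config.knn.k,
                "accuracy_pct": knn["accuracy_pct"],
                "n": knn["n"],
                "n_correct": knn["n_correct"],
                **{f"misclassified_{c}": v for c, v in knn["misclassified_per_class"].items()},
            }
        ]
    )
    knn_df.to_csv(out / "knn_report.csv", index=False, float_format=FLOAT_FORMAT)

    # --- summary + log ---------------------------------------------------
    top = ranking.iloc[0]
    summary = [
        f"nodetex run (seed={config.seed}, config={config.config_hash()})",
        f"lesions: {len(lesions)} ({int(benign_mask.sum())} benign, {int((~benign_mask).sum())} malignant)",
        f"features extracted: {feats.shape[1]}",
        f"top feature: {ranking.index[0]} (F = {top['F']:.4g})",
        f"features passing F > {config.fisher_cutoff:g}: {int(ranking['passes_cutoff'].sum())}",
        f"top-{config.top_k} selected: {', '.join(selected)}",
        f"KNN (k={config.knn.k}) LOO accuracy: {knn['accuracy_pct']:.2f}%",
        f"top-feature AUC: {rocs[top_feature].auc:.3f} "
        f"({rocs[top_feature].auc_ci[0]:.3f}-{rocs[top_feature].auc_ci[1]:.3f})",
        f"combined model R2 = {regression.r2:.4f}, "
        f"sens = {100*comb.sensitivity:.2f}%, spec = {100*comb.specificity:.2f}%",
        f"ROC comparison top-vs-combined: p = {comparison['p']:.4g}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("nodetex")
    except Exception:
        pkg_version = "unknown"
    run_log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_lesions": len(lesions),
        "n_features": int(feats.shape[1]),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")

    return {
        "features": table,
        "ranking": ranking,
        "selected": selected,
        "group_comparison": pd.DataFrame(comparison_rows),
        "rocs": rocs,
        "regression": regression,
        "combined_roc": comb,
        "roc_comparison": comparison,
        "knn": knn,
        "out_dir": str(out),
    }
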