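"""End-to-end orchestration: phantoms -> preprocess -> segment -> features
-> classify -> evaluate, fully determined by one master seed.

``run_pipeline`` executes the classical path on a balanced synthetic
cohort and returns a ``RunReport`` with per-stage timings, the feature
table, the held-out confusion matrix and all derived metrics, plus
segmentation agreement against the generated ground truth.  The master
seed fans out to per-stage seeds through ``numpy.random.SeedSequence``
spawning, so any single stage can be re-run reproducibly in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import FeatureConfig, extract_feature_vector, FEATURE_NAMES
from .ml import CVResult, cross_validate
from .phantom import (
    LabeledImage,
    default_normal_spec,
    default_pcos_spec,
    generate_dataset,
)
from .preprocess import PreprocessConfig, preprocess_image
from .reference_tables import TableCheck, verify_reference_tables
from .segmentation import SegmentConfig, count_follicles, segment_follicles

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "verify_reference_tables"]


@dataclass
class PipelineConfig:
    """Everything a full classical run needs; ``seed`` is mandatory."""

    seed: int
    n_per_class: int = 40
    classifier: str = "sgd"
    test_fraction: float = 0.2
    pcos_spec_overrides: dict = field(default_factory=dict)
    normal_spec_overrides: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a plain mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config requires an explicit master seed")
        return cls(**raw)


@dataclass
class RunReport:
    config: PipelineConfig
    timings: dict[str, float]
    feature_table: pd.DataFrame
    cv: CVResult
    metrics_percent: dict[str, float | None]
    auc: float
    agreement: ev.AgreementReport
    count_errors: list[int]  # per-image |detected - true| follicle counts
    output_dir: Path | None = None

    @property
    def accuracy(self) -> float:
        return self.cv.accuracy


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def extract_features_for_dataset(
    dataset: list[LabeledImage],
    preprocess_cfg: PreprocessConfig,
    segment_cfg: SegmentConfig,
    feature_cfg: FeatureConfig,
) -> tuple[pd.DataFrame, list, list[int]]:
    """Preprocess, segment and featurize every image of a labeled set.

    Returns the feature table (one row per image, with label), the final
    segmentation masks, and per-image absolute follicle-count errors.
    """
    rows, masks, count_errors = [], [], []
    for item in dataset:
        pre = preprocess_image(item.image, preprocess_cfg)
        seg = segment_follicles(pre, segment_cfg)
        n_detected, _ = count_follicles(seg)
        fv = extract_feature_vector(pre, seg.mask, feature_cfg)
        row = {"label": item.label, "n_detected": n_detected, "n_true": item.n_follicles}
        row.update(fv.to_dict())
        rows.append(row)
        masks.append(seg)
        count_errors.append(abs(n_detected - item.n_follicles))
    return pd.DataFrame(rows), masks, count_errors


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> RunReport:
    """Run the full classical path; see the module docstring."""
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    pcos_spec = default_pcos_spec(**config.pcos_spec_overrides)
    normal_spec = default_normal_spec(**config.normal_spec_overrides)
    dataset = generate_dataset(config.n_per_class, pcos_spec, normal_spec, seed=seeds[0])
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seg_cfg = dataclasses.replace(
        config.segment, fcm=dataclasses.replace(config.segment.fcm, seed=seeds[1])
    )
    table, masks, count_errors = extract_features_for_dataset(
        dataset, config.preprocess, seg_cfg, config.features
    )
    timings["segment_features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    x = table[list(FEATURE_NAMES)].to_numpy()
    y = table["label"].to_numpy()
    cv = cross_validate(
        config.classifier, x, y, test_fraction=config.test_fraction, seed=seeds[2]
    )
    auc, _, _ = ev.roc_auc(cv.scores, cv.y_true)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spacing = dataset[0].spec.pixel_spacing
    agreement = ev.segmentation_agreement(
        [m.mask for m in masks], [d.mask for d in dataset], spacing
    )
    timings["agreement"] = time.perf_counter() - t0

    report = RunReport(
        config=config,
        timings=timings,
        feature_table=table,
        cv=cv,
        metrics_percent=ev.metrics(cv.confusion).as_percent(),
        auc=auc,
        agreement=agreement,
        count_errors=count_errors,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        cm = cv.confusion
        payload = {
            "seed": config.seed,
            "classifier": config.classifier,
            "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "metrics_percent": report.metrics_percent,
            "auc": auc,
            "agreement": {
                "mean_distance_mm": agreement.mean_distance_mm,
                "sd_distance_mm": agreement.sd_distance_mm,
                "r": agreement.r,
            },
            "median_abs_count_error": float(np.median(count_errors)),
            "timings_s": timings,
        }
        (out / "metrics.json").write_text(json.dumps(payload, indent=2))
        report.output_dir = out
    return report


def format_table_checks(checks: list[TableCheck]) -> str:
    """Human-readable verdict listing for the published-table fixtures."""
    lines = []
    for c in checks:
        verdict = "PASS" if c.passed else ("INFO" if c.passed is None else "FAIL")
        lines.append(
            f"{verdict:4s}  {c.name:42s} computed={c.computed:9.4f} "
            f"printed={c.expected:8.2f} tol={c.tolerance:g}"
            + (f"  [{c.note}]" if c.note else "")
        )
    n_checked = sum(c.passed is not None for c in checks)
    n_pass = sum(bool(c.passed) for c in checks)
    lines.append(f"{n_pass}/{n_checked} checks passed "
                 f"({len(checks) - n_checked} informational)")
    return "\n".join(lines)
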