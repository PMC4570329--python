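"""Dataset manifests, accuracy metrics and result serialisation.

Reporting conventions: per-image counting error is the absolute difference
between estimated and true count (signed errors are kept alongside for
diagnostic plots); single-image accuracy relates the mean absolute error
to the mean true count; sequence accuracy relates the de-duplicated
sequence total to the true distinct-plant total.  When several datasets
are combined, per-image error statistics are weighted by each dataset's
image count, while sequence accuracies are averaged unweighted (each
row-sequence is one experiment regardless of its length).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .counting import RegionOfInterest

__all__ = [
    "DatasetManifest",
    "MetricsReport",
    "single_image_accuracy",
    "sequence_accuracy",
    "overlap_error",
    "count_error_stats",
    "aggregate_report",
    "load_manifest",
    "save_manifest",
]


@dataclass(frozen=True)
class DatasetManifest:
    """One dataset: ordered frames, ROI, calibration and optional truth."""

    images: tuple[str, ...]
    roi: RegionOfInterest | None = None
    calibration: str | None = None
    true_counts: tuple[int, ...] | None = None
    true_distinct_total: int | None = None
    true_overlaps_pct: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.images) == 0:
            raise ValueError("manifest lists no images")
        if self.true_counts is not None and len(self.true_counts) != len(self.images):
            raise ValueError("true_counts length must match the image list")


@dataclass
class MetricsReport:
    """Counting and overlap metrics for one dataset (or an aggregate)."""

    n_images: int
    per_image_abs_errors: list[float] = field(default_factory=list)
    per_image_signed_errors: list[float] = field(default_factory=list)
    mean_abs_error: float = float("nan")
    std_abs_error: float = float("nan")
    single_image_accuracy_pct: float = float("nan")
    sequence_accuracy_pct: float = float("nan")
    mean_overlap_error_pct: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def single_image_accuracy(mean_abs_error: float, mean_truth: float) -> float:
    """Percent accuracy of per-image counting, to one decimal.

    100 * (1 - mean_abs_error / mean_truth); e.g. 0.51 mistakes out of
    10.54 plants per image gives 95.2.
    """
    if mean_truth <= 0:
        raise ValueError("mean true count must be > 0")
    return round(100.0 * (1.0 - mean_abs_error / mean_truth), 1)


def sequence_accuracy(estimated_total: float, true_total: float) -> float:
    """Percent accuracy of a de-duplicated sequence total."""
    if true_total <= 0:
        raise ValueError("true total must be > 0")
    return 100.0 * (1.0 - abs(estimated_total - true_total) / true_total)


def overlap_error(estimated_pct: float, actual_pct: float) -> float:
    """Absolute overlap-estimation error in percentage points."""
    for v in (estimated_pct, actual_pct):
        if not 0 <= v <= 100:
            raise ValueError(f"overlap percentage out of range: {v}")
    return abs(estimated_pct - actual_pct)


def count_error_stats(estimated: list[int], truth: list[int]) -> MetricsReport:
    """Per-image error statistics and single-image accuracy for one dataset."""
    if len(estimated) != len(truth):
        raise ValueError("estimated and true count lists differ in length")
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    signed = est - tru
    abs_err = np.abs(signed)
    report = MetricsReport(
        n_images=len(est),
        per_image_abs_errors=abs_err.tolist(),
        per_image_signed_errors=signed.tolist(),
        mean_abs_error=float(abs_err.mean()),
        std_abs_error=float(abs_err.std(ddof=0)),
    )
    if tru.mean() > 0:
        report.single_image_accuracy_pct = single_image_accuracy(abs_err.mean(), tru.mean())
    return report


def aggregate_report(per_set: list[MetricsReport], weights: list[float]) -> MetricsReport:
    """Combine per-dataset reports into an overall report.

    Per-image error means and accuracies are weighted by image counts;
    the overall sequence accuracy is the unweighted mean of the per-set
    sequence accuracies (each sequence is one experiment); overlap errors
    are averaged unweighted over sets for the same reason.
    """
    if len(per_set) != len(weights):
        raise ValueError("per_set and weights differ in length")
    if len(per_set) == 0:
        raise ValueError("nothing to aggregate")
    w = np.asarray(weights, dtype=np.float64)
    mean_err = np.array([r.mean_abs_error for r in per_set])
    out = MetricsReport(n_images=int(w.sum()))
    out.mean_abs_error = float((mean_err * w).sum() / w.sum())
    all_abs = [e for r in per_set for e in r.per_image_abs_errors]
    all_signed = [e for r in per_set for e in r.per_image_signed_errors]
    out.per_image_abs_errors = all_abs
    out.per_image_signed_errors = all_signed
    if all_abs:
        out.std_abs_error = float(np.std(all_abs, ddof=0))
    acc = np.array([r.single_image_accuracy_pct for r in per_set])
    if np.all(np.isfinite(acc)):
        out.single_image_accuracy_pct = round(float((acc * w).sum() / w.sum()), 1)
    seq = np.array([r.sequence_accuracy_pct for r in per_set])
    if np.all(np.isfinite(seq)):
        out.sequence_accuracy_pct = round(float(seq.mean()), 1)
    ovl = np.array([r.mean_overlap_error_pct for r in per_set])
    if np.all(np.isfinite(ovl)):
        out.mean_overlap_error_pct = float(ovl.mean())
    return out


def run_dataset(manifest: DatasetManifest, base_dir: str | Path = "."):
    """Run the full pipeline on a manifest: calibrate, count, de-duplicate.

    Uses the manifest's calibration file when given, otherwise
    auto-determines the straightening parameters on the first frame.
    Returns ``(sequence_count, report)`` where the report holds whatever
    metrics the manifest's ground truth allows.
    """
    from imageio.v3 import imread

    from .geometry import auto_determine_params, load_calibration
    from .registration import count_sequence

    base = Path(base_dir)
    images = [np.asarray(imread(base / p))[..., :3] for p in manifest.images]
    if manifest.calibration is not None:
        params, _ = load_calibration(base / manifest.calibration)
    else:
        params = auto_determine_params(images[0], roi=manifest.roi)
    seq = count_sequence(images, params, roi=manifest.roi)
    report = build_report(seq, manifest)
    return seq, report


def build_report(seq, manifest: DatasetManifest) -> MetricsReport:
    """Metrics for one processed dataset, given its available ground truth."""
    estimated = [c.n_plants for c in seq.image_counts]
    if manifest.true_counts is not None:
        report = count_error_stats(estimated, list(manifest.true_counts))
    else:
        report = MetricsReport(n_images=len(estimated))
    if manifest.true_distinct_total is not None:
        report.sequence_accuracy_pct = sequence_accuracy(
            seq.total, manifest.true_distinct_total
        )
    if manifest.true_overlaps_pct is not None and seq.pair_records:
        errs = [
            overlap_error(rec.overlap_pct, actual)
            for rec, actual in zip(seq.pair_records, manifest.true_overlaps_pct)
        ]
        if errs:
            report.mean_overlap_error_pct = float(np.mean(errs))
    return report


def per_image_dataframe(seq):
    """Per-image result records (one CSV row per frame)."""
    import pandas as pd

    return pd.DataFrame([c.to_record(image_id=str(i)) for i, c in enumerate(seq.image_counts)])


def per_pair_dataframe(seq):
    """Per-pair registration records (one CSV row per consecutive pair)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(seq.pair_records):
        rows.append(
            {
                "prev_frame": i,
                "curr_frame": i + 1,
                "n_matches": rec.n_matches,
                "n_inliers": rec.n_inliers,
                "h13": rec.h13,
                "affine_valid": rec.affine_valid,
                "fallback": rec.fallback,
                "overlap_pct": rec.overlap_pct,
                "n_duplicates": int(rec.decision.duplicate.sum()) if rec.decision else 0,
                "n_new": rec.decision.n_new if rec.decision else 0,
            }
        )
    return pd.DataFrame(rows)


def _roi_to_list(roi: RegionOfInterest) -> list[int]:
    return [roi.x_min, roi.x_max, roi.y_min, roi.y_max]


def save_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    doc: dict = {"images": list(manifest.images)}
    if manifest.roi is not None:
        doc["roi"] = _roi_to_list(manifest.roi)
    if manifest.calibration is not None:
        doc["calibration"] = manifest.calibration
    truth: dict = {}
    if manifest.true_counts is not None:
        truth["per_image_counts"] = list(manifest.true_counts)
    if manifest.true_distinct_total is not None:
        truth["distinct_total"] = manifest.true_distinct_total
    if manifest.true_overlaps_pct is not None:
        truth["per_pair_overlap_pct"] = list(manifest.true_overlaps_pct)
    if truth:
        doc["ground_truth"] = truth
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_manifest(path: str | Path) -> DatasetManifest:
    doc = yaml.safe_load(Path(path).read_text())
    roi = None
    if "roi" in doc:
        x_min, x_max, y_min, y_max = doc["roi"]
        roi = RegionOfInterest(x_min, x_max, y_min, y_max)
    truth = doc.get("ground_truth", {})
    return DatasetManifest(
        images=tuple(doc["images"]),
        roi=roi,
        calibration=doc.get("calibration"),
        true_counts=tuple(truth["per_image_counts"]) if "per_image_counts" in truth else None,
        true_distinct_total=truth.get("distinct_total"),
        true_overlaps_pct=(
            tuple(truth["per_pair_overlap_pct"]) if "per_pair_overlap_pct" in truth else None
        ),
    )
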