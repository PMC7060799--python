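"""Post-analysis quality control: consistency rules and curve classifiers.

Three families of checks run after volumetry/strain:

* geometric plane-consistency rules on the aligned study (do the LAX planes
  hit the LV in the basal and apical SAX slices; does each view's LV extent
  cover >= 90% of the other's along the long axis);
* clinical output rules (LV vs RV stroke volume within 10%; first vs last
  cardiac phase volumes within 10%);
* SVM curve-shape classifiers over normalized curve + scalar features,
  trained on labelled exemplars (see ``phantom.make_curve_dataset``).

Every rule reports its measured value and threshold for audit; any flagged
rule or anomalous classifier verdict flags the exam for clinician review.

A pre-analysis (image-quality) hook is exposed as ``QC1Hook`` so external
artefact/planning detectors can be plugged in; the package ships none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage

from .model import LV_LABELS, CineStudy, LabelledStack, intersect_planes, plane_of, slice_fov
from .volumetrics import VolumeCurve, VolumetryReport

QC_SCHEMA_VERSION = 1

#: pluggable pre-analysis QC: callable(study) -> list[QCRuleResult]
QC1Hook = Callable[[CineStudy], list]


def no_qc1(study: CineStudy) -> list:
    """Default pre-analysis hook: no image-quality screening."""
    return []


@dataclass
class QCRuleResult:
    rule_id: str
    status: str  # pass | flag | not_applicable
    measured_value: Optional[float] = None
    threshold: Optional[float] = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("pass", "flag", "not_applicable"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "flag" and not self.message:
            raise ValueError("flagged rules must carry a message")

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "status": self.status,
            "measured": self.measured_value,
            "threshold": self.threshold,
            "message": self.message,
        }


@dataclass
class SVMResult:
    label: str  # good | anomalous
    margin: float

    def to_dict(self) -> dict:
        return {"label": self.label, "margin": self.margin}


@dataclass
class QCVerdict:
    rules: list
    svm_volume: Optional[SVMResult] = None
    svm_strain: Optional[SVMResult] = None
    overall: str = "accept"

    def to_dict(self) -> dict:
        return {
            "rules": [r.to_dict() for r in self.rules],
            "svm": {
                "volume": self.svm_volume.to_dict() if self.svm_volume else None,
                "strain": self.svm_strain.to_dict() if self.svm_strain else None,
            },
            "overall": self.overall,
        }


def qc_verdict(
    rules: Sequence[QCRuleResult],
    svm_volume: Optional[SVMResult] = None,
    svm_strain: Optional[SVMResult] = None,
) -> QCVerdict:
    """Aggregate: flag_for_review iff any rule flags or any SVM is anomalous."""
    flagged = any(r.status == "flag" for r in rules)
    for svm in (svm_volume, svm_strain):
        if svm is not None and svm.label == "anomalous":
            flagged = True
    return QCVerdict(
        rules=list(rules),
        svm_volume=svm_volume,
        svm_strain=svm_strain,
        overall="flag_for_review" if flagged else "accept",
    )


# ---------------------------------------------------------------------------
# geometric plane-consistency rules
# ---------------------------------------------------------------------------


def _lv_extent_along(stack: LabelledStack, axis: np.ndarray, frame: int = 0):
    """(min, max) projection of LV-labelled voxel centres onto an axis (mm)."""
    lab = stack.labels[:, :, :, frame]
    idx = np.nonzero(np.isin(lab, LV_LABELS))
    if len(idx[0]) == 0:
        return None
    homog = np.stack([idx[0], idx[1], idx[2], np.ones(len(idx[0]))])
    world = (stack.affine @ homog)[:3]
    proj = axis @ world
    return float(proj.min()), float(proj.max())


def _line_crosses_lv(study: CineStudy, slice_index: int, lax: LabelledStack) -> Optional[bool]:
    sax = study.sax
    inter = intersect_planes(
        plane_of(sax, slice_index), plane_of(lax, 0),
        slice_fov(sax, slice_index), slice_fov(lax, 0),
    )
    if inter is None:
        return None
    inv = np.linalg.inv(sax.affine)
    pts = inter.sample_points
    homog = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
    vox = (inv @ homog.T)[:3]
    vox[2, :] = slice_index
    mask = np.isin(sax.labels[:, :, :, 0], LV_LABELS).astype(float)
    vals = ndimage.map_coordinates(mask, vox, order=1, mode="constant", cval=0.0)
    return bool(np.any(vals >= 0.5))


def check_plane_consistency(
    study: CineStudy, coverage_threshold: float = 0.90
) -> list:
    """The three geometric QC rules on an (already aligned) study."""
    sax = study.sax
    axis = sax.affine[:3, 2] / np.linalg.norm(sax.affine[:3, 2])

    lv_slices = [
        s
        for s in range(sax.n_slices)
        if np.isin(sax.labels[:, :, s, 0], LV_LABELS).any()
    ]
    # extreme slices for the intersection rule need a minimally meaningful
    # cross-section (>= 10 mm^2); a lone boundary voxel is not an anchor
    dr, dc = sax.voxel_size
    min_vox = max(int(np.ceil(10.0 / (dr * dc))), 1)
    anchor_slices = [
        s
        for s in lv_slices
        if np.isin(sax.labels[:, :, s, 0], LV_LABELS).sum() >= min_vox
    ] or lv_slices
    results: list[QCRuleResult] = []
    if not lv_slices:
        return [
            QCRuleResult(r, "not_applicable", message="no LV segmentation in SAX")
            for r in ("lax_intersects_sax_extremes", "sax_covers_lax", "lax_covers_sax")
        ]

    # rule (i): both LAX planes must cross LV labels in the most basal and
    # most apical segmented SAX slices
    checks, n_app = [], 0
    for lax in (study.lax2ch, study.lax4ch):
        for s in (anchor_slices[0], anchor_slices[-1]):
            hit = _line_crosses_lv(study, s, lax)
            if hit is not None:
                n_app += 1
                checks.append(hit)
    if n_app == 0:
        results.append(
            QCRuleResult(
                "lax_intersects_sax_extremes", "not_applicable",
                message="LAX planes do not intersect the SAX stack",
            )
        )
    else:
        frac = float(np.mean(checks))
        results.append(
            QCRuleResult(
                "lax_intersects_sax_extremes",
                "pass" if frac >= 1.0 else "flag",
                measured_value=frac,
                threshold=1.0,
                message="" if frac >= 1.0 else
                "a LAX plane misses the LV in a basal/apical SAX slice (possible off-axis planning)",
            )
        )

    # rules (ii)+(iii): long-axis LV extent coverage, symmetric, >= threshold
    sax_ext = _lv_extent_along(sax, axis)
    half = sax.slice_thickness / 2.0
    sax_iv = (sax_ext[0] - half, sax_ext[1] + half)
    lax_exts = [
        e
        for e in (
            _lv_extent_along(study.lax2ch, axis),
            _lv_extent_along(study.lax4ch, axis),
        )
        if e is not None
    ]
    if not lax_exts:
        for rid in ("sax_covers_lax", "lax_covers_sax"):
            results.append(
                QCRuleResult(rid, "not_applicable", message="no LV segmentation in LAX")
            )
        return results
    lax_iv = (min(e[0] for e in lax_exts), max(e[1] for e in lax_exts))

    def coverage(target, other):
        """Fraction of `target` extent overlapped by `other`."""
        lo = max(target[0], other[0])
        hi = min(target[1], other[1])
        span = target[1] - target[0]
        return max(0.0, hi - lo) / span if span > 0 else 0.0

    cov_of_lax = coverage(lax_iv, sax_iv)  # did SAX cover the LAX segmentation?
    results.append(
        QCRuleResult(
            "sax_covers_lax",
            "pass" if cov_of_lax >= coverage_threshold else "flag",
            measured_value=cov_of_lax,
            threshold=coverage_threshold,
            message="" if cov_of_lax >= coverage_threshold else
            f"SAX stack covers only {100 * cov_of_lax:.0f}% of the LAX LV extent (missing slices?)",
        )
    )
    cov_of_sax = coverage(sax_iv, lax_iv)
    results.append(
        QCRuleResult(
            "lax_covers_sax",
            "pass" if cov_of_sax >= coverage_threshold else "flag",
            measured_value=cov_of_sax,
            threshold=coverage_threshold,
            message="" if cov_of_sax >= coverage_threshold else
            f"LAX segmentation reaches only {100 * cov_of_sax:.0f}% of the SAX LV extent",
        )
    )
    return results


# ---------------------------------------------------------------------------
# clinical output rules
# ---------------------------------------------------------------------------


def check_output_rules(
    lv: VolumetryReport,
    rv: VolumetryReport,
    lv_curve: VolumeCurve,
    rv_curve: VolumeCurve,
    sv_tolerance: float = 0.10,
    closure_tolerance: float = 0.10,
) -> list:
    """LV/RV stroke-volume agreement and first/last-phase closure rules.

    The SV difference is taken relative to the mean of the two stroke
    volumes (configurable denominator convention).
    """
    results = []
    mean_sv = 0.5 * (lv.sv + rv.sv)
    if mean_sv <= 0:
        results.append(
            QCRuleResult(
                "sv_difference", "flag", measured_value=None, threshold=sv_tolerance,
                message="degenerate SV",
            )
        )
    else:
        rel = abs(lv.sv - rv.sv) / mean_sv
        results.append(
            QCRuleResult(
                "sv_difference",
                "pass" if rel <= sv_tolerance else "flag",
                measured_value=rel,
                threshold=sv_tolerance,
                message="" if rel <= sv_tolerance else
                f"LV SV {lv.sv:.0f} ml vs RV SV {rv.sv:.0f} ml differ by {100 * rel:.1f}%",
            )
        )
    worst, chamber = 0.0, ""
    for curve in (lv_curve, rv_curve):
        v0, v_end = curve.values[0], curve.values[-1]
        if v0 <= 0:
            worst, chamber = np.inf, curve.chamber
            continue
        gap = abs(v0 - v_end) / v0
        if gap > worst:
            worst, chamber = gap, curve.chamber
    results.append(
        QCRuleResult(
            "phase_closure",
            "pass" if worst <= closure_tolerance else "flag",
            measured_value=None if np.isinf(worst) else worst,
            threshold=closure_tolerance,
            message="" if worst <= closure_tolerance else
            f"{chamber} volume differs by {100 * worst:.1f}% between first and last phase",
        )
    )
    return results


# ---------------------------------------------------------------------------
# curve features and SVM classifiers
# ---------------------------------------------------------------------------

N_SHAPE_POINTS = 32


def curve_features(values: np.ndarray, times: Optional[np.ndarray] = None) -> np.ndarray:
    """Deterministic feature vector: normalized 32-point shape + scalars.

    Scalars: fractional excursion (EF-like), normalized up/down rates,
    closure gap, largest frame-to-frame jump, and the position of the
    extremum in the cycle.  Amplitude normalization is guarded so constant
    curves yield finite features.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 20:
        raise ValueError("curve_features needs at least 20 samples")
    t = np.linspace(0.0, 1.0, len(v))
    ts = np.linspace(0.0, 1.0, N_SHAPE_POINTS)
    shape = np.interp(ts, t, v)
    amp = shape.max() - shape.min()
    denom = amp if amp > 1e-9 else 1.0
    shape_n = (shape - shape.min()) / denom

    dv = np.diff(v)
    scale = max(np.abs(v).max(), 1e-9)
    excursion = amp / scale
    closure = abs(v[0] - v[-1]) / max(amp, 1e-9)
    max_jump = np.abs(dv).max() / max(amp, 1e-9)
    up = dv.max() / max(amp, 1e-9)
    down = -dv.min() / max(amp, 1e-9)
    extremum_pos = (np.argmin(v) if abs(v.min() - v[0]) > abs(v.max() - v[0]) else np.argmax(v)) / len(v)
    scalars = np.array([excursion, closure, max_jump, up, down, extremum_pos])
    return np.concatenate([shape_n, scalars])


@dataclass
class QCClassifier:
    """Fitted curve-shape classifier with its cross-validated accuracy."""

    pipeline: object
    kind: str
    cv_balanced_accuracy: float
    seed: int
    version: int = QC_SCHEMA_VERSION

    def predict_curve(self, values: np.ndarray) -> SVMResult:
        x = curve_features(values)[None, :]
        y = int(self.pipeline.predict(x)[0])
        margin = float(self.pipeline.decision_function(x)[0])
        return SVMResult(label="anomalous" if y == 1 else "good", margin=margin)

    def save(self, path) -> None:
        joblib.dump(
            {
                "pipeline": self.pipeline,
                "kind": self.kind,
                "cv_balanced_accuracy": self.cv_balanced_accuracy,
                "seed": self.seed,
                "version": self.version,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "QCClassifier":
        d = joblib.load(path)
        if d.get("version") != QC_SCHEMA_VERSION:
            raise ValueError("incompatible classifier file version")
        return cls(
            pipeline=d["pipeline"],
            kind=d["kind"],
            cv_balanced_accuracy=d["cv_balanced_accuracy"],
            seed=d["seed"],
        )


def train_qc_svm(
    dataset,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma="scale",
    seed: int = 0,
    cv_folds: int = 5,
) -> QCClassifier:
    """Soft-margin kernel SVM on standardized curve features, 5-fold CV."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both good and bad curves")
    X = np.stack([curve_features(c) for c in dataset.curves])
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed))]
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    bacc = float(np.mean(cross_val_score(pipe, X, y, cv=cv, scoring="balanced_accuracy")))
    pipe.fit(X, y)
    return QCClassifier(pipeline=pipe, kind=dataset.kind, cv_balanced_accuracy=bacc, seed=seed)
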