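"""Facial metric computation from 20-point landmark sets.

Seven metrics are computed, all in millimetre units (pixel-unit landmark
sets are converted first; they must carry a scale):

* ``PAR`` — perimeter-to-area ratio (1/mm) of the lower-face polygon
  running P3 → P5 → P2 → P6 → P4 → P3.  Lower PAR means a rounder face.
* ``WHR`` — facial width-to-height ratio: cheekbone width d(P3,P4) over
  the brow-to-upper-lip height d(P7,P8).  Larger WHR means a wider face.
* ``CJWR`` — cheek-to-jaw-width ratio: d(P3,P4) / d(P5,P6).  Smaller CJWR
  means a squarer face.
* ``eye_size`` (mm) — mean single-eye width,
  (d(P9,P10) − d(P11,P12)) / 2 with outer minus inner corner spans.
* ``LF_FH`` — lower-face to face-height ratio: the vertical distance *a*
  between the chin line (through P2) and the pupil line (through P13 and
  P14), divided by d(P1,P2).
* ``FW_LFH`` — face-width to lower-face-height ratio: d(P3,P4) / a.
* ``EH_mean`` (mm) — mean eyebrow height: mean of the six distances from
  each periocular point P9..P14 to its primed eyebrow point.

"Horizontal line" distances (*a*) use |Δy| following the image convention
with heads postured upright; all other distances are Euclidean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet

__all__ = [
    "MetricVector",
    "METRIC_NAMES",
    "polygon_perimeter_area",
    "par",
    "whr",
    "cjwr",
    "eye_size",
    "lf_fh",
    "fw_lfh",
    "eh_mean",
    "metric_vector",
    "metrics_table",
    "reliability_cv",
]

#: Metric column order used throughout the package.
METRIC_NAMES: tuple[str, ...] = (
    "PAR",
    "WHR",
    "CJWR",
    "eye_size",
    "LF_FH",
    "FW_LFH",
    "EH_mean",
)

_POLYGON_CYCLE = ("P3", "P5", "P2", "P6", "P4")


@dataclass(frozen=True)
class MetricVector:
    """The seven facial metrics plus the intermediate lower-face height *a* (mm)."""

    PAR: float
    WHR: float
    CJWR: float
    eye_size: float
    LF_FH: float
    FW_LFH: float
    EH_mean: float
    a: float

    def as_dict(self, include_a: bool = True) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if include_a:
            d["a"] = self.a
        return d


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polygon_perimeter_area(vertices: np.ndarray) -> tuple[float, float]:
    """Closed-cycle perimeter and absolute shoelace area of a simple polygon.

    ``vertices`` is an (n, 2) array in cyclic order (closing edge implied).
    Raises ``ValueError`` on self-intersection or zero area.
    """
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    nxt = np.roll(v, -1, axis=0)
    edges = nxt - v
    perimeter = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    area = 0.5 * float(np.sum(v[:, 0] * nxt[:, 1] - nxt[:, 0] * v[:, 1]))
    # check simplicity: no two non-adjacent edges may cross
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j - i) % n == 1 or (i - j) % n == 1:
                continue
            if _segments_intersect(v[i], nxt[i], v[j], nxt[j]):
                raise ValueError(
                    f"polygon is self-intersecting (edges {i} and {j} cross)"
                )
    area = abs(area)
    if area == 0.0:
        raise ValueError("polygon has zero area")
    return perimeter, area


def _lower_face_polygon(lm: LandmarkSet) -> np.ndarray:
    return np.array([lm.points[p] for p in _POLYGON_CYCLE], dtype=float)


def par(lm: LandmarkSet) -> float:
    """Perimeter-to-area ratio (1/mm) of the P3–P5–P2–P6–P4 polygon."""
    lm = lm.to_mm()
    perimeter, area = polygon_perimeter_area(_lower_face_polygon(lm))
    return perimeter / area


def whr(lm: LandmarkSet) -> float:
    """Facial width-to-height ratio d(P3,P4)/d(P7,P8)."""
    lm = lm.to_mm()
    height = lm.distance("P7", "P8")
    if height == 0:
        raise ValueError("WHR undefined: d(P7,P8) is zero")
    return lm.distance("P3", "P4") / height


def cjwr(lm: LandmarkSet) -> float:
    """Cheek-to-jaw-width ratio d(P3,P4)/d(P5,P6)."""
    lm = lm.to_mm()
    jaw = lm.distance("P5", "P6")
    if jaw == 0:
        raise ValueError("CJWR undefined: d(P5,P6) is zero")
    return lm.distance("P3", "P4") / jaw


def eye_size(lm: LandmarkSet) -> float:
    """Mean single-eye width (mm): (d(P9,P10) − d(P11,P12)) / 2."""
    lm = lm.to_mm()
    value = (lm.distance("P9", "P10") - lm.distance("P11", "P12")) / 2.0
    if value < 0:
        warnings.warn(
            f"subject {lm.subject_id!r}: negative eye size — inner eye-corner "
            "span exceeds outer span, check landmark order",
            stacklevel=2,
        )
    return value


def lower_face_height(lm: LandmarkSet) -> float:
    """The distance *a* (mm): |y(P2) − mean(y(P13), y(P14))|, vertical."""
    lm = lm.to_mm()
    pupil_y = 0.5 * (lm.points["P13"][1] + lm.points["P14"][1])
    return abs(lm.points["P2"][1] - pupil_y)


def lf_fh(lm: LandmarkSet) -> float:
    """Lower-face to face-height ratio: a / d(P1,P2)."""
    lm = lm.to_mm()
    fh = lm.distance("P1", "P2")
    if fh == 0:
        raise ValueError("LF/FH undefined: d(P1,P2) is zero")
    return lower_face_height(lm) / fh


def fw_lfh(lm: LandmarkSet) -> float:
    """Face-width to lower-face-height ratio: d(P3,P4) / a."""
    lm = lm.to_mm()
    a = lower_face_height(lm)
    if a == 0:
        raise ValueError("FW/LFH undefined: lower-face height a is zero")
    return lm.distance("P3", "P4") / a


def eh_mean(lm: LandmarkSet) -> float:
    """Mean eyebrow height (mm): mean of d(Pk, Pkp) for k = 9..14."""
    lm = lm.to_mm()
    return float(
        np.mean([lm.distance(f"P{i}", f"P{i}p") for i in range(9, 15)])
    )


def metric_vector(lm: LandmarkSet) -> MetricVector:
    """All seven metrics plus the intermediate lower-face height *a*."""
    lm = lm.to_mm()
    return MetricVector(
        PAR=par(lm),
        WHR=whr(lm),
        CJWR=cjwr(lm),
        eye_size=eye_size(lm),
        LF_FH=lf_fh(lm),
        FW_LFH=fw_lfh(lm),
        EH_mean=eh_mean(lm),
        a=lower_face_height(lm),
    )


def metrics_table(sets) -> pd.DataFrame:
    """Per-subject metric table for a collection of landmark sets."""
    rows = []
    for lm in sets:
        mv = metric_vector(lm)
        rows.append({"subject_id": lm.subject_id, **mv.as_dict()})
    return pd.DataFrame(rows)


def reliability_cv(repeated: dict[str, list[MetricVector]]) -> pd.DataFrame:
    """Test–retest coefficient of variation per metric.

    ``repeated`` maps subject id to two or more metric vectors from repeated
    landmarkings of the same photograph.  For each metric the CV per subject
    is 100·SD/mean across the repeats (sample SD); the summary is the
    min–max range over subjects.

    Returns a DataFrame indexed by metric with columns ``cv_min``,
    ``cv_max`` and ``cv_mean`` (percent).
    """
    per_subject: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for sid, mvs in repeated.items():
        if len(mvs) < 2:
            raise ValueError(f"subject {sid!r}: need at least 2 repeats, got {len(mvs)}")
        for m in METRIC_NAMES:
            vals = np.array([getattr(mv, m) for mv in mvs], dtype=float)
            mean = vals.mean()
            if mean == 0:
                raise ValueError(f"subject {sid!r}: zero mean for {m}, CV undefined")
            per_subject[m].append(100.0 * vals.std(ddof=1) / abs(mean))
    return pd.DataFrame(
        {
            "cv_min": {m: float(np.min(v)) for m, v in per_subject.items()},
            "cv_max": {m: float(np.max(v)) for m, v in per_subject.items()},
            "cv_mean": {m: float(np.mean(v)) for m, v in per_subject.items()},
        }
    ).loc[list(METRIC_NAMES)]
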