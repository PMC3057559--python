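"""Facial landmark data model and file I/O.

The landmarking scheme places 20 points on a frontal 2-D photograph: 14
base points P1..P14 and six "primed" eyebrow points P9p..P14p directly
above the periocular points P9..P14.  Coordinates follow the image
convention (x rightward, y downward); distances labelled "vertical" in the
metric definitions are absolute y differences.

Point semantics (the package's documented convention, configurable via
:data:`POINT_SEMANTICS`):

========  ====================================================
P1        top of forehead, midline (hairline)
P2        chin, midline (gnathion)
P3 / P4   left / right cheekbone extremes (zygion)
P5 / P6   left / right jaw points (gonion)
P7 / P8   midline brow and upper-lip points (the facial
          width-to-height ratio height endpoints)
P9 / P10  left / right outer eye corners (exocanthion)
P11 / P12 left / right inner eye corners (endocanthion)
P13 / P14 left / right pupil centres
P9p..P14p eyebrow points directly above P9..P14
========  ====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "POINT_NAMES",
    "POINT_SEMANTICS",
    "LandmarkSet",
    "LandmarkError",
    "read_landmarks",
    "write_landmarks",
    "read_demographics",
    "compute_bmi",
]

_BASE_POINTS = tuple(f"P{i}" for i in range(1, 15))
_PRIMED_POINTS = tuple(f"P{i}p" for i in range(9, 15))

#: The 20 point names every :class:`LandmarkSet` must carry.  Primed points
#: use an ASCII ``p`` suffix (P9p) because the prime glyph is file-hostile.
POINT_NAMES: tuple[str, ...] = _BASE_POINTS + _PRIMED_POINTS

POINT_SEMANTICS: dict[str, str] = {
    "P1": "top of forehead, midline",
    "P2": "chin, midline",
    "P3": "left cheekbone extreme",
    "P4": "right cheekbone extreme",
    "P5": "left jaw (gonion)",
    "P6": "right jaw (gonion)",
    "P7": "midline brow point (upper fWHR endpoint)",
    "P8": "midline upper-lip point (lower fWHR endpoint)",
    "P9": "left outer eye corner",
    "P10": "right outer eye corner",
    "P11": "left inner eye corner",
    "P12": "right inner eye corner",
    "P13": "left pupil centre",
    "P14": "right pupil centre",
    **{f"P{i}p": f"eyebrow point above P{i}" for i in range(9, 15)},
}


class LandmarkError(ValueError):
    """Raised for malformed landmark tables or landmark sets."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2-D facial points for one subject, with physical scale.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    points
        Mapping from point name to ``(x, y)`` coordinates.  Must contain
        exactly the 20 names in :data:`POINT_NAMES`.
    unit
        ``"mm"`` or ``"pixel"``.
    mm_per_pixel
        Positive scale factor; required when ``unit="pixel"``.
    """

    subject_id: str
    points: dict[str, tuple[float, float]]
    unit: str = "mm"
    mm_per_pixel: float | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [p for p in POINT_NAMES if p not in self.points]
        if missing:
            raise LandmarkError(
                f"subject {self.subject_id!r}: missing point {missing[0]}"
            )
        extra = set(self.points) - set(POINT_NAMES)
        if extra:
            raise LandmarkError(
                f"subject {self.subject_id!r}: unknown point(s) {sorted(extra)}"
            )
        for name, (x, y) in self.points.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise LandmarkError(
                    f"subject {self.subject_id!r}: non-finite coordinate at {name}"
                )
        if self.unit not in ("mm", "pixel"):
            raise LandmarkError(f"unknown unit {self.unit!r}")
        if self.unit == "pixel":
            if self.mm_per_pixel is None or not self.mm_per_pixel > 0:
                raise LandmarkError(
                    "pixel-unit landmarks require a positive mm_per_pixel scale"
                )

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    def to_mm(self) -> "LandmarkSet":
        """Return this set expressed in millimetres."""
        if self.unit == "mm":
            return self
        s = float(self.mm_per_pixel)
        pts = {k: (x * s, y * s) for k, (x, y) in self.points.items()}
        return replace(self, points=pts, unit="mm", mm_per_pixel=None)

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance between points ``a`` and ``b``."""
        (xa, ya), (xb, yb) = self.points[a], self.points[b]
        return math.hypot(xa - xb, ya - yb)


def read_landmarks(path, mm_per_pixel: float | None = None) -> list[LandmarkSet]:
    """Read a delimited landmark table into one :class:`LandmarkSet` per subject.

    The file must have a header row with columns ``subject_id, point, x, y``
    (comma- or tab-separated).  When ``mm_per_pixel`` is given, coordinates
    are treated as pixels and converted to mm; otherwise they are taken to
    be mm already.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"subject_id": str})
    required = {"subject_id", "point", "x", "y"}
    if not required.issubset(df.columns):
        raise LandmarkError(
            f"landmark file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna()].iloc[0]
            raise LandmarkError(
                f"non-numeric coordinate for subject {bad['subject_id']!r}, "
                f"point {bad['point']!r}: {bad[col]!r}"
            )
        df[col] = vals

    out: list[LandmarkSet] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        dup = grp["point"].duplicated()
        if dup.any():
            raise LandmarkError(
                f"subject {sid!r}: duplicate point {grp.loc[dup, 'point'].iloc[0]}"
            )
        pts = {row.point: (float(row.x), float(row.y)) for row in grp.itertuples()}
        if mm_per_pixel is not None:
            lm = LandmarkSet(str(sid), pts, unit="pixel", mm_per_pixel=mm_per_pixel)
            lm = lm.to_mm()
        else:
            lm = LandmarkSet(str(sid), pts, unit="mm")
        out.append(lm)
    return out


def write_landmarks(sets, path) -> None:
    """Write landmark sets to CSV (columns subject_id, point, x, y), in mm."""
    rows = []
    for lm in sets:
        lm = lm.to_mm()
        for name in POINT_NAMES:
            x, y = lm.points[name]
            rows.append({"subject_id": lm.subject_id, "point": name, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    """Read a demographics CSV: subject_id, sex, age_group, type, height_m, weight_kg.

    Adds a ``bmi`` column computed as weight / height².
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sex", "age_group", "type", "height_m", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkError(f"demographics file missing columns {sorted(missing)}")
    df = df.rename(columns={"type": "sasang_type"})
    df["bmi"] = [
        compute_bmi(w, h) for w, h in zip(df["weight_kg"], df["height_m"])
    ]
    return df


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight in kg divided by the square of height in m."""
    if not weight_kg > 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if not height_m > 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2
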