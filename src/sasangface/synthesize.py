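"""Synthetic subject generation calibrated to the published group summaries.

Two levels of synthesis are provided:

* **metric level** — per Sasang type, (BMI, facial metrics) are drawn from a
  multivariate normal whose means and SDs are the published per-group
  values and whose within-type BMI–metric correlations are *calibrated* so
  the pooled (across-type) Pearson correlations reproduce the published
  pooled values.

* **geometry level** — for each synthetic subject a full 20-point landmark
  set is constructed whose metric vector equals the subject's sampled
  metric targets, by deforming a canonical face template.

Calibration works by moment matching.  For groups g with sizes n_g, means
μ_g and SDs σ_g of BMI (B) and a metric (M), the pooled covariance of a
mixture with a common within-type correlation ρ_w decomposes as

    cov_tot = cov_between + ρ_w · Σ_g n_g σ_gB σ_gM / N

and the pooled variances as var_tot = var_within + var_between, with
size-weighted moments throughout.  Solving

    r_target · σtot_B · σtot_M = cov_between + ρ_w · Σ_g n_g σ_gB σ_gM / N

for ρ_w yields the within-type correlation that makes the generated pooled
correlation converge to the target.  A single ρ_w shared by the three
types is the minimal sufficient assumption, since only pooled correlations
are published.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .landmarks import LandmarkSet
from .metrics import METRIC_NAMES, MetricVector, metric_vector, polygon_perimeter_area

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "CalibrationError",
    "calibrate_within_correlation",
    "calibrated_correlation_matrix",
    "nearest_positive_definite_correlation",
    "generate_metric_level",
    "generate_geometry_level",
    "landmarks_from_metrics",
    "template_landmarks",
    "default_config",
]

VARIABLES: tuple[str, ...] = ("bmi",) + METRIC_NAMES


class CalibrationError(ValueError):
    """Raised when a target pooled correlation is unattainable."""


@dataclass(frozen=True)
class GroupSpec:
    """Distribution parameters of one (stratum, Sasang type) group."""

    sex: str
    age_group: str
    sasang_type: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group size must be positive, got {self.n}")
        bad = [k for k, v in self.sds.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive SD for {bad}")

    @property
    def stratum(self) -> str:
        return f"{self.sex}{self.age_group}"


@dataclass
class SyntheticConfig:
    """Generator configuration: group specs, correlation targets, seed.

    ``target_pooled_r[stratum][metric]`` holds the pooled BMI–metric
    correlation to calibrate to; metrics absent from the mapping get a
    within-type correlation of zero.  ``within_metric_corr`` is the
    metric–metric within-type correlation (the published tables give none,
    so it defaults to zero).  ``size_multiplier`` scales every group size,
    for large-sample checks.
    """

    group_specs: list[GroupSpec]
    target_pooled_r: dict[str, dict[str, float]] = field(default_factory=dict)
    within_metric_corr: float = 0.0
    seed: int = 0
    size_multiplier: int = 1

    @property
    def strata(self) -> list[str]:
        seen: list[str] = []
        for spec in self.group_specs:
            if spec.stratum not in seen:
                seen.append(spec.stratum)
        return seen

    def stratum_specs(self, stratum: str) -> list[GroupSpec]:
        return [s for s in self.group_specs if s.stratum == stratum]


def default_config(
    strata=None,
    seed: int = 0,
    size_multiplier: int = 1,
    within_metric_corr: float = 0.0,
) -> SyntheticConfig:
    """Configuration reproducing the published study conditions.

    Group sizes, means and SDs come from the published per-group summaries;
    pooled correlation targets are the published pooled BMI–metric values.
    """
    strata = list(strata) if strata is not None else list(ref.STRATA)
    specs = []
    for stratum in strata:
        sex, age = stratum[0], stratum[1:]
        for t in ref.TYPES:
            g = ref.GROUP_SUMMARIES[(stratum, t)]
            specs.append(
                GroupSpec(sex=sex, age_group=age, sasang_type=t, n=g["n"],
                          means=dict(g["mean"]), sds=dict(g["sd"]))
            )
    targets = {s: dict(ref.POOLED_BMI_CORRELATIONS[s]) for s in strata}
    return SyntheticConfig(
        group_specs=specs,
        target_pooled_r=targets,
        within_metric_corr=within_metric_corr,
        seed=seed,
        size_multiplier=size_multiplier,
    )


def _pooled_moments(specs, key):
    ns = np.array([s.n for s in specs], dtype=float)
    mus = np.array([s.means[key] for s in specs], dtype=float)
    sds = np.array([s.sds[key] for s in specs], dtype=float)
    N = ns.sum()
    grand = float(np.sum(ns * mus) / N)
    var_between = float(np.sum(ns * (mus - grand) ** 2) / N)
    var_within = float(np.sum(ns * sds**2) / N)
    return grand, var_within, var_between, ns, mus, sds


def calibrate_within_correlation(specs, metric: str, target_pooled_r: float) -> float:
    """Within-type BMI–metric correlation ρ_w matching a pooled target.

    ``specs`` are the per-type group specs of one stratum.  Solves the
    mixture moment identity (module docstring) for ρ_w; raises
    :class:`CalibrationError` when |ρ_w| ≥ 1, i.e. the target pooled
    correlation cannot be produced by any within-type correlation given the
    group structure.
    """
    if not -1.0 < target_pooled_r < 1.0:
        raise CalibrationError(f"|target r| must be < 1, got {target_pooled_r}")
    gB, vwB, vbB, ns, muB, sdB = _pooled_moments(specs, "bmi")
    gM, vwM, vbM, _, muM, sdM = _pooled_moments(specs, metric)
    N = ns.sum()
    cov_between = float(np.sum(ns * (muB - gB) * (muM - gM)) / N)
    sd_product_within = float(np.sum(ns * sdB * sdM) / N)
    sigma_tot = math.sqrt((vwB + vbB) * (vwM + vbM))
    rho_w = (target_pooled_r * sigma_tot - cov_between) / sd_product_within
    if not -1.0 < rho_w < 1.0:
        raise CalibrationError(
            f"target correlation {target_pooled_r} for {metric} unattainable "
            f"with given group structure (implied within-type rho = {rho_w:.3f})"
        )
    return rho_w


def nearest_positive_definite_correlation(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-definite correlation matrix."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def calibrated_correlation_matrix(config: SyntheticConfig, stratum: str) -> np.ndarray:
    """Within-type correlation matrix over (bmi, metrics) for one stratum.

    Row/column order follows :data:`VARIABLES`.  Repaired to the nearest
    positive-definite matrix (with a warning) if the assembled matrix is
    not positive definite.
    """
    specs = config.stratum_specs(stratum)
    if not specs:
        raise KeyError(f"config has no groups for stratum {stratum!r}")
    targets = config.target_pooled_r.get(stratum, {})
    k = len(VARIABLES)
    corr = np.full((k, k), config.within_metric_corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    for j, metric in enumerate(METRIC_NAMES, start=1):
        r = targets.get(metric)
        rho = 0.0 if r is None else calibrate_within_correlation(specs, metric, r)
        corr[0, j] = corr[j, 0] = rho
    if np.linalg.eigvalsh(corr).min() <= 0:
        warnings.warn(
            f"stratum {stratum}: assembled within-type correlation matrix is "
            "not positive definite; repaired to the nearest PD matrix",
            stacklevel=2,
        )
        corr = nearest_positive_definite_correlation(corr)
    return corr


def generate_metric_level(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Sample subject records (demographics + BMI + metrics) from the config.

    Returns a DataFrame with columns subject_id, sex, age_group,
    sasang_type, height_m, weight_kg, bmi and the seven metrics.  BMI and
    metrics are drawn jointly per type from the calibrated multivariate
    normal; height is drawn independently from the group's height
    distribution and weight derived as BMI·height² (BMI, the analysis
    variable, is matched to the published distributions exactly).
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    frames = []
    for stratum in config.strata:
        corr = calibrated_correlation_matrix(config, stratum)
        for spec in config.stratum_specs(stratum):
            n = spec.n * config.size_multiplier
            sds = np.array([spec.sds[v] for v in VARIABLES])
            means = np.array([spec.means[v] for v in VARIABLES])
            cov = corr * np.outer(sds, sds)
            draws = rng.multivariate_normal(means, cov, size=n, method="cholesky")
            height = rng.normal(spec.means["height_m"], spec.sds["height_m"], size=n)
            df = pd.DataFrame(draws, columns=list(VARIABLES))
            df.insert(0, "subject_id",
                      [f"{stratum}-{spec.sasang_type}-{i:06d}" for i in range(n)])
            df.insert(1, "sex", spec.sex)
            df.insert(2, "age_group", spec.age_group)
            df.insert(3, "sasang_type", spec.sasang_type)
            df.insert(4, "height_m", height)
            df.insert(5, "weight_kg", df["bmi"].to_numpy() * height**2)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# geometry level
# --------------------------------------------------------------------------

# Canonical-frame shape constants not determined by the seven metrics:
# inner eye-corner span, pupil half-separation, brow midline height (all mm)
# and the cheek/jaw vertical positions as fractions of the lower-face height.
_DEFAULT_SHAPE = {
    "inner_span": 30.0,
    "pupil_dx": 31.0,
    "brow_y": -25.0,
    "cheek_rel": 0.15,
    "jaw_rel": 0.70,
}


def _shape_from_template(template: LandmarkSet) -> dict[str, float]:
    t = template.to_mm()
    pupil_y = 0.5 * (t["P13"][1] + t["P14"][1])
    a = abs(t["P2"][1] - pupil_y)
    return {
        "inner_span": t.distance("P11", "P12"),
        "pupil_dx": 0.5 * abs(t["P14"][0] - t["P13"][0]),
        "brow_y": t["P7"][1] - pupil_y,
        "cheek_rel": (t["P3"][1] - pupil_y) / a,
        "jaw_rel": (t["P5"][1] - pupil_y) / a,
    }


def landmarks_from_metrics(
    targets,
    template: LandmarkSet | None = None,
    subject_id: str = "synthetic",
    rtol: float = 1e-9,
) -> LandmarkSet:
    """Construct a 20-point landmark set whose metrics equal ``targets``.

    ``targets`` is a :class:`MetricVector` or a mapping with the seven
    metric names.  The construction works in a canonical frame (midline at
    x = 0, pupil line at y = 0, y increasing downward): the lower-face
    polygon's shape is fixed by the ratio metrics, then scaled uniformly to
    hit PAR (PAR scales as 1/s while the ratios are invariant), and the
    eye, pupil, brow and fWHR points are placed from the mm-valued targets.
    Shape degrees of freedom the metrics do not constrain (pupil
    separation, inner eye span, cheek/jaw vertical positions) are taken
    from ``template`` (the shipped synthetic template by default).

    The result is verified against :func:`metric_vector`; a mismatch above
    ``rtol`` raises ``ValueError`` naming the offending metric.
    """
    if isinstance(targets, MetricVector):
        tgt = targets.as_dict(include_a=False)
    else:
        tgt = {m: float(targets[m]) for m in METRIC_NAMES}
    shape = _DEFAULT_SHAPE if template is None else _shape_from_template(template)

    for name in ("PAR", "WHR", "CJWR", "FW_LFH"):
        if not tgt[name] > 0:
            raise ValueError(f"infeasible target: {name} must be positive, got {tgt[name]}")
    if not 0 < tgt["LF_FH"] < 1:
        raise ValueError(f"infeasible target: LF_FH must lie in (0, 1), got {tgt['LF_FH']}")
    if tgt["eye_size"] < 0:
        raise ValueError(f"infeasible target: eye_size negative ({tgt['eye_size']})")
    if tgt["EH_mean"] < 0:
        raise ValueError(f"infeasible target: EH_mean negative ({tgt['EH_mean']})")

    # lower-face polygon at reference scale, then uniform rescale for PAR
    a0 = 100.0
    c0 = tgt["FW_LFH"] * a0
    j0 = c0 / tgt["CJWR"]
    poly0 = np.array([
        (-c0 / 2, shape["cheek_rel"] * a0),   # P3
        (-j0 / 2, shape["jaw_rel"] * a0),     # P5
        (0.0, a0),                            # P2
        (j0 / 2, shape["jaw_rel"] * a0),      # P6
        (c0 / 2, shape["cheek_rel"] * a0),    # P4
    ])
    per0, area0 = polygon_perimeter_area(poly0)
    s = (per0 / area0) / tgt["PAR"]
    poly = poly0 * s
    a = a0 * s
    c = c0 * s

    pts: dict[str, tuple[float, float]] = {}
    for name, (x, y) in zip(("P3", "P5", "P2", "P6", "P4"), poly):
        pts[name] = (float(x), float(y))
    pts["P1"] = (0.0, a - a / tgt["LF_FH"])
    h78 = c / tgt["WHR"]
    pts["P7"] = (0.0, shape["brow_y"])
    pts["P8"] = (0.0, shape["brow_y"] + h78)
    half_in = shape["inner_span"] / 2
    pts["P11"] = (-half_in, 0.0)
    pts["P12"] = (half_in, 0.0)
    pts["P9"] = (-(half_in + tgt["eye_size"]), 0.0)
    pts["P10"] = (half_in + tgt["eye_size"], 0.0)
    pts["P13"] = (-shape["pupil_dx"], 0.0)
    pts["P14"] = (shape["pupil_dx"], 0.0)
    for i in range(9, 15):
        x, y = pts[f"P{i}"]
        pts[f"P{i}p"] = (x, y - tgt["EH_mean"])

    lm = LandmarkSet(subject_id, pts, unit="mm")
    achieved = metric_vector(lm).as_dict(include_a=False)
    for name in METRIC_NAMES:
        denom = max(abs(tgt[name]), 1e-12)
        if abs(achieved[name] - tgt[name]) / denom > rtol:
            raise ValueError(
                f"landmark construction did not converge for metric {name}: "
                f"target {tgt[name]!r}, achieved {achieved[name]!r}"
            )
    return lm


def template_landmarks() -> LandmarkSet:
    """The shipped synthetic face template (canonical frame, mm units).

    A synthetic stand-in for a measured average face: constructed from the
    published TE male-twenties mean metrics with default shape constants.
    """
    means = ref.GROUP_SUMMARIES[("M20s", "TE")]["mean"]
    targets = {m: means[m] for m in METRIC_NAMES}
    return landmarks_from_metrics(targets, template=None, subject_id="template")


def generate_geometry_level(
    config: SyntheticConfig,
    template: LandmarkSet | None = None,
    with_records: bool = False,
):
    """Landmark sets whose metrics realise a metric-level sample.

    Draws subject records with :func:`generate_metric_level` under the
    config's seed, then constructs one landmark set per subject matching
    the sampled metric vector.  Returns the list of landmark sets, or
    ``(landmark_sets, records)`` when ``with_records`` is true.
    """
    template = template if template is not None else template_landmarks()
    records = generate_metric_level(config)
    sets = [
        landmarks_from_metrics(
            {m: row[m] for m in METRIC_NAMES},
            template=template,
            subject_id=row["subject_id"],
        )
        for _, row in records.iterrows()
    ]
    if with_records:
        return sets, records
    return sets
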