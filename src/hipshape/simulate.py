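"""Synthetic MrOS-like cohorts with planted deformity modes and effect sizes.

No landmark-level hip shape dataset is publicly deposited, so the
pipeline is exercised on cohorts generated from a drawn 58-point
right-hip template.  Shape variation is planted as a small set of
orthonormal deformation fields — a pincer-like field (lateral acetabular
over-coverage), a cam-like field (extra bone at the superior head-neck
junction) and nuisance fields (lesser-trochanter size, neck-shaft
angle) — with Gaussian loadings of known SD, isotropic landmark noise,
and a random similarity transform per image.  Outcomes are planted by
inverting the analysis models: radiographic hip OA case status follows
a logistic model on the standardized true loadings (plus covariates),
cases then receive component grades constructed to reproduce their
Croft grade; pain outcomes follow their own logistic models and WOMAC a
proportional-odds model.  Intercepts are calibrated numerically so
simulated prevalences land on the cohort targets (RHOA 7.1%, pain on
examination 11.4%, pain on walking 20.2%, WOMAC mean 0.9).

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` children, so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io import LandmarkConfiguration, PointTemplate, write_landmarks
from .outcomes import RadiographReading, readings_to_frame

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "DeformationFields",
    "CalibrationError",
    "make_hip_template",
    "make_deformation_fields",
    "sample_shapes",
    "plant_outcomes",
    "generate_cohort",
]


class CalibrationError(RuntimeError):
    """Achieved outcome prevalence missed its target by more than 2 points."""


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

_HEAD_CENTER = np.array([100.0, 80.0])
_HEAD_R = 22.0
_ACET_R = 28.0

_SEGMENT_FRACTIONS = {
    "acetabulum": 12,
    "femoral_head": 14,
    "superior_neck": 6,
    "greater_trochanter": 5,
    "lateral_shaft": 5,
    "medial_shaft": 5,
    "lesser_trochanter": 5,
    "inferior_neck": 6,
}
_SEGMENT_MINIMUM = {"acetabulum": 3}


def _arc(center, r, deg0, deg1, t):
    phi = np.deg2rad(deg0 + (deg1 - deg0) * t)
    return center + r * np.column_stack([np.cos(phi), np.sin(phi)])


def _line(p0, p1, t, bulge=0.0):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    n = np.array([-d[1], d[0]])
    n = n / np.linalg.norm(n)
    pts = p0 + np.outer(t, d)
    return pts + np.outer(bulge * np.sin(np.pi * t), n)


def _segment_points(name: str, count: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, count)
    hc = _HEAD_CENTER
    if name == "acetabulum":
        # superior arc over the head; t=0 medial "eyebrow" end, t=1 lateral rim
        return _arc(hc, _ACET_R, -165.0, -30.0, t)
    if name == "femoral_head":
        # from the superior head-neck junction over the top, medially, to inferior
        return _arc(hc, _HEAD_R, -60.0, -270.0, t)
    if name == "superior_neck":
        # saddle from the junction out to the greater trochanter
        return _line((111.0, 61.0), (145.0, 70.0), t, bulge=4.0)
    if name == "greater_trochanter":
        return _line((145.0, 70.0), (148.0, 96.0), t, bulge=-4.0)
    if name == "lateral_shaft":
        return _line((148.0, 96.0), (146.0, 150.0), t)
    if name == "medial_shaft":
        return _line((126.0, 150.0), (124.0, 120.0), t)
    if name == "lesser_trochanter":
        return _line((124.0, 120.0), (119.0, 101.0), t, bulge=-4.0)
    if name == "inferior_neck":
        # calcar, concave superiorly, running medially to under the head
        return _line((119.0, 101.0), (102.0, 101.5), t, bulge=3.0)
    raise KeyError(name)


def _allocate(P: int) -> dict:
    total = sum(_SEGMENT_FRACTIONS.values())
    names = list(_SEGMENT_FRACTIONS)
    ideal = {k: P * v / total for k, v in _SEGMENT_FRACTIONS.items()}
    counts = {k: max(_SEGMENT_MINIMUM.get(k, 2), int(math.floor(ideal[k]))) for k in names}
    # distribute the remainder by largest fractional part, deterministically
    while sum(counts.values()) < P:
        frac = {k: ideal[k] - counts[k] for k in names}
        counts[max(names, key=lambda k: (frac[k], -names.index(k)))] += 1
    while sum(counts.values()) > P:
        frac = {k: ideal[k] - counts[k] for k in names}
        shrinkable = [k for k in names if counts[k] > _SEGMENT_MINIMUM.get(k, 2)]
        if not shrinkable:
            raise ValueError(f"P={P} too small to allocate all contour segments")
        counts[min(shrinkable, key=lambda k: (frac[k], names.index(k)))] -= 1
    return counts


def make_hip_template(P: int = 58) -> PointTemplate:
    """Draw the canonical right-hip template (pixel frame, y down).

    Deterministic for fixed P.  Key points: one medial acetabular
    ("eyebrow" end) and two lateral acetabular points on the outer edge
    of the acetabulum, plus femoral head, superior/inferior femoral
    neck, and greater/lesser trochanter key points.
    """
    if P < 20:
        raise ValueError(f"P={P} too small; need at least 20 points")
    counts = _allocate(P)
    segments = {}
    coords = []
    roles = ["intermediate"] * P
    start = 0
    for name, cnt in counts.items():
        segments[name] = (start, start + cnt)
        coords.append(_segment_points(name, cnt))
        start += cnt
    reference = np.vstack(coords)

    a_lo, a_hi = segments["acetabulum"]
    h_lo, h_hi = segments["femoral_head"]
    sn_lo, sn_hi = segments["superior_neck"]
    gt_lo, gt_hi = segments["greater_trochanter"]
    lt_lo, lt_hi = segments["lesser_trochanter"]
    in_lo, in_hi = segments["inferior_neck"]
    key_points = {
        "medial_acetabular": a_lo,
        "lateral_acetabular_1": a_hi - 2,
        "lateral_acetabular_2": a_hi - 1,
        # most medial head point: angle -180 deg sits 120/210 of the way round
        "femoral_head": h_lo + round((h_hi - h_lo - 1) * 120.0 / 210.0),
        "femoral_neck_superior": (sn_lo + sn_hi) // 2,
        "greater_trochanter": (gt_lo + gt_hi) // 2,
        "lesser_trochanter": (lt_lo + lt_hi) // 2,
        "femoral_neck_inferior": (in_lo + in_hi) // 2,
    }
    for name, idx in key_points.items():
        roles[idx] = f"key:{name}"
    return PointTemplate(
        P=P, roles=tuple(roles), key_points=key_points, segments=segments,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationFields:
    """Labelled deformation fields over a template.

    ``raw`` holds the anatomically constructed per-point displacement
    fields (pixels); ``fields`` are the same after projecting out the
    similarity-transform tangent directions at the template and
    Gram-Schmidt orthonormalization in label order.  Shape modelling
    happens in the similarity quotient, so only the projected component
    of a field is identifiable; planting the projected fields keeps the
    planted subspace recoverable after Procrustes alignment.
    """

    labels: tuple
    fields: np.ndarray  # (k, 2P), orthonormal
    raw: np.ndarray     # (k, 2P)


def _similarity_tangent_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal (4, 2P) basis of translations, scaling and rotation."""
    pts = reference - reference.mean(axis=0)
    P = pts.shape[0]
    tx = np.zeros(2 * P)
    ty = np.zeros(2 * P)
    tx[0::2] = 1.0
    ty[1::2] = 1.0
    scale = pts.reshape(-1)
    rot = np.column_stack([-pts[:, 1], pts[:, 0]]).reshape(-1)
    basis = np.vstack([tx, ty, scale, rot])
    return basis / np.linalg.norm(basis, axis=1, keepdims=True)


def make_deformation_fields(template: PointTemplate) -> DeformationFields:
    """Construct the planted pincer, cam and nuisance deformation fields."""
    P = template.P
    ref = template.reference
    hc = _HEAD_CENTER
    fields = {}

    # pincer: lateral acetabular rim pushed laterally and inferiorly over
    # the femoral head, weight ramping toward the lateral edge
    f = np.zeros((P, 2))
    lo, hi = template.segments["acetabulum"]
    t = np.linspace(0.0, 1.0, hi - lo)
    w = np.clip((t - 0.45) / 0.55, 0.0, 1.0) ** 2
    radial = ref[lo:hi] - hc
    radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
    f[lo:hi] = w[:, None] * (radial + np.array([0.35, 0.55]))
    fields["pincer_like"] = f

    # cam: outward bone apposition at the superior head-neck junction
    f = np.zeros((P, 2))
    h_lo, h_hi = template.segments["femoral_head"]
    th = np.linspace(0.0, 1.0, h_hi - h_lo)
    wh = np.exp(-0.5 * (th / 0.08) ** 2)  # junction is at the head arc start
    radial = ref[h_lo:h_hi] - hc
    radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
    f[h_lo:h_hi] = wh[:, None] * radial
    n_lo, n_hi = template.segments["superior_neck"]
    tn = np.linspace(0.0, 1.0, n_hi - n_lo)
    wn = np.exp(-0.5 * (tn / 0.25) ** 2)
    out_normal = np.array([-9.0, -34.0]) / 35.17  # superior-lateral off the neck
    f[n_lo:n_hi] = wn[:, None] * out_normal
    fields["cam_like"] = f

    # nuisance 1: lesser trochanter size
    f = np.zeros((P, 2))
    lo, hi = template.segments["lesser_trochanter"]
    t = np.linspace(0.0, 1.0, hi - lo)
    f[lo:hi] = np.outer(np.sin(np.pi * t), np.array([-1.0, 0.0]))
    fields["nuisance_lesser_trochanter"] = f

    # nuisance 2: neck-shaft angle, a linearized rotation of head + neck
    # about a pivot at the neck base
    f = np.zeros((P, 2))
    pivot = np.array([138.0, 80.0])
    for seg in ("femoral_head", "superior_neck", "inferior_neck"):
        lo, hi = template.segments[seg]
        rel = ref[lo:hi] - pivot
        f[lo:hi] = 0.02 * np.column_stack([-rel[:, 1], rel[:, 0]])
    fields["nuisance_neck_shaft_angle"] = f

    labels = tuple(fields)
    raw = np.vstack([fields[k].reshape(-1) for k in labels])

    sim = _similarity_tangent_basis(ref)
    ortho = raw.copy()
    for i in range(ortho.shape[0]):
        v = ortho[i]
        v = v - sim.T @ (sim @ v)
        for j in range(i):
            v = v - np.dot(ortho[j], v) * ortho[j]
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError(f"field {labels[i]} degenerate after projection")
        ortho[i] = v / norm
    return DeformationFields(labels=labels, fields=ortho, raw=raw)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_outcome_models() -> dict:
    return {
        "rhoa": {
            "prevalence": 0.071,
            "log_or": {"pincer_like": math.log(1.23), "cam_like": math.log(1.37)},
            "covariate_log_or": {"age": 0.03, "weight": 0.01},
        },
        "pain_internal_rotation": {
            "prevalence": 0.114,
            "log_or": {"cam_like": math.log(1.19)},
            "covariate_log_or": {"age": 0.02},
        },
        "walking_pain": {
            "prevalence": 0.202,
            "log_or": {"cam_like": math.log(1.14)},
            "covariate_log_or": {"age": 0.02},
            # baseline category mix of the raw 0-4 walking-pain score,
            # conditional structure of the proportional-odds thresholds
            "baseline_probs": [0.798, 0.12, 0.05, 0.022, 0.01],
        },
        "womac": {
            "mean": 0.9,
            "log_or": {"cam_like": math.log(1.15)},
            "covariate_log_or": {"age": 0.02},
            "p_zero": 0.72,
            "tail_ratio": 0.689,
        },
    }


def _default_covariates() -> dict:
    return {
        "age": (72.8, 5.5),
        "height": (174.4, 7.0),
        "weight": (83.6, 13.0),
        "race_probs": {
            "white": 0.907,
            "asian": 0.033,
            "african_american": 0.032,
            "other": 0.028,
        },
    }


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``mode_sds`` are the per-field SDs of the raw Gaussian loadings in
    template pixels, ordered as the deformation-field labels (pincer,
    cam, then nuisance fields); ``landmark_noise_sd`` is isotropic
    digitization noise per coordinate; ``transform_jitter`` gives the
    half-ranges of the random similarity transform applied per image
    (rotation radians, log-scale, translation pixels).
    """

    n: int = 4100
    P: int = 58
    mode_sds: tuple = (3.0, 2.0, 1.5, 1.0)
    landmark_noise_sd: float = 0.2
    transform_jitter: dict = field(
        default_factory=lambda: {"rotation": 0.15, "log_scale": 0.1, "translation": 25.0}
    )
    outcome_models: dict = field(default_factory=_default_outcome_models)
    covariate_distributions: dict = field(default_factory=_default_covariates)
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    landmarks: list
    true_scores: pd.DataFrame   # image_id + loading_<label> columns (raw pixels)
    covariates: pd.DataFrame    # image_id, age, height, weight, race
    readings: pd.DataFrame      # image_id + component grades + croft_grade
    pain: pd.DataFrame          # image_id, pain_internal_rotation, walking_pain_raw, womac
    config: SimulationConfig
    template: PointTemplate
    fields: DeformationFields

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landmarks(self.landmarks, out / "landmarks.csv")
        self.true_scores.to_csv(out / "true_scores.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.readings.to_csv(out / "readings.csv", index=False)
        self.pain.to_csv(out / "pain.csv", index=False)
        self.config.to_json(out / "truth.json")
        self.template.to_json(out / "template.json")
        return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[stage])


def sample_shapes(
    config: SimulationConfig,
    template: PointTemplate | None = None,
    fields: DeformationFields | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Draw landmark configurations and their true raw loadings.

    shape_i = template + sum_j b_ij field_j + noise, followed by a
    random similarity transform per image.
    """
    template = template or make_hip_template(config.P)
    fields = fields or make_deformation_fields(template)
    rng = rng or _stage_rng(config.seed, 0)
    k = len(fields.labels)
    sds = np.asarray(config.mode_sds, dtype=float)
    if sds.shape[0] != k:
        raise ValueError(f"mode_sds has {sds.shape[0]} entries for {k} fields")

    b = rng.normal(0.0, 1.0, size=(config.n, k)) * sds
    base = template.reference.reshape(-1)
    shapes = base + b @ fields.fields
    if config.landmark_noise_sd > 0:
        shapes = shapes + rng.normal(0.0, config.landmark_noise_sd, size=shapes.shape)

    jit = config.transform_jitter
    rots = rng.uniform(-jit["rotation"], jit["rotation"], size=config.n)
    scales = np.exp(rng.uniform(-jit["log_scale"], jit["log_scale"], size=config.n))
    trans = rng.uniform(-jit["translation"], jit["translation"], size=(config.n, 2))

    ids = [f"img{i:05d}" for i in range(config.n)]
    configs = []
    for i in range(config.n):
        xy = shapes[i].reshape(-1, 2)
        c, s = np.cos(rots[i]), np.sin(rots[i])
        R = np.array([[c, -s], [s, c]])
        xy = scales[i] * xy @ R.T + trans[i]
        configs.append(LandmarkConfiguration(image_id=ids[i], side="right", points=xy))
    scores = pd.DataFrame(b, columns=[f"loading_{lab}" for lab in fields.labels])
    scores.insert(0, "image_id", ids)
    return configs, scores


# ---------------------------------------------------------------------------
# outcome planting
# ---------------------------------------------------------------------------

def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    f = lambda a: expit(a + eta).mean() - target
    return brentq(f, -30.0, 30.0)


def _linear_predictor(z: pd.DataFrame, covariates: pd.DataFrame, model: dict) -> np.ndarray:
    eta = np.zeros(len(z))
    for lab, g in model.get("log_or", {}).items():
        eta = eta + g * z[f"z_{lab}"].to_numpy()
    for cov, g in model.get("covariate_log_or", {}).items():
        x = covariates[cov].to_numpy(dtype=float)
        eta = eta + g * (x - x.mean())
    return eta


def _sample_ordinal(rng, eta: np.ndarray, baseline_probs: np.ndarray,
                    shift: float = 0.0) -> np.ndarray:
    """Proportional-odds draw: thresholds from baseline probs, shifted."""
    cum = np.cumsum(baseline_probs)[:-1]
    theta = logit(np.clip(cum, 1e-12, 1 - 1e-12)) + shift
    # P(y <= k | eta) = expit(theta_k - eta)
    cdf = expit(theta[None, :] - eta[:, None])
    u = rng.uniform(size=eta.shape[0])
    return (u[:, None] > cdf).sum(axis=1)


def _calibrate_ordinal_shift(eta, baseline_probs, target_mean) -> float:
    cum = np.cumsum(baseline_probs)[:-1]
    theta0 = logit(np.clip(cum, 1e-12, 1 - 1e-12))
    levels = np.arange(len(baseline_probs))

    def mean_at(shift):
        cdf = expit((theta0 + shift)[None, :] - eta[:, None])
        pmf = np.diff(np.concatenate([np.zeros((len(eta), 1)), cdf,
                                      np.ones((len(eta), 1))], axis=1), axis=1)
        return (pmf @ levels).mean() - target_mean

    return brentq(mean_at, -20.0, 20.0)


_CASE_GRADE_DIST = {2: 0.654, 3: 0.20, 4: 0.10, 5: 0.046}
_JSN_REGION_PROBS = {"jsn_medial": 0.62, "jsn_lateral": 0.26, "jsn_concentric": 0.12}
_OSTEO_SITE_PROBS = {
    "osteophyte_lateral_acetabular": 0.55,
    "osteophyte_lateral_femoral": 0.17,
    "osteophyte_inferior_acetabular": 0.17,
    "osteophyte_inferior_femoral": 0.11,
}
_NONCASE_OSTEO_PROBS = {
    "osteophyte_lateral_acetabular": 0.18,
    "osteophyte_lateral_femoral": 0.08,
    "osteophyte_inferior_acetabular": 0.08,
    "osteophyte_inferior_femoral": 0.05,
}


def _choice(rng, dist: dict):
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.array([dist[k]
                                                  for k in keys]) / sum(dist.values()))]


def _case_reading(rng) -> RadiographReading:
    """Component grades for an RHOA case, constructed to hit a Croft grade."""
    target = _choice(rng, _CASE_GRADE_DIST)
    grades: dict = {}

    def add_jsn():
        region = _choice(rng, _JSN_REGION_PROBS)
        grades[region] = _choice(rng, {1: 0.6, 2: 0.3, 3: 0.1})
        if rng.uniform() < 0.25:
            other = _choice(rng, {k: v for k, v in _JSN_REGION_PROBS.items()
                                  if k != region})
            grades[other] = _choice(rng, {1: 0.7, 2: 0.3})

    def add_osteo():
        site = _choice(rng, _OSTEO_SITE_PROBS)
        grades[site] = _choice(rng, {1: 0.6, 2: 0.3, 3: 0.1})
        if rng.uniform() < 0.35:
            other = _choice(rng, {k: v for k, v in _OSTEO_SITE_PROBS.items()
                                  if k != site})
            grades[other] = _choice(rng, {1: 0.7, 2: 0.3})

    def add_scler():
        grades["sclerosis"] = _choice(rng, {1: 0.7, 2: 0.25, 3: 0.05})

    def add_cysts():
        grades["cysts"] = _choice(rng, {1: 0.8, 2: 0.2})

    if target == 2:
        add_jsn()
    elif target == 3:
        combo = _choice(rng, {"oj": 0.55, "js": 0.2, "os": 0.2, "oc": 0.05})
        pairs = {"oj": (add_osteo, add_jsn), "js": (add_jsn, add_scler),
                 "os": (add_osteo, add_scler), "oc": (add_osteo, add_cysts)}
        for fn in pairs[combo]:
            fn()
    elif target == 4:
        add_osteo(); add_jsn()
        (add_scler if rng.uniform() < 0.7 else add_cysts)()
    else:  # grade 5
        add_osteo(); add_jsn(); add_scler()
        if rng.uniform() < 0.2:
            add_cysts()
        grades["head_deformity"] = _choice(rng, {1: 0.7, 2: 0.3})
    grades["chondrocalcinosis"] = bool(rng.uniform() < 0.002)
    return RadiographReading(**grades)


def _noncase_reading(rng) -> RadiographReading:
    """Grades for a non-case: at most osteophytes (Croft <= 1), or
    sclerosis alone (outside the osteophyte/JSN-based 1-5 ladder)."""
    grades: dict = {}
    for site, p in _NONCASE_OSTEO_PROBS.items():
        if rng.uniform() < p:
            grades[site] = _choice(rng, {1: 0.8, 2: 0.15, 3: 0.05})
    if not grades and rng.uniform() < 0.05:
        grades["sclerosis"] = _choice(rng, {1: 0.8, 2: 0.2})
    grades["chondrocalcinosis"] = bool(rng.uniform() < 0.002)
    return RadiographReading(**grades)


def plant_outcomes(
    true_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate radiographic readings and pain outcomes from true loadings.

    Loadings are standardized to SD units using their own cohort SD, so
    the planted log-odds-ratios are per-SD effects — the scale on which
    the association battery reports.  Returns (readings, pain) frames.
    """
    rng = rng or _stage_rng(config.seed, 2)
    n = len(true_scores)
    z = pd.DataFrame({"image_id": true_scores["image_id"]})
    for col in true_scores.columns:
        if col.startswith("loading_"):
            lab = col[len("loading_"):]
            v = true_scores[col].to_numpy(dtype=float)
            z[f"z_{lab}"] = (v - v.mean()) / v.std(ddof=1)

    models = config.outcome_models

    # radiographic hip OA
    m = models["rhoa"]
    eta = _linear_predictor(z, covariates, m)
    alpha = _calibrate_intercept(eta, m["prevalence"])
    p_case = expit(alpha + eta)
    case = rng.uniform(size=n) < p_case
    _check_calibration("rhoa", case.mean(), m["prevalence"], n)
    readings = [(_case_reading(rng) if c else _noncase_reading(rng)) for c in case]
    readings_df = readings_to_frame(readings, ids=true_scores["image_id"].tolist())

    # binary pain on internal rotation
    m = models["pain_internal_rotation"]
    eta = _linear_predictor(z, covariates, m)
    alpha = _calibrate_intercept(eta, m["prevalence"])
    pain_rot = rng.uniform(size=n) < expit(alpha + eta)
    _check_calibration("pain_internal_rotation", pain_rot.mean(), m["prevalence"], n)

    # walking pain, raw 0-4 via proportional odds calibrated on P(>=1)
    m = models["walking_pain"]
    eta = _linear_predictor(z, covariates, m)
    probs = np.asarray(m["baseline_probs"], dtype=float)
    probs = probs / probs.sum()

    def any_walking(shift):
        cdf0 = expit(logit(np.clip(probs[0], 1e-12, 1 - 1e-12)) + shift - eta)
        return (1.0 - cdf0).mean() - m["prevalence"]

    shift = brentq(any_walking, -20.0, 20.0)
    walking_raw = _sample_ordinal(rng, eta, probs, shift)
    _check_calibration("walking_pain", (walking_raw >= 1).mean(), m["prevalence"], n)

    # WOMAC 0-20 via proportional odds calibrated on the mean
    m = models["womac"]
    eta = _linear_predictor(z, covariates, m)
    tail = m["tail_ratio"] ** np.arange(20)
    probs = np.concatenate([[m["p_zero"]], (1 - m["p_zero"]) * tail / tail.sum()])
    shift = _calibrate_ordinal_shift(eta, probs, m["mean"])
    womac = _sample_ordinal(rng, eta, probs, shift)

    pain_df = pd.DataFrame({
        "image_id": true_scores["image_id"],
        "pain_internal_rotation": pain_rot.astype(int),
        "walking_pain_raw": walking_raw.astype(int),
        "womac": womac.astype(int),
    })
    return readings_df, pain_df


def _check_calibration(name: str, achieved: float, target: float, n: int) -> None:
    if n >= 4000 and abs(achieved - target) > 0.02:
        raise CalibrationError(
            f"{name}: achieved prevalence {achieved:.3f} misses target "
            f"{target:.3f} by more than 2 percentage points"
        )


def _sample_covariates(config: SimulationConfig, rng: np.random.Generator,
                       ids: list) -> pd.DataFrame:
    dist = config.covariate_distributions
    n = len(ids)
    race_probs = dist["race_probs"]
    races = list(race_probs)
    p = np.array([race_probs[r] for r in races], dtype=float)
    return pd.DataFrame({
        "image_id": ids,
        "age": rng.normal(*dist["age"], size=n),
        "height": rng.normal(*dist["height"], size=n),
        "weight": rng.normal(*dist["weight"], size=n),
        "race": np.array(races)[rng.choice(len(races), p=p / p.sum(), size=n)],
    })


def generate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; one seed governs all stages."""
    config = config or SimulationConfig()
    template = make_hip_template(config.P)
    fields = make_deformation_fields(template)
    landmarks, true_scores = sample_shapes(
        config, template, fields, rng=_stage_rng(config.seed, 0)
    )
    covariates = _sample_covariates(
        config, _stage_rng(config.seed, 1), true_scores["image_id"].tolist()
    )
    readings, pain = plant_outcomes(
        true_scores, covariates, config, rng=_stage_rng(config.seed, 2)
    )
    return SyntheticCohort(
        landmarks=landmarks, true_scores=true_scores, covariates=covariates,
        readings=readings, pain=pain, config=config, template=template,
        fields=fields,
    )
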