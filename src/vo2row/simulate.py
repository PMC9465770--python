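"""Synthetic cohort generation.

Emulates per-sex cohorts of elite adolescent rowers with the joint
distributional structure the downstream analysis assumes: lean body
mass, the 4-minute all-out distance and mean power output are drawn
jointly Gaussian with configurable correlations; measured VO2max is the
sex-specific published linear equation evaluated on the draw plus
Gaussian residual noise.  The residual SD can be given directly or
calibrated so the population R² of VO2max on (lean body mass, distance)
hits a target — by default 0.715 for boys and 0.769 for girls, the
squared multiple correlations the equations were reported with.

Default predictor moments are the published per-sex cohort descriptives
(mean ± SD) for the development groups.  Ancillary variables not in the
equations (age, height, heart rate, stroke rate, body mass, fat %) are
drawn independently with their own moments; they exist to exercise
stepwise selection with uninformative candidates.  Out-of-range rows
(non-positive quantities, fat % outside (0, 60), lean mass ≥ body mass)
are rejected and resampled, so the marginals are mildly truncated
Gaussians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .cohort import Cohort, RowerRecord
from .regression import frozen_equation

__all__ = [
    "CohortSpec",
    "MethodPairsSpec",
    "REFERENCE_MOMENTS",
    "DEFAULT_TARGET_R2",
    "generate_cohort",
    "calibrate_noise_sd",
    "linear_predictor_sd",
    "generate_method_pairs",
]

#: published development-cohort descriptives, per sex: field -> (mean, SD)
REFERENCE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "age": (15.27, 2.70),
        "body_mass": (72.37, 10.96),
        "height": (179.76, 7.92),
        "fat_pct": (16.03, 4.19),
        "lean_body_mass": (57.04, 10.23),
        "distance_4min": (1175.78, 102.12),
        "stroke_rate": (32.54, 1.92),
        "mean_power": (330.72, 74.01),
        "hr_max": (188.39, 12.39),
    },
    "female": {
        "age": (15.00, 2.11),
        "body_mass": (62.50, 7.14),
        "height": (167.93, 6.14),
        "fat_pct": (24.53, 3.94),
        "lean_body_mass": (45.62, 5.07),
        "distance_4min": (1021.73, 100.80),
        "stroke_rate": (33.62, 2.67),
        "mean_power": (223.71, 41.85),
        "hr_max": (187.89, 11.95),
    },
}

#: default population R² targets for noise calibration, per sex
DEFAULT_TARGET_R2 = {"male": 0.715, "female": 0.769}

CALIBRATE = "calibrate-to-r2"

_JOINT = ("body_mass", "lean_body_mass", "distance_4min", "mean_power")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters driving synthesis of one sex's cohort.

    ``noise_sd`` is either the residual SD of VO2max around the linear
    predictor (mL·min⁻¹) or the token ``"calibrate-to-r2"``, in which
    case the SD is derived from ``target_r2``.  The joint Gaussian
    couples body mass — lean body mass — distance — mean power as a
    Markov chain with edge correlations ``corr_lbm_body_mass``,
    ``corr_lbm_distance`` and ``corr_distance_power``; non-adjacent
    correlations are products along the chain (conditional
    independence), which keeps the matrix positive semi-definite for
    any valid edge values.  Coupling body mass to lean mass keeps the
    lean-mass < body-mass constraint from truncating the lean-mass
    distribution noticeably.
    """

    sex: str
    n: int
    seed: Optional[int] = None
    predictor_moments: Mapping[str, tuple[float, float]] = None  # type: ignore[assignment]
    corr_lbm_distance: float = 0.5
    corr_distance_power: float = 0.9
    corr_lbm_body_mass: float = 0.9
    noise_sd: Union[float, str] = CALIBRATE
    target_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in REFERENCE_MOMENTS:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.predictor_moments is None:
            object.__setattr__(
                self, "predictor_moments", dict(REFERENCE_MOMENTS[self.sex])
            )
        if self.target_r2 is None:
            object.__setattr__(self, "target_r2", DEFAULT_TARGET_R2[self.sex])
        if self.n < 2:
            raise ValueError(f"n must be ≥ 2, got {self.n}")
        for name, (mu, sd) in self.predictor_moments.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be ≥ 0, got {sd}")
        for r in (self.corr_lbm_distance, self.corr_distance_power,
                  self.corr_lbm_body_mass):
            if not -1 <= r <= 1:
                raise ValueError(f"correlation {r} outside [−1, 1]")
        if isinstance(self.noise_sd, str) and self.noise_sd != CALIBRATE:
            raise ValueError(
                f"noise_sd must be a number or {CALIBRATE!r}, got {self.noise_sd!r}"
            )
        if not isinstance(self.noise_sd, str) and self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        # fail before sampling if the implied 3x3 correlation is not PSD
        eigs = np.linalg.eigvalsh(self._correlation_matrix())
        if eigs.min() < -1e-10:
            raise ValueError("implied correlation structure is not positive semi-definite")

    def _correlation_matrix(self) -> np.ndarray:
        # chain body_mass — lbm — distance — power; off-chain entries are
        # products along the path, so the matrix is PSD by construction
        c, a, b = self.corr_lbm_body_mass, self.corr_lbm_distance, self.corr_distance_power
        return np.array(
            [
                [1, c, c * a, c * a * b],
                [c, 1, a, a * b],
                [c * a, a, 1, b],
                [c * a * b, a * b, b, 1],
            ],
            dtype=float,
        )

    def moment(self, name: str) -> tuple[float, float]:
        return self.predictor_moments[name]

    def resolved_noise_sd(self) -> float:
        if isinstance(self.noise_sd, str):
            return calibrate_noise_sd(self, self.target_r2)
        return float(self.noise_sd)


def linear_predictor_sd(spec: CohortSpec) -> float:
    """Population SD of the sex's frozen linear predictor under ``spec``.

    With coefficients (b₁, b₂) on lean body mass and distance,
    Var = b₁²σ₁² + b₂²σ₂² + 2·b₁b₂·ρ·σ₁σ₂.
    """
    eq = frozen_equation(spec.sex)
    coef = dict(eq.terms)
    b1, b2 = coef["lean_body_mass"], coef["distance_4min"]
    s1 = spec.moment("lean_body_mass")[1]
    s2 = spec.moment("distance_4min")[1]
    rho = spec.corr_lbm_distance
    var = (b1 * s1) ** 2 + (b2 * s2) ** 2 + 2 * b1 * b2 * rho * s1 * s2
    return math.sqrt(max(var, 0.0))


def calibrate_noise_sd(spec: CohortSpec, target_r2: float) -> float:
    """Residual SD giving the generative model a population R² of ``target_r2``.

    σe = SD(linear predictor) · sqrt((1 − R²)/R²); at R² = 0.5 the noise
    SD equals the linear-predictor SD, and σe → 0 as R² → 1.
    """
    if not 0 < target_r2 < 1:
        raise ValueError(f"target_r2 must lie in (0, 1), got {target_r2}")
    return linear_predictor_sd(spec) * math.sqrt((1 - target_r2) / target_r2)


def _draw_block(spec: CohortSpec, rng: np.random.Generator, m: int, noise_sd: float):
    """Draw m candidate rows as a dict of column arrays (unvalidated)."""
    means = np.array([spec.moment(f)[0] for f in _JOINT])
    sds = np.array([spec.moment(f)[1] for f in _JOINT])
    cov = spec._correlation_matrix() * np.outer(sds, sds)
    joint = rng.multivariate_normal(means, cov, size=m, method="svd")
    cols = {f: joint[:, i] for i, f in enumerate(_JOINT)}
    for f in ("age", "height", "fat_pct", "stroke_rate", "hr_max"):
        mu, sd = spec.moment(f)
        cols[f] = rng.normal(mu, sd, size=m) if sd > 0 else np.full(m, mu)
    eq = frozen_equation(spec.sex)
    linpred = (
        eq.intercept
        + dict(eq.terms)["lean_body_mass"] * cols["lean_body_mass"]
        + dict(eq.terms)["distance_4min"] * cols["distance_4min"]
    )
    noise = rng.normal(0.0, noise_sd, size=m) if noise_sd > 0 else np.zeros(m)
    cols["vo2max_measured"] = linpred + noise
    return cols


def _valid_mask(cols: Mapping[str, np.ndarray]) -> np.ndarray:
    ok = np.ones(len(cols["age"]), dtype=bool)
    for f in ("age", "body_mass", "height", "lean_body_mass", "distance_4min",
              "stroke_rate", "mean_power", "hr_max", "vo2max_measured"):
        ok &= cols[f] > 0
    ok &= (cols["fat_pct"] > 0) & (cols["fat_pct"] < 60)
    ok &= cols["lean_body_mass"] < cols["body_mass"]
    return ok


def generate_cohort(spec: CohortSpec, label: str = "") -> Cohort:
    """Generate a synthetic cohort; deterministic for a fixed seed.

    Rows violating physical-range constraints are rejected and redrawn
    (truncation by resampling), so record validation always passes.
    """
    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.resolved_noise_sd()
    kept: dict[str, list[float]] = {}
    total = 0
    attempts = 0
    while total < spec.n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                "resampling failed to produce enough in-range rows; "
                "check the spec's moments"
            )
        block = _draw_block(spec, rng, max(spec.n, 16), noise_sd)
        mask = _valid_mask(block)
        for f, arr in block.items():
            kept.setdefault(f, []).extend(arr[mask])
        total = len(kept["age"])

    records = []
    for i in range(spec.n):
        records.append(
            RowerRecord(
                athlete_id=f"{spec.sex}-{i + 1:03d}",
                sex=spec.sex,
                **{f: float(kept[f][i]) for f in kept},
            )
        )
    return Cohort(
        tuple(records),
        label=label or f"synthetic-{spec.sex}",
        sex_filter=spec.sex,
    )


@dataclass(frozen=True)
class MethodPairsSpec:
    """Parameters for direct simulation of measured/predicted pairs.

    ``bias`` and ``sd_diff`` are the mean and SD of (predicted −
    measured) differences in mL·min⁻¹; measured values are Gaussian with
    the given moments.
    """

    n: int
    bias: float = 0.0
    sd_diff: float = 0.0
    measured_mean: float = 3900.0
    measured_sd: float = 700.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be ≥ 2, got {self.n}")
        if self.sd_diff < 0 or self.measured_sd < 0:
            raise ValueError("SDs must be ≥ 0")


def generate_method_pairs(spec: MethodPairsSpec):
    """Measured ~ N(mean, sd); predicted = measured + N(bias, sd_diff)."""
    from .agreement import MethodPairs  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    measured = rng.normal(spec.measured_mean, spec.measured_sd, size=spec.n)
    predicted = measured + rng.normal(spec.bias, spec.sd_diff, size=spec.n)
    return MethodPairs(measured=measured, predicted=predicted, label="synthetic-pairs")
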