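"""Seeded synthetic cohort generator.

No measurement data are distributed with the study this package models, so
every pipeline stage is exercised on synthetic cohorts that reproduce the
study's *structure*: per patient a true ST and GT cross-section geometry,
eight MRI measurements (2 readers x 2 sessions x 2 tendons) corrupted by
reader noise and quantized to the workstation's 0.1-mm grid, and an integer
actual graft diameter concentrated on 7-9 mm.

The generative model, in the order it runs per patient:

1.  True mean tendon diameters are drawn Normal(st_mean, st_sd) and
    Normal(gt_mean, gt_sd).  True major/minor diameters are derived from the
    mean and a fixed eccentricity (major/minor ratio) and materialised on
    the measurement grid — the underlying size as the imaging workstation
    would render it — so zero reader noise yields exactly repeatable
    measurements.
2.  The true predicted graft diameter (PGD) is the sum of the two true
    tendon means, rounded up to the next full millimetre.
3.  The actual (surgical) graft diameter is the true rounded PGD shifted by
    +1 mm with probability ``p_under`` (the prediction will under-call), by
    -1 mm (or -2 mm with probability ``over_magnitude_2mm_prob``) with
    probability ``p_over``, else equal.  Generating the actual size from the
    *noise-free* PGD keeps biological discordance and reader noise
    separately controllable.
4.  Each of the eight measurements is the true diameter plus
    Normal(0, noise_sd), quantized to the grid; within a tendon the pair is
    re-ordered so major >= minor (the tendon mean is unaffected).

Default distribution parameters are calibration choices — selected so the
simulated cohort reproduces the published summary landscape (median raw
prediction near 7.5 mm, actual sizes centred on 8 mm, repeatability
coefficients of a few hundredths of a mm) — not measured population values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    Cohort,
    PatientRecord,
    Session,
    Sex,
    Side,
    Tendon,
    TendonMeasurement,
)
from .prediction import predicted_graft_diameter

READERS = ("R1", "R2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator (lengths in mm)."""

    n_patients: int = 92
    seed: int = 0
    st_mean_mm: float = 4.3
    st_sd_mm: float = 0.45
    gt_mean_mm: float = 3.2
    gt_sd_mm: float = 0.40
    eccentricity: float = 1.2  # major/minor ratio of the cross-section
    noise_sd_mm: float = 0.03  # per-measurement reader noise SD
    quantum_mm: float = 0.1  # measurement grid
    p_under: float = 0.087  # P(actual = rounded PGD + 1)
    p_over: float = 0.065  # P(actual below rounded PGD)
    over_magnitude_2mm_prob: float = 1 / 6  # P(-2 mm | over)
    male_fraction: float = 73 / 92
    age_range: tuple[int, int] = (18, 55)

    def validate(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        for name in ("p_under", "p_over", "over_magnitude_2mm_prob", "male_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name}={v} outside [0, 1]")
        if self.p_under + self.p_over > 1.0:
            errors.append("p_under + p_over exceeds 1")
        for name in ("st_sd_mm", "gt_sd_mm"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.eccentricity < 1.0:
            errors.append("eccentricity must be >= 1")
        if self.quantum_mm <= 0:
            errors.append("quantum_mm must be > 0")
        elif abs(self.quantum_mm * 10 - round(self.quantum_mm * 10)) > 1e-9:
            errors.append("quantum_mm must be a multiple of 0.1 mm (storage grid)")
        if self.noise_sd_mm < 0:
            errors.append("noise_sd_mm must be >= 0")
        # minor diameter = 2/(1+e) * mean must stay safely positive
        for prefix in ("st", "gt"):
            mean = getattr(self, f"{prefix}_mean_mm")
            sd = getattr(self, f"{prefix}_sd_mm")
            minor_scale = 2.0 / (1.0 + self.eccentricity)
            if (mean - 4 * sd) * minor_scale <= self.quantum_mm:
                errors.append(
                    f"{prefix} diameters risk non-positive values "
                    f"(mean - 4 SD too close to zero)"
                )
        if self.age_range[0] < 18 or self.age_range[1] < self.age_range[0]:
            errors.append("age_range must be within adults, low <= high")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d


def calibrated_default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The calibrated default configuration (optionally overridden)."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def _quantize(value_mm: float, quantum_mm: float) -> float:
    q = round(value_mm / quantum_mm) * quantum_mm
    return max(q, quantum_mm)  # diameters stay positive on the grid


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort; byte-identical output for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    e = config.eccentricity
    major_scale = 2.0 * e / (1.0 + e)
    minor_scale = 2.0 / (1.0 + e)

    records = []
    width = max(3, len(str(config.n_patients)))
    for i in range(config.n_patients):
        true_grid: dict[Tendon, tuple[float, float]] = {}
        for tendon, mean, sd in (
            (Tendon.ST, config.st_mean_mm, config.st_sd_mm),
            (Tendon.GT, config.gt_mean_mm, config.gt_sd_mm),
        ):
            m = rng.normal(mean, sd)
            major = _quantize(major_scale * m, config.quantum_mm)
            minor = _quantize(minor_scale * m, config.quantum_mm)
            minor = min(minor, major)
            true_grid[tendon] = (major, minor)

        true_pred = predicted_graft_diameter(
            true_grid[Tendon.ST][0],
            true_grid[Tendon.ST][1],
            true_grid[Tendon.GT][0],
            true_grid[Tendon.GT][1],
        )
        u = rng.random()
        if u < config.p_under:
            shift = 1
        elif u < config.p_under + config.p_over:
            shift = -2 if rng.random() < config.over_magnitude_2mm_prob else -1
        else:
            shift = 0
        actual = int(np.clip(true_pred.pgd_rounded_mm + shift, 5, 12))

        sex = Sex.M if rng.random() < config.male_fraction else Sex.F
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))

        measurements = []
        for reader in READERS:
            for session in (Session.T0, Session.T1MONTH):
                for tendon in (Tendon.ST, Tendon.GT):
                    true_major, true_minor = true_grid[tendon]
                    if config.noise_sd_mm > 0:
                        obs_major = _quantize(
                            true_major + rng.normal(0.0, config.noise_sd_mm),
                            config.quantum_mm,
                        )
                        obs_minor = _quantize(
                            true_minor + rng.normal(0.0, config.noise_sd_mm),
                            config.quantum_mm,
                        )
                    else:
                        obs_major, obs_minor = true_major, true_minor
                    if obs_minor > obs_major:  # reorder; tendon mean unchanged
                        obs_major, obs_minor = obs_minor, obs_major
                    measurements.append(
                        TendonMeasurement.from_mm(
                            tendon=tendon,
                            reader=reader,
                            session=session,
                            major_mm=round(obs_major, 1),
                            minor_mm=round(obs_minor, 1),
                        )
                    )

        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                age_years=age,
                sex=sex,
                side=side,
                actual_graft_mm=actual,
                measurements=tuple(measurements),
            )
        )

    return Cohort(
        records=tuple(records),
        metadata={"source": "synthetic", "seed": config.seed, "config": config.as_dict()},
    )
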