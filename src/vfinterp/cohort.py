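"""Synthetic visual-field cohorts.

Stands in for undeposited clinical data: parametric hills of vision for
normal eyes and two retinitis-pigmentosa phenotypes (ring scotoma and
concentric constriction), sampled on the perimetric grid with Gaussian
test-retest noise.  The default cohort reproduces the study structure of the
source data: 10 normal subjects contributing 46 examinations and 10 RP
patients contributing 83, both eyes each, with the per-eye replicate counts
frozen to the published schedule.

Sensitivities are differential luminance sensitivities in dB, clamped to
[floor, ceiling] (0-35 dB, the realistic span of size-V static perimetry).
A subtractive scotoma depth in dB is a multiplicative suppression of linear
luminance sensitivity, which is why the RP models subtract in dB space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Eye, TestGrid, generate_test_grid
from .loocv import Examination

__all__ = ["HovModel", "CohortConfig", "evaluate_hov", "simulate_exam", "simulate_cohort"]

#: Per-eye replicate counts (OD, OS) of the emulated study cohort.
NORMAL_SCHEDULE: tuple[tuple[int, int], ...] = (
    (2, 2), (3, 3), (2, 2), (3, 3), (2, 2), (2, 2), (3, 3), (2, 2), (2, 2), (2, 2),
)  # 46 exams
PATIENT_SCHEDULE: tuple[tuple[int, int], ...] = (
    (5, 5), (5, 5), (4, 4), (4, 4), (2, 2), (5, 5), (4, 4), (5, 5), (4, 3), (4, 4),
)  # 83 exams


@dataclass(frozen=True)
class HovModel:
    """Parametric hill of vision for one subject (defined for the OD;
    the OS field is its mirror image)."""

    kind: str = "normal"          # normal | rp_ring | rp_constricted
    peak_db: float = 32.0         # sensitivity at fixation
    ecc_slope: float = 0.25       # dB lost per degree of eccentricity
    blind_spot_center: tuple[float, float] = (15.0, -1.5)  # OD convention
    blind_spot_radius: float = 4.0
    ring_ecc: float = 25.0        # ring-scotoma center eccentricity
    ring_width: float = 15.0      # full width of the annular loss
    ring_depth_db: float = 25.0   # dB suppressed at the ring center
    island_radius: float = 10.0   # preserved central island (rp_constricted)
    edge_width: float = 5.0       # ramp width of the constriction edge
    floor: float = 0.0
    ceiling: float = 35.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "rp_ring", "rp_constricted"):
            raise ValueError(f"unknown HOV kind {self.kind!r}")
        if not 0 <= self.floor < self.ceiling:
            raise ValueError("need 0 <= floor < ceiling")


def evaluate_hov(model: HovModel, location, eye: Eye | str = Eye.OD) -> float | np.ndarray:
    """Deterministic model sensitivity (dB) at one or many (x, y) locations."""
    loc_arr = np.asarray(location, dtype=float)
    single = loc_arr.ndim == 1
    loc = np.atleast_2d(loc_arr)
    x, y = loc[:, 0].copy(), loc[:, 1]
    if Eye(eye) is Eye.OS:
        x = -x  # evaluate in OD frame; the OS field is the mirror image
    ecc = np.hypot(x, y)
    z = model.peak_db - model.ecc_slope * ecc

    if model.kind == "rp_ring":
        sigma = model.ring_width / 2.0
        z = z - model.ring_depth_db * np.exp(-0.5 * ((ecc - model.ring_ecc) / sigma) ** 2)
    elif model.kind == "rp_constricted":
        r, w = model.island_radius, model.edge_width
        ramp = np.clip((r + w - ecc) / w, 0.0, 1.0)  # 1 inside island, 0 beyond r+w
        z = model.floor + (z - model.floor) * ramp

    bs = np.hypot(x - model.blind_spot_center[0], y - model.blind_spot_center[1])
    z = np.where(bs <= model.blind_spot_radius, model.floor, z)
    z = np.clip(z, model.floor, model.ceiling)
    return float(z[0]) if single else z


def simulate_exam(
    model: HovModel,
    grid: TestGrid,
    noise_sd: float,
    rng: np.random.Generator | int,
    subject_id: str = "S1",
    group: str = "normal",
    replicate_index: int = 1,
    reliability_pass: bool = True,
) -> Examination:
    """One noisy examination of a model eye on a test grid."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    truth = evaluate_hov(model, grid.locations, grid.eye)
    noise = rng.normal(0.0, noise_sd, size=len(grid.locations)) if noise_sd > 0 else 0.0
    z = np.clip(truth + noise, model.floor, model.ceiling)
    return Examination(
        subject_id=subject_id,
        group=group,
        eye=grid.eye,
        replicate_index=replicate_index,
        locations=grid.locations.copy(),
        z=z,
        reliability_pass=reliability_pass,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort structure and noise model.

    With the default 10+10 subjects the per-eye replicate counts follow the
    frozen study schedule (46 normal and 83 patient exams); other subject
    counts draw replicate counts uniformly from ``exams_per_eye``.
    """

    n_normals: int = 10
    n_patients: int = 10
    exams_per_eye: tuple[int, int] = (2, 5)
    noise_sd: float = 2.5
    seed: int = 0
    reliability_fail_rate: float = 0.0
    phenotype_mix: tuple[float, float] = (0.5, 0.5)  # (rp_ring, rp_constricted)

    def __post_init__(self) -> None:
        if self.n_normals < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.reliability_fail_rate <= 1:
            raise ValueError("reliability_fail_rate must be in [0, 1]")


def _draw_normal_model(rng: np.random.Generator) -> HovModel:
    return HovModel(
        kind="normal",
        peak_db=float(rng.normal(32.0, 1.5)),
        ecc_slope=float(rng.uniform(0.22, 0.28)),
    )


def _draw_patient_model(rng: np.random.Generator, mix: tuple[float, float]) -> HovModel:
    p = np.asarray(mix, dtype=float)
    kind = rng.choice(["rp_ring", "rp_constricted"], p=p / p.sum())
    if kind == "rp_ring":
        return HovModel(
            kind="rp_ring",
            peak_db=float(rng.normal(30.0, 2.0)),
            ecc_slope=float(rng.uniform(0.22, 0.30)),
            ring_ecc=float(rng.uniform(20.0, 35.0)),
            ring_width=float(rng.uniform(10.0, 20.0)),
            ring_depth_db=float(rng.uniform(15.0, 30.0)),
        )
    return HovModel(
        kind="rp_constricted",
        peak_db=float(rng.normal(29.0, 2.0)),
        ecc_slope=float(rng.uniform(0.22, 0.30)),
        island_radius=float(rng.uniform(8.0, 20.0)),
    )


def simulate_cohort(config: CohortConfig) -> list[Examination]:
    """Both-eye replicate examinations for every subject in the cohort."""
    rng = np.random.default_rng(config.seed)
    grids = {Eye.OD: generate_test_grid(Eye.OD), Eye.OS: generate_test_grid(Eye.OS)}
    exams: list[Examination] = []

    def run_subject(sid: str, group: str, model: HovModel, counts: tuple[int, int]) -> None:
        for eye, n_rep in zip((Eye.OD, Eye.OS), counts):
            for rep in range(1, n_rep + 1):
                passed = bool(rng.random() >= config.reliability_fail_rate)
                exams.append(
                    simulate_exam(
                        model, grids[eye], config.noise_sd, rng,
                        subject_id=sid, group=group, replicate_index=rep,
                        reliability_pass=passed,
                    )
                )

    lo, hi = config.exams_per_eye
    for i in range(config.n_normals):
        counts = (
            NORMAL_SCHEDULE[i]
            if config.n_normals == len(NORMAL_SCHEDULE)
            else (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        )
        run_subject(f"N{i + 1}", "normal", _draw_normal_model(rng), counts)
    for i in range(config.n_patients):
        counts = (
            PATIENT_SCHEDULE[i]
            if config.n_patients == len(PATIENT_SCHEDULE)
            else (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        )
        run_subject(f"P{i + 1}", "patient", _draw_patient_model(rng, config.phenotype_mix), counts)
    return exams
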