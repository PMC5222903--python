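"""File formats, run configuration, and the end-to-end pipeline.

All data travel as plain CSV/JSON.  Examination files use the columns
``subject_id,group,eye,replicate,x_deg,y_deg,sensitivity_db`` with one row
per tested location.  Dense surfaces are written as a JSON header (nx, ny,
extent, spacing, method) plus a whitespace-delimited matrix, row-major in j
(axis 0 of the matrix indexes x ascending, axis 1 indexes y ascending).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .exceptions import SchemaError, ValidationError
from .grid import BlindSpotSpec, Eye, TestGrid, generate_test_grid
from .interpolate import METHODS, InterpolatorSpec
from .loocv import Examination, average_truth, compute_accuracy, loocv_residuals
from .stats import (
    MetricRecord,
    build_comparison_tables,
    build_group_difference_table,
    records_to_frame,
)
from .surface import DenseSurface, augment_boundary, compute_smoothness, dense_resample

__all__ = [
    "EXAM_COLUMNS",
    "RunConfig",
    "read_examinations",
    "write_examinations",
    "read_grid_csv",
    "write_grid_csv",
    "write_surface",
    "read_surface",
    "run_pipeline",
]

log = logging.getLogger(__name__)

EXAM_COLUMNS = [
    "subject_id", "group", "eye", "replicate", "x_deg", "y_deg", "sensitivity_db",
]


def write_grid_csv(grid: TestGrid, path) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(grid.n_points),
            "x_deg": grid.locations[:, 0],
            "y_deg": grid.locations[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")


def read_grid_csv(path, eye: Eye | str = Eye.OD) -> TestGrid:
    df = pd.read_csv(path)
    for col in ("index", "x_deg", "y_deg"):
        if col not in df.columns:
            raise SchemaError(f"grid file missing column {col!r}")
    df = df.sort_values("index")
    return TestGrid(df[["x_deg", "y_deg"]].to_numpy(), Eye(eye))


def write_examinations(exams: list[Examination], path) -> None:
    """Deterministic CSV dump: subject, eye, replicate, canonical (x, y) order."""
    frames = []
    for ex in sorted(exams, key=lambda e: (e.subject_id, e.eye.value, e.replicate_index)):
        order = ex.canonical_order()
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ex.subject_id,
                    "group": ex.group,
                    "eye": ex.eye.value,
                    "replicate": ex.replicate_index,
                    "x_deg": ex.locations[order, 0],
                    "y_deg": ex.locations[order, 1],
                    "sensitivity_db": ex.z[order],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EXAM_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")


def read_examinations(path) -> list[Examination]:
    df = pd.read_csv(path)
    for col in EXAM_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"examination file missing column {col!r}")
    neg = df.index[df["sensitivity_db"] < 0]
    if len(neg):
        raise ValidationError(f"negative sensitivity at row {int(neg[0]) + 2}")  # 1-based + header
    bad_eye = set(df["eye"]) - {"OD", "OS"}
    if bad_eye:
        raise ValidationError(f"unknown eye value(s): {sorted(bad_eye)}")
    bad_group = set(df["group"]) - {"normal", "patient"}
    if bad_group:
        raise ValidationError(f"unknown group value(s): {sorted(bad_group)}")
    exams = []
    for (sid, group, eye, rep), sub in df.groupby(
        ["subject_id", "group", "eye", "replicate"], sort=True
    ):
        exams.append(
            Examination(
                subject_id=str(sid), group=str(group), eye=Eye(eye),
                replicate_index=int(rep),
                locations=sub[["x_deg", "y_deg"]].to_numpy(),
                z=sub["sensitivity_db"].to_numpy(),
            )
        )
    return exams


def write_surface(surface: DenseSurface, prefix) -> None:
    """Write ``<prefix>.json`` (header), ``<prefix>.mat.txt`` and ``<prefix>.mask.txt``."""
    prefix = Path(prefix)
    nx, ny = surface.shape
    header = {
        "nx": nx, "ny": ny, "extent": surface.extent,
        "spacing": surface.spacing, "method": surface.method,
        "orientation": "values[i,j] = h(x_i, y_j); axis 0 is x ascending",
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(prefix.with_suffix(".mat.txt"), surface.values, fmt="%.6f")
    np.savetxt(prefix.with_suffix(".mask.txt"), surface.mask.astype(int), fmt="%d")


def read_surface(prefix) -> DenseSurface:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    values = np.loadtxt(prefix.with_suffix(".mat.txt"))
    mask = np.loadtxt(prefix.with_suffix(".mask.txt")).astype(bool)
    return DenseSurface(
        values=values, extent=header["extent"], spacing=header["spacing"],
        mask=mask, method=header.get("method", ""),
    )


@dataclass
class RunConfig:
    """Flat configuration for the one-shot pipeline."""

    # cohort
    n_normals: int = 10
    n_patients: int = 10
    exams_per_eye: tuple[int, int] = (2, 5)
    noise_sd: float = 2.5
    reliability_fail_rate: float = 0.0
    # methods
    methods: tuple[str, ...] = METHODS
    # blind spot
    blind_spot_x: float = 15.0
    blind_spot_y: float = -1.5
    blind_spot_radius: float = 6.0
    # surfaces
    surface_n: int = 501
    surface_extent: float = 90.0
    boundary_n: int = 72
    boundary_radius: float = 120.0
    boundary_value: float = 0.0
    save_surfaces: bool = False
    # statistics
    alpha: float = 0.05
    n_comparisons: int = 9
    reference_method: str = "RBFlin"
    # run
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.exams_per_eye = tuple(self.exams_per_eye)
        if not self.methods:
            raise ValueError("methods list must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["exams_per_eye"] = list(self.exams_per_eye)
        return d

    def blind_spot(self) -> BlindSpotSpec:
        return BlindSpotSpec(
            center_od=(self.blind_spot_x, self.blind_spot_y),
            exclusion_radius=self.blind_spot_radius,
        )

    def cohort(self) -> CohortConfig:
        return CohortConfig(
            n_normals=self.n_normals, n_patients=self.n_patients,
            exams_per_eye=self.exams_per_eye, noise_sd=self.noise_sd,
            seed=self.seed, reliability_fail_rate=self.reliability_fail_rate,
        )


def evaluate_examinations(
    exams: list[Examination],
    methods: tuple[str, ...],
    blind_spot: BlindSpotSpec,
    surface_n: int | None = 501,
    surface_extent: float = 90.0,
    boundary_n: int = 72,
    boundary_radius: float = 120.0,
    boundary_value: float = 0.0,
    surface_sink=None,
) -> list[MetricRecord]:
    """LOOCV accuracy plus surface smoothness for every (exam, method).

    ``surface_n=None`` skips the surface/TV stage.  ``surface_sink`` is an
    optional callable ``(exam, method, DenseSurface) -> None`` used by the
    pipeline to persist surfaces.
    """
    usable = [ex for ex in exams if ex.reliability_pass]
    truths = {}
    for ex in usable:
        truths.setdefault((ex.subject_id, ex.eye), []).append(ex)
    truth_fields = {k: average_truth(v) for k, v in truths.items()}

    records: list[MetricRecord] = []
    for ex in usable:
        truth = truth_fields[(ex.subject_id, ex.eye)]
        aug = (
            augment_boundary(ex.points, boundary_n, boundary_radius, boundary_value)
            if surface_n
            else None
        )
        for m in methods:
            spec = InterpolatorSpec(method=m)
            rs = loocv_residuals(ex, truth, spec, blind_spot)
            acc = compute_accuracy(rs)
            tv1 = tv2 = np.nan
            if surface_n:
                surf = dense_resample(
                    spec, aug, n=surface_n, extent=surface_extent,
                    hull_points=ex.locations,
                )
                sm = compute_smoothness(surf)
                tv1, tv2 = sm.tv1, sm.tv2
                if surface_sink is not None:
                    surface_sink(ex, m, surf)
            records.append(
                MetricRecord(
                    subject_id=ex.subject_id, group=ex.group, eye=ex.eye.value,
                    replicate=ex.replicate_index, method=m,
                    mae=acc.mae, rmse=acc.rmse, d1=acc.d1, tv1=tv1, tv2=tv2,
                    fallback_count=rs.fallback_count,
                )
            )
        log.info(
            "evaluated %s/%s rep %d over %d methods",
            ex.subject_id, ex.eye.value, ex.replicate_index, len(methods),
        )
    return records


def write_metric_records(records, path) -> None:
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")


def write_comparison_tables(tables, group_table: pd.DataFrame, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tables:
        for m, mean in t.means.items():
            rows.append(
                {
                    "metric": t.metric, "scope": t.scope, "method": m, "mean": mean,
                    "p_vs_reference": t.pvalues.get(m, np.nan),
                    "flag": t.flags.get(m, False),
                    "reference": t.reference, "alpha_corrected": t.alpha_corrected,
                }
            )
    pd.DataFrame(rows).to_csv(
        out_dir / "comparison_tables.csv", index=False, float_format="%.6g"
    )
    group_table.to_csv(out_dir / "group_differences.csv", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Simulate -> LOOCV -> surfaces -> comparison, all under one seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    log.info("stage 1/4: simulating cohort (seed=%d)", config.seed)
    exams = simulate_cohort(config.cohort())
    write_examinations(exams, out / "cohort.csv")
    write_grid_csv(generate_test_grid(Eye.OD), out / "grid_od.csv")

    log.info("stage 2/4+3/4: LOOCV and surfaces for %d exams", len(exams))
    sink = None
    if config.save_surfaces:
        sdir = out / "surfaces"
        sdir.mkdir(exist_ok=True)

        def sink(ex, m, surf):  # noqa: F811
            write_surface(surf, sdir / f"{ex.subject_id}_{ex.eye.value}_{ex.replicate_index}_{m}")

    records = evaluate_examinations(
        exams, config.methods, config.blind_spot(),
        surface_n=config.surface_n, surface_extent=config.surface_extent,
        boundary_n=config.boundary_n, boundary_radius=config.boundary_radius,
        boundary_value=config.boundary_value, surface_sink=sink,
    )
    write_metric_records(records, out / "metrics.csv")

    log.info("stage 4/4: statistical comparison")
    ref = config.reference_method if config.reference_method in config.methods else config.methods[0]
    if len(config.methods) > 1:
        tables = build_comparison_tables(
            records, ref, alpha=config.alpha, n_comparisons=config.n_comparisons
        )
        group_table = build_group_difference_table(records, alpha=config.alpha)
        write_comparison_tables(tables, group_table, out / "tables")

    manifest = {"config": config.to_dict(), "seed": config.seed, "version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
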