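"""File formats, configuration and result serialization.

One dialect per kind of artifact, all plain text: YAML for configuration
and geometry scalars, CSV for tables (pressure traces, point sets, tension
profiles), JSON for structured results (schema-versioned). Units are fixed
at kPa / mm / ml in every file; there is no unit auto-detection.

Frames directory layout (written by ``diastolefit insilico generate`` and
read by ``diastolefit estimate``)::

    template.yaml    reference-family geometry constants + quadrature counts
    points.csv       material coordinates, weights, fiber angles
    pressures.csv    frame,pressure_kpa
    frame_001.csv..  x_mm,y_mm,z_mm per material point
    truth.json       (optional) generation ground truth
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import (
    DEFAULT_BETA,
    GuccioneParams,
    ReformulatedParams,
    reformulate,
)
from .estimator import EstimationResult, FramesData, SweepConfig
from .exceptions import FormatError, ValidationError
from .forward_model import MaterialPointSet, UnloadedGeometry

__all__ = [
    "RunConfig",
    "load_pressure_trace",
    "write_result",
    "read_result",
    "write_frames",
    "load_frames",
    "load_config",
    "save_config",
    "export_vtk_points",
]

RESULT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Top-level run configuration (YAML round-trippable)."""

    frames_dir: str | None = None
    pressures_csv: str | None = None
    output_dir: str = "."
    sweep: SweepConfig = field(default_factory=SweepConfig)
    quadrature: tuple = (5, 5, 8)
    beta: float = DEFAULT_BETA
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep"]["alpha_grid"] = [float(x) for x in self.sweep.alpha_grid]
        d["sweep"]["c1_grid"] = [float(x) for x in self.sweep.c1_grid]
        d["sweep"]["at_range"] = list(self.sweep.at_range)
        d["quadrature"] = list(self.quadrature)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sweep = d.pop("sweep", {})
        if isinstance(sweep, dict):
            sweep = dict(sweep)
            for key in ("alpha_grid", "c1_grid"):
                if key in sweep:
                    sweep[key] = np.asarray(sweep[key], dtype=float)
            if "at_range" in sweep:
                sweep["at_range"] = tuple(sweep["at_range"])
            sweep = SweepConfig(**sweep)
        d["quadrature"] = tuple(d.get("quadrature", (5, 5, 8)))
        return cls(sweep=sweep, **d)

    def config_hash(self) -> str:
        """Stable digest of the configuration, logged with every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# pressure traces


def load_pressure_trace(path) -> np.ndarray:
    """Frame-indexed cavity pressures (kPa) from a two-column CSV.

    The file must have a ``frame,pressure_kpa`` header; rows may be in any
    order and are sorted by frame index. Duplicate frames, non-numeric
    entries and negative pressures are rejected.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable CSV ({exc})") from None
    required = {"frame", "pressure_kpa"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: no pressure rows")
    frames = pd.to_numeric(df["frame"], errors="coerce")
    pressures = pd.to_numeric(df["pressure_kpa"], errors="coerce")
    if frames.isna().any() or pressures.isna().any():
        raise FormatError(f"{path}: non-numeric entries")
    if frames.duplicated().any():
        dup = sorted(frames[frames.duplicated()].unique())
        raise FormatError(f"{path}: duplicate frames {dup}")
    if (pressures < 0).any():
        raise FormatError(f"{path}: negative pressures rejected")
    order = np.argsort(frames.to_numpy(), kind="stable")
    return pressures.to_numpy(dtype=float)[order]


# ---------------------------------------------------------------------------
# geometry / frames


def _geometry_to_dict(g: UnloadedGeometry) -> dict:
    return {k: float(v) for k, v in dataclasses.asdict(g).items()}


def _geometry_from_dict(d: dict) -> UnloadedGeometry:
    return UnloadedGeometry(**{k: float(v) for k, v in d.items()})


def write_frames(frames: FramesData, out_dir, truth: dict | None = None) -> Path:
    """Write a frames directory (template, points, pressures, per-frame
    positions and optionally the generation truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "template": _geometry_to_dict(frames.template),
        "base_z": None if frames.base_z is None else float(frames.base_z),
        "n_frames": frames.n,
    }
    (out / "template.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    pts = frames.points
    pd.DataFrame(
        {
            "lam": pts.lam,
            "mu": pts.mu,
            "theta": pts.theta,
            "weight_mm3": pts.weights,
            "fiber_angle_rad": pts.fiber_angle,
        }
    ).to_csv(out / "points.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        {"frame": np.arange(1, frames.n + 1), "pressure_kpa": frames.pressures}
    ).to_csv(out / "pressures.csv", index=False, float_format="%.17g")
    for i, pos in enumerate(frames.positions, start=1):
        pd.DataFrame(pos, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            out / f"frame_{i:03d}.csv", index=False, float_format="%.17g"
        )
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out


def load_frames(frames_dir) -> FramesData:
    """Read a frames directory written by :func:`write_frames`."""
    d = Path(frames_dir)
    if not (d / "template.yaml").exists():
        raise FormatError(f"{d}: missing template.yaml")
    meta = yaml.safe_load((d / "template.yaml").read_text())
    template = _geometry_from_dict(meta["template"])
    ptdf = pd.read_csv(d / "points.csv")
    pressures = load_pressure_trace(d / "pressures.csv")
    n = int(meta["n_frames"])
    positions = []
    for i in range(1, n + 1):
        f = d / f"frame_{i:03d}.csv"
        if not f.exists():
            raise FormatError(f"{d}: missing {f.name}")
        positions.append(pd.read_csv(f).to_numpy(dtype=float))
    pts = MaterialPointSet(
        lam=ptdf["lam"].to_numpy(),
        mu=ptdf["mu"].to_numpy(),
        theta=ptdf["theta"].to_numpy(),
        weights=ptdf["weight_mm3"].to_numpy(),
        fiber_angle=ptdf["fiber_angle_rad"].to_numpy(),
        positions=positions[0],
        template=template,
    )
    base_z = meta.get("base_z")
    return FramesData(
        positions=positions,
        pressures=pressures,
        points=pts,
        template=template,
        base_z=None if base_z is None else float(base_z),
    )


# ---------------------------------------------------------------------------
# results


def write_result(result: EstimationResult, out_dir) -> dict:
    """Write result JSON + AT-profile CSV + human-readable summary.

    Returns the paths written; :func:`read_result` reproduces the stored
    quantities exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = result.reformulated
    payload = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "params": result.params.as_dict(),
        "reformulated": r.as_dict(),
        "x0": _geometry_to_dict(result.x0),
        "at_profile_kpa": [float(x) for x in result.at_profile],
        "reference_frame": int(result.reference_frame),
        "objectives_mm2": [float(x) for x in result.objectives],
        "rmse_mm": [float(x) for x in result.rmse],
        "criterion_satisfied": bool(result.criterion_satisfied),
        "no_residual_at": bool(result.no_residual_at),
        "boundary_warnings": [list(map(int, w)) for w in result.boundary_warnings],
    }
    json_path = out / "result.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    csv_path = out / "at_profile.csv"
    pd.DataFrame(
        {
            "frame": np.arange(1, len(result.at_profile) + 1),
            "tz_kpa": result.at_profile,
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")

    summary = out / "summary.txt"
    lines = [
        "diastolefit estimation summary",
        f"reference frame k = {result.reference_frame}",
        f"constitutive (c1, c2, c3, c4) kPa/-: "
        f"{result.params.c1:.6g}, {result.params.c2:.6g}, "
        f"{result.params.c3:.6g}, {result.params.c4:.6g}",
        f"reformulated (c1, alpha, r2, r3, r4): "
        f"{r.c1:.6g}, {r.alpha:.6g}, {r.r2:.6g}, {r.r3:.6g}, {r.r4:.6g}",
        f"unloaded endocardial radius = {result.x0.endo_radius:.6g} mm",
        "AT profile (kPa): "
        + ", ".join(f"{x:.3f}" for x in result.at_profile),
        f"per-frame RMSE (mm): "
        + ", ".join(f"{x:.4f}" for x in result.rmse),
        f"criterion satisfied: {result.criterion_satisfied}"
        + ("  [no residual AT detected]" if result.no_residual_at else ""),
    ]
    summary.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "csv": csv_path, "summary": summary}


def read_result(out_dir) -> EstimationResult:
    """Reconstruct an :class:`EstimationResult` from :func:`write_result`."""
    payload = json.loads((Path(out_dir) / "result.json").read_text())
    if payload.get("schema_version") != RESULT_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported result schema {payload.get('schema_version')!r}"
        )
    params = GuccioneParams(**payload["params"])
    return EstimationResult(
        params=params,
        reformulated=ReformulatedParams(**payload["reformulated"]),
        x0=_geometry_from_dict(payload["x0"]),
        at_profile=np.asarray(payload["at_profile_kpa"], dtype=float),
        reference_frame=int(payload["reference_frame"]),
        objectives=np.asarray(payload["objectives_mm2"], dtype=float),
        rmse=np.asarray(payload["rmse_mm"], dtype=float),
        criterion_satisfied=bool(payload["criterion_satisfied"]),
        no_residual_at=bool(payload["no_residual_at"]),
        boundary_warnings=[tuple(w) for w in payload["boundary_warnings"]],
    )


def export_vtk_points(path, positions: np.ndarray, scalars: dict | None = None):
    """Legacy-ASCII VTK point-cloud export for visualization."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValidationError("positions must be (n, 3)")
    n = len(pos)
    lines = [
        "# vtk DataFile Version 3.0",
        "diastolefit point set",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in pos]
    lines += [f"VERTICES {n} {2 * n}"] + [f"1 {i}" for i in range(n)]
    if scalars:
        lines.append(f"POINT_DATA {n}")
        for name, values in scalars.items():
            v = np.asarray(values, dtype=float)
            if v.shape != (n,):
                raise ValidationError(f"scalar field {name!r} must have length {n}")
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [f"{x:.10g}" for x in v]
    Path(path).write_text("\n".join(lines) + "\n")
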