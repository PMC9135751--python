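"""End-to-end orchestration: simulate → volumes → surface → features → stats → report.

A run is fully reproducible from its configuration plus seed: the config is
schema-validated up front, hashed, and the hash is stamped into every output
table.  Each stage writes plain files into the run directory and is
resumable (existing outputs are reused when ``resume=True``).

The imaging stages rasterize only a configurable handful of scans through
the phantom → volumetry → surface → folding-metrics path (the full cohort's
outcome table comes from the simulator's growth curves); this keeps the
demonstration run cheap while exercising every stage on real geometry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, SimulatedCohort, simulate_cohort
from .distress import DEFAULT_THRESHOLDS
from .errors import ValidationError
from .features import (
    LGIParams,
    aggregate_features,
    local_gyrification_index,
    sulcal_depth,
)
from .io import load_surface_ply, write_surface_ply, write_table
from .phantom import PhantomSpec, make_phantom
from .stats import BATTERY_NAMES, enumerate_models, growth_fit, run_battery
from .surface import assign_regions, convex_hull_mesh, extract_junction_mesh
from .volume import LOBES, TISSUES, LabelVolume
from .volumetry import tissue_volumes

log = logging.getLogger(__name__)

#: labels forming the inside of the gray-white junction surface
JUNCTION_INNER_LABELS = ("wm", "dgm", "ventricles")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    lgi: LGIParams = field(default_factory=LGIParams)
    thresholds: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    alpha: float = 0.05
    batteries: tuple[str, ...] = BATTERY_NAMES
    step3_measures: tuple[str, ...] = ("pss", "epds")
    n_phantom_scans: int = 2
    antialias_sigma: float = 1.0
    smoothing_iterations: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_phantom_scans < 0:
            raise ValidationError("n_phantom_scans must be >= 0")
        unknown = set(self.batteries) - set(BATTERY_NAMES)
        if unknown:
            raise ValidationError(f"unknown batteries {sorted(unknown)}")
        self.cohort.validate()

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        if "cohort" in data and isinstance(data["cohort"], dict):
            data["cohort"] = _build_dataclass(CohortSpec, data["cohort"])
        if "lgi" in data and isinstance(data["lgi"], dict):
            data["lgi"] = _build_dataclass(LGIParams, data["lgi"])
        for key in ("batteries", "step3_measures"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_dataclass(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        elif isinstance(v, dict):
            v = {
                kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()
            }
            v = {
                kk: {k3: tuple(v3) if isinstance(v3, list) else v3 for k3, v3 in vv.items()}
                if isinstance(vv, dict)
                else vv
                for kk, vv in v.items()
            }
        coerced[k] = v
    return cls(**coerced)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _provenance(config: PipelineConfig) -> str:
    return f"fetalfold={__version__} config_hash={config.config_hash} seed={config.seed}"


# -- stages -------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> SimulatedCohort:
    sim = simulate_cohort(config.cohort, seed=config.seed)
    write_table(sim.records, outdir / "cohort.csv", _provenance(config))
    params = pd.DataFrame(
        {
            "scan_id": list(sim.phantom_specs),
            "wm_radius": [s.wm_radius for s in sim.phantom_specs.values()],
            "fold_amplitude": [
                s.fold_amplitude for s in sim.phantom_specs.values()
            ],
        }
    )
    write_table(params, outdir / "phantom_params.csv", _provenance(config))
    return sim


def _demo_specs(config: PipelineConfig, outdir: Path) -> dict[str, PhantomSpec]:
    params = pd.read_csv(outdir / "phantom_params.csv", comment="#")
    out: dict[str, PhantomSpec] = {}
    for _, row in params.head(config.n_phantom_scans).iterrows():
        out[row["scan_id"]] = PhantomSpec.create(
            wm_radius=float(row["wm_radius"]),
            fold_amplitude=float(row["fold_amplitude"]),
            spacing=config.cohort.phantom_spacing,
        )
    return out


def stage_volumes(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for scan_id, spec in _demo_specs(config, outdir).items():
        seg, parc = make_phantom(spec, seed=config.seed)
        seg.save(str(outdir / f"{scan_id}_seg.nii.gz"))
        parc.save(str(outdir / f"{scan_id}_parc.nii.gz"))
        vols = tissue_volumes(seg)
        row = {"scan_id": scan_id}
        for t in TISSUES:
            row[f"{t}_cm3"] = vols[t]
        rows.append(row)
    df = pd.DataFrame(rows)
    write_table(df, outdir / "volumes_measured.csv", _provenance(config))
    return df


def stage_surface(config: PipelineConfig, outdir: Path) -> None:
    for scan_id, spec in _demo_specs(config, outdir).items():
        seg = LabelVolume.load(str(outdir / f"{scan_id}_seg.nii.gz"))
        parc = LabelVolume.load(str(outdir / f"{scan_id}_parc.nii.gz"))
        mesh = extract_junction_mesh(
            seg,
            JUNCTION_INNER_LABELS,
            antialias_sigma=config.antialias_sigma,
            smoothing_iterations=config.smoothing_iterations,
        )
        assign_regions(mesh, parc)
        write_surface_ply(mesh, outdir / f"{scan_id}_surface.ply")


def stage_features(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for scan_id in _demo_specs(config, outdir):
        path = outdir / f"{scan_id}_surface.ply"
        if not path.exists():
            raise PipelineError(f"features: missing surface for {scan_id}")
        mesh = load_surface_ply(path)
        hull_all = convex_hull_mesh(mesh, "both")
        lgi = local_gyrification_index(mesh, hull_all, config.lgi)
        depth = np.full(len(mesh.vertices), np.nan)
        for hemi in ("left", "right"):
            hull_h = convex_hull_mesh(mesh, hemi)
            d = sulcal_depth(mesh, hull_h)
            depth = np.where(np.isnan(d), depth, d)
        feats = aggregate_features(mesh, lgi, depth)
        write_surface_ply(
            mesh, path, extra_vertex_properties={"lgi": lgi, "sulcal_depth": depth}
        )
        rows.append({"scan_id": scan_id, **feats.as_row()})
    df = pd.DataFrame(rows)
    write_table(df, outdir / "features_measured.csv", _provenance(config))
    return df


def stage_stats(config: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    records = pd.read_csv(outdir / "cohort.csv", comment="#")
    if records.empty:
        raise PipelineError("stats: empty cohort table")
    out = {}
    for battery in config.batteries:
        specs = enumerate_models(
            battery,
            step3_measures=config.step3_measures,
            thresholds=config.thresholds,
        )
        result = run_battery(
            records,
            specs,
            alpha=config.alpha,
            with_lsmeans=battery in ("step2", "step3"),
        )
        write_table(result, outdir / f"stats_{battery}.csv", _provenance(config))
        out[battery] = result
    return out


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    render_report(outdir, config)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, resume: bool = False
) -> Path:
    """Execute every stage in order; returns the run directory.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    Any stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "package": "fetalfold",
                "version": __version__,
                "config_hash": config.config_hash,
                "seed": config.seed,
            },
            indent=2,
        )
    )
    stages = [
        ("simulate", stage_simulate, "cohort.csv"),
        ("volumes", stage_volumes, "volumes_measured.csv"),
        ("surface", stage_surface, None),
        ("features", stage_features, "features_measured.csv"),
        ("stats", stage_stats, None),
        ("report", stage_report, None),
    ]
    for name, fn, marker in stages:
        if resume and marker and (outdir / marker).exists():
            log.info("stage %s: outputs present, skipping", name)
            continue
        log.info("stage %s", name)
        try:
            fn(config, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage context for the operator
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return outdir


# -- report -------------------------------------------------------------------


def render_report(outdir: str | Path, config: PipelineConfig | None = None) -> None:
    """Growth-curve figures and the Table-2/3-style grids from a stats run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    cohort_path = outdir / "cohort.csv"
    if not cohort_path.exists():
        raise PipelineError("report: missing cohort.csv (run stats first)")
    records = pd.read_csv(cohort_path, comment="#")
    if records.empty:
        (outdir / "report.txt").write_text("no data: empty cohort\n")
        return

    colors = {0: "tab:blue", 1: "tab:red"}
    labels = {0: "pre-pandemic", 1: "pandemic"}

    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    for ax, tissue in zip(axes.ravel(), TISSUES):
        for cohort_value, sub in records.groupby("cohort"):
            ax.scatter(
                sub["ga_mri_weeks"], sub[tissue], s=6, alpha=0.5,
                color=colors[cohort_value], label=labels[cohort_value],
            )
            fit = growth_fit(sub["ga_mri_weeks"], sub[tissue], "exponential")
            ga = np.linspace(records["ga_mri_weeks"].min(), records["ga_mri_weeks"].max(), 80)
            ax.plot(ga, fit.predict(ga), color=colors[cohort_value])
        ax.set_title(tissue)
        ax.set_xlabel("GA at MRI (weeks)")
        ax.set_ylabel("volume (cm$^3$)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "fig_volumes_vs_ga.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(3, 4, figsize=(15, 9))
    for i, feat in enumerate(("area", "lgi", "depth")):
        for j, lobe in enumerate(LOBES):
            ax = axes[i, j]
            col = f"{feat}_{lobe}"
            sub_ok = records.dropna(subset=[col])
            for cohort_value, sub in sub_ok.groupby("cohort"):
                ax.scatter(
                    sub["ga_mri_weeks"], sub[col], s=6, alpha=0.5,
                    color=colors[cohort_value],
                )
                fit = growth_fit(sub["ga_mri_weeks"], sub[col], "linear")
                ga = np.linspace(sub_ok["ga_mri_weeks"].min(), sub_ok["ga_mri_weeks"].max(), 50)
                ax.plot(ga, fit.predict(ga), color=colors[cohort_value])
            ax.set_title(col, fontsize=9)
    fig.tight_layout()
    fig.savefig(outdir / "fig_features_vs_ga.png", dpi=110)
    plt.close(fig)

    # Table-2-style grid: cohort beta/p per outcome x adjusting measure
    step2_path = outdir / "stats_step2.csv"
    if step2_path.exists():
        step2 = pd.read_csv(step2_path, comment="#")
        adjusted = step2[step2["covariates"].str.count("\\+") == 3].copy()
        if not adjusted.empty:
            adjusted["measure"] = adjusted["covariates"].str.split(" \\+ ").str[-1]
            grid = adjusted.pivot(
                index="outcome", columns="measure", values=["beta", "p", "q"]
            )
            grid.columns = [f"{a}_{b}" for a, b in grid.columns]
            grid.reset_index().to_csv(outdir / "table_step2_grid.csv", index=False)

    step3_path = outdir / "stats_step3.csv"
    if step3_path.exists():
        step3 = pd.read_csv(step3_path, comment="#")
        keep = [
            c
            for c in (
                "outcome", "subset", "lsmean_pre", "lsmean_se_pre",
                "lsmean_pandemic", "lsmean_se_pandemic", "p", "q",
            )
            if c in step3.columns
        ]
        step3[keep].to_csv(outdir / "table_lsmeans.csv", index=False)
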