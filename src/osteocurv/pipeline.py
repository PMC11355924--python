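"""End-to-end experiment pipeline.

Generates a cohort of synthetic trabecular cubes, measures every sample
(histomorphometry, plate/rod geometry, optional micro-FE stiffness),
builds the 4-channel curvature projection images, and trains/evaluates
one CNN per requested target set. Every stage is seeded; rerunning with
an identical config reproduces all CSV outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import histomorphometry as hm
from . import micro_fe as fe
from . import plate_rod as pr
from .curvature import (derived_curvatures, extract_surface, mask_cut_faces,
                        principal_curvatures)
from .microstructure import (GeneratorSpec, VoxelVolume, exclusion_filter,
                             generate_grf_cube)
from .projection import CURVATURE_KINDS, projection_stack

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "SampleRecord", "build_dataset",
           "run_experiment", "ablation_run", "measure_sample"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Reproducible description of one experiment.

    The generator ranges define the cohort: bone volume fraction,
    trabecular feature size (correlation length, voxels) and uniaxial
    anisotropy stretch are drawn uniformly per sample. All randomness
    derives from ``seed``; there is no wall-clock default anywhere.
    """

    n_samples: int = 300
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 0.035
    bvtv_range: tuple[float, float] = (0.08, 0.40)
    correlation_length_range: tuple[float, float] = (1.5, 3.0)
    anisotropy_range: tuple[float, float] = (1.0, 2.5)
    seed: int = 0

    # surface / curvature settings (the marching-cubes smoothing preset)
    smooth_sigma: float = 1.0
    taubin_iterations: int = 20
    normal_smooth_iterations: int = 6
    projection_axis: int = 2
    # clip |k1|, |k2| at curvature_clip / spacing before projecting: radii
    # below one voxel are discretization noise and would drown the signal
    curvature_clip: float = 1.0

    # measurement settings
    mil_directions: int = 96
    mil_origins: int = 24
    min_bvtv: float = 0.05
    min_component_size: int = 100

    # micro-FE (slow; off unless the stiffness task is requested)
    fe_material: fe.MaterialModel = field(default_factory=fe.MaterialModel)
    fe_tol: float = 1e-6
    fe_mode: str = "tet"

    # CNN
    tasks: tuple[str, ...] = ("histomorphometric",)
    train_fraction: float = 0.8
    n_epochs: int | None = None       # None -> per-task tuned default
    ablation_channels: tuple[str, ...] = CURVATURE_KINDS

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("need at least 5 samples")
        for task in self.tasks:
            if task not in cnn_mod.TABLE_CONFIGS:
                raise ValueError(f"unknown task {task!r}")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    def sample_specs(self) -> list[GeneratorSpec]:
        """Per-sample generator specs, derived deterministically from the
        master seed."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 911]))
        specs = []
        for i in range(self.n_samples):
            bv = rng.uniform(*self.bvtv_range)
            cl = rng.uniform(*self.correlation_length_range)
            stretch = rng.uniform(*self.anisotropy_range)
            scales = [1.0, 1.0, 1.0]
            scales[rng.integers(0, 3)] = stretch
            sub = int(rng.integers(0, 2 ** 31 - 1))
            specs.append(GeneratorSpec(
                shape=self.shape, target_bvtv=float(bv),
                correlation_length=float(cl),
                anisotropy_scales=tuple(scales), seed=sub,
                spacing=self.spacing))
        return specs


@dataclass
class SampleRecord:
    """Everything measured for one cube (None where a stage was skipped or
    the sample excluded)."""

    sample_id: int
    spec: GeneratorSpec
    excluded: bool = False
    exclusion_reason: str | None = None
    image: np.ndarray | None = None
    channel_ranges: list[tuple[float, float]] | None = None
    histo: hm.HistomorphometricSet | None = None
    platerod: pr.PlateRodMetrics | None = None
    stiffness: dict[str, float] | None = None


def measure_sample(
    volume: VoxelVolume,
    config: ExperimentConfig,
    with_platerod: bool = False,
    with_fe: bool = False,
) -> dict:
    """Measure one volume: projection image, histomorphometry, and
    optionally plate/rod metrics and the fabric-frame stiffness constants."""
    mesh = extract_surface(volume, smooth_sigma=config.smooth_sigma,
                           taubin_iterations=config.taubin_iterations)
    field_ = principal_curvatures(
        mesh, normal_smooth_iterations=config.normal_smooth_iterations)
    if config.curvature_clip > 0:
        bound = config.curvature_clip / volume.spacing
        field_.k1 = np.clip(field_.k1, -bound, bound)
        field_.k2 = np.clip(field_.k2, -bound, bound)
    field_ = derived_curvatures(field_)
    field_.valid_mask = mask_cut_faces(mesh, volume.bounds,
                                       tolerance=volume.spacing)
    # raw (unrescaled) projections: absolute curvature magnitudes carry the
    # morphometric signal; CNN input normalization happens dataset-wide on
    # the training split, mirroring the output treatment
    image, ranges = projection_stack(mesh, field_, volume,
                                     axis=config.projection_axis,
                                     rescale=False)
    fabric = hm.mil_fabric(volume, config.mil_directions, config.mil_origins,
                           seed=0, clamp_degenerate=True)
    histo = hm.HistomorphometricSet(
        bvtv=hm.bvtv(volume),
        bs=hm.bone_surface(mesh, field_.valid_mask),
        tbth=hm.trabecular_thickness(volume),
        smi=hm.smi(volume, mesh=mesh, valid_mask=field_.valid_mask),
        da=fabric.da,
        connd=hm.connectivity_density(volume),
    )
    out = {"mesh": mesh, "field": field_, "image": image,
           "channel_ranges": ranges, "histo": histo, "fabric": fabric}
    if with_platerod:
        out["platerod"] = pr.measure(pr.decompose(volume), volume)
    if with_fe:
        C = fe.homogenized_stiffness(volume, config.fe_material,
                                     mode=config.fe_mode, tol=config.fe_tol)
        Cf, discarded = fe.rotate_to_fabric(C, fabric.axes)
        consts = fe.orthotropic_constants(Cf)
        consts["discarded_norm"] = discarded
        out["stiffness"] = consts
    return out


def build_dataset(config: ExperimentConfig, progress: bool = False) -> list[SampleRecord]:
    """Generate and measure the whole cohort. Excluded samples (low BV/TV
    or minimal trabeculae after component pruning) carry a reason instead
    of measurements."""
    with_pr = "geometric" in config.tasks
    with_fe = "stiffness" in config.tasks
    records: list[SampleRecord] = []
    t0 = time.time()
    for i, spec in enumerate(config.sample_specs()):
        rec = SampleRecord(sample_id=i, spec=spec)
        try:
            volume = generate_grf_cube(spec)
        except Exception as exc:
            rec.excluded, rec.exclusion_reason = True, f"generation error: {exc}"
            records.append(rec)
            continue
        decision = exclusion_filter(volume, config.min_bvtv,
                                    config.min_component_size)
        if not decision.keep:
            rec.excluded, rec.exclusion_reason = True, decision.reason
            records.append(rec)
            continue
        m = measure_sample(volume, config, with_platerod=with_pr,
                           with_fe=with_fe)
        rec.image = m["image"].astype(np.float32)
        rec.channel_ranges = m["channel_ranges"]
        rec.histo = m["histo"]
        rec.platerod = m.get("platerod")
        rec.stiffness = m.get("stiffness")
        records.append(rec)
        if progress and (i + 1) % 25 == 0:
            log.info("measured %d/%d samples (%.1f s elapsed)",
                     i + 1, config.n_samples, time.time() - t0)
    return records


_TASK_TARGETS = {
    "histomorphometric": hm.HistomorphometricSet.names,
    "geometric": pr.PlateRodMetrics.names,
    "stiffness": ("C11", "C22", "C33", "C12", "C13", "C23",
                  "C44", "C55", "C66"),
}


def _target_matrix(records: list[SampleRecord], task: str):
    names = _TASK_TARGETS[task]
    rows, keep = [], []
    for rec in records:
        if rec.excluded:
            continue
        if task == "histomorphometric":
            vals = rec.histo.as_array()
        elif task == "geometric":
            vals = rec.platerod.as_array()
        else:
            vals = np.array([rec.stiffness[n] for n in names])
        if np.isfinite(vals).all():
            rows.append(vals)
            keep.append(rec)
    return np.asarray(rows), keep, names


def _normalize_images(images: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Input-image preparation: signed square root of the bin values (a
    variance-stabilizing compression of the heavy-tailed curvature sums),
    then per-channel min-max normalization using the training split's
    statistics only (no test leakage)."""
    images = np.sign(images) * np.sqrt(np.abs(images))
    tr = images[train_idx]
    mn = tr.min(axis=(0, 2, 3), keepdims=True)[0]
    mx = tr.max(axis=(0, 2, 3), keepdims=True)[0]
    span = np.where(mx > mn, mx - mn, 1.0)
    return np.clip((images - mn) / span, 0.0, 1.0)


def train_task(
    records: list[SampleRecord],
    task: str,
    config: ExperimentConfig,
    channels: tuple[str, ...] | None = None,
) -> tuple[cnn_mod.RegressionReport, list[float]]:
    """Split, normalize (training statistics only), train and evaluate the
    CNN for one target set; optionally restricted to a channel subset."""
    y, keep, names = _target_matrix(records, task)
    if len(keep) < 5:
        raise ValueError(f"too few usable samples for task {task!r}")
    images = np.stack([rec.image for rec in keep])
    if channels is not None:
        if len(channels) == 0:
            raise ValueError("channel subset must not be empty")
        sel = [CURVATURE_KINDS.index(c) for c in channels]
        images = images[:, sel]
    base = cnn_mod.TABLE_CONFIGS[task]
    cfg = dataclasses.replace(
        base, seed=config.seed,
        n_epochs=config.n_epochs if config.n_epochs is not None else base.n_epochs)
    tr, te = cnn_mod.split_dataset(len(keep), config.train_fraction,
                                   seed=config.seed)
    images = _normalize_images(images, tr)
    y_norm, normalizer = cnn_mod.minmax_normalize(y[tr], names)
    model = cnn_mod.build_model(cfg, images.shape[2:], n_channels=images.shape[1])
    history = cnn_mod.train(model, images[tr], y_norm, cfg)
    report = cnn_mod.evaluate(model, images[te], y[te], normalizer, names)
    return report, history


# ---------------------------------------------------------------------------
# experiment directory output


def _records_frame(records: list[SampleRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id, "seed": rec.spec.seed,
               "target_bvtv": rec.spec.target_bvtv,
               "correlation_length": rec.spec.correlation_length,
               "anisotropy": max(rec.spec.anisotropy_scales),
               "excluded": rec.excluded,
               "exclusion_reason": rec.exclusion_reason or ""}
        if rec.histo is not None:
            row.update({n: getattr(rec.histo, n)
                        for n in hm.HistomorphometricSet.names})
        if rec.platerod is not None:
            row.update({n: getattr(rec.platerod, n)
                        for n in pr.PlateRodMetrics.names})
        if rec.stiffness is not None:
            row.update(rec.stiffness)
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Run the full pipeline and write a reproducible experiment directory:
    ``samples.csv`` (per-sample measurements and exclusions), per-task
    ``report_<task>.csv``/``loss_<task>.csv``, and ``manifest.json`` with
    the config, per-file hashes and stage timings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.time()
    records = build_dataset(config, progress=True)
    timings["dataset_s"] = round(time.time() - t0, 2)

    samples = _records_frame(records)
    samples.to_csv(out / "samples.csv", index=False)

    reports = {}
    for task in config.tasks:
        t1 = time.time()
        report, history = train_task(records, task, config)
        timings[f"train_{task}_s"] = round(time.time() - t1, 2)
        df = pd.DataFrame({"target": report.names, "r2": report.r2,
                           "p_value": report.p_value})
        df.to_csv(out / f"report_{task}.csv", index=False)
        pd.DataFrame({"epoch": np.arange(len(history)),
                      "mse": history}).to_csv(
            out / f"loss_{task}.csv", index=False)
        reports[task] = report.as_dict()

    manifest = {
        "config": dataclasses.asdict(config),
        "n_samples": config.n_samples,
        "n_excluded": int(samples["excluded"].sum()),
        "reports": reports,
        "timings": timings,
        "hashes": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out


def ablation_run(
    config: ExperimentConfig,
    channel_subset: tuple[str, ...],
    records: list[SampleRecord] | None = None,
    task: str = "histomorphometric",
) -> cnn_mod.RegressionReport:
    """Train the same architecture using only a subset of the curvature
    channels (e.g. a single-curvature model) and report per-target R2."""
    if len(channel_subset) == 0:
        raise ValueError("channel subset must not be empty")
    for c in channel_subset:
        if c not in CURVATURE_KINDS:
            raise ValueError(f"unknown curvature channel {c!r}")
    if records is None:
        records = build_dataset(config)
    report, _ = train_task(records, task, config, channels=tuple(channel_subset))
    return report
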