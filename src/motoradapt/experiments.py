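"""Seeded experiment grids: train, adapt, measure, aggregate.

A grid cell is one (task, encoding, repertoire size, perturbation, seed)
combination. Each cell is fully determined by its config and seed, so
completed cells are cached on disk (HDF5 run file + JSON sidecar) and
skipped on resume. Metrics are aggregated into a tidy table (one row per
cell x metric) from which all summary statistics are computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from . import adaptation_metrics as am
from . import geometry as geo
from .rnn import init_network, simulate
from .tasks import (
    Perturbation,
    TaskConfig,
    build_trial_batch,
    center_out_config,
    ellipse_config,
)
from .training import adaptation_config, de_novo_config, train_stage

__all__ = [
    "CellSpec",
    "ExperimentGrid",
    "MetricsRecord",
    "run_cell",
    "run_grid",
    "summarize",
    "bootstrap_ci",
    "paired_wilcoxon",
    "paired_ttest",
    "vr_adaptation_grid",
]


@dataclass(frozen=True)
class CellSpec:
    """One experiment cell: a network trained de novo then adapted."""

    task_kind: str = "center_out"  # "center_out" | "ellipse"
    encoding: str = "angular"  # center_out: angular|categorical; ellipse: sine|cosine (varied)
    n_movements: int = 4
    perturbation: Perturbation = field(default_factory=Perturbation)
    seed: int = 0
    n_units: int = 300
    batch_size: int = 64
    de_novo_trials: int = 750
    adaptation_trials: int | None = None  # default per perturbation kind

    def task(self) -> TaskConfig:
        if self.task_kind == "center_out":
            return center_out_config(self.n_movements, self.encoding)
        return ellipse_config(self.n_movements, varied=self.encoding)

    def label(self) -> str:
        return (
            f"{self.task_kind}-{self.encoding}-{self.n_movements}mov-"
            f"{self.perturbation.kind}-seed{self.seed}"
        )

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentGrid:
    cells: list[CellSpec]
    out_dir: Path

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)


def vr_adaptation_grid(
    out_dir,
    seeds=range(10),
    repertoire_sizes=(1, 2, 3, 4),
    encodings=("angular",),
    theta_r_deg: float = 10.0,
    **cell_kwargs,
) -> ExperimentGrid:
    """The visuomotor-rotation design: sizes x encodings x seeds."""
    cells = [
        CellSpec(
            encoding=enc,
            n_movements=n,
            perturbation=Perturbation(kind="vr", theta_r_deg=theta_r_deg),
            seed=s,
            **cell_kwargs,
        )
        for enc in encodings
        for n in repertoire_sizes
        for s in seeds
    ]
    return ExperimentGrid(cells=cells, out_dir=out_dir)


@dataclass
class MetricsRecord:
    seed: int
    task_kind: str
    encoding: str
    n_movements: int
    perturbation: str
    metric: str
    value: float


def _seed_stream(seed: int) -> dict[str, int]:
    """Disjoint sub-seeds for the independent random draws of a cell."""
    ss = np.random.SeedSequence(seed)
    names = ("init", "de_novo", "adaptation", "eval", "probe")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_cell(spec: CellSpec, compute_metrics: bool = True) -> dict:
    """Train one cell end to end and compute its adaptation metrics.

    Returns a dict with trained parameter sets, loss curves, and a list of
    MetricsRecord. Deterministic given the spec.
    """
    seeds = _seed_stream(spec.seed)
    task = spec.task()
    params0 = init_network(
        seeds["init"], n_units=spec.n_units, n_inputs=task.n_inputs
    )
    params_pre, curve_dn = train_stage(
        params0,
        task,
        de_novo_config(
            seed=seeds["de_novo"],
            n_trials=spec.de_novo_trials,
            batch_size=spec.batch_size,
        ),
    )
    result = {
        "spec": spec,
        "task": task,
        "params_init": params0,
        "params_pre": params_pre,
        "de_novo_curve": curve_dn,
    }
    records = [
        MetricsRecord(
            spec.seed, spec.task_kind, spec.encoding, spec.n_movements,
            spec.perturbation.kind, "de_novo_final_loss",
            float(curve_dn.smoothed[-1]),
        )
    ]
    if spec.perturbation.kind != "none":
        params_post, curve_ad = train_stage(
            params_pre,
            task,
            adaptation_config(
                spec.task_kind,
                spec.perturbation.kind,
                seed=seeds["adaptation"],
                n_trials=spec.adaptation_trials,
                batch_size=spec.batch_size,
            ),
            perturbation=spec.perturbation,
        )
        result["params_post"] = params_post
        result["adaptation_curve"] = curve_ad
        records.append(
            MetricsRecord(
                spec.seed, spec.task_kind, spec.encoding, spec.n_movements,
                spec.perturbation.kind, "adaptation_final_loss",
                float(curve_ad.smoothed[-1]),
            )
        )
        if compute_metrics:
            records.extend(_adaptation_metrics(result, seeds))
    result["records"] = records
    return result


def _trial_averaged_latents(
    params, task, model, movement_id, seed, n_trials=8, window=None
):
    batch = build_trial_batch(
        task, np.full(n_trials, movement_id, dtype=np.int64)
    )
    trace = simulate(params, batch, seed=seed)
    sm = geo.smooth_rates(trace.r, 0.05, task.dt_s)
    if window is not None:
        sm = sm[:, window]
    return model.transform(sm.mean(axis=0))


def _adaptation_metrics(result: dict, seeds: dict) -> list[MetricsRecord]:
    """Overlap, relative dJ, deviation angle, congruence, decay constant."""
    spec: CellSpec = result["spec"]
    task: TaskConfig = result["task"]
    params_pre = result["params_pre"]
    params_post = result["params_post"]
    epochs = geo.EpochSpec()
    window = epochs.window(task.go_cue_step, task.dt_s, task.n_steps)

    def pooled_smoothed(params, seed):
        batch = build_trial_batch(task, np.zeros(8, dtype=np.int64))
        trace = simulate(params, batch, seed=seed)
        sm = geo.smooth_rates(trace.r, 0.05, task.dt_s)[:, window]
        return sm.reshape(-1, sm.shape[-1])

    pre_pool = pooled_smoothed(params_pre, seeds["eval"])
    post_pool = pooled_smoothed(params_post, seeds["eval"] + 1)
    k = min(10, pre_pool.shape[1])
    overlap, _, _ = am.manifold_overlap(pre_pool, post_pool, k=k)
    rel_dj, _ = am.relative_weight_change(params_pre.J, params_post.J)

    base = dict(
        seed=spec.seed, task_kind=spec.task_kind, encoding=spec.encoding,
        n_movements=spec.n_movements, perturbation=spec.perturbation.kind,
    )
    records = [
        MetricsRecord(**base, metric="manifold_overlap", value=overlap),
        MetricsRecord(**base, metric="relative_dj", value=rel_dj),
    ]

    fit = am.fit_decay_constant(result["adaptation_curve"].loss)
    if fit.success:
        records.append(
            MetricsRecord(**base, metric="decay_constant", value=fit.tau_trials)
        )

    if spec.n_movements >= 2:
        model = geo.fit_manifold(pre_pool, k=k)
        x1 = _trial_averaged_latents(
            params_pre, task, model, 0, seeds["eval"] + 2, window=window
        )
        x2 = _trial_averaged_latents(
            params_pre, task, model, 1, seeds["eval"] + 3, window=window
        )
        x1p = _trial_averaged_latents(
            params_post, task, model, 0, seeds["eval"] + 4, window=window
        )
        dev = am.deviation_angles(x1, x2, x1p)
        records.append(
            MetricsRecord(**base, metric="deviation_angle_deg", value=dev.summary)
        )
    if spec.n_movements >= 3:
        model = geo.fit_manifold(pre_pool, k=k)
        trajs = [
            _trial_averaged_latents(
                params_pre, task, model, m, seeds["eval"] + 10 + m, window=window
            )
            for m in range(spec.n_movements)
        ]
        records.append(
            MetricsRecord(
                **base, metric="congruence",
                value=am.congruence(am.input_rdm(task), am.neural_rdm(trajs)),
            )
        )
    return records


def _cell_paths(grid: ExperimentGrid, spec: CellSpec):
    stem = f"{spec.label()}-{spec.content_hash()}"
    return grid.out_dir / f"{stem}.h5", grid.out_dir / f"{stem}.json"


def run_grid(grid: ExperimentGrid, resume: bool = True) -> pd.DataFrame:
    """Run all cells (skipping completed ones) and return the tidy table."""
    grid.out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for spec in grid.cells:
        h5_path, json_path = _cell_paths(grid, spec)
        if resume and h5_path.exists() and json_path.exists():
            frames.append(pd.read_json(json_path, orient="records"))
            continue
        result = run_cell(spec)
        records = pd.DataFrame([dataclasses.asdict(r) for r in result["records"]])
        _save_cell(h5_path, result)
        records.to_json(json_path, orient="records")
        frames.append(pd.read_json(json_path, orient="records"))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(grid.out_dir / "metrics.csv", index=False)
    manifest = {
        "cells": [
            {"label": s.label(), "hash": s.content_hash(), "seed": s.seed}
            for s in grid.cells
        ],
    }
    (grid.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return table


def _save_cell(path, result: dict) -> None:
    with h5py.File(path, "w") as f:
        for tag in ("params_pre", "params_post"):
            if tag in result:
                grp = f.create_group(tag)
                for name in ("J", "B", "W"):
                    grp.create_dataset(name, data=getattr(result[tag], name))
        for tag in ("de_novo_curve", "adaptation_curve"):
            if tag in result:
                f.create_dataset(tag, data=result[tag].loss)
        f.attrs["label"] = result["spec"].label()


def bootstrap_ci(
    values: np.ndarray,
    n_resamples: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    statistic=np.mean,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of a statistic over seeds."""
    values = np.asarray(values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    boots = statistic(values[idx], axis=1)
    lo = (1 - ci) / 2
    return float(np.quantile(boots, lo)), float(np.quantile(boots, 1 - lo))


def paired_wilcoxon(a, b, alternative: str = "greater"):
    """One-sided Wilcoxon signed-rank test on seed-paired samples."""
    return stats.wilcoxon(a, b, alternative=alternative)


def paired_ttest(a, b, alternative: str = "two-sided"):
    return stats.ttest_rel(a, b, alternative=alternative)


def summarize(
    records: pd.DataFrame,
    metric: str,
    group_cols=("encoding", "n_movements"),
    ci_seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean/median with bootstrap CIs for one metric."""
    sub = records[records["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    rows = []
    for key, grp in sub.groupby(list(group_cols)):
        vals = grp["value"].to_numpy()
        lo, hi = bootstrap_ci(vals, seed=ci_seed)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_cols, key))
            | {
                "metric": metric,
                "n": len(vals),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)
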