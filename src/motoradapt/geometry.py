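"""Latent-dynamics geometry of simulated population activity.

Smoothing, PCA manifolds, trial-to-trial variance (including the
output-null / output-potent split with respect to the readout), trajectory
tangling, and noise-robustness curves. Analyses are run over a preparation
epoch (500 ms before the go cue) and an execution epoch (1000 ms after),
except output variance which uses execution only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .rnn import NetworkParams, simulate
from .tasks import TaskConfig, build_trial_batch

__all__ = [
    "LatentModel",
    "EpochSpec",
    "TanglingResult",
    "smooth_rates",
    "fit_manifold",
    "project_latents",
    "trial_variance",
    "latent_normalization_distance",
    "null_potent_variance",
    "output_subspaces",
    "tangling",
    "noise_robustness",
]


@dataclass(frozen=True)
class EpochSpec:
    """Analysis epochs relative to the go cue, in seconds."""

    prep_before_go_s: float = 0.5
    exec_after_go_s: float = 1.0

    def slices(self, go_step: int, dt_s: float, n_steps: int):
        prep = int(round(self.prep_before_go_s / dt_s))
        exe = int(round(self.exec_after_go_s / dt_s))
        if go_step - prep < 0 or go_step + exe > n_steps:
            raise ValueError("epochs extend outside the trial")
        return slice(go_step - prep, go_step), slice(go_step, go_step + exe)

    def window(self, go_step: int, dt_s: float, n_steps: int) -> slice:
        prep, exe = self.slices(go_step, dt_s, n_steps)
        return slice(prep.start, exe.stop)


@dataclass
class LatentModel:
    """A fitted linear manifold: mean, k ordered orthonormal axes, variances."""

    mean: np.ndarray  # (N,)
    components: np.ndarray  # (k, N), orthonormal rows
    variances: np.ndarray  # (k,), non-increasing
    variance_explained_fraction: float

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project (..., N) data onto the manifold axes -> (..., k)."""
        return (data - self.mean) @ self.components.T


def smooth_rates(rates: np.ndarray, kernel_std_s: float, dt_s: float) -> np.ndarray:
    """Gaussian-smooth along the time axis (axis -2 of (..., T, N) arrays).

    The kernel (std 50 ms by default usage) is truncated at +/- 4 std and
    renormalized where it overhangs the edges, so constants are preserved.
    """
    if kernel_std_s < dt_s:
        raise ValueError("kernel std must be at least one time step")
    std = kernel_std_s / dt_s
    half = int(np.ceil(4 * std))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / std) ** 2)
    kernel /= kernel.sum()
    num = convolve1d(rates, kernel, axis=-2, mode="constant", cval=0.0)
    norm = convolve1d(
        np.ones(rates.shape[-2]), kernel, mode="constant", cval=0.0
    )
    return num / norm[:, None]


def fit_manifold(samples: np.ndarray, k: int = 10) -> LatentModel:
    """PCA manifold of pooled activity samples (rows = time points x trials)."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (observations x units)")
    if samples.shape[0] < k:
        raise ValueError("fewer samples than requested components")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(samples)
    return LatentModel(
        mean=pca.mean_,
        components=pca.components_,
        variances=pca.explained_variance_,
        variance_explained_fraction=float(pca.explained_variance_ratio_.sum()),
    )


def project_latents(model: LatentModel, rates: np.ndarray) -> np.ndarray:
    return model.transform(rates)


def trial_variance(data: np.ndarray, mode: str = "median_all") -> float:
    """Across-trial variance of go-cue-aligned data (trials, time, features).

    Population variance (divide by n) per time point and feature, then
    either the median over all (time, feature) cells (``median_all``) or
    the median over time of the feature-summed total (``median_total``).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need (trials, time, features) with >= 2 trials")
    var = data.var(axis=0, ddof=0)  # (time, features)
    if mode == "median_all":
        return float(np.median(var))
    if mode == "median_total":
        return float(np.median(var.sum(axis=1)))
    raise ValueError(f"unknown mode {mode!r}")


def latent_normalization_distance(latents: np.ndarray) -> float:
    """Median step length of the trial-averaged latent trajectory.

    Used to put latent trial variance from different neural spaces on a
    common scale before comparison.
    """
    mean_traj = np.asarray(latents, dtype=np.float64).mean(axis=0)
    steps = np.linalg.norm(np.diff(mean_traj, axis=0), axis=1)
    d = float(np.median(steps))
    if d <= 0:
        raise ValueError("degenerate (constant) trial-averaged trajectory")
    return d


def output_subspaces(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases of the output-potent (row) and output-null spaces of W."""
    W = np.asarray(W, dtype=np.float64)
    if np.linalg.matrix_rank(W) < W.shape[0]:
        raise ValueError("readout matrix is rank-deficient")
    _, _, vt = np.linalg.svd(W, full_matrices=True)
    d = W.shape[0]
    return vt[:d], vt[d:]  # potent (d, N), null (N-d, N)


def null_potent_variance(
    activity: np.ndarray, W: np.ndarray, mode: str = "median_all"
) -> tuple[float, float]:
    """Trial variance of activity inside the output-potent / output-null spaces.

    Activity in the null space cannot reach the output: p = W r is blind to
    it. Under the summed-variance convention potent + null equals the total
    variance (orthogonal decomposition).
    """
    potent, null = output_subspaces(W)
    return (
        trial_variance(activity @ potent.T, mode=mode),
        trial_variance(activity @ null.T, mode=mode),
    )


@dataclass
class TanglingResult:
    """Tangling Q(t) of a trajectory, with its 90th-percentile summary."""

    q: np.ndarray
    epsilon: float

    @property
    def summary(self) -> float:
        return float(np.percentile(self.q, 90))


def tangling(signal: np.ndarray, dt_s: float) -> TanglingResult:
    """Q(t) = max_t' ||xdot_t - xdot_t'||^2 / (||x_t - x_t'||^2 + eps).

    High tangling means similar states lead to dissimilar futures, i.e.
    fragile dynamics. ``eps`` is 0.1 x the mean squared magnitude of the
    signal; derivatives are central differences (one-sided at the edges).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    xdot = np.gradient(x, dt_s, axis=0)
    eps = 0.1 * float(np.mean(np.sum(np.square(x), axis=1)))
    dnum = cdist(xdot, xdot, "sqeuclidean")
    dden = cdist(x, x, "sqeuclidean") + eps
    q = np.max(dnum / dden, axis=1)
    return TanglingResult(q=q, epsilon=eps)


def noise_robustness(
    params: NetworkParams,
    task: TaskConfig,
    noise_grid: np.ndarray | list[float],
    seeds: list[int],
    movement_id: int = 0,
    n_trials: int = 8,
) -> pd.DataFrame:
    """Test MSE of the shared movement across simulation noise levels.

    Grid values are the replacement noise std: 1.0 is five times the 0.2
    training noise. Returns a tidy frame (noise_std, seed, mse).
    """
    from .training import compute_loss

    batch = build_trial_batch(
        task, np.full(n_trials, movement_id, dtype=np.int64)
    )
    exec_slice = EpochSpec().slices(task.go_cue_step, task.dt_s, task.n_steps)[1]
    rows = []
    for sigma in noise_grid:
        for seed in seeds:
            trace = simulate(
                params, batch, seed=seed, noise_std=float(sigma), return_states=False
            )
            x_vel = np.gradient(trace.p[:, exec_slice, 0], task.dt_s, axis=1)
            rows.append(
                {
                    "noise_std": float(sigma),
                    "seed": seed,
                    "mse": compute_loss(trace.p, batch.targets.astype(np.float32)),
                    "mean_x_velocity": float(x_vel.mean()),
                }
            )
    return pd.DataFrame(rows)
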