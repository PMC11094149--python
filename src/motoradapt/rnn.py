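"""Continuous-time rate network with linear position readout.

The model is a fully connected tanh rate network

    tau dx_i/dt = -x_i + sum_j J_ij r_j + sum_k B_ik s_k + eta_i,
    r = tanh(x),  p = W r,

integrated with forward Euler at step ``dt`` (dt/tau = 0.2 by default, well
inside the stable range). Process noise eta is redrawn i.i.d. from
N(0, noise_std) per unit and time step and enters the drift unscaled, and
initial states are redrawn per trial from U(-x0_range, x0_range), which is
the model's source of trial-to-trial variability. Simulation is float32
throughout; with a fixed seed a run is bitwise reproducible on one thread.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .tasks import TaskConfig, TrialBatch, build_trial_batch

__all__ = ["NetworkParams", "NetworkTrace", "init_network", "simulate",
           "probe_intermediate", "save_params", "load_params"]


@dataclass
class NetworkParams:
    """Weights and integration constants of one network."""

    J: np.ndarray  # (N, N) recurrent
    B: np.ndarray  # (N, I) input
    W: np.ndarray  # (2, N) readout, fixed (non-plastic) by default
    g: float = 1.2
    tau: float = 0.05
    dt: float = 0.01
    noise_std: float = 0.2
    x0_range: float = 0.1

    def __post_init__(self):
        N = self.J.shape[0]
        if self.J.shape != (N, N) or self.B.shape[0] != N or self.W.shape != (2, N):
            raise ValueError("inconsistent parameter shapes")
        if not self.tau > self.dt > 0:
            raise ValueError("need tau > dt > 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.dt / self.tau >= 1:
            raise ValueError("Euler step dt/tau >= 1 is unstable")

    @property
    def n_units(self) -> int:
        return self.J.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    def copy(self) -> "NetworkParams":
        return replace(self, J=self.J.copy(), B=self.B.copy(), W=self.W.copy())


@dataclass
class NetworkTrace:
    """One simulated run: hidden states, rates, and output positions.

    x, r: (batch, T, N); p: (batch, T, 2) cm. ``p_raw`` additionally holds
    the un-transformed output when an output transform (visuomotor
    rotation) was applied, so geometry analyses can see both.
    """

    x: np.ndarray
    r: np.ndarray
    p: np.ndarray
    p_raw: np.ndarray | None = None


def init_network(
    seed: int, n_units: int = 300, n_inputs: int = 3, g: float = 1.2, **kwargs
) -> NetworkParams:
    """Draw initial weights: J ~ N(0, g/sqrt(N)), B, W ~ U(-1, 1)."""
    if n_units <= 0 or n_inputs <= 0:
        raise ValueError("n_units and n_inputs must be positive")
    rng = np.random.default_rng(seed)
    J = rng.normal(0.0, g / np.sqrt(n_units), size=(n_units, n_units))
    B = rng.uniform(-1.0, 1.0, size=(n_units, n_inputs))
    W = rng.uniform(-1.0, 1.0, size=(2, n_units))
    return NetworkParams(
        J=J.astype(np.float32),
        B=B.astype(np.float32),
        W=W.astype(np.float32),
        g=g,
        **kwargs,
    )


def simulate(
    params: NetworkParams,
    batch: TrialBatch,
    seed: int,
    noise_std: float | None = None,
    output_transform: np.ndarray | None = None,
    return_states: bool = True,
) -> NetworkTrace:
    """Forward-Euler simulation of a trial batch.

    ``noise_std`` overrides the parameter default (0 gives a repeatable
    noise-free run); ``output_transform`` is a 2x2 matrix applied to the
    output position at every step (the visuomotor rotation).
    """
    if batch.inputs.shape[2] != params.n_inputs:
        raise ValueError(
            f"batch has {batch.inputs.shape[2]} input channels, "
            f"network expects {params.n_inputs}"
        )
    sigma = params.noise_std if noise_std is None else float(noise_std)
    n_trials, T, _ = batch.inputs.shape
    N = params.n_units
    alpha = np.float32(params.dt / params.tau)
    rng = np.random.default_rng(seed)

    J = params.J.astype(np.float32, copy=False)
    B = params.B.astype(np.float32, copy=False)
    W = params.W.astype(np.float32, copy=False)
    s = batch.inputs.astype(np.float32, copy=False)

    x = rng.uniform(-params.x0_range, params.x0_range, size=(n_trials, N)).astype(
        np.float32
    )
    xs = np.empty((n_trials, T, N), dtype=np.float32) if return_states else None
    rs = np.empty((n_trials, T, N), dtype=np.float32)
    feed = s @ B.T  # (n_trials, T, N) precomputed input drive
    for t in range(T):
        if return_states:
            xs[:, t] = x
        r = np.tanh(x)
        rs[:, t] = r
        drive = r @ J.T + feed[:, t]
        if sigma > 0:
            drive += sigma * rng.standard_normal((n_trials, N), dtype=np.float32)
        x = x + alpha * (drive - x)
    p_raw = rs @ W.T
    if output_transform is not None:
        p = p_raw @ np.asarray(output_transform, dtype=np.float32).T
        return NetworkTrace(x=xs, r=rs, p=p, p_raw=p_raw)
    return NetworkTrace(x=xs, r=rs, p=p_raw, p_raw=p_raw)


def probe_intermediate(
    params: NetworkParams,
    config: TaskConfig,
    angle_deg: float | None = None,
    sine_amp: float | None = None,
    n_trials: int = 10,
    seed: int = 0,
    noise_std: float | None = None,
) -> NetworkTrace:
    """Simulate a cue the network was never trained on (no training occurs).

    Only continuous encodings extrapolate: the angular reach encoding
    accepts any angle and the ellipse sine channel any amplitude. A
    categorical (one-hot) encoding has no defined input for an unseen cue.
    """
    from dataclasses import replace as dc_replace

    from .tasks import MovementSpec

    if config.task_kind == "center_out":
        if config.encoding != "angular":
            raise ValueError("categorical encoding cannot express an unseen cue")
        probe = MovementSpec(cue_index=0, angle_deg=angle_deg)
    else:
        if sine_amp is None:
            raise ValueError("ellipse probe needs sine_amp")
        shared = config.movements[0]
        probe = MovementSpec(
            cue_index=shared.cue_index, sine_amp=sine_amp, cosine_amp=shared.cosine_amp
        )
    probe_config = dc_replace(config, movements=(probe,))
    batch = build_trial_batch(probe_config, np.zeros(n_trials, dtype=int))
    return simulate(params, batch, seed=seed, noise_std=noise_std)


def save_params(path, params: NetworkParams, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for name in ("J", "B", "W"):
            grp.create_dataset(name, data=getattr(params, name))
        for name in ("g", "tau", "dt", "noise_std", "x0_range"):
            grp.attrs[name] = getattr(params, name)
        for key, val in (meta or {}).items():
            f.attrs[key] = val


def load_params(path) -> NetworkParams:
    with h5py.File(path, "r") as f:
        grp = f["params"]
        return NetworkParams(
            J=grp["J"][()],
            B=grp["B"][()],
            W=grp["W"][()],
            **{k: float(grp.attrs[k]) for k in ("g", "tau", "dt", "noise_std", "x0_range")},
        )
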