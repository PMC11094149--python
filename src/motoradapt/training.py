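"""Two-stage gradient training of the rate network.

Stage 1 ("de novo") learns a movement repertoire from random weights with
Adam (lr 1e-4); stage 2 ("adaptation") counteracts a perturbation on the
single shared movement with plain SGD (lr 5e-3), modelling fast short-term
learning on top of a consolidated skill. Unless overridden, only J and B
are plastic; the readout W stays fixed.

The objective is

    L_R = L + R_W + R_R,

where L is the mean squared output error, skipping the first 50 of the
T = 400 steps so the dynamics can relax, normalized by 1/(2 B (T-50)):

    L = 1/(2 B (T-50)) sum_{b,t>=50,d} (p_target - p_output)^2 ;

R_R = beta/(B T N) sum r^2 penalizes firing rates over *all* T steps; and
R_W = alpha (||J|| + ||B|| + ||W||) penalizes weights with the plain
(unsquared) Frobenius norm. The squared-norm variant conventionally meant
by "L2 regularization" is available via ``reg_squared_norm``. The loss
reported in curves is L alone, before regularization.

Gradients are computed by backpropagation through time through the Euler
update, the global gradient norm over plastic matrices is clipped at 0.2,
and one optimizer update is made per training trial index (n_trials
updates of batch 64). All arithmetic is float32; runs are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rnn import NetworkParams, simulate
from .tasks import Perturbation, TaskConfig, TrialBatch, apply_perturbation, build_trial_batch

__all__ = [
    "TrainConfig",
    "LossCurve",
    "TrainingDiverged",
    "compute_loss",
    "compute_regularizers",
    "train_stage",
    "evaluate",
    "smooth_loss_curve",
    "de_novo_config",
    "adaptation_config",
    "ADAPTATION_N_TRIALS",
]

#: Adaptation lengths (optimizer updates) per perturbation, reach / ellipse.
ADAPTATION_N_TRIALS = {
    ("center_out", "vr"): 100,
    ("center_out", "reassociation"): 300,
    ("ellipse", "sine_amp"): 100,
    ("ellipse", "cos_amp"): 100,
    ("ellipse", "reassociation"): 400,
}


class TrainingDiverged(RuntimeError):
    """Raised when the loss goes non-finite; carries a diagnostic snapshot."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class TrainConfig:
    stage: str = "de_novo"  # "de_novo" | "adaptation"
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 64
    n_trials: int = 750  # optimizer updates
    grad_clip_norm: float = 0.2
    reg_alpha: float = 0.001
    reg_beta: float = 0.5
    reg_squared_norm: bool = False
    plastic: tuple[str, ...] = ("J", "B")
    loss_skip_steps: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not set(self.plastic) <= {"J", "B", "W"}:
            raise ValueError("plastic must be a subset of {J, B, W}")


def de_novo_config(seed: int = 0, n_trials: int = 750, **kwargs) -> TrainConfig:
    return TrainConfig(
        stage="de_novo", optimizer="adam", learning_rate=1e-4,
        n_trials=n_trials, seed=seed, **kwargs,
    )


def adaptation_config(
    task_kind: str, pert_kind: str, seed: int = 0, n_trials: int | None = None, **kwargs
) -> TrainConfig:
    if n_trials is None:
        n_trials = ADAPTATION_N_TRIALS[(task_kind, pert_kind)]
    return TrainConfig(
        stage="adaptation", optimizer="sgd", learning_rate=5e-3,
        n_trials=n_trials, seed=seed, **kwargs,
    )


@dataclass
class LossCurve:
    """Per-update pre-regularization loss, with its 5-trial smoothed form."""

    loss: np.ndarray
    grad_norms: np.ndarray | None = None

    @property
    def smoothed(self) -> np.ndarray:
        return smooth_loss_curve(self.loss)


def smooth_loss_curve(loss: np.ndarray, window: int = 5) -> np.ndarray:
    """Backward moving average: entry n averages entries max(0, n-w+1)..n."""
    loss = np.asarray(loss, dtype=float)
    out = np.empty_like(loss)
    csum = np.concatenate([[0.0], np.cumsum(loss)])
    for n in range(len(loss)):
        lo = max(0, n - window + 1)
        out[n] = (csum[n + 1] - csum[lo]) / (n + 1 - lo)
    return out


def compute_loss(
    p_output: np.ndarray,
    p_target: np.ndarray,
    skip_steps: int = 50,
    batch_size: int | None = None,
) -> float:
    """Mean squared output error over kept steps: 1/(2B(T-s)) sum (dp)^2."""
    if p_output.shape != p_target.shape:
        raise ValueError("output/target shape mismatch")
    B, T, _ = p_output.shape
    if skip_steps >= T:
        raise ValueError("skip_steps must be < T")
    if batch_size is None:
        batch_size = B
    diff = p_output[:, skip_steps:] - p_target[:, skip_steps:]
    return float(np.sum(np.square(diff)) / (2.0 * batch_size * (T - skip_steps)))


def compute_regularizers(
    rates: np.ndarray,
    params: NetworkParams,
    alpha: float = 0.001,
    beta: float = 0.5,
    squared_norm: bool = False,
) -> tuple[float, float]:
    """(R_R, R_W): rate penalty over all steps, weight-norm penalty."""
    B, T, N = rates.shape
    r_r = beta / (B * T * N) * float(np.sum(np.square(rates)))
    if squared_norm:
        r_w = alpha * sum(
            float(np.sum(np.square(m))) for m in (params.J, params.B, params.W)
        )
    else:
        r_w = alpha * sum(
            float(np.linalg.norm(m)) for m in (params.J, params.B, params.W)
        )
    return r_r, r_w


def _forward_backward(
    params: NetworkParams,
    batch: TrialBatch,
    cfg: TrainConfig,
    rng: np.random.Generator,
    output_transform: np.ndarray | None,
):
    """One batch: simulate, then BPTT gradients of L_R w.r.t. J, B, W.

    Returns (loss L, gradients dict). The backward pass propagates

        g_t = (1 - r_t^2) o (e_t + alpha J^T g_{t+1}) + (1 - alpha) g_{t+1}

    where e_t collects the readout error (through W and the optional
    output rotation) and the rate-regularizer pull, and accumulates
    dJ = alpha sum_t g_{t+1}^T r_t (and likewise for B with the inputs).
    """
    J = params.J
    Bmat = params.B
    W = params.W
    s = batch.inputs.astype(np.float32, copy=False)
    targets = batch.targets.astype(np.float32, copy=False)
    n_tr, T, _ = s.shape
    N = params.n_units
    alpha = np.float32(params.dt / params.tau)
    sigma = params.noise_std
    skip = cfg.loss_skip_steps

    # forward
    x = rng.uniform(-params.x0_range, params.x0_range, size=(n_tr, N)).astype(
        np.float32
    )
    rs = np.empty((n_tr, T, N), dtype=np.float32)
    feed = s @ Bmat.T
    for t in range(T):
        r = np.tanh(x)
        rs[:, t] = r
        drive = r @ J.T + feed[:, t]
        if sigma > 0:
            drive += sigma * rng.standard_normal((n_tr, N), dtype=np.float32)
        x = x + alpha * (drive - x)

    p_raw = rs @ W.T
    p = p_raw if output_transform is None else p_raw @ output_transform.T.astype(np.float32)
    loss = compute_loss(p, targets, skip_steps=skip)
    if not np.isfinite(loss):
        raise TrainingDiverged(
            "non-finite loss during training",
            {"p": p, "rates": rs, "params": params},
        )

    # readout-error signal dL/dp, mapped back through the rotation if any
    dL_dp = np.zeros_like(p)
    dL_dp[:, skip:] = (p[:, skip:] - targets[:, skip:]) / np.float32(
        n_tr * (T - skip)
    )
    if output_transform is not None:
        dL_dp = dL_dp @ output_transform.astype(np.float32)

    c_rate = np.float32(2.0 * cfg.reg_beta / (n_tr * T * N))
    e = dL_dp @ W + c_rate * rs  # (n_tr, T, N): dL_R/dr_t, local terms

    dJ = np.zeros_like(J)
    dB = np.zeros_like(Bmat)
    g_next = np.zeros((n_tr, N), dtype=np.float32)  # dL_R/dx_{t+1}
    one_minus_alpha = np.float32(1.0 - alpha)
    for t in range(T - 1, -1, -1):
        r_t = rs[:, t]
        back = e[:, t]
        if t < T - 1:
            back = back + alpha * (g_next @ J)
        g_t = (1.0 - np.square(r_t)) * back + one_minus_alpha * g_next
        if t > 0:
            # accumulate dJ/dB contributions of the t-1 -> t transition
            dJ += g_t.T @ rs[:, t - 1]
            dB += g_t.T @ s[:, t - 1]
        g_next = g_t
    dJ *= alpha
    dB *= alpha

    grads = {"J": dJ, "B": dB}
    if "W" in cfg.plastic:
        dW = np.einsum("btd,btn->dn", dL_dp, rs, optimize=True)
        grads["W"] = dW

    # weight-regularizer gradients on plastic matrices
    mats = {"J": J, "B": Bmat, "W": W}
    for name in cfg.plastic:
        m = mats[name]
        if cfg.reg_squared_norm:
            grads[name] = grads.setdefault(name, np.zeros_like(m)) + np.float32(
                2.0 * cfg.reg_alpha
            ) * m
        else:
            nrm = float(np.linalg.norm(m))
            if nrm > 0:
                grads[name] = grads.setdefault(name, np.zeros_like(m)) + (
                    np.float32(cfg.reg_alpha / nrm) * m
                )
    return loss, grads


def _clip_gradients(grads: dict, max_norm: float) -> float:
    total = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads.values()))
    if total > max_norm > 0:
        scale = np.float32(max_norm / total)
        for g in grads.values():
            g *= scale
    return total


class _Adam:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: NetworkParams, grads: dict) -> None:
        cfg = self.cfg
        self.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * np.square(g)
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            mat = getattr(params, name)
            mat -= (cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)).astype(
                mat.dtype
            )


class _SGD:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg

    def step(self, params: NetworkParams, grads: dict) -> None:
        for name, g in grads.items():
            mat = getattr(params, name)
            mat -= (self.cfg.learning_rate * g).astype(mat.dtype)


def _balanced_movement_ids(
    n_movements: int, batch_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Equal trial counts per movement within a batch (shuffled)."""
    ids = np.resize(np.arange(n_movements), batch_size)
    rng.shuffle(ids)
    return ids


def train_stage(
    params: NetworkParams,
    task: TaskConfig,
    cfg: TrainConfig,
    perturbation: Perturbation | None = None,
) -> tuple[NetworkParams, LossCurve]:
    """Run one training stage and return (trained params, loss curve).

    De novo training samples all repertoire movements with equal counts per
    batch; adaptation training presents only the perturbation's trained
    movements (the shared movement by default) under the perturbed mapping.
    ``params`` is not modified; a trained copy is returned.
    """
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    if cfg.stage == "adaptation":
        if perturbation is None:
            raise ValueError("adaptation stage needs a perturbation")
        trained = perturbation.trained_movements
        if trained is None:
            trained = (
                tuple(range(len(task.movements)))
                if perturbation.kind == "reassociation"
                else (0,)
            )
        pool = np.asarray(trained, dtype=np.int64)
    else:
        pool = np.arange(len(task.movements), dtype=np.int64)

    opt = _Adam(cfg) if cfg.optimizer == "adam" else _SGD(cfg)
    losses = np.empty(cfg.n_trials)
    grad_norms = np.empty(cfg.n_trials)
    for k in range(cfg.n_trials):
        ids = pool[_balanced_movement_ids(len(pool), cfg.batch_size, rng)]
        batch = build_trial_batch(task, ids)
        transform = None
        if perturbation is not None and perturbation.kind != "none":
            batch, transform = apply_perturbation(task, batch, perturbation)
        loss, grads = _forward_backward(params, batch, cfg, rng, transform)
        losses[k] = loss
        grads = {name: grads[name] for name in cfg.plastic if name in grads}
        grad_norms[k] = _clip_gradients(grads, cfg.grad_clip_norm)
        if grads:
            opt.step(params, grads)
    return params, LossCurve(loss=losses, grad_norms=grad_norms)


def evaluate(
    params: NetworkParams,
    task: TaskConfig,
    n_eval_trials: int = 8,
    noise_std: float | None = None,
    seed: int = 0,
    perturbation: Perturbation | None = None,
) -> dict[int, float]:
    """Per-movement test loss (no learning). Keys are movement indices."""
    out: dict[int, float] = {}
    for mid in range(len(task.movements)):
        batch = build_trial_batch(task, np.full(n_eval_trials, mid, dtype=np.int64))
        transform = None
        if perturbation is not None and perturbation.kind != "none":
            batch, transform = apply_perturbation(task, batch, perturbation)
        trace = simulate(
            params,
            batch,
            seed=seed + mid,
            noise_std=noise_std,
            output_transform=transform,
            return_states=False,
        )
        out[mid] = compute_loss(trace.p, batch.targets.astype(np.float32))
    return out
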