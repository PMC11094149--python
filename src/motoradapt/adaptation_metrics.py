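"""Metrics that quantify how a network adapted to a perturbation.

Manifold overlap between activity before and after adaptation, relative
recurrent-weight change, deviation angles between the adaptation shift and
the pre-existing inter-movement structure, input/neural representational
dissimilarity matrices (RDMs) with their Pearson congruence, and
exponential decay-constant fits to adaptation loss curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .geometry import fit_manifold
from .tasks import TaskConfig
from .training import smooth_loss_curve

__all__ = [
    "RDM",
    "AdaptationVectors",
    "DecayFit",
    "manifold_overlap",
    "relative_weight_change",
    "deviation_angles",
    "input_rdm",
    "neural_rdm",
    "congruence",
    "fit_decay_constant",
]


def manifold_overlap(
    activity_before: np.ndarray, activity_after: np.ndarray, k: int = 10
) -> tuple[float, float, float]:
    """Overlap ratio beta2/beta1 between two activity sets.

    V1 holds the top-``k`` principal axes of ``activity_before``; beta_i is
    the fraction of set i's covariance trace captured by V1:

        beta_i = Tr(V1 C_i V1^T) / Tr(C_i).

    beta1 is the variance the manifold explains of its own data, beta2 the
    variance of the post-adaptation activity explained by the
    pre-adaptation manifold. Returns (ratio, beta1, beta2).
    """
    a1 = np.asarray(activity_before, dtype=np.float64)
    a2 = np.asarray(activity_after, dtype=np.float64)
    c1 = np.cov(a1, rowvar=False)
    c2 = np.cov(a2, rowvar=False)
    if np.trace(c1) <= 0 or np.trace(c2) <= 0:
        raise ValueError("zero-variance activity")
    v1 = fit_manifold(a1, k=k).components
    beta1 = float(np.trace(v1 @ c1 @ v1.T) / np.trace(c1))
    beta2 = float(np.trace(v1 @ c2 @ v1.T) / np.trace(c2))
    return beta2 / beta1, beta1, beta2


def relative_weight_change(
    j_before: np.ndarray, j_after: np.ndarray
) -> tuple[float, int]:
    """Median over entries of |(J_after - J_before) / J_before|.

    Exact zeros in J_before are excluded (their relative change is
    undefined); the count of excluded entries is returned alongside.
    """
    j_before = np.asarray(j_before, dtype=np.float64)
    j_after = np.asarray(j_after, dtype=np.float64)
    if j_before.shape != j_after.shape:
        raise ValueError("shape mismatch")
    mask = j_before != 0
    n_excluded = int(j_before.size - mask.sum())
    rel = np.abs((j_after[mask] - j_before[mask]) / j_before[mask])
    return float(np.median(rel)), n_excluded


@dataclass
class AdaptationVectors:
    """Per-time adjacent-movement and adaptation vectors with their angle.

    v_adj(t) points from the trained movement's pre-adaptation latent
    trajectory toward the adjacent movement's; v_adp(t) is the shift of the
    trained movement's trajectory produced by adaptation. Both live in the
    pre-adaptation latent space. Small deviation angles mean adaptation
    moved the activity along the existing inter-movement structure.
    """

    v_adj: np.ndarray  # (T, k)
    v_adp: np.ndarray  # (T, k)
    angles_deg: np.ndarray  # (T_kept,)
    n_dropped: int

    @property
    def summary(self) -> float:
        return float(np.median(self.angles_deg))


def deviation_angles(
    latents_m1_pre: np.ndarray,
    latents_m2_pre: np.ndarray,
    latents_m1_post: np.ndarray,
) -> AdaptationVectors:
    """Angle between the adaptation vector and the adjacent-movement vector.

    All three trajectories are (T, k) trial averages projected on the
    pre-adaptation manifold and aligned on the go cue. Time points where
    either vector vanishes are dropped.
    """
    x1 = np.asarray(latents_m1_pre, dtype=np.float64)
    x2 = np.asarray(latents_m2_pre, dtype=np.float64)
    x1p = np.asarray(latents_m1_post, dtype=np.float64)
    if not x1.shape == x2.shape == x1p.shape:
        raise ValueError("trajectories must share (T, k) shape")
    v_adj = x2 - x1
    v_adp = x1p - x1
    n_adj = np.linalg.norm(v_adj, axis=1)
    n_adp = np.linalg.norm(v_adp, axis=1)
    keep = (n_adj > 0) & (n_adp > 0)
    cosang = np.sum(v_adj[keep] * v_adp[keep], axis=1) / (n_adj[keep] * n_adp[keep])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return AdaptationVectors(
        v_adj=v_adj,
        v_adp=v_adp,
        angles_deg=angles,
        n_dropped=int((~keep).sum()),
    )


@dataclass
class RDM:
    """Movement-pair dissimilarity matrix (symmetric, zero diagonal)."""

    values: np.ndarray
    kind: str  # "input_cosine" | "neural_distance"
    movement_ids: tuple[int, ...]

    def upper_triangle(self) -> np.ndarray:
        n = self.values.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


def input_rdm(config: TaskConfig) -> RDM:
    """Cosine dissimilarity (1 - cos) between target-signal cue vectors.

    Only the target channels enter; the hold channel is shared by all
    movements and excluded.
    """
    vecs = np.stack([config.cue_vector(m) for m in config.movements])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero cue vector")
    d = squareform(pdist(vecs, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return RDM(
        values=d,
        kind="input_cosine",
        movement_ids=tuple(range(len(config.movements))),
    )


def neural_rdm(latents_per_movement: list[np.ndarray]) -> RDM:
    """Normalized median latent distance between movement trajectories.

    Raw entry: D = med_t ||x_i(t) - x_j(t)|| over corresponding time
    points. To compare across neural spaces, D is divided by the median
    within-trajectory step ||x_m(t) - x_m(t-1)|| pooled over all
    movements.
    """
    trajs = [np.asarray(x, dtype=np.float64) for x in latents_per_movement]
    if any(x.shape[0] < 2 for x in trajs):
        raise ValueError("trajectories need at least 2 time points")
    steps = np.concatenate(
        [np.linalg.norm(np.diff(x, axis=0), axis=1) for x in trajs]
    )
    denom = float(np.median(steps))
    if denom <= 0:
        raise ValueError("degenerate trajectories (no movement in latent space)")
    n = len(trajs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.median(np.linalg.norm(trajs[i] - trajs[j], axis=1)))
            d[i, j] = d[j, i] = dist / denom
    return RDM(values=d, kind="neural_distance", movement_ids=tuple(range(n)))


def congruence(rdm_a: RDM, rdm_b: RDM) -> float:
    """Pearson r between the upper triangles of two RDMs.

    Needs >= 3 movements (3 upper-triangle entries); with 2 movements the
    correlation of a single pair is undefined.
    """
    ua, ub = rdm_a.upper_triangle(), rdm_b.upper_triangle()
    if ua.shape != ub.shape:
        raise ValueError("RDMs cover different numbers of movements")
    if ua.size < 3:
        raise ValueError("congruence undefined for fewer than 3 movements")
    return float(pearsonr(ua, ub).statistic)


@dataclass
class DecayFit:
    """Exponential fit L(n) = a exp(-n / tau) + c to a loss curve."""

    amplitude: float
    tau_trials: float
    offset: float
    residual: float
    success: bool


def fit_decay_constant(
    loss_curve: np.ndarray, smooth: bool = True, max_tau_factor: float = 10.0
) -> DecayFit:
    """Nonlinear least-squares decay-constant fit to an adaptation curve.

    The curve is first smoothed with the 5-trial backward moving average
    (as for reported loss curves). Fits that fail to converge, hit a
    non-positive tau, or exceed ``max_tau_factor`` times the curve length
    are flagged unsuccessful and should be excluded from summaries.
    """
    y = np.asarray(loss_curve, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("loss curve contains non-finite values")
    if smooth:
        y = smooth_loss_curve(y)
    n = np.arange(len(y), dtype=np.float64)
    if np.ptp(y) <= 1e-12:  # constant curve: no decay to fit
        return DecayFit(0.0, np.nan, float(y[0]), 0.0, success=False)

    def model(n, a, tau, c):
        return a * np.exp(-n / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model,
            n,
            y,
            p0=[max(y[0] - y[-1], 1e-6), max(len(y) / 5.0, 1.0), y[-1]],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return DecayFit(np.nan, np.nan, np.nan, np.nan, success=False)
    a, tau, c = popt
    resid = float(np.sqrt(np.mean((model(n, *popt) - y) ** 2)))
    ok = np.isfinite(tau) and 0 < tau <= max_tau_factor * len(y) and a > 0
    return DecayFit(float(a), float(tau), float(c), resid, success=bool(ok))
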