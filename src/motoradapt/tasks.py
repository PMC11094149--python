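"""Synthetic motor tasks: center-out reaches and sinusoidal ellipses.

Builds the trial batches (network inputs + target outputs) used for both
stages of training, and the perturbations applied during adaptation
(visuomotor rotation, cue-target reassociation, amplitude changes).

Conventions: positions in cm, angles in degrees externally (radians
internally, counterclockwise from +x), times in seconds, workspace origin
at the center of the reach circle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

__all__ = [
    "MovementSpec",
    "TaskConfig",
    "TrialBatch",
    "Perturbation",
    "make_reach_trajectory",
    "make_ellipse_trajectory",
    "build_trial_batch",
    "apply_vr",
    "rotation_matrix",
    "apply_perturbation",
    "center_out_config",
    "ellipse_config",
    "save_batch",
    "load_batch",
]

#: Hold-channel magnitude before the go cue and cue-channel magnitude.
CUE_MAGNITUDE = 2.0


@dataclass(frozen=True)
class MovementSpec:
    """One movement of a repertoire.

    For center-out reaches ``angle_deg`` is the reach direction; for
    ellipses ``sine_amp`` / ``cosine_amp`` are the y/x amplitudes in cm.
    ``cue_index`` is the slot used for one-hot (categorical) encodings.
    """

    cue_index: int
    angle_deg: float | None = None
    sine_amp: float | None = None
    cosine_amp: float | None = None


@dataclass(frozen=True)
class TaskConfig:
    """Trial structure and repertoire for one task.

    ``encoding`` is ``"angular"`` or ``"categorical"`` for center-out
    reaches; the ellipse task uses a fixed mixed encoding (continuous sine
    amplitude channel + one-hot cosine channel) named ``"mixed"``.
    """

    task_kind: str  # "center_out" | "ellipse"
    movements: tuple[MovementSpec, ...]
    encoding: str = "angular"
    trial_duration_s: float = 4.0
    dt_s: float = 0.01
    reach_length_cm: float = 8.0
    a_max_cm: float = 7.0
    n_cycles: int = 3
    movement_duration_s: float = 1.0
    target_cue_s: float = 1.75
    go_cue_s: float = 2.75
    n_onehot: int = 4  # width of the one-hot block for categorical/mixed

    def __post_init__(self):
        n_steps = self.trial_duration_s / self.dt_s
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("trial_duration_s must be a multiple of dt_s")
        if not (0 < self.target_cue_s < self.go_cue_s):
            raise ValueError("need 0 < target cue < go cue")
        if self.go_cue_s + self.movement_duration_s > self.trial_duration_s:
            raise ValueError("movement must end within the trial")
        if not 1 <= len(self.movements) <= 4:
            raise ValueError("repertoire size must be 1-4")
        # movements must be distinguishable by their cue vectors; for the
        # varied-sine ellipse repertoire the one-hot slot is legitimately
        # shared (the continuous sine channel disambiguates)
        cues = [tuple(np.round(self.cue_vector(m), 12)) for m in self.movements]
        if len(set(cues)) != len(cues):
            raise ValueError("cue vectors must be unique within a repertoire")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration_s / self.dt_s))

    @property
    def target_cue_step(self) -> int:
        return int(round(self.target_cue_s / self.dt_s))

    @property
    def go_cue_step(self) -> int:
        return int(round(self.go_cue_s / self.dt_s))

    @property
    def n_inputs(self) -> int:
        if self.task_kind == "ellipse":
            return 2 + self.n_onehot  # hold + sine amp + one-hot cosine
        if self.encoding == "angular":
            return 3  # hold + (cos, sin)
        if self.encoding == "categorical":
            return 1 + self.n_onehot
        raise ValueError(f"unknown encoding {self.encoding!r}")

    def cue_vector(self, movement: MovementSpec) -> np.ndarray:
        """Target-signal channels (hold channel excluded) for a movement."""
        if self.task_kind == "ellipse":
            v = np.zeros(1 + self.n_onehot)
            v[0] = CUE_MAGNITUDE * movement.sine_amp / self.a_max_cm
            v[1 + movement.cue_index] = CUE_MAGNITUDE
            return v
        if self.encoding == "angular":
            th = np.deg2rad(movement.angle_deg)
            return CUE_MAGNITUDE * np.array([np.cos(th), np.sin(th)])
        v = np.zeros(self.n_onehot)
        v[movement.cue_index] = CUE_MAGNITUDE
        return v


def center_out_config(
    n_movements: int,
    encoding: str = "angular",
    arc_deg: tuple[float, float] = (-10.0, -50.0),
    **kwargs,
) -> TaskConfig:
    """Center-out repertoire of ``n_movements`` reaches equally spaced on an arc.

    The first movement (the one every repertoire shares) sits at the start
    of the arc, -10 degrees by default.
    """
    if n_movements == 1:
        angles = [arc_deg[0]]
    else:
        angles = list(np.linspace(arc_deg[0], arc_deg[1], n_movements))
    moves = tuple(
        MovementSpec(cue_index=i, angle_deg=a) for i, a in enumerate(angles)
    )
    return TaskConfig(
        task_kind="center_out",
        movements=moves,
        encoding=encoding,
        movement_duration_s=1.0,
        **kwargs,
    )


def ellipse_config(
    n_movements: int,
    varied: str = "sine",
    amp_range_cm: tuple[float, float] = (1.0, 7.0),
    **kwargs,
) -> TaskConfig:
    """Ellipse repertoire with sine or cosine amplitudes spanning ``amp_range_cm``.

    ``varied="sine"`` varies the sine-wave (y) amplitude with a constant
    1 cm cosine wave; ``varied="cosine"`` the reverse. The shared movement
    (both amplitudes 1 cm) is always first. Target cue fixed at 0.8 s and
    go cue at 1.3 s.
    """
    if n_movements == 1:
        amps = [amp_range_cm[0]]
    else:
        amps = list(np.linspace(amp_range_cm[0], amp_range_cm[1], n_movements))
    moves = []
    for i, a in enumerate(amps):
        if varied == "sine":
            moves.append(MovementSpec(cue_index=0, sine_amp=a, cosine_amp=1.0))
        elif varied == "cosine":
            moves.append(MovementSpec(cue_index=i, sine_amp=1.0, cosine_amp=a))
        else:
            raise ValueError("varied must be 'sine' or 'cosine'")
    kwargs.setdefault("target_cue_s", 0.8)
    kwargs.setdefault("go_cue_s", 1.3)
    return TaskConfig(
        task_kind="ellipse",
        movements=tuple(moves),
        encoding="mixed",
        movement_duration_s=2.0,
        **kwargs,
    )


@dataclass
class TrialBatch:
    """Inputs and target outputs for a batch of trials.

    inputs: (batch, T, I); targets: (batch, T, 2) in cm;
    movement_id: (batch,) repertoire index of the *cued* movement;
    target_id: (batch,) repertoire index of the movement the target output
    traces (differs from movement_id only under reassociation);
    cue_steps: (target_cue_step, go_cue_step), shared across trials.
    """

    inputs: np.ndarray
    targets: np.ndarray
    movement_id: np.ndarray
    cue_steps: tuple[int, int]
    target_id: np.ndarray | None = None

    def __post_init__(self):
        if self.target_id is None:
            self.target_id = self.movement_id.copy()

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[1]


@dataclass(frozen=True)
class Perturbation:
    """Declarative description of an adaptation perturbation.

    kind: "vr" (counterclockwise rotation of the produced output by
    ``theta_r_deg``), "reassociation" (``cue_permutation[i]`` is the
    movement now required when cue ``i`` is shown), "sine_amp"/"cos_amp"
    (the shared ellipse movement must be produced with ``new_amplitude``),
    or "none".
    """

    kind: str = "none"
    theta_r_deg: float = 0.0
    cue_permutation: tuple[int, ...] | None = None
    new_amplitude: float = 2.0
    trained_movements: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("vr", "reassociation", "sine_amp", "cos_amp", "none"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "reassociation":
            p = self.cue_permutation
            if p is None or sorted(p) != list(range(len(p))):
                raise ValueError("cue_permutation must be a bijection over cues")


def make_reach_trajectory(
    length_cm: float, duration_s: float = 1.0, dt_s: float = 0.01
) -> np.ndarray:
    """Sigmoid center-out reach along +x: radius l / (1 + exp(-12 t + 6)).

    Returns a (duration/dt, 2) position series in cm; the caller rotates it
    to the reach direction. The radial profile is monotone non-decreasing.
    """
    if length_cm <= 0 or dt_s <= 0:
        raise ValueError("length_cm and dt_s must be positive")
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    radius = length_cm / (1.0 + np.exp(-12.0 * t + 6.0))
    return np.column_stack([radius, np.zeros_like(radius)])


def make_ellipse_trajectory(
    cosine_amp_cm: float,
    sine_amp_cm: float,
    n_cycles: int = 3,
    duration_s: float = 2.0,
    dt_s: float = 0.01,
    a_max_cm: float = 7.0,
) -> np.ndarray:
    """x = A_c cos(2 pi n t / dur), y = A_s sin(2 pi n t / dur) over the movement."""
    for a in (cosine_amp_cm, sine_amp_cm):
        if not 0 < a <= a_max_cm:
            raise ValueError(f"amplitude {a} outside (0, {a_max_cm}]")
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    phase = 2.0 * np.pi * n_cycles * t / duration_s
    return np.column_stack(
        [cosine_amp_cm * np.cos(phase), sine_amp_cm * np.sin(phase)]
    )


def rotation_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def apply_vr(positions: np.ndarray, theta_r_deg: float) -> np.ndarray:
    """Rotate 2-D positions counterclockwise by theta_r about the origin.

    Applied to the *produced* output during visuomotor-rotation trials;
    the loss is then taken between the rotated output and the unrotated
    target, so the network must counter-rotate to succeed.
    """
    return positions @ rotation_matrix(theta_r_deg).T


def _movement_target(config: TaskConfig, movement: MovementSpec) -> np.ndarray:
    """Full-trial (T, 2) target: zero before go, trajectory, then hold."""
    T = config.n_steps
    go = config.go_cue_step
    if config.task_kind == "center_out":
        traj = make_reach_trajectory(
            config.reach_length_cm, config.movement_duration_s, config.dt_s
        )
        traj = traj @ rotation_matrix(movement.angle_deg).T
    else:
        traj = make_ellipse_trajectory(
            movement.cosine_amp,
            movement.sine_amp,
            config.n_cycles,
            config.movement_duration_s,
            config.dt_s,
            config.a_max_cm,
        )
        # movement starts from the hold position: shift the ellipse so its
        # first point is the origin (x = A_c (cos - 1)); a raw cosine would
        # demand a discontinuous jump to x = A_c at the go cue, adding an
        # irreducible loss that grows with the squared amplitude
        traj = traj - traj[0]
    target = np.zeros((T, 2))
    end = go + traj.shape[0]
    target[go:end] = traj
    target[end:] = traj[-1]  # hold final position to trial end
    return target


def _trial_inputs(config: TaskConfig, movement: MovementSpec) -> np.ndarray:
    """(T, I) input time series: hold channel + sustained target cue."""
    T = config.n_steps
    s = np.zeros((T, config.n_inputs))
    s[: config.go_cue_step, 0] = CUE_MAGNITUDE  # hold drops to 0 at go
    s[config.target_cue_step :, 1:] = config.cue_vector(movement)
    return s


def build_trial_batch(
    config: TaskConfig,
    movement_ids: np.ndarray | list[int],
    target_ids: np.ndarray | list[int] | None = None,
) -> TrialBatch:
    """Assemble a batch: inputs cue movement_ids, targets are target_ids.

    ``target_ids`` defaults to ``movement_ids``; a reassociation
    perturbation passes a permuted copy so that a known cue demands a
    different known movement.
    """
    movement_ids = np.asarray(movement_ids, dtype=np.int64)
    if movement_ids.min(initial=0) < 0 or movement_ids.max(initial=0) >= len(
        config.movements
    ):
        raise ValueError("movement_id outside the repertoire")
    if target_ids is None:
        target_ids = movement_ids
    target_ids = np.asarray(target_ids, dtype=np.int64)

    input_bank = np.stack([_trial_inputs(config, m) for m in config.movements])
    target_bank = np.stack([_movement_target(config, m) for m in config.movements])
    return TrialBatch(
        inputs=input_bank[movement_ids],
        targets=target_bank[target_ids],
        movement_id=movement_ids.copy(),
        cue_steps=(config.target_cue_step, config.go_cue_step),
        target_id=target_ids.copy(),
    )


def apply_perturbation(
    config: TaskConfig, batch: TrialBatch, pert: Perturbation
) -> tuple[TrialBatch, np.ndarray | None]:
    """Return the perturbed batch and an output transform (or None).

    - vr: batch unchanged; returns the rotation matrix applied to the
      network's output inside the simulation loop.
    - reassociation: inputs unchanged, targets remapped cue -> permuted
      movement.
    - sine_amp / cos_amp: targets of the shared movement rebuilt with the
      perturbed amplitude; cues unchanged.
    - none: identity.
    """
    if pert.kind == "none":
        return batch, None
    if pert.kind == "vr":
        return batch, rotation_matrix(pert.theta_r_deg)
    if pert.kind == "reassociation":
        perm = np.asarray(pert.cue_permutation, dtype=np.int64)
        return (
            build_trial_batch(config, batch.movement_id, perm[batch.target_id]),
            None,
        )
    # amplitude perturbations act on the shared (first) movement
    shared = config.movements[0]
    if pert.kind == "sine_amp":
        new_move = replace(shared, sine_amp=pert.new_amplitude)
    else:
        new_move = replace(shared, cosine_amp=pert.new_amplitude)
    new_target = _movement_target(config, new_move)
    targets = batch.targets.copy()
    targets[batch.target_id == 0] = new_target
    return (
        TrialBatch(
            batch.inputs,
            targets,
            batch.movement_id,
            batch.cue_steps,
            target_id=batch.target_id.copy(),
        ),
        None,
    )


def save_batch(path, batch: TrialBatch) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=batch.inputs)
        f.create_dataset("targets", data=batch.targets)
        f.create_dataset("movement_id", data=batch.movement_id)
        f.create_dataset("cue_steps", data=np.asarray(batch.cue_steps))


def load_batch(path) -> TrialBatch:
    with h5py.File(path, "r") as f:
        return TrialBatch(
            inputs=f["inputs"][()],
            targets=f["targets"][()],
            movement_id=f["movement_id"][()],
            cue_steps=tuple(int(v) for v in f["cue_steps"][()]),
        )
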