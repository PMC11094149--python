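"""Shared fixtures: a pool of trained networks reused across test modules.

Training is the expensive step, so networks are trained once per session at
a reduced scale — fewer units and updates than the full-scale defaults,
while the task structure, trial length, noise level, optimizers, and loss
are the study conditions — and shared by the geometry, adaptation, and
acceptance tests. docs/methods.md records which findings survive this
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from motoradapt import rnn, tasks, training

# reduced-scale problem sizes used throughout the suite
POOL_N_UNITS = 100
POOL_BATCH = 32
POOL_DE_NOVO_TRIALS = 300
POOL_SEEDS = (0, 1, 2)

# the oscillatory task needs more units and updates than the reaches to
# reach its de novo plateau (~0.12 smoothed loss) at reduced scale
ELLIPSE_N_UNITS = 150
ELLIPSE_DE_NOVO_TRIALS = 2500
ELLIPSE_REASSOC_TRIALS = 400
ELLIPSE_SEEDS = (0, 1)


@dataclass
class TrainedNet:
    """A de novo-trained network with its task and training curve."""

    task: tasks.TaskConfig
    params_init: rnn.NetworkParams
    params: rnn.NetworkParams
    curve: training.LossCurve
    seed: int


def _train(
    task: tasks.TaskConfig, seed: int, n_trials: int, n_units: int = POOL_N_UNITS
) -> TrainedNet:
    ss = np.random.SeedSequence(seed)
    s_init, s_train = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    params0 = rnn.init_network(s_init, n_units=n_units, n_inputs=task.n_inputs)
    params, curve = training.train_stage(
        params0,
        task,
        training.de_novo_config(
            seed=s_train, n_trials=n_trials, batch_size=POOL_BATCH
        ),
    )
    return TrainedNet(
        task=task, params_init=params0, params=params, curve=curve, seed=seed
    )


def _adapt(net: TrainedNet, pert: tasks.Perturbation, n_trials=None):
    params, curve = training.train_stage(
        net.params,
        net.task,
        training.adaptation_config(
            net.task.task_kind,
            pert.kind,
            seed=net.seed + 1000,
            n_trials=n_trials,
            batch_size=POOL_BATCH,
        ),
        perturbation=pert,
    )
    return params, curve


@pytest.fixture(scope="session")
def reach_pool():
    """Trained center-out networks: encodings x repertoire sizes x seeds."""
    pool = {}
    for enc, sizes in (("angular", (1, 2, 4)), ("categorical", (2, 4))):
        for nmov in sizes:
            for seed in POOL_SEEDS:
                task = tasks.center_out_config(nmov, enc)
                pool[(enc, nmov, seed)] = _train(
                    task, seed=seed * 17 + nmov, n_trials=POOL_DE_NOVO_TRIALS
                )
    return pool


@pytest.fixture(scope="session")
def vr_adapted_pool(reach_pool):
    """The reach pool after 10 degree visuomotor-rotation adaptation."""
    pert = tasks.Perturbation(kind="vr", theta_r_deg=10.0)
    return {key: _adapt(net, pert) for key, net in reach_pool.items()}


@pytest.fixture(scope="session")
def ellipse_pool():
    """Ellipse networks (varied sine / varied cosine) after cue
    reassociation, keyed by (varied, seed)."""
    pert = tasks.Perturbation(kind="reassociation", cue_permutation=(1, 2, 0))
    pool = {}
    for varied in ("sine", "cosine"):
        for seed in ELLIPSE_SEEDS:
            task = tasks.ellipse_config(3, varied=varied)
            net = _train(
                task,
                seed=seed * 31 + 5,
                n_trials=ELLIPSE_DE_NOVO_TRIALS,
                n_units=ELLIPSE_N_UNITS,
            )
            pool[(varied, seed)] = _adapt(
                net, pert, n_trials=ELLIPSE_REASSOC_TRIALS
            )
    return pool


@pytest.fixture(scope="session")
def adapt_fn():
    return _adapt
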