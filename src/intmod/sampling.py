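"""Replica-exchange Gibbs sampling over rigid-body poses, flexible-bead
coordinates, and nuisance parameters.

One Gibbs sweep is a cycle of Metropolis Monte Carlo steps that moves every
mobile rigid body (random translation up to 2 Å and rotation up to 0.04 rad
about a random axis through the body center) and every flexible bead
(random translation up to 3 Å) once, followed by nuisance updates for sigma
and the per-class psi values within their bounds.  Replicas at a ladder of
temperatures attempt adjacent swaps each sweep (alternating odd/even
pairs); only the coldest chain's frames enter downstream analysis.

All randomness flows from numpy SeedSequences spawned off a single seed, so
runs are bitwise reproducible and independent of scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .restraints import INTER, INTRA, NuisanceParams

__all__ = [
    "ModelState",
    "MoveParams",
    "ReplicaLadder",
    "Frame",
    "Trajectory",
    "build_movers",
    "random_rotation_matrix",
    "propose_move",
    "metropolis_accept",
    "swap_accept",
    "gibbs_sweep",
    "run_metropolis",
    "run_replica_exchange",
    "random_initial_state",
]


@dataclass
class ModelState:
    """All mobile coordinates plus nuisance parameters and cached score."""

    rot: np.ndarray  # (n_rigid, 3, 3)
    trans: np.ndarray  # (n_rigid, 3)
    flex: np.ndarray  # (n_flex, 3)
    nuisances: NuisanceParams = field(default_factory=NuisanceParams)
    score: float | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            rot=self.rot.copy(),
            trans=self.trans.copy(),
            flex=self.flex.copy(),
            nuisances=self.nuisances.copy(),
            score=self.score,
        )

    def with_nuisances(self, nuisances: NuisanceParams) -> "ModelState":
        st = self.copy()
        st.nuisances = nuisances.copy()
        return st

    @classmethod
    def reference(cls, model) -> "ModelState":
        """The state that reproduces the build-time (reference) geometry."""
        n = model.n_rigid
        rot = np.tile(np.eye(3), (n, 1, 1))
        trans = np.array([b.origin for b in model.rigid_bodies]) if n else np.zeros((0, 3))
        flex = (
            np.array([fb.center for fb in model.flex_beads])
            if model.n_flex
            else np.zeros((0, 3))
        )
        return cls(rot=rot, trans=trans, flex=flex)


@dataclass
class MoveParams:
    rigid_translation: float = 2.0  # Å
    rigid_rotation: float = 0.04  # rad
    flex_translation: float = 3.0  # Å
    sigma_step: float = 0.5  # Å
    psi_step: float = 0.02


@dataclass
class ReplicaLadder:
    """Geometric ladder of strictly increasing temperatures."""

    temperatures: np.ndarray

    def __post_init__(self):
        self.temperatures = np.atleast_1d(np.asarray(self.temperatures, dtype=float))
        if (np.diff(self.temperatures) <= 0).any():
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def geometric(cls, n_replicas: int, t_min: float = 1.0, t_max: float = 2.5):
        if n_replicas == 1:
            return cls(np.array([t_min]))
        return cls(np.geomspace(t_min, t_max, n_replicas))

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class Frame:
    sweep: int
    run: int
    rot: np.ndarray
    trans: np.ndarray
    flex: np.ndarray
    sigma: float
    psi: dict
    score: float

    def to_state(self) -> ModelState:
        return ModelState(
            rot=self.rot.copy(),
            trans=self.trans.copy(),
            flex=self.flex.copy(),
            nuisances=NuisanceParams(sigma=self.sigma, psi=dict(self.psi)),
            score=self.score,
        )


@dataclass
class Trajectory:
    run: int
    save_interval: int
    frames: list = field(default_factory=list)

    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.frames])


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------


def build_movers(model, nuisance_classes=(INTRA, INTER)) -> list:
    """Mover descriptors: one per mobile rigid body, flexible bead, and
    nuisance parameter."""
    movers = [("rb", bi) for bi in model.mobile_rigid]
    movers += [("flex", qi) for qi in range(model.n_flex)]
    movers += [("sigma", None)] + [("psi", c) for c in nuisance_classes]
    return movers


def random_rotation_matrix(rng, max_angle: float) -> np.ndarray:
    """Rotation by a uniform angle in [0, max_angle] about a uniformly
    random axis (a symmetric proposal)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def propose_move(
    state: ModelState,
    rng: np.random.Generator,
    move_params: MoveParams | None = None,
    mover=None,
    movers=None,
    bounds=None,
) -> ModelState:
    """Perturb one element of the state (symmetric proposal).

    ``mover`` selects the element; if absent, one of ``movers`` is chosen at
    random.  ``bounds`` is a dict with optional "sigma" and "psi" (lo, hi)
    clamp intervals for the nuisance moves.
    """
    mp = move_params or MoveParams()
    if mover is None:
        if not movers:
            raise ValueError("state has no mobile elements")
        mover = movers[rng.integers(len(movers))]
    new = state.copy()
    new.score = None
    kind, idx = mover
    if kind == "rb":
        dR = random_rotation_matrix(rng, mp.rigid_rotation)
        new.rot[idx] = dR @ new.rot[idx]
        new.trans[idx] = new.trans[idx] + rng.uniform(
            -mp.rigid_translation, mp.rigid_translation, size=3
        )
    elif kind == "flex":
        new.flex[idx] = new.flex[idx] + rng.uniform(
            -mp.flex_translation, mp.flex_translation, size=3
        )
    elif kind == "sigma":
        lo, hi = (bounds or {}).get("sigma", (0.0, 100.0))
        new.nuisances.sigma = float(
            np.clip(state.nuisances.sigma + rng.uniform(-mp.sigma_step, mp.sigma_step), lo, hi)
        )
    elif kind == "psi":
        lo, hi = (bounds or {}).get("psi", (0.01, 0.30))
        new.nuisances.psi[idx] = float(
            np.clip(
                state.nuisances.psi[idx] + rng.uniform(-mp.psi_step, mp.psi_step), lo, hi
            )
        )
    else:
        raise ValueError(f"unknown mover kind {kind!r}")
    return new


def metropolis_accept(delta: float, temperature: float, rng) -> bool:
    """Accept with probability min(1, exp(-delta / T))."""
    if delta <= 0:
        return True
    return rng.random() < np.exp(-delta / temperature)


def swap_accept(score_i: float, score_j: float, t_i: float, t_j: float, rng) -> bool:
    """Standard replica-exchange criterion: accept the swap with
    probability min(1, exp((1/t_i - 1/t_j) * (score_i - score_j))).
    Equal temperatures always accept."""
    log_p = (1.0 / t_i - 1.0 / t_j) * (score_i - score_j)
    if log_p >= 0:
        return True
    return rng.random() < np.exp(log_p)


def gibbs_sweep(
    state: ModelState,
    score_fn,
    temperature: float,
    rng,
    movers,
    move_params: MoveParams | None = None,
    bounds=None,
):
    """One Gibbs step: a Metropolis move of every mover, in order.

    Returns (state, n_accepted); ``state.score`` is kept current.
    """
    if state.score is None:
        state.score = float(score_fn(state))
    accepted = 0
    for mover in movers:
        cand = propose_move(state, rng, move_params, mover=mover, bounds=bounds)
        cand.score = float(score_fn(cand))
        if metropolis_accept(cand.score - state.score, temperature, rng):
            state = cand
            accepted += 1
    return state, accepted


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def random_initial_state(model, rng, box_lo, box_hi, nuisances=None) -> ModelState:
    """Random initial configuration: every mobile rigid body gets a uniform
    random orientation and a center uniform in the box; every flexible bead
    a uniform position in the box.  Fixed bodies keep their reference pose.
    """
    state = ModelState.reference(model)
    for bi in model.mobile_rigid:
        state.rot[bi] = random_rotation_matrix(rng, np.pi) @ random_rotation_matrix(rng, np.pi)
        state.trans[bi] = rng.uniform(box_lo, box_hi)
    for qi in range(model.n_flex):
        state.flex[qi] = rng.uniform(box_lo, box_hi)
    if nuisances is not None:
        state.nuisances = nuisances.copy()
    return state


def _chain_rngs(run_seed_seq, n_replicas):
    children = run_seed_seq.spawn(n_replicas + 1)
    replica_rngs = [np.random.default_rng(c) for c in children[:n_replicas]]
    swap_rng = np.random.default_rng(children[n_replicas])
    return replica_rngs, swap_rng


def run_metropolis(
    score_fn,
    init_state_fn,
    temperature: float,
    n_sweeps: int,
    movers,
    seed_seq,
    move_params: MoveParams | None = None,
    bounds=None,
    save_interval: int = 10,
    run_id: int = 0,
) -> Trajectory:
    """Plain single-chain Metropolis-within-Gibbs sampling."""
    if isinstance(seed_seq, (int, np.integer)):
        seed_seq = np.random.SeedSequence(seed_seq)
    rngs, _ = _chain_rngs(seed_seq, 1)
    rng = rngs[0]
    state = init_state_fn(rng)
    state.score = float(score_fn(state))
    traj = Trajectory(run=run_id, save_interval=save_interval)
    for sweep in range(1, n_sweeps + 1):
        state, _ = gibbs_sweep(state, score_fn, temperature, rng, movers, move_params, bounds)
        if sweep % save_interval == 0:
            traj.frames.append(_snapshot(state, sweep, run_id))
    return traj


def _snapshot(state: ModelState, sweep: int, run_id: int) -> Frame:
    return Frame(
        sweep=sweep,
        run=run_id,
        rot=state.rot.copy(),
        trans=state.trans.copy(),
        flex=state.flex.copy(),
        sigma=state.nuisances.sigma,
        psi=dict(state.nuisances.psi),
        score=state.score,
    )


def run_replica_exchange(
    score_fn,
    init_state_fn,
    ladder: ReplicaLadder,
    n_sweeps: int,
    movers,
    seed,
    n_runs: int = 1,
    move_params: MoveParams | None = None,
    bounds=None,
    save_interval: int = 10,
) -> list:
    """Replica-exchange Gibbs sampling; returns one Trajectory per run.

    Each run starts every replica from an independent random initial
    configuration (via ``init_state_fn(rng)``).  Adjacent-replica swaps are
    attempted after every sweep with the standard exchange criterion,
    alternating odd/even pairs.  Only the coldest replica is recorded.
    With a single replica this reduces exactly to plain Metropolis.
    """
    base = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    run_seqs = base.spawn(n_runs)
    trajectories = []
    temps = ladder.temperatures
    n_rep = len(temps)
    for run_id, run_seq in enumerate(run_seqs):
        rngs, swap_rng = _chain_rngs(run_seq, n_rep)
        states = []
        for rng in rngs:
            st = init_state_fn(rng)
            st.score = float(score_fn(st))
            states.append(st)
        traj = Trajectory(run=run_id, save_interval=save_interval)
        for sweep in range(1, n_sweeps + 1):
            for ri in range(n_rep):
                states[ri], _ = gibbs_sweep(
                    states[ri], score_fn, temps[ri], rngs[ri], movers, move_params, bounds
                )
            if n_rep > 1:
                start = (sweep - 1) % 2
                for i in range(start, n_rep - 1, 2):
                    if swap_accept(
                        states[i].score, states[i + 1].score, temps[i], temps[i + 1], swap_rng
                    ):
                        states[i], states[i + 1] = states[i + 1], states[i]
            if sweep % save_interval == 0:
                traj.frames.append(_snapshot(states[0], sweep, run_id))
        trajectories.append(traj)
    return trajectories
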