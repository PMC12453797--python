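"""Particle swarm optimization of MLP hyperparameters.

A particle's position encodes (hidden-layer width, input-dropout rate,
minibatch size).  Velocities follow the standard rule

    v <- alpha * v + c1*r1*(pbest - p) + c2*r2*(gbest - p)

with fresh uniform r1, r2 per dimension, clamped velocities, and positions
clamped to per-dimension bounds (the clamped dimension's velocity is zeroed).
Coefficients are either fixed (the default: inertia 0.5, c1 = c2 = 1, the
constants the experiments use) or follow quadratic-in-k schedules:

    alpha(k) = (a_max - a_min)(k/K)^2 + a_min        (increasing)
    c1(k)    = (c1_max - c1_min)(k/K)^2 + c1_min     (increasing)
    c2(k)    = (c2_min - c2_max)(k/K)^2 + c2_max     (decreasing)

``strict_paper_signs=True`` flips the two attraction terms to (p - best),
reproducing a published variant of the update verbatim for auditability; it
repels particles from their bests and is not the default.

The fitness is 1 - mean stratified inner-CV validation accuracy of an MLP
built from the decoded hyperparameters, so PSO minimizes cross-validated
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .features import LabeledDataset, normalize_features
from .mlp import TrainConfig, init_mlp, predict, train_mlp

#: Default search bounds: hidden width, dropout rate, batch size.  They
#: contain the reported optimum (78, 0.14, 95).
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((8, 128), (0.0, 0.5), (16, 128))


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = np.inf


@dataclass
class SwarmConfig:
    n_particles: int = 20
    max_iter: int = 30
    coeff_mode: str = "fixed"  # "fixed" | "scheduled"
    inertia: float = 0.5
    c1: float = 1.0
    c2: float = 1.0
    alpha_min: float = 0.4
    alpha_max: float = 0.9
    c1_min: float = 0.5
    c1_max: float = 2.5
    c2_min: float = 0.5
    c2_max: float = 2.5
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    velocity_clamp_frac: float = 0.5
    strict_paper_signs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.max_iter < 1:
            raise ValueError("n_particles and max_iter must be >= 1")
        if self.coeff_mode not in ("fixed", "scheduled"):
            raise ValueError("coeff_mode must be 'fixed' or 'scheduled'")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must have lower < upper")


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (gbest, mean)

    @property
    def gbest_history(self) -> np.ndarray:
        return np.array([h[0] for h in self.history])


def inertia_at(k: int, K: int, alpha_min: float = 0.4, alpha_max: float = 0.9) -> float:
    """Quadratic inertia schedule, alpha_min at k=0 rising to alpha_max at k=K."""
    if K == 0:
        raise ValueError("K must be positive")
    return (alpha_max - alpha_min) * (k / K) ** 2 + alpha_min


def accel_at(
    k: int,
    K: int,
    c1_min: float = 0.5,
    c1_max: float = 2.5,
    c2_min: float = 0.5,
    c2_max: float = 2.5,
) -> tuple[float, float]:
    """Acceleration schedules: c1 increasing, c2 decreasing (both quadratic)."""
    if K == 0:
        raise ValueError("K must be positive")
    c1 = (c1_max - c1_min) * (k / K) ** 2 + c1_min
    c2 = (c2_min - c2_max) * (k / K) ** 2 + c2_max
    return c1, c2


def _vmax(cfg: SwarmConfig) -> np.ndarray:
    b = np.asarray(cfg.bounds, dtype=float)
    return cfg.velocity_clamp_frac * (b[:, 1] - b[:, 0])


def step_velocity(
    p: Particle,
    gbest: np.ndarray,
    alpha: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    vmax: Optional[np.ndarray] = None,
    strict_paper_signs: bool = False,
) -> np.ndarray:
    """One velocity update with fresh per-dimension r1, r2 ~ U(0,1)."""
    r1 = rng.random(p.position.size)
    r2 = rng.random(p.position.size)
    if strict_paper_signs:
        cognitive = p.position - p.best_position
        social = p.position - gbest
    else:
        cognitive = p.best_position - p.position
        social = gbest - p.position
    v = alpha * p.velocity + c1 * r1 * cognitive + c2 * r2 * social
    if vmax is not None:
        v = np.clip(v, -vmax, vmax)
    return v


def step_position(
    p: Particle, bounds: tuple[tuple[float, float], ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Position update p + v, clamped to bounds; clamped dims get zero velocity."""
    b = np.asarray(bounds, dtype=float)
    raw = p.position + p.velocity
    pos = np.clip(raw, b[:, 0], b[:, 1])
    vel = np.where(pos != raw, 0.0, p.velocity)
    return pos, vel


def decode_position(
    position: np.ndarray, bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
) -> tuple[int, float, int]:
    """Decode a raw position into (hidden width, dropout rate, batch size).

    Integer dimensions are rounded to the nearest integer and clipped to their
    bounds; the dropout rate stays real, clipped to [0, 0.9].
    """
    b = np.asarray(bounds, dtype=float)
    hidden = int(np.clip(np.rint(position[0]), np.ceil(b[0, 0]), np.floor(b[0, 1])))
    dropout = float(np.clip(position[1], max(b[1, 0], 0.0), min(b[1, 1], 0.9)))
    batch = int(np.clip(np.rint(position[2]), np.ceil(b[2, 0]), np.floor(b[2, 1])))
    return hidden, dropout, batch


def fitness(
    position: np.ndarray,
    ds: LabeledDataset,
    inner_folds: int = 3,
    seed: int = 0,
    n_hidden_layers: int = 2,
    train_cfg: Optional[TrainConfig] = None,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
) -> float:
    """1 - mean inner-CV validation accuracy of the decoded MLP.

    Normalization is fitted on each inner training split only; when the
    dataset carries trial metadata the inner folds are grouped by trial so
    hyperparameters are scored on unseen recordings.  Deterministic under
    (position, ds, seed).
    """
    hidden, dropout, batch = decode_position(position, bounds)
    base = train_cfg or TrainConfig()
    if ds.meta is not None and "trial_id" in ds.meta.columns:
        skf = StratifiedGroupKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        splits = skf.split(ds.X, ds.y, groups=ds.meta["trial_id"].to_numpy())
    else:
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        splits = skf.split(ds.X, ds.y)
    accs = []
    for tr, va in splits:
        Xtr, Xva, _ = normalize_features(ds.X[tr], ds.X[va], method="zscore")
        sizes = (ds.n_features, *([hidden] * n_hidden_layers), len(ds.class_names))
        model = init_mlp(sizes, seed=seed, keep_prob=1.0 - dropout)
        cfg = TrainConfig(
            learning_rate=base.learning_rate,
            max_iter=base.max_iter,
            stop_threshold=base.stop_threshold,
            batch_size=batch,
            seed=seed,
        )
        model, _ = train_mlp(model, Xtr, ds.y[tr], cfg)
        accs.append(float((predict(model, Xva) == ds.y[va]).mean()))
    return 1.0 - float(np.mean(accs))


def pso_optimize(
    cfg: SwarmConfig, fitness_fn: Callable[[np.ndarray], float]
) -> SwarmResult:
    """Minimize ``fitness_fn`` over the configured box.

    Particles start uniformly in the bounds with zero velocity; each iteration
    applies the coefficient lookup (fixed or scheduled), velocity and position
    steps, and personal/global best updates.  The gbest history is
    non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    b = np.asarray(cfg.bounds, dtype=float)
    dim = b.shape[0]
    vmax = _vmax(cfg)
    particles = []
    for _ in range(cfg.n_particles):
        pos = rng.uniform(b[:, 0], b[:, 1], size=dim)
        particles.append(Particle(pos, np.zeros(dim), pos.copy()))
    gbest = None
    gbest_f = np.inf
    for p in particles:
        f = fitness_fn(p.position)
        p.best_fitness = f
        if f < gbest_f:
            gbest_f, gbest = f, p.position.copy()
    history: list[tuple[float, float]] = []
    for k in range(1, cfg.max_iter + 1):
        if cfg.coeff_mode == "fixed":
            alpha, c1, c2 = cfg.inertia, cfg.c1, cfg.c2
        else:
            alpha = inertia_at(k, cfg.max_iter, cfg.alpha_min, cfg.alpha_max)
            c1, c2 = accel_at(
                k, cfg.max_iter, cfg.c1_min, cfg.c1_max, cfg.c2_min, cfg.c2_max
            )
        fits = []
        for p in particles:
            p.velocity = step_velocity(
                p, gbest, alpha, c1, c2, rng, vmax, cfg.strict_paper_signs
            )
            p.position, p.velocity = step_position(p, cfg.bounds)
            assert (p.position >= b[:, 0]).all() and (p.position <= b[:, 1]).all()
            try:
                f = fitness_fn(p.position)
            except Exception as exc:
                raise RuntimeError(
                    f"fitness evaluation failed at position {p.position}"
                ) from exc
            fits.append(f)
            if f < p.best_fitness:
                p.best_fitness = f
                p.best_position = p.position.copy()
            if f < gbest_f:
                gbest_f, gbest = f, p.position.copy()
        history.append((gbest_f, float(np.mean(fits))))
    return SwarmResult(best_position=gbest, best_fitness=gbest_f, history=history)
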