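"""Monte-Carlo-dropout active learning of the surrogate.

The training pool of (parameter set -> stress response) pairs is grown
iteratively: train the dropout surrogate for a few epochs, estimate its
predictive variance on a freshly sampled evaluation set by repeated
stochastic forward passes, sort candidates by variance, and accept the top
ones subject to a diversity constraint — a candidate must keep a minimum
normalized distance ``min(1 / |T|, min pairwise distance within T)`` to the
current pool (falling back to the highest-variance candidate if none
qualifies).  Accepted candidates are labeled with the high-fidelity forward
model and added to the pool; once the target size is reached the surrogate
is retrained from scratch-normalized weights with the dropout rate set to
zero.  A "random learning" baseline replaces the acquisition step with
uniform sampling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import qmc

from .constitutive import PARAM_NAMES, MaterialParameters
from .forward_model import LoadingProtocol, StressResponse, simulate_response
from .surrogate import (
    SurrogateConfig,
    build_inputs,
    build_model,
    mc_dropout_predict,
    r_squared,
    train,
)

__all__ = [
    "Box",
    "TrainingPool",
    "AcquisitionConfig",
    "DEFAULT_SAMPLING_BOX",
    "make_forward_labeler",
    "poisson_disk_init",
    "normalized_distance",
    "select_candidates",
    "n_iterations",
    "active_learning_loop",
    "random_learning_loop",
    "evaluate_checkpoints",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Box:
    """Axis-aligned sampling box in parameter space (``PARAM_NAMES`` order)."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.low, dtype=float)
        hi = np.asarray(self.high, dtype=float)
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("box must satisfy low < high per dimension")

    @property
    def dim(self) -> int:
        return self.low.size

    def to_unit(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.low) / (self.high - self.low)

    def from_unit(self, unit: np.ndarray) -> np.ndarray:
        return self.low + np.atleast_2d(unit) * (self.high - self.low)

    def sample_uniform(self, rng: np.random.Generator, count: int) -> np.ndarray:
        return self.from_unit(rng.random((count, self.dim)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        u = self.to_unit(points)
        return np.all((u >= -1e-12) & (u <= 1 + 1e-12), axis=1)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.low + self.high)


#: Training-data sampling box (also the surrogate-phase optimization bounds):
#: mu in [100, 2000] Pa, alpha in [-20, 20], eta in (0, 1e4] Pa s with the
#: zero lower bound replaced by a tiny positive sentinel.
DEFAULT_SAMPLING_BOX = Box(
    low=np.array([100.0, -20.0, 100.0, -20.0, 1e-3]),
    high=np.array([2000.0, 20.0, 2000.0, 20.0, 1e4]),
)


def make_forward_labeler(protocol: LoadingProtocol, nu: float = 0.45) -> Callable[[np.ndarray], StressResponse]:
    """High-fidelity labeler: parameter vector -> simulated stress response."""

    def labeler(theta: np.ndarray) -> StressResponse:
        return simulate_response(protocol, MaterialParameters.from_array(theta, nu=nu))

    labeler.protocol = protocol
    return labeler


@dataclass
class TrainingPool:
    """Labeled pool: parameter points and their stress responses on a shared
    protocol.  Points are stored in acquisition order, so a size-``k``
    snapshot of the pool is simply its first ``k`` rows."""

    protocol: LoadingProtocol
    thetas: np.ndarray = field(default_factory=lambda: np.empty((0, len(PARAM_NAMES))))
    responses: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 2)))

    def __len__(self) -> int:
        return self.thetas.shape[0]

    def add(self, thetas: np.ndarray, responses: np.ndarray) -> None:
        thetas = np.atleast_2d(thetas)
        responses = np.asarray(responses)
        if len(self) and any(np.all(self.thetas == t, axis=1).any() for t in thetas):
            raise ValueError("duplicate parameter point added to pool")
        if len(self) == 0:
            self.thetas = thetas.copy()
            self.responses = responses.copy()
        else:
            self.thetas = np.vstack([self.thetas, thetas])
            self.responses = np.concatenate([self.responses, responses], axis=0)

    def inputs(self, include_time: bool = True) -> np.ndarray:
        return build_inputs(self.thetas, self.protocol, include_time=include_time)

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        import pandas as pd

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.thetas, columns=list(PARAM_NAMES)).to_csv(d / "points.csv", index=False)
        pd.DataFrame(
            {"time": self.protocol.time, "stretch": self.protocol.stretch, "shear": self.protocol.shear}
        ).to_csv(d / "protocol.csv", index=False)
        for k in range(len(self)):
            pd.DataFrame(
                {"time": self.protocol.time, "P": self.responses[k, :, 0], "tau": self.responses[k, :, 1]}
            ).to_csv(d / f"response_{k:04d}.csv", index=False)
        (d / "meta.json").write_text(json.dumps({"size": len(self)}, indent=1))

    @classmethod
    def load(cls, directory) -> "TrainingPool":
        import pandas as pd

        d = Path(directory)
        prot = pd.read_csv(d / "protocol.csv")
        protocol = LoadingProtocol(prot["time"].to_numpy(), prot["stretch"].to_numpy(), prot["shear"].to_numpy())
        thetas = pd.read_csv(d / "points.csv").to_numpy()
        size = json.loads((d / "meta.json").read_text())["size"]
        responses = np.stack(
            [pd.read_csv(d / f"response_{k:04d}.csv")[["P", "tau"]].to_numpy() for k in range(size)]
        )
        return cls(protocol=protocol, thetas=thetas, responses=responses)


@dataclass
class AcquisitionConfig:
    """Schedule and acquisition settings of the learning loop."""

    n: int = 500  # target pool size
    m: int = 4  # points added per iteration
    eval_pool_size: int = 100
    mc_calls: int = 16
    init_size: int = 24
    intermediate_epochs: int = 100
    final_epochs: int = 1000
    seed: int = 0
    box: Box = field(default_factory=lambda: DEFAULT_SAMPLING_BOX)
    flip_distance_inequality: bool = False
    warm_start: bool = True

    def __post_init__(self):
        if self.m < 1 or self.n < self.init_size or self.eval_pool_size < self.m:
            raise ValueError("need m >= 1, n >= init_size and eval_pool_size >= m")


def n_iterations(init_size: int, m: int, n: int) -> int:
    """Number of acquisition iterations to grow the pool from ``init_size``
    to exactly ``n`` adding ``m`` points per iteration."""
    return math.ceil((n - init_size) / m)


def poisson_disk_init(
    box: Box, count: int, seed: int = 0, radius: float | None = None, return_radius: bool = False
):
    """Poisson-disk sample of ``count`` points in the box.

    Samples in the unit cube with a pairwise minimum distance ``radius``
    (auto-shrunk from a dimension-aware guess until ``count`` points fit),
    then maps to physical units.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    r = radius if radius is not None else 0.6 * count ** (-1.0 / box.dim)
    for _ in range(20):
        sampler = qmc.PoissonDisk(d=box.dim, radius=r, rng=np.random.default_rng(seed))
        unit = sampler.random(count)
        if unit.shape[0] >= count:
            pts = box.from_unit(unit[:count])
            return (pts, r) if return_radius else pts
        r *= 0.7
    raise RuntimeError(
        f"could not place {count} Poisson-disk points; retry with a smaller radius"
    )


def normalized_distance(p: np.ndarray, Q: np.ndarray, box: Box) -> float:
    """Min Euclidean distance from ``p`` to the set ``Q`` after mapping all
    coordinates to the unit box; ``+inf`` for an empty set."""
    Q = np.atleast_2d(Q) if np.size(Q) else np.empty((0, box.dim))
    if Q.shape[0] == 0:
        return float("inf")
    d = cdist(box.to_unit(p), box.to_unit(Q))
    return float(d.min())


def _min_pairwise(points: np.ndarray, box: Box) -> float:
    if points.shape[0] < 2:
        return float("inf")
    u = box.to_unit(points)
    d = cdist(u, u)
    return float(d[np.triu_indices_from(d, k=1)].min())


def select_candidates(
    E: np.ndarray, T: np.ndarray, m: int, box: Box, flip_inequality: bool = False
) -> np.ndarray:
    """Pick ``m`` acquisition points from ``E`` (sorted by variance, highest
    first) under the diversity constraint.

    The distance threshold is ``min(1 / |T|, min pairwise distance in T)``;
    a candidate is accepted when its normalized distance to the pool and the
    already-accepted points is at least the threshold (``flip_inequality``
    restores the opposite, at-most reading).  If a scan finds no admissible
    point, the highest-variance unselected candidate is taken regardless.
    """
    E = np.atleast_2d(E)
    T = np.atleast_2d(T) if np.size(T) else np.empty((0, box.dim))
    if E.shape[0] < m:
        raise ValueError("evaluation set smaller than number of points to select")
    threshold = min(1.0 / T.shape[0], _min_pairwise(T, box)) if T.shape[0] else float("inf")
    chosen: list[int] = []
    for _ in range(m):
        ref = np.vstack([T, E[chosen]]) if chosen else T
        pick = None
        for j in range(E.shape[0]):
            if j in chosen:
                continue
            d = normalized_distance(E[j], ref, box)
            ok = (d <= threshold) if flip_inequality else (d >= threshold)
            if ok:
                pick = j
                break
        if pick is None:  # fallback: highest-variance unselected point
            pick = next(j for j in range(E.shape[0]) if j not in chosen)
        chosen.append(pick)
    return E[chosen]


def _label(labeler, thetas: np.ndarray, max_failures: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Label points, skipping (with a log record) isolated failures."""
    ok_thetas, ys, failures = [], [], 0
    for theta in np.atleast_2d(thetas):
        try:
            resp = labeler(theta)
        except Exception as exc:  # noqa: BLE001 - labeler is user-supplied
            failures += 1
            logger.warning("labeler failed at %s: %s", theta, exc)
            if failures > max_failures:
                raise RuntimeError("too many labeler failures; aborting") from exc
            continue
        ok_thetas.append(theta)
        ys.append(resp.stack() if hasattr(resp, "stack") else np.asarray(resp))
    return np.array(ok_thetas), np.array(ys)


def _learning_loop(labeler, config: AcquisitionConfig, surrogate_config: SurrogateConfig, acquire):
    rng = np.random.default_rng(config.seed)
    init_thetas = poisson_disk_init(config.box, config.init_size, seed=config.seed)
    thetas0, Y0 = _label(labeler, init_thetas)
    protocol = getattr(labeler, "protocol", None)
    if not isinstance(protocol, LoadingProtocol):
        raise ValueError("labeler must expose its LoadingProtocol (see make_forward_labeler)")
    pool = TrainingPool(protocol=protocol)
    pool.add(thetas0, Y0)

    model = build_model(surrogate_config)
    history: list[dict] = []
    iteration = 0
    while len(pool) < config.n:
        if not config.warm_start and iteration > 0:
            model = build_model(surrogate_config)
        losses = train(
            model,
            pool.inputs(surrogate_config.include_time),
            pool.responses,
            epochs=config.intermediate_epochs,
        )
        iteration += 1
        m_eff = min(config.m, config.n - len(pool))
        new_thetas, mean_var = acquire(model, pool, rng, m_eff)
        lab_thetas, lab_Y = _label(labeler, new_thetas)
        pool.add(lab_thetas, lab_Y)
        history.append(
            {
                "iteration": iteration,
                "pool_size": len(pool),
                "mean_acquired_variance": mean_var,
                "train_loss": losses[-1] if losses else np.nan,
            }
        )
        logger.info("iteration %d: pool %d, variance %.3e", iteration, len(pool), mean_var)

    # Final training: a fresh dropout-free model on the completed pool, with
    # normalization statistics refit on all of it.  (The dropout-trained
    # intermediate weights only serve the acquisition; restarting avoids
    # carrying their noise-adapted basin and stale 24-point statistics into
    # the deliverable surrogate.)
    final_config = SurrogateConfig(**{**surrogate_config.__dict__, "dropout_rate": 0.0})
    model = build_model(final_config)
    final_losses = train(
        model,
        pool.inputs(surrogate_config.include_time),
        pool.responses,
        epochs=config.final_epochs,
    )
    history.append(
        {
            "iteration": iteration + 1,
            "pool_size": len(pool),
            "mean_acquired_variance": np.nan,
            "train_loss": final_losses[-1] if final_losses else np.nan,
        }
    )
    return pool, model, history


def active_learning_loop(labeler, config: AcquisitionConfig, surrogate_config: SurrogateConfig):
    """Grow the pool by MC-dropout variance acquisition (the main loop).

    Per iteration: train the dropout surrogate for ``intermediate_epochs``
    (warm start), sample ``eval_pool_size`` fresh uniform candidates,
    estimate each candidate's MC-dropout variance with ``mc_calls`` calls,
    and add the ``m`` highest-variance candidates admissible under the
    diversity constraint.  Ends with a dropout-free training of
    ``final_epochs``.  Returns ``(pool, model, history)``.
    """

    def acquire(model, pool, rng, m_eff):
        E = config.box.sample_uniform(rng, config.eval_pool_size)
        XE = build_inputs(E, pool.protocol, include_time=surrogate_config.include_time)
        _, var_scalar, _ = mc_dropout_predict(model, XE, n_calls=config.mc_calls, rng=rng)
        order = np.argsort(-var_scalar)
        selected = select_candidates(
            E[order], pool.thetas, m_eff, config.box, config.flip_distance_inequality
        )
        sel_idx = [np.flatnonzero(np.all(E == s, axis=1))[0] for s in selected]
        return selected, float(np.mean(var_scalar[sel_idx]))

    return _learning_loop(labeler, config, surrogate_config, acquire)


def random_learning_loop(labeler, config: AcquisitionConfig, surrogate_config: SurrogateConfig):
    """Baseline loop with the acquisition replaced by uniform sampling."""

    def acquire(model, pool, rng, m_eff):
        return config.box.sample_uniform(rng, m_eff), float("nan")

    return _learning_loop(labeler, config, surrogate_config, acquire)


def evaluate_checkpoints(
    pool: TrainingPool,
    test_thetas: np.ndarray,
    test_Y: np.ndarray,
    every_k: int,
    final_epochs: int,
    surrogate_config: SurrogateConfig,
    init_size: int,
    m: int,
):
    """Learning-curve evaluation: for every ``every_k``-th iteration snapshot
    of the pool (prefix of the acquisition order), train a fresh dropout-free
    model for ``final_epochs`` and compute test-set R².

    Returns a list of ``(pool_size, r2_mean, r2_std)`` rows.
    """
    total_iters = n_iterations(init_size, m, len(pool))
    rows = []
    for it in range(0, total_iters + 1, every_k):
        size = min(init_size + it * m, len(pool))
        cfg = SurrogateConfig(**{**surrogate_config.__dict__, "dropout_rate": 0.0})
        model = build_model(cfg)
        X = build_inputs(pool.thetas[:size], pool.protocol, include_time=cfg.include_time)
        train(model, X, pool.responses[:size], epochs=final_epochs)
        XT = build_inputs(test_thetas, pool.protocol, include_time=cfg.include_time)
        pred = model.predict(XT)
        _, mean, std = r_squared(test_Y, pred)
        rows.append((size, mean, std))
    return rows
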