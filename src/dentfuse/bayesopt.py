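"""Gaussian-process Bayesian optimization of the WBF hyperparameters.

The objective f(θ) — validation mAP@0.5 (or F1) of the fused ensemble — is
modeled with a GP surrogate, f(θ) ~ GP(μ(θ), k(θ, θ′)), over the search box
min-max scaled to the unit hypercube.  Each round the posterior mean μ(θ) and
standard deviation σ(θ) feed the Expected Improvement acquisition
a(θ) = E[max(f(θ) − f(θ⁺), 0)], whose argmax over a seeded Sobol candidate
set (plus local refinement around the incumbent) is evaluated next.

Kernel: Matérn-5/2 with one shared length-scale; the length-scale and signal
variance are refit every round by maximizing the marginal likelihood over a
small grid, with a fixed 1e-6 jitter on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import norm, qmc

from .evaluation import evaluate
from .io_formats import DatasetSplit, ImageRecord
from .wbf import FusionParams, fuse_dataset

__all__ = [
    "SearchSpace",
    "GPState",
    "OptimizationTrace",
    "gp_posterior",
    "expected_improvement",
    "propose_next",
    "optimize",
    "random_search",
    "optimize_wbf",
    "WBF_SEARCH_SPACE",
]

JITTER = 1e-6
_LENGTH_SCALE_GRID = np.geomspace(0.05, 2.0, 8)
_SIGNAL_FACTOR_GRID = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class SearchSpace:
    """Closed per-parameter intervals, in the parameters' native units."""

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names/lower/upper length mismatch")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if lo > hi:
                raise ValueError(f"{name}: lower {lo} > upper {hi}")

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_unit(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.asarray(theta, dtype=float) - lo) / span

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        return lo + np.clip(np.asarray(u, dtype=float), 0.0, 1.0) * (hi - lo)


#: The four WBF hyperparameters and their search ranges: clustering IoU
#: threshold 0.1–0.9, skip-box threshold 0.001–0.1, two model weights 1–10.
WBF_SEARCH_SPACE = SearchSpace(
    names=("iou_thr", "skip_box_thr", "weight1", "weight2"),
    lower=(0.1, 0.001, 1.0, 1.0),
    upper=(0.9, 0.1, 10.0, 10.0),
)


def _matern52(sq_dists: np.ndarray, length_scale: float, signal_var: float) -> np.ndarray:
    d = np.sqrt(np.maximum(sq_dists, 0.0)) / length_scale
    return signal_var * (1.0 + np.sqrt(5.0) * d + 5.0 / 3.0 * d**2) * np.exp(
        -np.sqrt(5.0) * d
    )


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)


@dataclass
class GPState:
    """Observed (θ, score) pairs plus fitted kernel hyperparameters.

    ``thetas`` live in the unit hypercube.  The prior mean is the mean of the
    observed scores; ``signal_var`` defaults to their variance.
    """

    thetas: np.ndarray  # (n, d)
    scores: np.ndarray  # (n,)
    length_scale: float = 0.5
    signal_var: float = 1.0
    noise_jitter: float = JITTER

    def __post_init__(self) -> None:
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.thetas) != len(self.scores):
            raise ValueError("thetas and scores length mismatch")

    @classmethod
    def fit(
        cls, thetas: np.ndarray, scores: np.ndarray, noise_jitter: float = JITTER
    ) -> "GPState":
        """Fit kernel hyperparameters by maximizing the log marginal
        likelihood over a small (length-scale × signal-variance) grid."""
        state = cls(thetas=thetas, scores=scores, noise_jitter=noise_jitter)
        base_var = float(np.var(state.scores))
        if base_var <= 0.0:
            base_var = 1.0
        best = (-np.inf, state.length_scale, state.signal_var)
        sq = _sq_dists(state.thetas, state.thetas)
        centered = state.scores - state.scores.mean()
        n = len(centered)
        for ls in _LENGTH_SCALE_GRID:
            for fac in _SIGNAL_FACTOR_GRID:
                sv = base_var * fac
                K = _matern52(sq, ls, sv) + noise_jitter * np.eye(n)
                try:
                    L = cholesky(K, lower=True)
                except np.linalg.LinAlgError:
                    continue
                alpha = cho_solve((L, True), centered)
                lml = (
                    -0.5 * centered @ alpha
                    - np.sum(np.log(np.diag(L)))
                    - 0.5 * n * np.log(2 * np.pi)
                )
                if lml > best[0]:
                    best = (lml, float(ls), float(sv))
        _, state.length_scale, state.signal_var = best
        return state


def gp_posterior(state: GPState, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GP regression posterior mean and standard deviation at query points.

    At an observed point the mean reproduces the observation to within the
    jitter; far from all observations (≫ length-scale) the mean reverts to
    the prior mean and the standard deviation to the prior signal std.
    """
    if len(state.thetas) == 0:
        raise ValueError("gp_posterior needs at least one observation")
    query = np.atleast_2d(np.asarray(query, dtype=float))
    prior_mean = state.scores.mean()
    centered = state.scores - prior_mean
    K = _matern52(
        _sq_dists(state.thetas, state.thetas), state.length_scale, state.signal_var
    ) + state.noise_jitter * np.eye(len(state.thetas))
    try:
        factor = cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance matrix singular beyond jitter {state.noise_jitter}: {exc}"
        ) from exc
    k_star = _matern52(
        _sq_dists(query, state.thetas), state.length_scale, state.signal_var
    )
    alpha = cho_solve(factor, centered)
    mean = prior_mean + k_star @ alpha
    v = cho_solve(factor, k_star.T)
    var = state.signal_var - np.sum(k_star * v.T, axis=1)
    std = np.sqrt(np.maximum(var, 0.0))
    return mean, std


def expected_improvement(
    mean: np.ndarray, std: np.ndarray, best_so_far: float
) -> np.ndarray:
    """Closed-form EI for maximization: Δ·Φ(z) + σ·φ(z), z = Δ/σ, with
    Δ = μ − f(θ⁺); reduces to max(Δ, 0) when σ = 0."""
    mean = np.asarray(mean, dtype=float)
    std = np.asarray(std, dtype=float)
    delta = mean - best_so_far
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, delta / np.where(std > 0, std, 1.0), 0.0)
        ei = np.where(
            std > 0,
            delta * norm.cdf(z) + std * norm.pdf(z),
            np.maximum(delta, 0.0),
        )
    return np.maximum(ei, 0.0)


def propose_next(
    state: GPState,
    space: SearchSpace,
    rng: np.random.Generator,
    n_candidates: int = 2048,
    n_local: int = 256,
) -> np.ndarray:
    """Maximize EI over a seeded Sobol candidate set plus Gaussian local
    refinement around the incumbent; returns a unit-cube point.

    When the posterior is flat (every candidate has EI = 0) the candidate
    with the largest posterior variance is returned instead, keeping the
    search exploring.
    """
    sobol = qmc.Sobol(d=space.dim, scramble=True, seed=int(rng.integers(2**31)))
    cand = sobol.random(n_candidates)
    incumbent = state.thetas[int(np.argmax(state.scores))]
    local = np.clip(
        incumbent + 0.05 * rng.standard_normal((n_local, space.dim)), 0.0, 1.0
    )
    cand = np.vstack([cand, local, incumbent[None, :]])
    mean, std = gp_posterior(state, cand)
    ei = expected_improvement(mean, std, float(np.max(state.scores)))
    if np.max(ei) <= 0.0:
        return cand[int(np.argmax(std))]
    return cand[int(np.argmax(ei))]


@dataclass
class OptimizationTrace:
    """Per-iteration record of an optimization run."""

    thetas: list[np.ndarray] = field(default_factory=list)  # native units
    scores: list[float] = field(default_factory=list)
    ei_values: list[float] = field(default_factory=list)
    failed: list[bool] = field(default_factory=list)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.scores))

    @property
    def best_theta(self) -> np.ndarray:
        return self.thetas[self.best_index]

    @property
    def best_score(self) -> float:
        return float(self.scores[self.best_index])

    @property
    def best_score_sequence(self) -> np.ndarray:
        return np.maximum.accumulate(np.asarray(self.scores))


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    budget: int = 50,
    n_init: int = 10,
    seed: int = 0,
    patience: int = 15,
    tol: float = 1e-4,
) -> OptimizationTrace:
    """Maximize ``objective`` over ``space`` by GP-EI Bayesian optimization.

    ``n_init`` seeded Latin-hypercube evaluations initialize the surrogate;
    afterwards each round refits the GP, maximizes EI and evaluates the
    proposal, stopping at ``budget`` evaluations or after ``patience``
    consecutive rounds without an improvement larger than ``tol``.  An
    objective that raises is recorded as a failed trial and penalized (worst
    observed score minus one signal std) so the surrogate avoids the region.
    Fully reproducible for a fixed seed.
    """
    if not budget >= n_init >= 2:
        raise ValueError(f"need budget >= n_init >= 2, got {budget}, {n_init}")
    rng = np.random.default_rng(seed)
    trace = OptimizationTrace()
    unit_pts: list[np.ndarray] = []
    raw_scores: list[float] = []  # penalized values for the surrogate

    def run_trial(u: np.ndarray, ei: float) -> None:
        theta = space.from_unit(u)
        try:
            score = float(objective(theta))
            failed = False
        except Exception:
            observed = [s for s, f in zip(raw_scores, trace.failed) if not f]
            base = min(observed) if observed else 0.0
            spread = np.std(observed) if len(observed) > 1 else 1.0
            score = base - max(float(spread), tol)
            failed = True
        unit_pts.append(u)
        raw_scores.append(score)
        trace.thetas.append(theta)
        trace.scores.append(score)
        trace.ei_values.append(ei)
        trace.failed.append(failed)

    lhs = qmc.LatinHypercube(d=space.dim, seed=int(rng.integers(2**31)))
    for u in lhs.random(n_init):
        run_trial(u, float("nan"))

    stall = 0
    while len(trace.scores) < budget and stall < patience:
        state = GPState.fit(np.asarray(unit_pts), np.asarray(raw_scores))
        u = propose_next(state, space, rng)
        mean, std = gp_posterior(state, u)
        ei = float(
            expected_improvement(mean, std, float(np.max(raw_scores)))[0]
        )
        best_before = max(trace.scores)
        run_trial(u, ei)
        stall = 0 if trace.scores[-1] > best_before + tol else stall + 1
    return trace


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    budget: int = 50,
    seed: int = 0,
) -> OptimizationTrace:
    """Seeded uniform random search over the same space — the baseline that
    GP-EI optimization is expected to beat at equal budget."""
    rng = np.random.default_rng(seed)
    trace = OptimizationTrace()
    for u in rng.uniform(size=(budget, space.dim)):
        theta = space.from_unit(u)
        trace.thetas.append(theta)
        trace.scores.append(float(objective(theta)))
        trace.ei_values.append(float("nan"))
        trace.failed.append(False)
    return trace


def _theta_to_params(theta: np.ndarray, model_ids: Sequence[str]) -> FusionParams:
    iou_thr, skip, *weights = (float(t) for t in theta)
    return FusionParams(
        iou_thr=iou_thr,
        skip_box_thr=skip,
        model_weights=dict(zip(model_ids, weights)),
    )


def optimize_wbf(
    records: Sequence[ImageRecord],
    split: DatasetSplit,
    space: SearchSpace = WBF_SEARCH_SPACE,
    budget: int = 50,
    n_init: int = 10,
    seed: int = 0,
    objective_metric: str = "map50",
) -> tuple[FusionParams, OptimizationTrace]:
    """Tune the WBF hyperparameters to maximize fused-ensemble quality on the
    validation partition.

    The objective maps θ = (iou_thr, skip_box_thr, weight₁, …) to the
    validation mAP@0.5 (or max-F1, per ``objective_metric``) of the fused
    predictions.  Returns the best :class:`FusionParams` in native units plus
    the full trace; evaluate the winner on the test partition separately.
    """
    if objective_metric not in ("map50", "f1"):
        raise ValueError(f"unknown objective metric {objective_metric!r}")
    model_ids = sorted({m for rec in records for m in rec.predictions})
    if len(model_ids) < 2:
        raise ValueError(
            f"optimize_wbf needs predictions from >= 2 models, found {model_ids}"
        )
    if space.dim != 2 + len(model_ids):
        raise ValueError(
            f"search space has {space.dim} dimensions but "
            f"{2 + len(model_ids)} are needed for {len(model_ids)} models"
        )
    val_records = [r for r in records if r.image_id in split.val_ids]
    if not val_records:
        raise ValueError("no records fall in the validation partition")
    gts = {r.image_id: r.ground_truth for r in val_records}

    def objective(theta: np.ndarray) -> float:
        params = _theta_to_params(theta, model_ids)
        fused = fuse_dataset(val_records, params)
        report = evaluate(fused, gts)
        return report.map50 if objective_metric == "map50" else report.f1

    trace = optimize(objective, space, budget=budget, n_init=n_init, seed=seed)
    return _theta_to_params(trace.best_theta, model_ids), trace
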