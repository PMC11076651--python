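"""Metaheuristic wrapper feature selection.

Three population searches — harmony search, the firefly algorithm and
elephant herding optimization — explore continuous positions in
[0, 1]^d; a position is thresholded into a binary feature mask whose
fitness is the cross-validated mean squared error of a classifier
trained on the masked features (lower is better).  Benchmark settings:
HMCR 0.95 / PAR 0.3 / BW 0.1 for harmony search; light absorption
γ = 0.1 and initial randomization 0.65 for firefly; α = β = 0.6 for
elephant herding; 1000 iterations or fitness ≤ 1e-5, whichever first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifiers import ClassifierSpec, cross_val_predict, stratified_folds

#: search stops once fitness falls to this level (or at max_iter)
TARGET_FITNESS = 1e-5


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """mask_i = 1 iff position_i > threshold; an all-zero mask falls back
    to selecting the single largest coordinate."""
    position = np.asarray(position, dtype=float)
    mask = (position > threshold).astype(int)
    if mask.sum() == 0:
        mask[int(np.argmax(position))] = 1
    return mask


class FitnessEvaluator:
    """Cross-validated MSE of a classifier on masked features, memoized.

    For 0/1 labels the MSE of hard predictions equals the pooled
    misclassification rate.  The fold scheme is built once per
    evaluator, so identical masks always see identical folds.
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 clf_spec: ClassifierSpec, folds: int = 3, seed: int = 0,
                 cache: bool = True, sparsity_penalty: float = 0.0):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if folds < 2:
            raise ValueError("folds must be >= 2")
        self.clf_spec = clf_spec
        self.scheme = stratified_folds(self.labels, k=folds, seed=seed)
        self.sparsity_penalty = sparsity_penalty
        self._cache: dict | None = {} if cache else None
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=int)
        if mask.size != self.features.shape[1]:
            raise ValueError(
                f"mask length {mask.size} != feature dimension {self.features.shape[1]}")
        if mask.sum() == 0:
            raise ValueError("mask selects no features")
        key = mask.tobytes()
        if self._cache is not None and key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1
        X = self.features[:, mask.astype(bool)]
        preds = cross_val_predict(self.clf_spec, X, self.labels, self.scheme)
        mse = float(np.mean((self.labels - preds.astype(int)) ** 2))
        mse += self.sparsity_penalty * mask.sum() / mask.size
        if self._cache is not None:
            self._cache[key] = mse
        return mse


def evaluate_fitness(mask, features, labels, clf_spec, folds: int = 3,
                     seed: int = 0) -> float:
    """One-shot convenience wrapper over :class:`FitnessEvaluator`."""
    return FitnessEvaluator(features, labels, clf_spec, folds=folds, seed=seed)(mask)


# ---------------------------------------------------------------------------
# Search configs and trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HSConfig:
    memory_size: int = 20
    hmcr: float = 0.95   # harmony memory consideration rate
    par: float = 0.3     # pitch adjusting rate
    bw: float = 0.1      # bandwidth of a pitch adjustment
    max_iter: int = 1000
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if not (0 <= self.hmcr <= 1 and 0 <= self.par <= 1):
            raise ValueError("HMCR and PAR must lie in [0, 1]")
        if self.bw <= 0 or self.memory_size < 2:
            raise ValueError("need BW > 0 and memory_size >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class FireflyConfig:
    gamma: float = 0.1        # light absorption coefficient
    beta0: float = 1.0        # attractiveness at distance 0
    alpha0: float = 0.65      # initial randomization scale
    alpha_decay: float = 0.97  # geometric decay of the randomization per iteration
    population: int = 25
    max_iter: int = 1000
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.gamma < 0 or self.population < 2:
            raise ValueError("need gamma >= 0 and population >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class EHOConfig:
    alpha: float = 0.6  # movement toward the clan best
    beta: float = 0.6   # attraction of the clan best to the clan centre
    n_clans: int = 3
    population: int = 30
    max_iter: int = 1000
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.n_clans < 1 or self.population % self.n_clans != 0:
            raise ValueError("population must divide evenly into n_clans")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SearchTrace:
    best_fitness: np.ndarray      # best-so-far per iteration, non-increasing
    best_position: np.ndarray
    n_evaluations: int
    seed: int

    @property
    def final_fitness(self) -> float:
        return float(self.best_fitness[-1])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, v in enumerate(self.best_fitness):
                fh.write(f"{i},{v:.10g}\n")


# ---------------------------------------------------------------------------
# Harmony search
# ---------------------------------------------------------------------------

def harmony_search(fitness_fn, d: int, config: HSConfig | None = None,
                   seed: int = 0, target: float = TARGET_FITNESS) -> SearchTrace:
    """Improvise one new harmony per iteration: each coordinate is copied
    from a random memory member with probability HMCR (then perturbed by
    ±BW·U(0,1) with probability PAR) or redrawn uniformly; the new
    harmony replaces the worst memory member when it improves on it."""
    cfg = config or HSConfig()
    lo, hi = cfg.bounds
    rng = np.random.default_rng(seed)
    memory = rng.uniform(lo, hi, size=(cfg.memory_size, d))
    fitness = np.array([fitness_fn(m) for m in memory])
    n_evals = cfg.memory_size
    best_trace = [float(fitness.min())]
    for _ in range(cfg.max_iter - 1):
        if best_trace[-1] <= target:
            break
        use_mem = rng.random(d) < cfg.hmcr
        donors = rng.integers(0, cfg.memory_size, size=d)
        new = np.where(use_mem, memory[donors, np.arange(d)], rng.uniform(lo, hi, d))
        adjust = use_mem & (rng.random(d) < cfg.par)
        steps = cfg.bw * rng.uniform(size=d) * rng.choice([-1.0, 1.0], size=d)
        new = np.clip(np.where(adjust, new + steps, new), lo, hi)
        f_new = fitness_fn(new)
        n_evals += 1
        worst = int(fitness.argmax())
        if f_new < fitness[worst]:
            memory[worst] = new
            fitness[worst] = f_new
        best_trace.append(float(min(best_trace[-1], fitness.min())))
    best = int(fitness.argmin())
    return SearchTrace(np.asarray(best_trace), memory[best].copy(), n_evals, seed)


# ---------------------------------------------------------------------------
# Firefly algorithm
# ---------------------------------------------------------------------------

def firefly_search(fitness_fn, d: int, config: FireflyConfig | None = None,
                   seed: int = 0, target: float = TARGET_FITNESS) -> SearchTrace:
    """Brightness is negative fitness.  Each iteration every firefly is
    pulled toward each brighter one with attractiveness β0·e^{−γ r²}
    (r the Euclidean distance) plus a uniform random kick whose scale
    decays geometrically from α0; positions are clipped to bounds and
    updated synchronously.  The best position found is never lost."""
    cfg = config or FireflyConfig()
    lo, hi = cfg.bounds
    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(cfg.population, d))
    fit = np.array([fitness_fn(x) for x in X])
    n_evals = cfg.population
    gbest_i = int(fit.argmin())
    gbest_x, gbest_f = X[gbest_i].copy(), float(fit[gbest_i])
    trace = [gbest_f]
    alpha = cfg.alpha0
    for _ in range(cfg.max_iter - 1):
        if trace[-1] <= target:
            break
        diff = X[None, :, :] - X[:, None, :]              # j - i
        r2 = (diff**2).sum(axis=2)
        beta = cfg.beta0 * np.exp(-cfg.gamma * r2)
        brighter = (fit[None, :] < fit[:, None]).astype(float)
        w = beta * brighter
        w /= np.maximum(w.sum(axis=1, keepdims=True), 1.0)  # temper the accumulated pull
        move = (w[:, :, None] * diff).sum(axis=1)
        X = np.clip(X + move + alpha * (rng.random((cfg.population, d)) - 0.5), lo, hi)
        X[int(fit.argmin())] = gbest_x  # elitism: keep the incumbent
        fit = np.array([fitness_fn(x) for x in X])
        n_evals += cfg.population
        i = int(fit.argmin())
        if fit[i] < gbest_f:
            gbest_x, gbest_f = X[i].copy(), float(fit[i])
        trace.append(gbest_f)
        alpha *= cfg.alpha_decay
    return SearchTrace(np.asarray(trace), gbest_x, n_evals, seed)


def firefly_attractiveness(beta0: float, gamma: float, r: float) -> float:
    """Attractiveness β(r) = β0 e^{−γ r²}."""
    return beta0 * np.exp(-gamma * r * r)


# ---------------------------------------------------------------------------
# Elephant herding optimization
# ---------------------------------------------------------------------------

def eho_search(fitness_fn, d: int, config: EHOConfig | None = None,
               seed: int = 0, target: float = TARGET_FITNESS) -> SearchTrace:
    """Clan updating: each member moves toward the clan best by
    α·(best − x)·r with r ~ U(0,1); the clan best is re-placed at
    β·centre (centre the clan mean).  Separating: the clan's worst
    member is replaced by min + (max − min + 1)·rand, clipped to
    bounds.  Elitism restores the global best each iteration."""
    cfg = config or EHOConfig()
    lo, hi = cfg.bounds
    rng = np.random.default_rng(seed)
    clan_size = cfg.population // cfg.n_clans
    X = rng.uniform(lo, hi, size=(cfg.population, d))
    fit = np.array([fitness_fn(x) for x in X])
    n_evals = cfg.population
    gi = int(fit.argmin())
    gbest_x, gbest_f = X[gi].copy(), float(fit[gi])
    trace = [gbest_f]
    clans = np.arange(cfg.population).reshape(cfg.n_clans, clan_size)
    for _ in range(cfg.max_iter - 1):
        if trace[-1] <= target:
            break
        newX = X.copy()
        for clan in clans:
            cf = fit[clan]
            best_local = clan[int(cf.argmin())]
            centre = X[clan].mean(axis=0)
            for i in clan:
                if i == best_local:
                    newX[i] = cfg.beta * centre
                else:
                    r = rng.random()
                    newX[i] = X[i] + cfg.alpha * (X[best_local] - X[i]) * r
            worst_local = clan[int(cf.argmax())]
            newX[worst_local] = lo + (hi - lo + 1.0) * rng.random(d)
        X = np.clip(newX, lo, hi)
        fit = np.array([fitness_fn(x) for x in X])
        n_evals += cfg.population
        # elitism: reinject the incumbent over the current worst
        wi = int(fit.argmax())
        if gbest_f < fit[wi]:
            X[wi], fit[wi] = gbest_x, gbest_f
        i = int(fit.argmin())
        if fit[i] < gbest_f:
            gbest_x, gbest_f = X[i].copy(), float(fit[i])
        trace.append(gbest_f)
    return SearchTrace(np.asarray(trace), gbest_x, n_evals, seed)


ALGORITHMS = {"HS": harmony_search, "FF": firefly_search, "EHO": eho_search}
DEFAULT_CONFIGS = {"HS": HSConfig, "FF": FireflyConfig, "EHO": EHOConfig}


def select_features(features: np.ndarray, labels: np.ndarray, algorithm: str,
                    clf_spec: ClassifierSpec, config=None, seed: int = 0,
                    fitness_folds: int = 3, threshold: float = 0.5,
                    sparsity_penalty: float = 0.0):
    """Run one metaheuristic over binary masks of the feature columns.

    Returns ``(mask, trace)`` where ``mask`` is the binarized best
    position found.  Identical seeds and configs reproduce identical
    masks.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    d = features.shape[1]
    evaluator = FitnessEvaluator(features, labels, clf_spec,
                                 folds=fitness_folds, seed=seed,
                                 sparsity_penalty=sparsity_penalty)

    def position_fitness(position):
        return evaluator(binarize_position(position, threshold))

    cfg = config if config is not None else DEFAULT_CONFIGS[algorithm]()
    trace = ALGORITHMS[algorithm](position_fitness, d, cfg, seed=seed)
    mask = binarize_position(trace.best_position, threshold)
    return mask, trace


def write_mask_json(path: str | Path, mask: np.ndarray, trace: SearchTrace,
                    algorithm: str, config) -> None:
    """Serialize a mask as selected indices plus search metadata."""
    payload = {
        "algorithm": algorithm,
        "selected_indices": np.flatnonzero(mask).tolist(),
        "n_features": int(mask.size),
        "final_fitness": trace.final_fitness,
        "n_evaluations": trace.n_evaluations,
        "seed": trace.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
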