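"""Wrapper feature selection by (improved) moth-flame optimization.

Moth-flame optimization (MFO) is a population metaheuristic in which moth
positions spiral toward flames — the best solutions found so far — with the
flame count shrinking linearly so the search focuses over time.  Here a
moth's continuous position vector is binarized into a feature gate and scored
by the wrapper fitness

    fitness = r * Error + (1 - r) * |selected| / Dim,

where Error is the hold-out misclassification rate of a cubic-kernel SVM
(one-vs-all) restricted to the gated columns and the second term penalizes
large subsets.  The improved variant (IMFO) binarizes through two adaptive
gates: a sigmoid gate thresholded at the row mean of the sigmoid-transformed
position, and, after each spiral update, an entropy gate thresholded at the
normalized Shannon entropy of the position's sigmoid histogram.  Plain MFO
uses a fixed sigmoid > 0.5 gate and no entropy pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix

POSITION_CLIP = 4.0
ENTROPY_BINS = 10


@dataclass
class FitnessConfig:
    """Accuracy/sparsity trade-off and error-estimation protocol.

    ``r_weight`` weighs classifier error against subset size; ``r_mode``
    'fixed' keeps it constant (required for oracle comparisons) while
    'random' redraws r uniformly in [0, 1] per evaluation.  Error comes from
    a single seeded stratified hold-out of the provided data.
    """

    r_weight: float = 0.9
    r_mode: str = "fixed"
    holdout_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_weight <= 1.0:
            raise ValueError("r_weight must be in [0, 1]")
        if self.r_mode not in ("fixed", "random"):
            raise ValueError("r_mode must be 'fixed' or 'random'")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must be in (0, 1)")


@dataclass
class MothState:
    """Positions, gates, flames and bookkeeping of one optimization run."""

    positions: np.ndarray
    gates: np.ndarray
    flames: np.ndarray
    flame_fitness: np.ndarray
    flame_gates: np.ndarray
    iteration: int = 0
    best_fitness_history: list = field(default_factory=list)
    best_gate: np.ndarray | None = None
    best_fitness: float = math.inf


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    reduced_matrix: FeatureMatrix
    final_fitness: float
    iterations_run: int
    seed: int
    fitness_history: list = field(default_factory=list)
    variant: str = "imfo"


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class FitnessEvaluator:
    """Memoized wrapper fitness around a cubic-SVM hold-out error.

    The stratified hold-out split is drawn once from ``cfg.seed`` and reused
    for every evaluation, so with ``r_mode='fixed'`` the fitness is a frozen
    deterministic function of the gate — the property the exhaustive oracle
    comparison relies on.  Hold-out errors are cached per unique gate.
    """

    def __init__(self, features, labels, cfg: FitnessConfig):
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
        y = np.asarray(labels)
        if np.unique(y).size < 2:
            raise ValueError("fitness evaluation requires at least two classes")
        self.cfg = cfg
        self.dim = X.shape[1]
        idx = np.arange(X.shape[0])
        tr, te = train_test_split(idx, test_size=cfg.holdout_frac,
                                  stratify=y, random_state=cfg.seed % (2**32))
        self.X_tr, self.X_te = X[tr], X[te]
        self.y_tr, self.y_te = y[tr], y[te]
        self._rng = np.random.default_rng(cfg.seed + 17)
        self._error_cache: dict[bytes, float] = {}
        self.n_error_evals = 0

    def holdout_error(self, gate: np.ndarray) -> float:
        gate = np.asarray(gate).astype(bool)
        key = np.packbits(gate).tobytes()
        err = self._error_cache.get(key)
        if err is None:
            cols = np.flatnonzero(gate)
            clf = OneVsRestClassifier(
                SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0))
            clf.fit(self.X_tr[:, cols], self.y_tr)
            err = float(np.mean(clf.predict(self.X_te[:, cols]) != self.y_te))
            self._error_cache[key] = err
            self.n_error_evals += 1
        return err

    def __call__(self, gate: np.ndarray) -> float:
        gate = np.asarray(gate).astype(bool)
        if not gate.any():
            return 1.0            # worst possible: no features selected
        r = self.cfg.r_weight if self.cfg.r_mode == "fixed" else float(self._rng.uniform())
        return r * self.holdout_error(gate) + (1.0 - r) * gate.sum() / self.dim


def evaluate_fitness(gate_row, features, labels, cfg: FitnessConfig) -> float:
    """Wrapper fitness of one gate (convenience around FitnessEvaluator)."""
    return FitnessEvaluator(features, labels, cfg)(gate_row)


def binarize_positions(positions: np.ndarray, V=None) -> np.ndarray:
    """Sigmoid mean-gate: 1 where sigmoid(position) strictly exceeds V.

    When V is omitted it is the row mean of the sigmoid-transformed
    positions, recomputed for every call (every iteration).
    """
    s = sigmoid(np.atleast_2d(positions))
    if V is None:
        V = s.mean(axis=1, keepdims=True)
    gates = (s > V).astype(np.uint8)
    return gates if np.asarray(positions).ndim > 1 else gates[0]


def row_entropy(positions: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of each row's sigmoid histogram.

    Sigmoid-transformed positions are histogrammed into 10 equal bins on
    [0, 1]; H = -sum p ln p / ln(10), so H in [0, 1].
    """
    s = sigmoid(np.atleast_2d(positions))
    H = np.empty(s.shape[0])
    for i, row in enumerate(s):
        counts, _ = np.histogram(row, bins=ENTROPY_BINS, range=(0.0, 1.0))
        p = counts[counts > 0] / counts.sum()
        H[i] = float(-(p * np.log(p)).sum() / np.log(ENTROPY_BINS))
    return H


def entropy_gate(positions: np.ndarray) -> np.ndarray:
    """Entropy gate: 1 where sigmoid(position) strictly exceeds the row's H."""
    pos = np.atleast_2d(positions)
    s = sigmoid(pos)
    H = row_entropy(pos)
    gates = (s > H[:, None]).astype(np.uint8)
    return gates if np.asarray(positions).ndim > 1 else gates[0]


def flame_count(n_pop: int, iteration: int, max_iter: int) -> int:
    """Linearly shrinking flame count: n_pop at iteration 0, 1 at max_iter."""
    return int(round(n_pop - iteration * (n_pop - 1) / max_iter))


def initialize_population(n_pop: int, dim: int, seed: int,
                          evaluator: FitnessEvaluator | None = None,
                          variant: str = "imfo") -> MothState:
    """Uniform [0, 1] positions; gates from the variant's binarization.

    With an evaluator, the initial flames are the population sorted by
    fitness (best first); without one, fitness is marked unknown.
    """
    if n_pop < 2 or dim < 1:
        raise ValueError("need n_pop >= 2 and dim >= 1")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n_pop, dim))
    gates = _variant_gates(positions, variant)
    if evaluator is not None:
        fitness = np.array([evaluator(g) for g in gates])
    else:
        fitness = np.full(n_pop, math.inf)
    order = np.argsort(fitness, kind="stable")
    state = MothState(
        positions=positions, gates=gates,
        flames=positions[order].copy(), flame_fitness=fitness[order],
        flame_gates=gates[order].copy(),
    )
    if evaluator is not None:
        state.best_fitness = float(state.flame_fitness[0])
        state.best_gate = state.flame_gates[0].copy()
    return state


def _variant_gates(positions: np.ndarray, variant: str) -> np.ndarray:
    if variant == "imfo":
        return binarize_positions(positions)
    if variant == "mfo":
        return (sigmoid(positions) > 0.5).astype(np.uint8)
    raise ValueError("variant must be 'imfo' or 'mfo'")


def update_moths(state: MothState, max_iter: int, rng=None, b: float = 1.0,
                 w_start: float = 0.9, w_end: float = 0.4) -> MothState:
    """One spiral position update of all moths toward their flames.

    Per dimension: new = d * exp(b*l) * cos(2*pi*l) + w*F + (1-w)*F, with
    d = |F - position|, F the matched flame's position, l uniform in [-1, 1]
    (l = -1 is the closest approach), w annealed linearly from w_start to
    w_end over the run, and moth i paired with flame min(i, n_flames - 1)
    under the linearly shrinking flame count.  Positions are clipped to
    [-4, 4].  Mutates and returns the state.
    """
    if state.flames.size == 0:
        raise ValueError("flames must be populated before updating moths")
    if rng is None:
        rng = np.random.default_rng(0)
    n_pop, dim = state.positions.shape
    it = min(state.iteration + 1, max_iter)
    n_f = max(flame_count(n_pop, it, max_iter), 1)
    w = w_start + (w_end - w_start) * it / max_iter
    flame_idx = np.minimum(np.arange(n_pop), n_f - 1)
    F = state.flames[flame_idx]
    d = np.abs(F - state.positions)
    l = rng.uniform(-1.0, 1.0, size=(n_pop, dim))
    spiral = d * np.exp(b * l) * np.cos(2.0 * np.pi * l)
    state.positions = np.clip(spiral + w * F + (1.0 - w) * F,
                              -POSITION_CLIP, POSITION_CLIP)
    state.iteration = it
    return state


def _merge_flames(state: MothState, positions, fitness, gates, n_pop: int) -> None:
    """Elitist flame update: best n_pop of (old flames) U (new solutions)."""
    all_pos = np.vstack([state.flames, positions])
    all_fit = np.concatenate([state.flame_fitness, fitness])
    all_gates = np.vstack([state.flame_gates, gates])
    order = np.argsort(all_fit, kind="stable")[:n_pop]
    state.flames = all_pos[order].copy()
    state.flame_fitness = all_fit[order].copy()
    state.flame_gates = all_gates[order].copy()
    if state.flame_fitness[0] < state.best_fitness:
        state.best_fitness = float(state.flame_fitness[0])
        state.best_gate = state.flame_gates[0].copy()


def select_features(features, labels, cfg: FitnessConfig | None = None,
                    n_iter: int = 100, seed: int = 0, variant: str = "imfo",
                    n_pop: int = 20,
                    evaluator: FitnessEvaluator | None = None) -> SelectionResult:
    """Run the full (I)MFO wrapper selection loop.

    Each iteration: binarize the population (sigmoid mean-gate for IMFO,
    fixed 0.5 gate for MFO), evaluate, merge into the elitist flame set,
    spiral-update the positions and — for IMFO — apply the entropy gate to
    the updated positions and re-evaluate.  The best-ever gate is returned;
    its recorded fitness history is non-increasing by construction.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    fm = features if isinstance(features, FeatureMatrix) else FeatureMatrix(X, labels)
    if cfg is None:
        cfg = FitnessConfig()
    if evaluator is None:
        evaluator = FitnessEvaluator(fm, labels, cfg)
    dim = X.shape[1]
    rng = np.random.default_rng(seed + 1)
    state = initialize_population(n_pop, dim, seed, evaluator, variant=variant)
    state.best_fitness_history.append(state.best_fitness)

    for _ in range(n_iter):
        update_moths(state, n_iter, rng=rng)
        gates = _variant_gates(state.positions, variant)
        fitness = np.array([evaluator(g) for g in gates])
        if variant == "imfo":
            e_gates = entropy_gate(state.positions)
            e_fitness = np.array([evaluator(g) for g in e_gates])
            better = e_fitness < fitness
            gates = np.where(better[:, None], e_gates, gates)
            fitness = np.where(better, e_fitness, fitness)
        state.gates = gates
        _merge_flames(state, state.positions, fitness, gates, n_pop)
        state.best_fitness_history.append(state.best_fitness)

    best_gate = state.best_gate
    if best_gate is None or not best_gate.any():
        # No informative gate was ever found; fall back to all features.
        best_gate = np.ones(dim, dtype=np.uint8)
    selected = np.flatnonzero(best_gate)
    return SelectionResult(
        selected_indices=selected,
        reduced_matrix=fm.select_columns(selected),
        final_fitness=float(state.best_fitness),
        iterations_run=state.iteration,
        seed=seed,
        fitness_history=list(state.best_fitness_history),
        variant=variant,
    )


def exhaustive_oracle(features, labels, cfg: FitnessConfig,
                      evaluator: FitnessEvaluator | None = None):
    """Evaluate the frozen fitness on all nonempty gates (dim <= 15).

    Returns (best_gate, best_fitness) with ties broken toward the
    lexicographically smallest gate vector.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    dim = X.shape[1]
    if dim > 15:
        raise ValueError("exhaustive search is guarded to dim <= 15")
    if cfg.r_mode != "fixed":
        raise ValueError("the oracle requires a frozen fitness (r_mode='fixed')")
    if evaluator is None:
        evaluator = FitnessEvaluator(features, labels, cfg)
    best_gate, best_fit = None, math.inf
    for g in range(1, 2 ** dim):
        gate = np.array([(g >> (dim - 1 - j)) & 1 for j in range(dim)], dtype=np.uint8)
        fit = evaluator(gate)
        if fit < best_fit:
            best_gate, best_fit = gate, fit
    return best_gate, float(best_fit)
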