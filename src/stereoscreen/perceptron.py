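"""Single-unit perceptron fusion of the four screening scores.

A weighted sum of the four condition scores (optionally through a logistic
sigmoid) yields one screening variable; low output means pathologic, high
means normal. Two trainers are provided:

* **Simulated annealing** on a contingency-table objective: classify by the
  weighted sum at a threshold, and minimise
  (1 - sensitivity)^2 + (1 - specificity)^2. Candidate weights are Gaussian
  perturbations of the current configuration; a worse candidate is accepted
  with the Boltzmann probability exp((F_old - F_new) / T) under geometric
  cooling.

* **Damped least squares (Levenberg-Marquardt style)** on a logistic-sigmoid
  output against 0/1 targets (0 = pathologic, 1 = normal), with uniform
  input jitter each epoch as a regulariser, random uniform [0, 1]
  initialisation, and a random 75/25 train/validation split per run.

The input-significance analysis trains every non-empty subset of the four
inputs (15 scenarios) over repeated reinitialised runs and compares the
validation-AUC distributions pairwise.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special, stats

from .evalstats import optimal_point, roc_auc

N_INPUTS = 4
SCORE_MAX = 5.0
INPUT_NAMES = ("S8", "D1", "D07", "D1N")


class Transfer(str, enum.Enum):
    LINEAR = "linear"
    LOGSIG = "logsig"


class CombineMode(str, enum.Enum):
    SUM = "sum"   # equal-weight sum, 0-20
    W = "w"       # weights optimised for amblyopia
    AW = "aw"     # weights optimised for all pathologic conditions


@dataclass
class PerceptronModel:
    weights: np.ndarray
    bias: float = 0.0
    transfer: Transfer = Transfer.LINEAR
    decision_threshold: float = 0.5
    input_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if self.input_mask is None:
            self.input_mask = np.ones_like(self.weights, dtype=bool)
        else:
            self.input_mask = np.asarray(self.input_mask, dtype=bool)

    def to_json(self, path: str | Path, **provenance) -> None:
        payload = {"weights": self.weights.tolist(), "bias": self.bias,
                   "transfer": self.transfer.value,
                   "decision_threshold": self.decision_threshold,
                   "input_mask": self.input_mask.tolist(), **provenance}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PerceptronModel":
        d = json.loads(Path(path).read_text())
        return cls(weights=np.array(d["weights"]), bias=d["bias"],
                   transfer=Transfer(d["transfer"]),
                   decision_threshold=d["decision_threshold"],
                   input_mask=np.array(d["input_mask"], dtype=bool))


def _logsig(z):
    return special.expit(z)


def forward(model: PerceptronModel, x) -> np.ndarray | float:
    """Network output for one score vector or a matrix of them.

    Low output indicates pathology, high output its absence.
    """
    x = np.asarray(x, dtype=float)
    w = np.where(model.input_mask, model.weights, 0.0)
    if x.shape[-1] != w.shape[0]:
        raise ValueError("input dimension does not match the weights")
    z = x @ w + model.bias
    out = _logsig(z) if model.transfer is Transfer.LOGSIG else z
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def combined_score(x, mode: CombineMode | str = CombineMode.SUM,
                   model: PerceptronModel | None = None) -> np.ndarray | float:
    """Combined screening score on the 0-20 scale.

    SUM is the plain addition of the four scores; W / AW rescale the
    weighted sum by its maximum attainable value (all scores at 5) onto
    [0, 20].
    """
    mode = CombineMode(mode)
    x = np.asarray(x, dtype=float)
    if mode is CombineMode.SUM:
        out = x.sum(axis=-1)
    else:
        if model is None:
            raise ValueError(f"mode {mode.value!r} requires a trained model")
        w = np.where(model.input_mask, model.weights, 0.0)
        max_attainable = float(np.abs(w).sum() * SCORE_MAX)
        if max_attainable == 0:
            raise ValueError("all-zero weights cannot be rescaled")
        out = (x @ w) / max_attainable * 20.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Simulated annealing on the sensitivity/specificity objective


@dataclass
class SATrainerConfig:
    initial_temperature: float = 1.0
    cooling_factor: float = 0.995
    proposal_sd: float = 0.2
    max_iterations: int = 5000
    threshold_mode: str = "roc"     # "roc" or "fixed"
    fixed_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass
class SAState:
    iteration: int
    temperature: float
    objective: float
    best_objective: float


def sens_spec_objective(weights, threshold: float, X, y_pathologic) -> float:
    """(1 - sensitivity)^2 + (1 - specificity)^2 of the thresholded weighted
    sum; a subject is called pathologic when the sum is at or below the
    threshold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_pathologic, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("dataset must contain both classes")
    s = X @ np.asarray(weights, dtype=float)
    called = s <= threshold
    sens = called[y].mean()
    spec = (~called[~y]).mean()
    return float((1.0 - sens) ** 2 + (1.0 - spec) ** 2)


def _youden_threshold(s: np.ndarray, y: np.ndarray) -> float:
    """Fast Youden-optimal cut of a raw score (pathologic called at s <= t),
    ties broken toward higher sensitivity."""
    thresholds = np.unique(s)
    path = np.sort(s[y])
    norm = np.sort(s[~y])
    sens = np.searchsorted(path, thresholds, side="right") / len(path)
    spec = 1.0 - np.searchsorted(norm, thresholds, side="right") / len(norm)
    j = sens + spec - 1.0
    best = np.lexsort((spec, sens, j))[-1]
    return float(thresholds[best])


def _objective_at_roc_optimum(weights, X, y) -> tuple[float, float]:
    s = X @ np.asarray(weights, dtype=float)
    if np.ptp(s) == 0:
        return sens_spec_objective(weights, s[0], X, y), float(s[0])
    thr = _youden_threshold(s, y)
    return sens_spec_objective(weights, thr, X, y), thr


def sa_optimize(X, y_pathologic, config: SATrainerConfig | None = None
                ) -> tuple[PerceptronModel, list[SAState]]:
    """Simulated-annealing search for the fusion weights.

    Proposes Gaussian perturbations of the current weight vector, cools the
    temperature geometrically, always accepts improvements and accepts
    regressions with probability exp((F_old - F_new) / T). Returns the
    best-so-far configuration as a LINEAR model whose decision threshold is
    the Youden-optimal cut of its weighted score.
    """
    config = config or SATrainerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_pathologic, dtype=bool)
    rng = np.random.default_rng(config.seed)
    current = rng.uniform(0, 1, size=X.shape[1])

    def evaluate(w):
        if config.threshold_mode == "roc":
            return _objective_at_roc_optimum(w, X, y)
        return (sens_spec_objective(w, config.fixed_threshold, X, y),
                config.fixed_threshold)

    f_current, thr_current = evaluate(current)
    best_w, f_best, thr_best = current.copy(), f_current, thr_current
    temperature = config.initial_temperature
    trace: list[SAState] = []
    for it in range(config.max_iterations):
        candidate = current + rng.normal(0.0, config.proposal_sd,
                                         size=current.shape)
        temperature *= config.cooling_factor
        f_candidate, thr_candidate = evaluate(candidate)
        accept = f_candidate < f_current or (
            rng.random() < np.exp((f_current - f_candidate)
                                  / max(temperature, 1e-300)))
        if accept:
            current, f_current, thr_current = candidate, f_candidate, thr_candidate
            if f_current < f_best:
                best_w, f_best, thr_best = current.copy(), f_current, thr_current
        trace.append(SAState(iteration=it, temperature=temperature,
                             objective=f_current, best_objective=f_best))
        if f_best == 0.0:
            break
    model = PerceptronModel(weights=best_w, transfer=Transfer.LINEAR,
                            decision_threshold=thr_best)
    return model, trace


# ---------------------------------------------------------------------------
# Damped least-squares (LM-style) training of the logsig unit


@dataclass
class GradientTrainerConfig:
    train_fraction: float = 0.75
    noise_margin: float = 0.03          # fraction of the score range
    init_range: tuple[float, float] = (0.0, 1.0)
    n_runs: int = 100
    max_epochs: int = 200
    convergence_tolerance: float = 1e-8
    initial_damping: float = 1e-2
    # trust-region cap on one update's norm; keeps a single early step from
    # throwing the unit into irrecoverable sigmoid saturation
    max_step_norm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


@dataclass
class TrainingReport:
    model: PerceptronModel
    objective_trajectory: list[float]
    train_auc: float
    validation_auc: float
    input_subset: tuple[int, ...]
    run_index: int
    seed: int
    converged: bool


def _split_sizes(n: int, train_fraction: float) -> int:
    # round half up: 0.75 * 182 = 136.5 -> 137 training vectors
    return int(np.floor(n * train_fraction + 0.5))


def _auc_normal_positive(outputs: np.ndarray, y_pathologic: np.ndarray) -> float:
    # AUC of the output for separating the classes; orientation-free summary
    return roc_auc(outputs, y_pathologic, higher_is_normal=True).auc


def gradient_train(X, y_pathologic, subset: tuple[int, ...] | None = None,
                   config: GradientTrainerConfig | None = None,
                   run_index: int = 0, seed: int | None = None) -> TrainingReport:
    """One damped-Gauss-Newton training run of the logsig unit.

    Targets are 0 for pathologic and 1 for normal subjects. Each epoch the
    training inputs are jittered with uniform noise of half-width
    ``noise_margin`` times the score range, then one Levenberg-Marquardt
    step on the sum of squared residuals is attempted; the damping factor is
    divided by 10 on success and multiplied by 10 on failure.
    """
    config = config or GradientTrainerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_pathologic, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("dataset must contain both classes")
    subset = tuple(range(X.shape[1])) if subset is None else tuple(subset)
    if not subset:
        raise ValueError("input subset must be non-empty")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n = len(y)
    n_train = _split_sizes(n, config.train_fraction)
    perm = rng.permutation(n)
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    Xs = X[:, subset]
    target = (~y).astype(float)          # 1 = normal, 0 = pathologic

    k = len(subset)
    lo, hi = config.init_range
    theta = rng.uniform(lo, hi, size=k + 1)   # weights + bias
    damping = config.initial_damping
    jitter_halfwidth = config.noise_margin * SCORE_MAX

    def residuals(th, A, t):
        z = A[:, :k] @ th[:k] + th[k]
        return _logsig(z) - t, _logsig(z)

    trajectory: list[float] = []
    converged = False
    Xtr, ttr = Xs[train_idx], target[train_idx]
    for _ in range(config.max_epochs):
        A = Xtr + rng.uniform(-jitter_halfwidth, jitter_halfwidth, Xtr.shape)
        r, yhat = residuals(theta, A, ttr)
        sse = float(r @ r)
        trajectory.append(sse)
        # Jacobian of the residuals wrt (weights, bias)
        g = yhat * (1.0 - yhat)
        J = np.column_stack([A * g[:, None], g])
        JtJ = J.T @ J
        Jtr = J.T @ r
        stepped = False
        for _attempt in range(8):
            try:
                # Marquardt diagonal scaling plus a Levenberg identity floor:
                # the floor bounds the step when the unit saturates and the
                # Jacobian (hence diag(JtJ)) collapses toward zero
                delta = np.linalg.solve(
                    JtJ + damping * (np.diag(np.diag(JtJ)) + np.eye(k + 1)),
                    -Jtr)
            except np.linalg.LinAlgError:
                damping *= 10
                continue
            norm = float(np.linalg.norm(delta))
            if norm > config.max_step_norm:
                delta = delta * (config.max_step_norm / norm)
            r_new, _ = residuals(theta + delta, A, ttr)
            if float(r_new @ r_new) < sse:
                theta = theta + delta
                damping = max(damping / 10, 1e-12)
                stepped = True
                break
            damping *= 10
        if not stepped:
            converged = True
            break
        if len(trajectory) >= 2 and abs(trajectory[-2] - trajectory[-1]) \
                < config.convergence_tolerance:
            converged = True
            break

    weights = np.zeros(X.shape[1])
    mask = np.zeros(X.shape[1], dtype=bool)
    weights[list(subset)] = theta[:k]
    mask[list(subset)] = True
    model = PerceptronModel(weights=weights, bias=float(theta[k]),
                            transfer=Transfer.LOGSIG, input_mask=mask)
    out_train = forward(model, X[train_idx])
    out_val = forward(model, X[val_idx])

    def safe_auc(outputs, idx):
        ysub = y[idx]
        if ysub.all() or not ysub.any():
            return float("nan")
        return _auc_normal_positive(outputs, ysub)

    return TrainingReport(model=model, objective_trajectory=trajectory,
                          train_auc=safe_auc(out_train, train_idx),
                          validation_auc=safe_auc(out_val, val_idx),
                          input_subset=subset, run_index=run_index,
                          seed=seed, converged=converged)


def all_input_subsets(n_inputs: int = N_INPUTS) -> list[tuple[int, ...]]:
    """All non-empty input subsets: 15 scenarios for four inputs
    (4 singles, 6 pairs, 4 triplets, 1 full set)."""
    subsets: list[tuple[int, ...]] = []
    for r in range(1, n_inputs + 1):
        subsets.extend(itertools.combinations(range(n_inputs), r))
    return subsets


@dataclass
class SignificanceResult:
    auc_by_subset: dict[tuple[int, ...], list[float]]
    pairwise_p: np.ndarray               # raw t-test p-values, subsets x subsets
    pairwise_p_adjusted: np.ndarray      # Bonferroni by the full matrix size
    subsets: list[tuple[int, ...]]

    def subset_label(self, subset: tuple[int, ...]) -> str:
        return "+".join(INPUT_NAMES[i] for i in subset)

    def tidy(self):
        import pandas as pd
        rows = [{"subset": self.subset_label(s), "run": i, "auc": a}
                for s in self.subsets
                for i, a in enumerate(self.auc_by_subset[s])]
        return pd.DataFrame(rows)


def input_significance(X, y_pathologic,
                       config: GradientTrainerConfig | None = None
                       ) -> SignificanceResult:
    """Validation-AUC distributions for all 15 input subsets.

    Per subset, ``n_runs`` independent trainings with fresh initialisation
    and a fresh random train/validation split; the pairwise matrix holds
    two-sample t-test p-values Bonferroni-corrected by the full matrix size
    (15 x 15)."""
    config = config or GradientTrainerConfig()
    subsets = all_input_subsets(np.asarray(X).shape[1])
    master = np.random.default_rng(config.seed)
    auc_by_subset: dict[tuple[int, ...], list[float]] = {}
    for subset in subsets:
        aucs = []
        for run in range(config.n_runs):
            run_seed = int(master.integers(2**31))
            rep = gradient_train(X, y_pathologic, subset, config,
                                 run_index=run, seed=run_seed)
            aucs.append(rep.validation_auc)
        auc_by_subset[subset] = aucs
    k = len(subsets)
    raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(auc_by_subset[subsets[i]])
            b = np.asarray(auc_by_subset[subsets[j]])
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) > 1 and len(b) > 1 and (a.std() > 0 or b.std() > 0):
                raw[i, j] = raw[j, i] = stats.ttest_ind(a, b).pvalue
            elif len(a) and len(b) and np.mean(a) == np.mean(b):
                raw[i, j] = raw[j, i] = 1.0
            else:
                raw[i, j] = raw[j, i] = 0.0
    adjusted = np.minimum(1.0, raw * k * k)
    return SignificanceResult(auc_by_subset=auc_by_subset, pairwise_p=raw,
                              pairwise_p_adjusted=adjusted, subsets=subsets)


@dataclass
class OverfittingSummary:
    train_mean: float
    train_sd: float
    validation_mean: float
    validation_sd: float
    t_statistic: float
    p: float


def overfitting_check(reports: list[TrainingReport]) -> OverfittingSummary:
    """Two-sample t-test of train vs validation AUC over repeated runs;
    a non-significant difference argues against overfitting."""
    if len(reports) < 2:
        raise ValueError("need at least two training reports")
    tr = np.array([r.train_auc for r in reports])
    va = np.array([r.validation_auc for r in reports])
    tr, va = tr[~np.isnan(tr)], va[~np.isnan(va)]
    if np.array_equal(tr, va):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(tr, va)
    return OverfittingSummary(train_mean=float(tr.mean()),
                              train_sd=float(tr.std(ddof=1)),
                              validation_mean=float(va.mean()),
                              validation_sd=float(va.std(ddof=1)),
                              t_statistic=float(t), p=float(p))
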