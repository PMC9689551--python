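"""Bayesian hyperparameter optimization over the training-recipe space.

Sequential model-based search: after a random warm-up phase, a Gaussian
process surrogate (Matern 5/2 kernel) is fit to the evaluated points and
the next candidate maximizes expected improvement over the incumbent.
Continuous dimensions spanning several decades (learning rate, gamma,
weight decay, all on [1e-5, 0.1]) are sampled and modeled on a log10
scale; categorical dimensions (optimizer choice) are one-hot encoded and
ordinal dimensions (step_size) are index-scaled to [0, 1].

The search maximizes the objective (validation accuracy); failed trials
score -inf and the search continues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = [
    "FloatDim",
    "CategoricalDim",
    "OrdinalDim",
    "SearchSpace",
    "Trial",
    "HPOResult",
    "default_space",
    "optimize",
    "tune_and_train",
]


@dataclass(frozen=True)
class FloatDim:
    """Continuous dimension; log=True samples/encodes log10-uniformly."""

    name: str
    low: float
    high: float
    log: bool = True

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")

    def sample(self, rng):
        if self.log:
            return float(10 ** rng.uniform(math.log10(self.low), math.log10(self.high)))
        return float(rng.uniform(self.low, self.high))

    def encode(self, v):
        if self.log:
            lo, hi = math.log10(self.low), math.log10(self.high)
            return [(math.log10(v) - lo) / (hi - lo)]
        return [(v - self.low) / (self.high - self.low)]

    def contains(self, v):
        return self.low <= v <= self.high

    @property
    def width(self):
        return 1


@dataclass(frozen=True)
class CategoricalDim:
    name: str
    choices: tuple

    def sample(self, rng):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, v):
        out = [0.0] * len(self.choices)
        out[self.choices.index(v)] = 1.0
        return out

    def contains(self, v):
        return v in self.choices

    @property
    def width(self):
        return len(self.choices)


@dataclass(frozen=True)
class OrdinalDim:
    """Ordered discrete choices (e.g. step_size grid), index-scaled."""

    name: str
    choices: tuple

    def sample(self, rng):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, v):
        i = self.choices.index(v)
        return [i / max(1, len(self.choices) - 1)]

    def contains(self, v):
        return v in self.choices

    @property
    def width(self):
        return 1


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple

    def sample(self, rng) -> dict:
        return {d.name: d.sample(rng) for d in self.dims}

    def encode(self, params: dict) -> np.ndarray:
        vec = []
        for d in self.dims:
            vec.extend(d.encode(params[d.name]))
        return np.asarray(vec)

    def contains(self, params: dict) -> bool:
        return all(d.contains(params[d.name]) for d in self.dims)

    def __iter__(self):
        return iter(self.dims)


def default_space(model_family: str = "CNN") -> SearchSpace:
    """Search space per model family.

    CNN family: optimizer {SGD, Adam}; learning_rate, gamma, weight_decay
    in [1e-5, 0.1]; step_size in {10, 15, 20, 25, 30}. The BPNN variant
    adds a hidden-layer width in {10, 12, ..., 24}, uses step_size in
    {600, 800, 1000, 1200, 1400}, and has no weight decay.
    """
    if model_family == "CNN":
        return SearchSpace((
            CategoricalDim("optimizer", ("SGD", "Adam")),
            FloatDim("learning_rate", 1e-5, 0.1),
            OrdinalDim("step_size", (10, 15, 20, 25, 30)),
            FloatDim("gamma", 1e-5, 0.1),
            FloatDim("weight_decay", 1e-5, 0.1),
        ))
    if model_family == "BPNN":
        return SearchSpace((
            OrdinalDim("hidden", (10, 12, 14, 16, 18, 20, 22, 24)),
            CategoricalDim("optimizer", ("SGD", "Adam")),
            FloatDim("learning_rate", 1e-5, 0.1),
            OrdinalDim("step_size", (600, 800, 1000, 1200, 1400)),
            FloatDim("gamma", 1e-5, 0.1),
        ))
    raise ValueError(f"unknown model family {model_family!r}; choose CNN or BPNN")


@dataclass
class Trial:
    index: int
    params: dict
    value: float  # objective (validation accuracy); -inf for failed trials
    failed: bool = False


@dataclass
class HPOResult:
    trials: list[Trial] = field(default_factory=list)

    @property
    def best(self) -> Trial:
        ok = [t for t in self.trials if not t.failed]
        if not ok:
            raise RuntimeError("all trials failed")
        return max(ok, key=lambda t: t.value)

    @property
    def best_so_far(self) -> list[float]:
        """Running maximum of the objective, -inf until the first success."""
        out, cur = [], -np.inf
        for t in self.trials:
            if not t.failed:
                cur = max(cur, t.value)
            out.append(cur)
        return out

    def to_dataframe(self):
        import pandas as pd

        rows = [{"trial": t.index, **t.params, "objective": t.value,
                 "failed": t.failed} for t in self.trials]
        return pd.DataFrame(rows)


def _expected_improvement(mu, sigma, incumbent, xi=0.01):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - incumbent - xi) / sigma
    return (mu - incumbent - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def optimize(objective, space: SearchSpace, n_trials: int, seed: int = 0,
             n_warmup: int = 10, n_candidates: int = 512) -> HPOResult:
    """Maximize `objective` over `space` with GP + expected improvement.

    The first `n_warmup` trials are random; afterwards a GP is refit on
    all successful trials and the point with the highest expected
    improvement among `n_candidates` random proposals is evaluated next.
    A trial whose objective raises is marked failed (value -inf) and the
    search continues; if every trial fails the search errors.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    result = HPOResult()
    X_ok: list[np.ndarray] = []
    y_ok: list[float] = []

    for i in range(n_trials):
        if i < n_warmup or len(X_ok) < 2:
            params = space.sample(rng)
        else:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(length_scale=np.ones(len(X_ok[0])),
                                                    nu=2.5),
                alpha=1e-6, normalize_y=True, optimizer="fmin_l_bfgs_b",
                n_restarts_optimizer=0, random_state=0,
            )
            with warnings.catch_warnings():
                # surrogate quality is insensitive to running the kernel
                # hyperparameter optimizer to full convergence
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.vstack(X_ok), np.asarray(y_ok))
            cands = [space.sample(rng) for _ in range(n_candidates)]
            enc = np.vstack([space.encode(c) for c in cands])
            mu, sigma = gp.predict(enc, return_std=True)
            ei = _expected_improvement(mu, sigma, max(y_ok))
            params = cands[int(np.argmax(ei))]
        try:
            value = float(objective(params))
            trial = Trial(i, params, value)
            X_ok.append(space.encode(params))
            y_ok.append(value)
        except Exception:
            trial = Trial(i, params, -np.inf, failed=True)
        result.trials.append(trial)
    result.best  # raises if every trial failed
    return result


def tune_and_train(plan, X_train, y_train, X_val, y_val, space: SearchSpace,
                   n_trials: int, seed: int = 0, epochs_per_trial: int = 5,
                   batch_size: int = 64, n_warmup: int = 10):
    """Search the space with validation accuracy as the objective, then
    retrain with the best hyperparameters.

    Each trial builds a fresh model from `plan`, trains it for
    `epochs_per_trial` epochs with the sampled recipe and scores the best
    validation accuracy reached. Returns (HPOResult, final model, final
    history)."""
    from . import arch
    from .train import HyperParams, train_model

    def make_hp(params: dict) -> HyperParams:
        return HyperParams(
            optimizer=params["optimizer"],
            learning_rate=params["learning_rate"],
            step_size=int(params["step_size"]),
            gamma=params["gamma"],
            weight_decay=params["weight_decay"],
            batch_size=batch_size,
            epochs=epochs_per_trial,
        )

    def objective(params: dict) -> float:
        model = arch.build_model(plan, rng=np.random.default_rng(seed))
        _, best = train_model(model, X_train, y_train, make_hp(params),
                              rng=np.random.default_rng(seed + 1),
                              X_val=X_val, y_val=y_val)
        return best["val_acc"]

    result = optimize(objective, space, n_trials, seed=seed, n_warmup=n_warmup)
    final_model = arch.build_model(plan, rng=np.random.default_rng(seed))
    history, best = train_model(final_model, X_train, y_train,
                                make_hp(result.best.params),
                                rng=np.random.default_rng(seed + 1),
                                X_val=X_val, y_val=y_val)
    final_model.load_state_dict(best["state"])
    return result, final_model, history
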