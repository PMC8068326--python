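"""Bayesian optimization of the detail-coefficient mapping constants.

The search space is the box a, b, c in [0, 0.1], d in [0.001, 1] crossed with
a categorical wavelet choice (haar, sym2, db2, bior1.3).  Optimization runs in
two phases: seeded uniform random exploration, then a Gaussian-process
surrogate (Matérn-5/2 kernel) with the expected-improvement acquisition.  The
categorical dimension is handled by maintaining one surrogate per wavelet and
proposing the point/wavelet combination with the largest expected improvement,
avoiding any fake metric structure between unrelated wavelets.

Every run is reproducible from its seed and fully recorded in a
:class:`BOTrace` that can be serialized for replay and audit.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .dataset import FoldAssignment, LabeledDataset
from .swt import SUPPORTED_WAVELETS, MappingParams

__all__ = [
    "SearchDomain",
    "BOTrace",
    "bayes_optimize",
    "objective_from_pipeline",
]


@dataclass(frozen=True)
class SearchDomain:
    """Box constraints for the mapping constants plus the wavelet choices."""

    a: tuple[float, float] = (0.0, 0.1)
    b: tuple[float, float] = (0.0, 0.1)
    c: tuple[float, float] = (0.0, 0.1)
    d: tuple[float, float] = (0.001, 1.0)
    wavelets: tuple[str, ...] = SUPPORTED_WAVELETS

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")
        unknown = set(self.wavelets) - set(SUPPORTED_WAVELETS)
        if unknown or not self.wavelets:
            raise ValueError(f"unsupported wavelets {sorted(unknown)}")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=np.float64)

    def sample(self, rng: np.random.Generator) -> MappingParams:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        x = rng.uniform(lo, hi)
        wavelet = self.wavelets[rng.integers(len(self.wavelets))]
        return MappingParams(*x, wavelet=wavelet)

    def to_unit(self, params: MappingParams) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (np.array([params.a, params.b, params.c, params.d]) - lo) / (hi - lo)

    def from_unit(self, u: np.ndarray, wavelet: str) -> MappingParams:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        x = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
        return MappingParams(*x, wavelet=wavelet)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d,
                "wavelets": list(self.wavelets)}


@dataclass
class Iteration:
    """One evaluated (or failed) point of the optimization trace."""

    params: MappingParams
    value: float | None
    phase: str  # "random" or "bayes"
    failed: bool = False


@dataclass
class BOTrace:
    """Ordered record of an optimization run."""

    iterations: list[Iteration] = field(default_factory=list)
    seed: int = 0
    domain: SearchDomain = field(default_factory=SearchDomain)

    def __len__(self) -> int:
        return len(self.iterations)

    @property
    def best_values(self) -> list[float]:
        """Running maximum of the objective along the trace (non-decreasing)."""
        best = -math.inf
        out = []
        for it in self.iterations:
            if not it.failed and it.value is not None:
                best = max(best, it.value)
            out.append(best)
        return out

    @property
    def best(self) -> Iteration:
        ok = [it for it in self.iterations if not it.failed and it.value is not None]
        if not ok:
            raise RuntimeError("no successful iterations")
        return max(ok, key=lambda it: it.value)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "domain": self.domain.to_dict(),
            "iterations": [
                {
                    "params": {"a": it.params.a, "b": it.params.b, "c": it.params.c,
                               "d": it.params.d, "wavelet": it.params.wavelet},
                    "value": it.value,
                    "phase": it.phase,
                    "failed": it.failed,
                }
                for it in self.iterations
            ],
        }
        with open(os.fspath(path), "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "BOTrace":
        with open(os.fspath(path)) as fh:
            d = json.load(fh)
        dom = d["domain"]
        domain = SearchDomain(tuple(dom["a"]), tuple(dom["b"]), tuple(dom["c"]),
                              tuple(dom["d"]), tuple(dom["wavelets"]))
        trace = cls(seed=d["seed"], domain=domain)
        for rec in d["iterations"]:
            p = rec["params"]
            trace.iterations.append(
                Iteration(MappingParams(p["a"], p["b"], p["c"], p["d"], p["wavelet"]),
                          rec["value"], rec["phase"], rec["failed"])
            )
        return trace


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          xi: float = 0.01) -> np.ndarray:
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def _fit_gp(x: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(x.shape[1], 0.3),
                 length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  n_restarts_optimizer=1,
                                  random_state=seed)
    with warnings.catch_warnings():
        # hyperparameters pinned at their bounds are acceptable for a surrogate
        warnings.simplefilter("ignore")
        gp.fit(x, y)
    return gp


def bayes_optimize(
    objective,
    domain: SearchDomain | None = None,
    n_random: int = 25,
    n_bayes: int = 20,
    seed: int = 0,
) -> BOTrace:
    """Maximize ``objective(params)`` over the search domain.

    Phase 1 draws ``n_random`` seeded uniform samples; phase 2 runs ``n_bayes``
    steps of GP/expected-improvement proposals (one surrogate per wavelet;
    the proposal is the candidate with the largest EI across wavelets,
    maximized by multi-start random + local perturbation search over the box).
    Objective exceptions mark the iteration failed; the surrogate skips it.
    """
    if domain is None:
        domain = SearchDomain()
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    rng = np.random.default_rng(seed)
    trace = BOTrace(seed=seed, domain=domain)

    def evaluate(params: MappingParams, phase: str) -> None:
        try:
            value = float(objective(params))
            if not np.isfinite(value):
                raise ValueError(f"objective returned non-finite value {value!r}")
            trace.iterations.append(Iteration(params, value, phase))
        except Exception:  # noqa: BLE001 - recorded as failed, surrogate skips it
            trace.iterations.append(Iteration(params, None, phase, failed=True))

    for _ in range(n_random):
        evaluate(domain.sample(rng), "random")

    successes = [it for it in trace.iterations if not it.failed]
    if n_bayes > 0 and not successes:
        raise RuntimeError("all random-phase evaluations failed; cannot start surrogate phase")

    for step in range(n_bayes):
        ok = [it for it in trace.iterations if not it.failed]
        best_val = max(it.value for it in ok)
        best_proposal: tuple[float, MappingParams] | None = None
        for wavelet in domain.wavelets:
            obs = [it for it in ok if it.params.wavelet == wavelet]
            # candidate pool: uniform + perturbations of the wavelet's best point
            cand = rng.random((192, 4))
            if obs:
                inc = domain.to_unit(max(obs, key=lambda it: it.value).params)
                local = np.clip(inc + 0.05 * rng.standard_normal((64, 4)), 0.0, 1.0)
                cand = np.vstack([cand, local])
            if len(obs) >= 2:
                x = np.vstack([domain.to_unit(it.params) for it in obs])
                y = np.array([it.value for it in obs])
                gp = _fit_gp(x, y, seed=(seed + step) % (2**31 - 1))
                mu, sd = gp.predict(cand, return_std=True)
                ei = _expected_improvement(mu, sd, best_val)
            else:
                # too few points for a surrogate: treat all candidates as
                # maximally uncertain (pure exploration for this wavelet)
                ei = np.full(len(cand), np.inf)
            j = int(np.argmax(ei))
            score = float(ei[j])
            if best_proposal is None or score > best_proposal[0]:
                best_proposal = (score, domain.from_unit(cand[j], wavelet))
        evaluate(best_proposal[1], "bayes")

    return trace


def objective_from_pipeline(
    dataset: LabeledDataset,
    model,
    folds: FoldAssignment,
):
    """Closure evaluating mapping constants by the full grading pipeline.

    Given ``params`` it enhances every image, runs the augment/train/score
    cycle on each fold (training folds augmented, test fold untouched) and
    returns the fold-mean micro-averaged AUC — the quantity the tuner
    monitors.
    """
    from .harness import run_classification_cv

    def objective(params: MappingParams) -> float:
        report = run_classification_cv(dataset, model, params=params, folds=folds)
        return report.mean("auc_micro")

    return objective
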