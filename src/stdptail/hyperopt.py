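"""Bayesian optimization of STDP hyperparameters against the BG index.

The BG index is a test-set-independent proxy for generalization error:
it is computed from the training trajectory alone, so minimizing it
searches for hyperparameters that generalize well without ever touching
test data.  The optimizer is standard sequential model-based optimization
(SMBO): a Gaussian-process surrogate (Matern-5/2 kernel) is fit to the
evaluated configurations and the expected-improvement acquisition

    EI(x) = (f_min - mu(x)) Phi(z) + sd(x) phi(z),   z = (f_min - mu)/sd

is maximized over the search space to pick the next configuration, where
``f_min`` is the best objective value observed so far and Phi/phi are the
standard normal CDF/density.

The objective cross-validates: the training stream is split into K
folds, one network is trained per fold, and the mean BG index over folds
is returned.  Divergent or unresponsive runs score a fixed penalty of
2.0 — the upper bound of the BG index — so failures are maximally
unattractive without distorting the objective's scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from . import training as tr
from .config import ExperimentConfig, desk_config, network_stdp_config
from .encoding import train_test_split
from .experiments import load_dataset, repeat_stream
from .heavytail import bg_index
from .lif import NeuronParams, build_network
from .training import TrainSchedule

__all__ = [
    "Dimension",
    "SearchSpace",
    "BORun",
    "default_search_space",
    "expected_improvement",
    "objective",
    "propose_next",
    "smbo_loop",
    "PENALTY_BG",
]

PENALTY_BG = 2.0  # BG upper bound; scored for divergent/unresponsive runs


@dataclass(frozen=True)
class Dimension:
    """One hyperparameter domain: continuous, log-scaled, or integer."""

    name: str
    low: float
    high: float
    kind: str = "float"  # float | log | int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.low >= self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.kind not in ("float", "log", "int"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires low > 0")

    def to_unit(self, value: float) -> float:
        if self.kind == "log":
            return (math.log(value) - math.log(self.low)) / (
                math.log(self.high) - math.log(self.low)
            )
        return (value - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.kind == "log":
            v = math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low)))
        else:
            v = self.low + u * (self.high - self.low)
        if self.kind == "int":
            v = int(round(v))
            v = int(min(max(v, self.low), self.high))
        return v


@dataclass
class SearchSpace:
    """Ordered collection of dimensions; maps to/from the unit cube."""

    dimensions: list

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")

    @property
    def names(self):
        return [d.name for d in self.dimensions]

    def __len__(self) -> int:
        return len(self.dimensions)

    def to_unit(self, cfg: dict) -> np.ndarray:
        return np.array([d.to_unit(cfg[d.name]) for d in self.dimensions])

    def from_unit(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(float(x)) for d, x in zip(self.dimensions, u)}

    def sample(self, rng: np.random.Generator) -> dict:
        return self.from_unit(rng.random(len(self)))


def default_search_space() -> SearchSpace:
    """The log-STDP optimization domain.

    eta in [0.05, 0.2] (log-scaled), noise sigma in [0.1, 1], integer
    saturation degree S in [1, 10] and LTP decay gamma in [10, 100],
    fixed-point weight W0 in (0, 1], both scaling amplitudes in (0, 1],
    and the window constants tau+ in [10, 20] ms, tau- in [20, 40] ms.
    Lower edges of the nominally half-open domains are clamped strictly
    positive so every sampled configuration is valid.
    """
    return SearchSpace([
        Dimension("eta", 0.05, 0.2, "log"),
        Dimension("sigma", 0.1, 1.0),
        Dimension("S", 1, 10, "int"),
        Dimension("gamma", 10, 100, "int"),
        Dimension("W0", 0.01, 1.0),
        Dimension("c_plus", 0.01, 1.0),
        Dimension("c_minus", 0.01, 1.0),
        Dimension("tau_plus", 10.0, 20.0),
        Dimension("tau_minus", 20.0, 40.0),
    ])


@dataclass
class BORun:
    """Full record of one optimization run."""

    space: SearchSpace
    configs: list = field(default_factory=list)
    values: list = field(default_factory=list)
    aux: list = field(default_factory=list)  # per-evaluation diagnostics
    incumbent_trace: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def f_min(self) -> float:
        return float(np.min(self.values))

    @property
    def incumbent(self) -> dict:
        return self.configs[int(np.argmin(self.values))]

    def record(self, cfg: dict, value: float, aux: dict | None = None) -> None:
        self.configs.append(cfg)
        self.values.append(float(value))
        self.aux.append(aux or {})
        self.incumbent_trace.append(self.f_min)


def expected_improvement(mu, sd, f_min):
    """Closed-form EI for minimization; sd = 0 collapses to max(f_min - mu, 0)."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (sd < 0).any():
        raise ValueError("sd must be >= 0")
    improve = f_min - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(
        sd > 0,
        improve * stats.norm.cdf(z) + sd * stats.norm.pdf(z),
        np.maximum(improve, 0.0),
    )
    return ei if ei.shape else float(ei)


def objective(
    lambda_cfg: dict,
    base: ExperimentConfig | None = None,
    K_folds: int = 2,
    seed: int = 0,
    record_train_accuracy: bool = True,
):
    """Mean BG index of STDP hyperparameters over K cross-validation folds.

    Each fold trains a fresh network on its share of the training stream
    and measures the BG index of the learning trajectory; no test data is
    touched.  Returns ``(mean_bg, aux)`` with per-fold values and, when
    requested, the training accuracy of each fold (logged so the
    generalizability-trainability tradeoff is plottable afterwards).
    """
    if K_folds < 2:
        raise ValueError("K_folds must be >= 2")
    base = base or desk_config("log", seed=seed)
    stdp_doc = dict(base.stdp)
    stdp_doc.update(lambda_cfg)
    rule = stdp_doc.pop("rule", "log")
    try:
        stdp_cfg = network_stdp_config(rule, **stdp_doc)
    except ValueError as err:
        return PENALTY_BG, {"status": f"invalid config: {err}", "folds": []}

    dataset = load_dataset(base)
    train_set, _ = train_test_split(dataset, base.dataset.test_fraction, seed=base.seed)
    exc_params = NeuronParams.excitatory(**base.neuron)
    inh_params = NeuronParams.inhibitory()
    schedule = TrainSchedule(**base.schedule)

    n = len(train_set)
    fold_ids = np.arange(n) % K_folds
    bgs, aux_folds = [], []
    for k in range(K_folds):
        fold = train_set.subset(np.flatnonzero(fold_ids == k))
        stream = repeat_stream(
            fold, base.dataset.n_train_presentations // K_folds, seed=seed + 11 * k
        )
        topo = build_network(
            dataset.n_pixels, base.network.n_exc,
            fixed_weights=(base.network.w_ei, base.network.w_ie),
            init_seed=seed + 17 * k + 1,
            w_min=base.network.w_min, w_max=base.network.w_max,
        )
        try:
            run = tr.train(stream, topo, exc_params, inh_params, stdp_cfg,
                           schedule, seed=seed + 23 * k + 2)
            n_inc = run.trajectory.snapshots.shape[0] - 1
            bg = bg_index(run.trajectory, last_k=min(3, n_inc)).bg_index
        except Exception as err:  # divergence scores the penalty, not an exception
            bgs.append(PENALTY_BG)
            aux_folds.append({"fold": k, "status": f"{type(err).__name__}: {err}"})
            continue
        entry = {"fold": k, "bg": bg, "status": "ok"}
        if record_train_accuracy:
            sub = fold.subset(np.arange(0, len(fold), 5))
            class_map = tr.assign_classes(run, sub, seed=seed + 3)
            entry["train_accuracy"] = tr.accuracy(run, class_map, sub, seed=seed + 4)
        bgs.append(bg)
        aux_folds.append(entry)
    return float(np.mean(bgs)), {"folds": aux_folds, "status": "ok"}


def _fit_surrogate(X: np.ndarray, y: np.ndarray) -> GaussianProcessRegressor:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(X.shape[1], 0.3),
        length_scale_bounds=(1e-2, 1e2),
        nu=2.5,
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=1e-6, normalize_y=True, n_restarts_optimizer=1,
        random_state=0,
    )
    with warnings.catch_warnings():
        # few-point fits routinely stop the kernel optimizer early; harmless
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def propose_next(
    surrogate: GaussianProcessRegressor,
    space: SearchSpace,
    rng: np.random.Generator,
    f_min: float,
    incumbent_u: np.ndarray | None = None,
    n_candidates: int = 512,
    flat: bool = False,
):
    """Maximize EI over the unit cube by multi-start candidate search.

    Candidates are uniform draws plus Gaussian perturbations of the
    incumbent; integer dimensions are rounded at evaluation time.  With a
    flat surrogate (all observed values equal) the proposal falls back to
    a uniform random draw, flagged to the caller.
    """
    if flat:
        return space.sample(rng), True
    U = rng.random((n_candidates, len(space)))
    if incumbent_u is not None:
        local = np.clip(
            incumbent_u[None, :] + rng.normal(0, 0.1, (n_candidates // 4, len(space))),
            0.0, 1.0,
        )
        U = np.vstack([U, local])
    # snap integer dims so the surrogate scores what will actually run
    for j, dim in enumerate(space.dimensions):
        if dim.kind == "int":
            U[:, j] = np.array([dim.to_unit(dim.from_unit(u)) for u in U[:, j]])
    mu, sd = surrogate.predict(U, return_std=True)
    ei = expected_improvement(mu, sd, f_min)
    best = int(np.argmax(ei))
    if ei[best] <= 0:
        return space.sample(rng), True
    return space.from_unit(U[best]), False


def smbo_loop(
    space: SearchSpace,
    objective_fn,
    n_init: int = 5,
    budget: int = 15,
    seed: int = 0,
) -> BORun:
    """Latin-hypercube initialization followed by EI-driven refinement.

    ``objective_fn(cfg: dict) -> float`` or ``-> (float, aux)``.  Penalty
    values (>= PENALTY_BG) are kept in the run record but excluded from
    surrogate fitting beyond a small cap so a run of failures cannot
    flatten the model.
    """
    if not budget >= n_init >= 2:
        raise ValueError("need budget >= n_init >= 2")
    rng = np.random.default_rng(seed)
    run = BORun(space=space)

    sampler = qmc.LatinHypercube(d=len(space), seed=int(rng.integers(2**31 - 1)))
    for u in sampler.random(n=n_init):
        cfg = space.from_unit(u)
        run.record(cfg, *_eval(objective_fn, cfg))

    while len(run.values) < budget:
        X = np.array([space.to_unit(c) for c in run.configs])
        y = np.array(run.values)
        keep = _surrogate_mask(y)
        flat = np.allclose(y[keep], y[keep][0])
        if flat:
            run.flags.append(f"flat surrogate at evaluation {len(y)}; random fallback")
            cfg, _ = propose_next(None, space, rng, np.inf, flat=True)
        else:
            gp = _fit_surrogate(X[keep], y[keep])
            incumbent_u = X[int(np.argmin(y))]
            cfg, fellback = propose_next(gp, space, rng, run.f_min, incumbent_u)
            if fellback:
                run.flags.append(f"EI degenerate at evaluation {len(y)}; random fallback")
        run.record(cfg, *_eval(objective_fn, cfg))
    return run


def _eval(objective_fn, cfg):
    out = objective_fn(cfg)
    if isinstance(out, tuple):
        return out[0], out[1]
    return out, {}


def _surrogate_mask(y: np.ndarray, max_penalties: int = 3) -> np.ndarray:
    """Keep all clean values and at most ``max_penalties`` penalty scores."""
    keep = np.ones(len(y), dtype=bool)
    penal = np.flatnonzero(y >= PENALTY_BG)
    if len(penal) > max_penalties:
        keep[penal[max_penalties:]] = False
    if not keep.any():
        keep[:] = True
    return keep
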