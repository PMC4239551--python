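"""Maximum-likelihood fitting of birth-death-gain models.

Fitting maximizes the ascertainment-corrected dataset log-likelihood over
log-transformed parameters (positivity by construction) with a
deterministic quasi-Newton optimizer (L-BFGS-B).  The outer convergence
rule mirrors the staged protocol: iteration stops when the increase in
ln L between consecutive accepted iterates falls below ``tol_lnl``
(default 0.01).

Models are fitted in stages of increasing complexity (C → L → FL2 → FL3 by
default), each stage initialized by embedding the previous stage's optimum,
which substantially stabilizes the high-dimensional fits.

The primary interface is :class:`BirthDeathGainModel`, a scikit-learn style
estimator; :func:`fit_model` and :func:`staged_fit` are functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .likelihood import PruningEngine, _stable_sum
from .models import (ModelParams, ModelSpec, embed, information_criteria,
                     parameter_count)
from .profiles import ProfileSet
from .tree import SpeciesTree

__all__ = ["FitResult", "StagePlan", "BirthDeathGainModel", "fit_model",
           "staged_fit", "DEFAULT_PLAN_SPECS"]

_RATE_BOUNDS = (1e-7, 50.0)
_PHI_BOUNDS = (1e-8, 200.0)
_SHAPE_BOUNDS = (1e-2, 1e6)


@dataclass
class FitResult:
    """Outcome of one model fit."""

    spec: ModelSpec
    params: ModelParams
    loglik: float
    aic: float
    bic: float
    m: int
    n: int
    iterations: int
    converged: bool
    trace: list[float] = field(default_factory=list)
    message: str = ""

    def summary(self) -> dict:
        return {
            "model": self.spec.name,
            "loglik": self.loglik,
            "m": self.m,
            "n": self.n,
            "aic": self.aic,
            "bic": self.bic,
            "iterations": self.iterations,
            "converged": self.converged,
        }


@dataclass
class StagePlan:
    """Ordered nested model specs plus optimizer settings."""

    specs: list[ModelSpec]
    tol_lnl: float = 0.01
    max_iter: int = 10_000
    init_shape: float = 1.0
    degenerate_start: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.specs, self.specs[1:]):
            if not a.nests_in(b):
                raise ValueError(f"stage {a.name} is not nested in {b.name}")


def DEFAULT_PLAN_SPECS() -> list[ModelSpec]:
    """C → L → FL2 → FL3."""
    return [ModelSpec.constant(), ModelSpec.lineage(),
            ModelSpec.family_lineage(2), ModelSpec.family_lineage(3)]


# ----------------------------------------------------------------------
# Parameter vector layout (log-scale free parameters per model spec)
# ----------------------------------------------------------------------

class _Layout:
    def __init__(self, spec: ModelSpec, tree: SpeciesTree):
        self.spec = spec
        self.tree = tree
        nb = tree.n_branches
        names: list[str] = []
        bounds: list[tuple[float, float]] = []
        blab = tree.branch_labels()
        if spec.model_class in ("C", "FO"):
            names += ["lam", "mu", "kap"]
            bounds += [_RATE_BOUNDS] * 3
        else:
            free = ("lam", "mu", "kap") if spec.normalization == "unit_time" \
                else ("t", "lam", "kap")
            for p in free:
                names += [f"{p}[{lbl}]" for lbl in blab]
                bounds += [_RATE_BOUNDS] * nb
        names.append("phi")
        bounds.append(_PHI_BOUNDS)
        self._shape_slots = [p for p in range(4) if spec.categories[p] > 1]
        for p in self._shape_slots:
            names.append(f"shape_{('t', 'lam', 'mu', 'kap')[p]}")
            bounds.append(_SHAPE_BOUNDS)
        self.names = names
        self.log_bounds = [(np.log(lo), np.log(hi)) for lo, hi in bounds]
        self.size = len(names)

    def pack(self, params: ModelParams) -> np.ndarray:
        spec, nb = self.spec, self.tree.n_branches
        vals: list[float] = []
        if spec.model_class in ("C", "FO"):
            vals += [params.lam_b[0], params.mu_b[0], params.kap_b[0]]
        elif spec.normalization == "unit_time":
            vals += [*params.lam_b, *params.mu_b, *params.kap_b]
        else:
            vals += [*params.t_b, *params.lam_b, *params.kap_b]
        vals.append(params.phi)
        vals += [params.shapes[p] for p in self._shape_slots]
        x = np.log(np.asarray(vals, dtype=float))
        lo = np.array([b[0] for b in self.log_bounds])
        hi = np.array([b[1] for b in self.log_bounds])
        return np.clip(x, lo, hi)

    def unpack(self, x: np.ndarray) -> ModelParams:
        spec, nb = self.spec, self.tree.n_branches
        v = np.exp(np.asarray(x, dtype=float))
        i = 0
        ones = np.ones(nb)
        if spec.model_class in ("C", "FO"):
            lam, mu, kap = v[0], v[1], v[2]
            t_b, lam_b = ones.copy(), np.full(nb, lam)
            mu_b, kap_b = np.full(nb, mu), np.full(nb, kap)
            i = 3
        elif spec.normalization == "unit_time":
            t_b = ones.copy()
            lam_b = v[i:i + nb]; i += nb
            mu_b = v[i:i + nb]; i += nb
            kap_b = v[i:i + nb]; i += nb
        else:
            t_b = v[i:i + nb]; i += nb
            lam_b = v[i:i + nb]; i += nb
            kap_b = v[i:i + nb]; i += nb
            mu_b = ones.copy()
        phi = float(v[i]); i += 1
        shapes = np.ones(4)
        for p in self._shape_slots:
            shapes[p] = v[i]; i += 1
        return ModelParams(spec, t_b=t_b, lam_b=lam_b, mu_b=mu_b, kap_b=kap_b,
                           phi=phi, shapes=shapes)


# ----------------------------------------------------------------------

def _fit(engine: PruningEngine, counts: np.ndarray, n: int, spec: ModelSpec,
         init: ModelParams, tol_lnl: float, max_iter: int) -> FitResult:
    tree = engine.tree
    layout = _Layout(spec, tree)
    x0 = layout.pack(init)

    def neg_loglik(x: np.ndarray) -> float:
        params = layout.unpack(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # frozen per-family truncation buckets; re-audited at the end
            ll = engine.family_logliks(params, counts, grow=False)
        total = _stable_sum(ll)
        if not np.isfinite(total):
            return 1e12  # off-manifold penalty; keeps the optimizer NaN-free
        return -total

    trace: list[float] = []
    state = {"best": -neg_loglik(x0)}
    trace.append(state["best"])
    if not np.isfinite(state["best"]) or state["best"] <= -1e11:
        raise FloatingPointError(
            "objective is non-finite at the initial point; check the data "
            "and initial parameters"
        )

    def callback(intermediate_result):
        lnl = max(-float(intermediate_result.fun), state["best"])
        improvement = lnl - state["best"]
        state["best"] = lnl
        trace.append(lnl)
        if improvement < tol_lnl:
            raise StopIteration

    res = minimize(neg_loglik, x0, method="L-BFGS-B",
                   bounds=layout.log_bounds, callback=callback,
                   options={"maxiter": max_iter, "maxfun": 200 * max_iter})
    x_hat = res.x if -res.fun >= trace[0] else x0
    params_hat = layout.unpack(x_hat)
    # re-audited evaluation at the optimum (truncation bound may grow)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loglik = _stable_sum(engine.family_logliks(params_hat, counts))
    iterations = len(trace) - 1
    converged = (len(trace) < 2) or (trace[-1] - trace[-2] < tol_lnl)
    if iterations >= max_iter:
        converged = False
    m = parameter_count(spec, tree)
    aic, bic = information_criteria(loglik, m, n)
    return FitResult(spec=spec, params=params_hat, loglik=loglik, aic=aic,
                     bic=bic, m=m, n=n, iterations=iterations,
                     converged=converged, trace=trace,
                     message=str(res.message))


def fit_model(data: ProfileSet, tree: SpeciesTree, spec: ModelSpec,
              init: ModelParams | None = None, ascertainment: bool = True,
              tol_lnl: float = 0.01, max_iter: int = 10_000) -> FitResult:
    """Fit one model by likelihood maximization (functional interface)."""
    est = BirthDeathGainModel(tree=tree, model=spec.model_class,
                              categories=spec.categories,
                              normalization=spec.normalization,
                              ascertainment=ascertainment, tol_lnl=tol_lnl,
                              max_iter=max_iter, init=init)
    est.fit(data)
    return est.result_


def staged_fit(data: ProfileSet, tree: SpeciesTree,
               plan: StagePlan | None = None, ascertainment: bool = True,
               ) -> list[FitResult]:
    """Fit a nested sequence of models, warm-starting each from the last.

    A stage that fails is recorded with a failure message and skipped; later
    stages start from the last successful stage's embedding.
    """
    if plan is None:
        plan = StagePlan(DEFAULT_PLAN_SPECS())
    engine = PruningEngine(tree, ascertainment=ascertainment)
    counts = data.matrix_for(tree)
    results: list[FitResult] = []
    prev: FitResult | None = None
    for spec in plan.specs:
        if prev is None:
            init = ModelParams.initial(spec, tree, shape=plan.init_shape)
        else:
            init = embed(prev.spec, prev.params, spec,
                         init_shape=plan.init_shape,
                         degenerate_start=plan.degenerate_start)
        try:
            res = _fit(engine, counts, data.n, spec, init,
                       plan.tol_lnl, plan.max_iter)
            results.append(res)
            prev = res
        except Exception as exc:  # stage failure does not abort the plan
            results.append(FitResult(
                spec=spec, params=init, loglik=float("nan"),
                aic=float("nan"), bic=float("nan"),
                m=parameter_count(spec, tree), n=data.n, iterations=0,
                converged=False, message=f"stage failed: {exc}"))
    return results


# ----------------------------------------------------------------------
# scikit-learn estimator
# ----------------------------------------------------------------------

class BirthDeathGainModel(BaseEstimator):
    """Phylogenetic birth-death-gain model as a scikit-learn estimator.

    Parameters
    ----------
    tree : SpeciesTree or str
        Rooted binary species tree (or its Newick string).
    model : {"C", "L", "FL", "FO"}
        Model class: Constant, Lineage, Family-Lineage, Family-Only.
    categories : int or 4-tuple of int
        Family rate categories per parameter (duration, expansion, loss,
        gain); scalars broadcast.  Must be 1 for the C and L classes.
    normalization : {"unit_time", "unit_loss"}
        Which branch parameter is fixed at 1: branch durations (default,
        free loss rates) or loss rates (free durations).
    ascertainment : bool
        Condition each family likelihood on presence in at least one leaf.
    tol_lnl : float
        Stop when the increase in ln L between accepted iterates is below
        this (default 0.01).
    max_iter : int
        Outer iteration cap (default 10,000).
    init : ModelParams, optional
        Warm start (e.g. an embedded simpler-model optimum).

    Attributes
    ----------
    params_ : ModelParams
        Fitted branch components, gamma shapes, and root mean Φ.
    loglik_, aic_, bic_ : float
    n_iter_ : int
    converged_ : bool
    trace_ : list of float
        ln L at each accepted iterate (non-decreasing).
    result_ : FitResult

    Examples
    --------
    >>> from bdgain import BirthDeathGainModel, simulate
    >>> tree, config = simulate.make_study_fixture(seed=0)
    >>> data = simulate.simulate_dataset(config).profiles
    >>> model = BirthDeathGainModel(tree=tree, model="C").fit(data)
    >>> model.loglik_  # doctest: +SKIP
    """

    def __init__(self, tree=None, model: str = "C", categories=1,
                 normalization: str = "unit_time", ascertainment: bool = True,
                 tol_lnl: float = 0.01, max_iter: int = 10_000,
                 init: ModelParams | None = None, init_shape: float = 1.0,
                 tail_tolerance: float = 1e-8, max_bound: int = 128):
        self.tree = tree
        self.model = model
        self.categories = categories
        self.normalization = normalization
        self.ascertainment = ascertainment
        self.tol_lnl = tol_lnl
        self.max_iter = max_iter
        self.init = init
        self.init_shape = init_shape
        self.tail_tolerance = tail_tolerance
        self.max_bound = max_bound

    # -- helpers --------------------------------------------------------
    def _tree(self) -> SpeciesTree:
        if isinstance(self.tree, SpeciesTree):
            return self.tree
        if isinstance(self.tree, str):
            return SpeciesTree.from_newick(self.tree)
        raise ValueError("tree must be a SpeciesTree or a Newick string")

    def _spec(self) -> ModelSpec:
        cats = self.categories
        if np.isscalar(cats):
            cats = (int(cats),) * 4
        return ModelSpec(self.model, tuple(cats), self.normalization)

    def _as_profiles(self, X) -> ProfileSet:
        if isinstance(X, ProfileSet):
            return X
        if isinstance(X, pd.DataFrame):
            return ProfileSet.from_dataframe(X)
        arr = np.asarray(X)
        tree = self._tree()
        if arr.ndim != 2 or arr.shape[1] != tree.n_leaves:
            raise ValueError(
                f"X must have one column per tree leaf ({tree.n_leaves})"
            )
        return ProfileSet(arr.astype(np.int64),
                          [f"F{i}" for i in range(arr.shape[0])],
                          tree.leaf_names)

    def _engine(self, tree: SpeciesTree) -> PruningEngine:
        return PruningEngine(tree, ascertainment=self.ascertainment,
                             tail_tolerance=self.tail_tolerance,
                             max_bound=self.max_bound)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None) -> "BirthDeathGainModel":
        """Estimate parameters by likelihood maximization on profiles X."""
        tree = self._tree()
        spec = self._spec()
        data = self._as_profiles(X)
        engine = self._engine(tree)
        counts = data.matrix_for(tree)
        init = self.init if self.init is not None else \
            ModelParams.initial(spec, tree, shape=self.init_shape)
        if init.spec != spec:
            init = embed(init.spec, init, spec, init_shape=self.init_shape)
        result = _fit(engine, counts, data.n, spec, init,
                      self.tol_lnl, self.max_iter)
        self.tree_ = tree
        self.engine_ = engine
        self.result_ = result
        self.params_ = result.params
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.trace_ = result.trace
        self.n_features_in_ = tree.n_leaves
        return self

    def score(self, X, y=None) -> float:
        """Mean per-family corrected log-likelihood under the fitted model."""
        data = self._as_profiles(X)
        counts = data.matrix_for(self.tree_)
        ll = self.engine_.family_logliks(self.params_, counts)
        return float(np.mean(ll))

    def score_samples(self, X) -> np.ndarray:
        """Per-family corrected log-likelihoods under the fitted model."""
        data = self._as_profiles(X)
        counts = data.matrix_for(self.tree_)
        return self.engine_.family_logliks(self.params_, counts)

    # -- second pass ------------------------------------------------------
    def predict_ancestral(self, X):
        """Posterior expected ancestral family sizes (families × nodes)."""
        from .events import ancestral_posterior
        data = self._as_profiles(X)
        rows = []
        for prof in data:
            post = ancestral_posterior(self.tree_, self.params_, prof,
                                       ascertainment=self.ascertainment)
            rows.append(post.expected_sizes)
        return pd.DataFrame(rows, index=data.family_ids)

    def predict_events(self, X):
        """Expected per-branch event counts aggregated over families."""
        from .events import aggregate_events
        data = self._as_profiles(X)
        return aggregate_events(self.tree_, self.params_, data,
                                ascertainment=self.ascertainment)
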