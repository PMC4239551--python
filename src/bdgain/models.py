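"""Nested model family for birth-death-gain inference.

Four model classes of increasing complexity are supported:

* **C** (Constant): one rate triple (λ*, µ*, κ*) shared by every branch and
  family, plus the root mean Φ — 4 parameters.
* **L** (Lineage): branch-specific rates (λ_b, µ_b, κ_b) — 3|B| + 1
  parameters.
* **FL** (Family-Lineage): each parameter is a product of a branch component
  and a family component; the family components of branch time, expansion,
  loss and gain each follow a mean-1 discretized gamma law with c equal-
  probability categories — 4c + 3|B| + 1 reported parameters.
* **FO** (Family-Only): family components over a single constant branch
  component — 4c + 4 reported parameters.

Model nesting (C ⊂ L ⊂ FL, C ⊂ FO ⊂ FL) supports staged estimation: each
model's optimum seeds the next via :func:`embed`.

Normalization: one branch parameter per branch is redundant against the
others; by default branch times are fixed at t_b = 1 with free loss rates
(``unit_time``), with the alternative µ_b = 1, free t_b (``unit_loss``)
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .core import BranchRates
from .tree import SpeciesTree

__all__ = [
    "FamilyRateLaw",
    "ModelSpec",
    "ModelParams",
    "discretize_gamma",
    "parameter_count",
    "information_criteria",
    "embed",
]

# Family-component order used throughout: (duration, expansion, loss, gain).
FAMILY_PARAMS = ("duration", "expansion", "loss", "gain")

#: Gamma shape at which the family law is numerically degenerate (all
#: category multipliers ≈ 1); used for "degenerate start" initialization.
DEGENERATE_SHAPE = 1e4


def discretize_gamma(shape: float, categories: int) -> np.ndarray:
    """Category multipliers of a mean-1 gamma law with equal-probability slices.

    The law Gamma(shape α, scale 1/α) has mean 1.  It is cut at its
    c-quantiles into c slices of probability 1/c each, and each category's
    multiplier is the conditional mean of its slice.  For the mean-1
    parametrization the conditional mean of slice (a, b] is
    c · [F_{α+1}(b) − F_{α+1}(a)] where F_{α+1} is the cdf of
    Gamma(α + 1, 1/α), so the multipliers average to exactly 1.

    Returns an increasing vector of length ``categories`` renormalized so its
    simple average is 1 to full precision.
    """
    if shape <= 0 or not np.isfinite(shape):
        raise ValueError(f"gamma shape must be positive and finite, got {shape!r}")
    c = int(categories)
    if c < 1:
        raise ValueError("categories must be >= 1")
    if c == 1:
        return np.array([1.0])
    scale = 1.0 / shape
    edges = gamma_dist.ppf(np.arange(1, c) / c, shape, scale=scale)
    if not np.all(np.isfinite(edges)):
        raise ValueError(
            f"gamma quantiles not computable at shape={shape!r}, c={c}"
        )
    cdf_hi = gamma_dist.cdf(np.concatenate([edges, [np.inf]]), shape + 1, scale=scale)
    cdf_lo = gamma_dist.cdf(np.concatenate([[0.0], edges]), shape + 1, scale=scale)
    mult = c * (cdf_hi - cdf_lo)
    mean = mult.mean()
    if mean <= 0 or not np.isfinite(mean):
        raise ValueError(f"degenerate discretization at shape={shape!r}, c={c}")
    return mult / mean


@dataclass(frozen=True)
class FamilyRateLaw:
    """Discretized mean-1 gamma law for one family-specific parameter."""

    shape: float
    categories: int

    def multipliers(self) -> np.ndarray:
        return discretize_gamma(self.shape, self.categories)


_CLASSES = ("C", "L", "FL", "FO")
# Nesting partial order: embed(a -> b) is legal when rank[a] <= rank[b] and
# the pair is on a chain (C ⊂ L ⊂ FL; C ⊂ FO ⊂ FL).  L and FO are not nested
# in each other.
_NESTS_IN = {
    "C": {"C", "L", "FL", "FO"},
    "L": {"L", "FL"},
    "FO": {"FO", "FL"},
    "FL": {"FL"},
}


@dataclass(frozen=True)
class ModelSpec:
    """Which nested model to fit, and how its parameters are counted.

    ``categories`` gives the family-component category count per parameter in
    the order (duration, expansion, loss, gain); e.g. the uniform 2-category
    family-lineage model is ``FL (2, 2, 2, 2)`` and the mixed model with four
    loss categories is ``FL (2, 2, 4, 2)``.
    """

    model_class: str
    categories: tuple[int, int, int, int] = (1, 1, 1, 1)
    normalization: str = "unit_time"

    def __post_init__(self) -> None:
        if self.model_class not in _CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.normalization not in ("unit_time", "unit_loss"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        cats = tuple(int(c) for c in self.categories)
        if len(cats) != 4 or any(c < 1 for c in cats):
            raise ValueError("categories must be 4 positive integers")
        object.__setattr__(self, "categories", cats)
        if self.model_class in ("C", "L") and any(c != 1 for c in cats):
            raise ValueError(f"{self.model_class} model admits no family categories")

    # -- constructors ---------------------------------------------------
    @classmethod
    def constant(cls, **kw) -> "ModelSpec":
        return cls("C", (1, 1, 1, 1), **kw)

    @classmethod
    def lineage(cls, **kw) -> "ModelSpec":
        return cls("L", (1, 1, 1, 1), **kw)

    @classmethod
    def family_lineage(cls, categories: int | tuple = 2, **kw) -> "ModelSpec":
        if np.isscalar(categories):
            categories = (categories,) * 4
        return cls("FL", tuple(categories), **kw)

    @classmethod
    def family_only(cls, categories: int | tuple = 2, **kw) -> "ModelSpec":
        if np.isscalar(categories):
            categories = (categories,) * 4
        return cls("FO", tuple(categories), **kw)

    # -------------------------------------------------------------------
    @property
    def has_family_variation(self) -> bool:
        return any(c > 1 for c in self.categories)

    @property
    def n_combinations(self) -> int:
        """K: number of family rate-category combinations."""
        return int(np.prod(self.categories))

    def nests_in(self, other: "ModelSpec") -> bool:
        if other.model_class not in _NESTS_IN[self.model_class]:
            return False
        if self.model_class == other.model_class:
            return all(a <= b for a, b in zip(self.categories, other.categories))
        return True

    @property
    def name(self) -> str:
        if self.model_class in ("C", "L"):
            return self.model_class
        cats = self.categories
        if len(set(cats)) == 1:
            return f"{self.model_class}{cats[0]}"
        return self.model_class + "".join(str(c) for c in cats)


def parameter_count(spec: ModelSpec, tree: SpeciesTree) -> int:
    """Reported free-parameter count m used for AIC/BIC.

    C: 4.  L: 3|B| + 1.  FL: Σc + 3|B| + 1 (4c + 3|B| + 1 at uniform c).
    FO: Σc + 4 (4c + 4 at uniform c).  The family-category counts enter the
    reported m directly; the internally optimized free parameters (gamma
    shapes rather than per-category values) are exposed separately via
    :func:`internal_parameter_count`.
    """
    b = tree.n_branches
    csum = sum(spec.categories)
    if spec.model_class == "C":
        return 4
    if spec.model_class == "L":
        return 3 * b + 1
    if spec.model_class == "FL":
        return csum + 3 * b + 1
    return csum + 4  # FO


def internal_parameter_count(spec: ModelSpec, tree: SpeciesTree) -> int:
    """Number of free parameters actually optimized (gamma-shape accounting)."""
    n_shapes = sum(1 for c in spec.categories if c > 1)
    if spec.model_class == "C":
        return 4
    if spec.model_class == "FO":
        return 4 + n_shapes
    return 3 * tree.n_branches + 1 + n_shapes


def information_criteria(loglik: float, m: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) = (2m − 2 lnL, m ln n − 2 lnL)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = 2.0 * m - 2.0 * loglik
    bic = m * math.log(n) - 2.0 * loglik
    return aic, bic


# ----------------------------------------------------------------------
# Parameter container
# ----------------------------------------------------------------------

@dataclass
class ModelParams:
    """Concrete parameter values for a :class:`ModelSpec` on a given tree.

    Branch components are stored densely (one value per branch in post-order)
    for every model class; under the C and FO classes all entries of each
    array are equal.  ``shapes`` holds the gamma shapes of the four family
    laws in the order (duration, expansion, loss, gain); entries for
    parameters with a single category are inert.
    """

    spec: ModelSpec
    t_b: np.ndarray
    lam_b: np.ndarray
    mu_b: np.ndarray
    kap_b: np.ndarray
    phi: float
    shapes: np.ndarray = field(default_factory=lambda: np.ones(4))

    @classmethod
    def initial(cls, spec: ModelSpec, tree: SpeciesTree,
                lam: float = 0.3, mu: float = 0.5, kap: float = 0.2,
                phi: float = 1.0, shape: float = 1.0) -> "ModelParams":
        b = tree.n_branches
        t = np.ones(b)
        if spec.normalization == "unit_loss":
            return cls(spec, t_b=t.copy(), lam_b=np.full(b, lam),
                       mu_b=np.ones(b), kap_b=np.full(b, kap), phi=phi,
                       shapes=np.full(4, float(shape)))
        return cls(spec, t_b=t, lam_b=np.full(b, lam), mu_b=np.full(b, mu),
                   kap_b=np.full(b, kap), phi=phi, shapes=np.full(4, float(shape)))

    def family_multipliers(self) -> list[np.ndarray]:
        """Category multipliers for (duration, expansion, loss, gain)."""
        return [discretize_gamma(self.shapes[p], self.spec.categories[p])
                for p in range(4)]

    def branch_rates(self, node: int, tree: SpeciesTree,
                     mult: tuple[float, float, float, float] = (1, 1, 1, 1),
                     ) -> BranchRates:
        """Effective rates on the branch above ``node``, scaled by family
        multipliers (t_f, λ_f, µ_f, κ_f)."""
        # post-order puts the root last, so branch position == node index
        b = tree.branch_nodes.index(node) if node >= tree.root else node
        return BranchRates(
            duration=self.t_b[b] * mult[0],
            expansion_rate=self.lam_b[b] * mult[1],
            loss_rate=self.mu_b[b] * mult[2],
            gain_rate=self.kap_b[b] * mult[3],
        )

    def rates_list(self) -> list[BranchRates]:
        """BranchRates per branch in post-order (family multipliers = 1)."""
        return [BranchRates(self.t_b[i], self.lam_b[i], self.mu_b[i], self.kap_b[i])
                for i in range(len(self.t_b))]

    def copy(self) -> "ModelParams":
        return ModelParams(self.spec, self.t_b.copy(), self.lam_b.copy(),
                           self.mu_b.copy(), self.kap_b.copy(), self.phi,
                           self.shapes.copy())


def embed(spec_from: ModelSpec, params: ModelParams, spec_to: ModelSpec,
          init_shape: float = 1.0, degenerate_start: bool = False,
          ) -> ModelParams:
    """Initial parameters for ``spec_to`` from a fit of the nested ``spec_from``.

    Branch components carry over directly (C's constant triple is already
    replicated per branch).  Family laws absent in ``spec_from`` are
    initialized at ``init_shape`` (or at a numerically degenerate shape when
    ``degenerate_start`` is set, so the embedded point's likelihood matches
    the simpler optimum to within discretization round-off).
    """
    if not spec_from.nests_in(spec_to):
        raise ValueError(f"{spec_from.name} is not nested in {spec_to.name}")
    out = params.copy()
    out.spec = spec_to
    shape0 = DEGENERATE_SHAPE if degenerate_start else float(init_shape)
    shapes = params.shapes.copy()
    for p in range(4):
        if spec_from.categories[p] == 1 and spec_to.categories[p] > 1:
            shapes[p] = shape0
    out.shapes = shapes
    return out


def branch_rates_table(params: ModelParams, tree: SpeciesTree):
    """Per-branch parameter table (branch label, t, λ, µ, κ) in post-order."""
    import pandas as pd

    return pd.DataFrame(
        {
            "branch": tree.branch_labels(),
            "duration": params.t_b,
            "expansion_rate": params.lam_b,
            "loss_rate": params.mu_b,
            "gain_rate": params.kap_b,
        }
    )
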