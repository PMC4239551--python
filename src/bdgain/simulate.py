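"""Forward simulation of phylogenetic profiles under the birth-death-gain
process, with recorded true histories.

Each family draws a root count from Poisson(Φ) and evolves down every branch
by exact jump-process (Gillespie) sampling of the linear birth-death chain
with gain: from state i the next event is a birth at rate λ·i + κ or a death
at rate µ·i, with exponential waiting times, until the branch duration is
exhausted.  Because the simulator samples paths rather than endpoint
kernels, it is an independent oracle for the matrix-exponential kernels of
the likelihood code.

Family-rate heterogeneity: multipliers (t_f, λ_f, µ_f, κ_f) can be drawn
either from continuous gamma laws (for model-misspecification experiments)
or from the discrete category law the inference uses (exact-model
experiments).  Recorded per-branch event labels are endpoint-defined, with
the same categories the posterior pass uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BranchRates, RootPrior
from .models import FamilyRateLaw, discretize_gamma
from .profiles import PhyloProfile, ProfileSet
from .tree import SpeciesTree

__all__ = ["SimConfig", "SimFamily", "SimDataset", "simulate_family",
           "simulate_dataset", "simulate_branch", "make_study_fixture",
           "STUDY_NEWICK"]

#: Six-genome study topology: fly sister to the vertebrates, worm outgroup.
STUDY_NEWICK = "(((((Human,Mouse),Chick),DanRe),DroMe),CaeEl);"

_HARD_CAP = 10 ** 6


@dataclass
class SimConfig:
    """Generating conditions for a synthetic profile dataset.

    ``family_laws`` optionally maps each of (duration, expansion, loss,
    gain) to a law for family multipliers: either ``("gamma", shape)`` for
    continuous mean-1 gamma draws or ``("categories", shape, c)`` for draws
    from the c discrete category means the inference model uses.  Absent
    laws mean multiplier 1 (pure lineage model).
    """

    tree: SpeciesTree
    branch_rates: list[BranchRates]
    root_mean: float = 1.0
    n_families: int = 100
    ascertainment: bool = True
    family_laws: dict[str, tuple] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if len(self.branch_rates) != self.tree.n_branches:
            raise ValueError("need one BranchRates per branch (post-order)")
        RootPrior(self.root_mean)  # validates >= 0


@dataclass
class SimFamily:
    """One simulated family with its full true history."""

    profile: PhyloProfile
    node_states: dict[str, int]
    branch_events: dict[str, str]
    multipliers: tuple[float, float, float, float]


@dataclass
class SimDataset:
    profiles: ProfileSet
    families: list[SimFamily]
    n_rejected: int = 0

    def truth_table(self) -> pd.DataFrame:
        """Sidecar of true node states and endpoint event labels per family."""
        rows = []
        for fam in self.families:
            row: dict[str, object] = {"family_id": fam.profile.family_id}
            row.update({f"state[{k}]": v for k, v in fam.node_states.items()})
            row.update({f"event[{k}]": v for k, v in fam.branch_events.items()})
            for name, v in zip(("t_f", "lam_f", "mu_f", "kap_f"),
                               fam.multipliers):
                row[name] = v
            rows.append(row)
        return pd.DataFrame(rows)


def classify_endpoint(parent: int, child: int) -> str:
    """Endpoint event label for a branch: gain 0→≥1, loss ≥1→0,
    expansion y>x≥1, contraction x>y≥1, else stasis."""
    if parent == 0 and child >= 1:
        return "gain"
    if parent >= 1 and child == 0:
        return "loss"
    if child > parent >= 1:
        return "expansion"
    if parent > child >= 1:
        return "contraction"
    return "stasis"


def simulate_branch(state: int, rates: BranchRates,
                    rng: np.random.Generator) -> int:
    """Evolve one count down one branch by exact jump sampling."""
    t_left = rates.duration
    i = int(state)
    lam, mu, kap = rates.expansion_rate, rates.loss_rate, rates.gain_rate
    while True:
        total = lam * i + kap + mu * i
        if total <= 0:
            return i
        wait = rng.exponential(1.0 / total)
        if wait >= t_left:
            return i
        t_left -= wait
        if rng.random() < (lam * i + kap) / total:
            i += 1
            if i > _HARD_CAP:
                raise RuntimeError(
                    f"runaway growth: count exceeded {_HARD_CAP} at rates {rates}"
                )
        else:
            i -= 1


def _draw_multipliers(config: SimConfig,
                      rng: np.random.Generator) -> tuple[float, ...]:
    laws = config.family_laws or {}
    out = []
    for name in ("duration", "expansion", "loss", "gain"):
        law = laws.get(name)
        if law is None:
            out.append(1.0)
        elif law[0] == "gamma":
            shape = float(law[1])
            out.append(float(rng.gamma(shape, 1.0 / shape)))
        elif law[0] == "categories":
            _, shape, c = law
            if int(c) == 1:
                out.append(1.0)  # degenerate law: no rng draw consumed
            else:
                mult = discretize_gamma(float(shape), int(c))
                out.append(float(mult[rng.integers(0, int(c))]))
        else:
            raise ValueError(f"unknown family law {law!r}")
    return tuple(out)


def simulate_family(config: SimConfig, rng: np.random.Generator) -> SimFamily:
    """Simulate one family: Poisson root draw, then jump sampling per branch."""
    tree = config.tree
    mult = _draw_multipliers(config, rng)
    states = np.zeros(tree.n_nodes, dtype=int)
    states[tree.root] = rng.poisson(config.root_mean)
    events: dict[str, str] = {}
    # walk root -> leaves (reverse post-order visits parents first)
    for node in range(tree.n_nodes - 2, -1, -1):
        parent = tree.parent[node]
        rates = config.branch_rates[node].scaled(*mult)
        states[node] = simulate_branch(states[parent], rates, rng)
        events[tree.labels[node]] = classify_endpoint(states[parent],
                                                      states[node])
    profile = PhyloProfile(
        "F", {tree.labels[i]: int(states[i]) for i in tree.leaves}
    )
    node_states = {tree.labels[i]: int(states[i]) for i in range(tree.n_nodes)}
    return SimFamily(profile, node_states, events, mult)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate ``config.n_families`` profiles; deterministic given the seed.

    With ascertainment on, all-zero families are rejected and redrawn (the
    rejection count is reported); a rejection rate above 99.9% raises a
    degenerate-configuration error.
    """
    rng = np.random.default_rng(config.seed)
    fams: list[SimFamily] = []
    n_rejected = 0
    while len(fams) < config.n_families:
        fam = simulate_family(config, rng)
        if config.ascertainment and not fam.profile.present_anywhere:
            n_rejected += 1
            if n_rejected > max(10_000, 1000 * config.n_families):
                raise RuntimeError(
                    "degenerate configuration: >99.9% of simulated families "
                    "are absent from every leaf"
                )
            continue
        fid = f"F{len(fams):05d}"
        fam.profile = PhyloProfile(fid, fam.profile.counts)
        fams.append(fam)
    profiles = ProfileSet.from_profiles([f.profile for f in fams],
                                        config.tree.leaf_names)
    return SimDataset(profiles, fams, n_rejected)


def make_study_fixture(seed: int = 0, n_families: int = 500,
                       heterogeneous: bool = True) -> tuple[SpeciesTree, SimConfig]:
    """The six-genome study topology with realistic placeholder rates.

    Branch rates emulate a metazoan domain-family regime: unit branch
    times, moderate per-copy turnover with loss on average exceeding birth,
    and a modest innovation rate.  With ``heterogeneous``, rates vary by
    roughly an order of magnitude from branch to branch (log-uniform,
    deterministic in ``seed``), the scale of lineage variation deep
    metazoan divergences exhibit.
    """
    tree = SpeciesTree.from_newick(STUDY_NEWICK)
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(tree.n_branches):
        if heterogeneous:
            lam = float(np.exp(rng.uniform(np.log(0.05), np.log(0.6))))
            mu = float(np.exp(rng.uniform(np.log(0.15), np.log(1.5))))
            kap = float(np.exp(rng.uniform(np.log(0.03), np.log(0.5))))
        else:
            lam, mu, kap = 0.3, 0.5, 0.2
        rates.append(BranchRates(1.0, lam, mu, kap))
    config = SimConfig(tree=tree, branch_rates=rates, root_mean=1.0,
                       n_families=n_families, ascertainment=True, seed=seed)
    return tree, config
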