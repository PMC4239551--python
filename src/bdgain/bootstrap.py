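"""Nonparametric bootstrap of estimator variance.

Each replicate resamples the n families with replacement, reruns the full
staged estimation plan, and (optionally) the second-pass event inference.
Across replicates, the per-estimator sample standard deviation is reported
as the bootstrap standard error (both SD and SE columns are emitted; they
coincide under this convention).  Replicates whose estimators stray more
than a threshold number of SDs from the replicate mean (default 9) are
flagged as outliers; exclusion is an explicit option, never automatic.

Replicate r derives its resampling seed deterministically as
base_seed + r, so results are reproducible and independent of scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitResult, StagePlan, staged_fit
from .events import EventSummary, aggregate_events
from .profiles import ProfileSet
from .tree import SpeciesTree

__all__ = ["BootstrapRun", "resample", "bootstrap_study", "flag_outliers"]


@dataclass
class BootstrapRun:
    """Replicate-level results and across-replicate summaries."""

    replicate_count: int
    base_seed: int
    indices: list[np.ndarray]
    fits: list[list[FitResult] | None]
    events: list[EventSummary | None]
    estimates: pd.DataFrame          # replicates × estimators
    summary: pd.DataFrame            # estimator, mean, sd, se, n_used
    failed: list[int] = field(default_factory=list)
    excluded: list[int] = field(default_factory=list)
    flags: pd.Series | None = None

    @property
    def n_used(self) -> int:
        return self.replicate_count - len(self.failed) - len(self.excluded)


def resample(data: ProfileSet, seed: int) -> ProfileSet:
    """Draw n profiles uniformly with replacement; deterministic in seed."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n, size=data.n)
    return data.subset(idx, disambiguate=True)


def _estimator_vector(fits: list[FitResult], tree: SpeciesTree,
                      events: EventSummary | None) -> pd.Series:
    """Flatten the final successful stage into named estimators."""
    final = None
    for fr in reversed(fits):
        if np.isfinite(fr.loglik):
            final = fr
            break
    if final is None:
        raise RuntimeError("no successful stage in replicate")
    p = final.params
    vals: dict[str, float] = {}
    for b, lbl in enumerate(tree.branch_labels()):
        vals[f"lam[{lbl}]"] = p.lam_b[b]
        vals[f"mu[{lbl}]"] = p.mu_b[b]
        vals[f"kap[{lbl}]"] = p.kap_b[b]
        vals[f"t[{lbl}]"] = p.t_b[b]
    vals["phi"] = p.phi
    for name, c, s in zip(("t", "lam", "mu", "kap"), p.spec.categories,
                          p.shapes):
        if c > 1:
            vals[f"shape_{name}"] = s
    vals["loglik"] = final.loglik
    if events is not None:
        for lbl, row in events.per_branch.iterrows():
            for kind in ("gains", "losses", "expansions", "contractions"):
                vals[f"{kind}[{lbl}]"] = row[kind]
    return pd.Series(vals)


def bootstrap_study(data: ProfileSet, tree: SpeciesTree,
                    plan: StagePlan | None = None, replicates: int = 100,
                    base_seed: int = 0, ascertainment: bool = True,
                    compute_events: bool = False,
                    outlier_threshold_sd: float = 9.0) -> BootstrapRun:
    """Resample, refit the staged plan, summarize estimator spread.

    Failed replicates are recorded and excluded from summaries, never
    silently dropped: summary counts + failed + excluded = R always.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for summaries")
    indices, fits_all, events_all, rows, failed = [], [], [], [], []
    for r in range(replicates):
        rng = np.random.default_rng(base_seed + r)
        idx = rng.integers(0, data.n, size=data.n)
        indices.append(idx)
        boot = data.subset(idx, disambiguate=True)
        try:
            fits = staged_fit(boot, tree, plan, ascertainment=ascertainment)
            ev = aggregate_events(tree, fits[-1].params, boot,
                                  ascertainment=ascertainment) \
                if compute_events and np.isfinite(fits[-1].loglik) else None
            rows.append(_estimator_vector(fits, tree, ev))
            fits_all.append(fits)
            events_all.append(ev)
        except Exception:
            failed.append(r)
            fits_all.append(None)
            events_all.append(None)
            rows.append(None)
    used = [r for r in range(replicates) if rows[r] is not None]
    est = pd.DataFrame([rows[r] for r in used], index=pd.Index(used, name="replicate"))
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1)
    summary = pd.DataFrame({
        "mean": mean, "sd": sd, "se": sd, "n_used": len(used),
    })
    summary.index.name = "estimator"
    run = BootstrapRun(replicate_count=replicates, base_seed=base_seed,
                       indices=indices, fits=fits_all, events=events_all,
                       estimates=est, summary=summary, failed=failed)
    run.flags = flag_outliers(run, threshold_sd=outlier_threshold_sd)
    return run


def flag_outliers(run: BootstrapRun, threshold_sd: float = 9.0) -> pd.Series:
    """Advisory outlier flags per used replicate.

    A replicate is flagged when any estimator lies more than ``threshold_sd``
    sample standard deviations from the across-replicate mean; estimators
    with zero SD are skipped.  Flags never exclude a replicate by
    themselves.
    """
    est = run.estimates
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        return pd.Series(False, index=est.index)
    z = (est.loc[:, ok] - mean[ok]) / sd[ok]
    return (z.abs() > threshold_sd).any(axis=1)
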