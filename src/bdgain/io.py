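"""Readers and writers for profile tables, trees, and result files.

The profile table is tab-delimited text: a header row with a family-id
column followed by one column per leaf taxon, then one row per family with
non-negative integer counts.  Columns are matched to tree leaves by name,
so column order is irrelevant.  Outputs are deterministic (post-order
branch rows, alphabetical estimator rows, floats at 6 significant digits)
with a machine-readable JSON mirror of every table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult
from .events import EventSummary
from .models import branch_rates_table
from .profiles import ProfileSet
from .tree import SpeciesTree

__all__ = ["read_tree", "read_profiles", "write_profiles",
           "summarize_profiles", "write_results"]


def read_tree(path: str | Path) -> SpeciesTree:
    """Parse a rooted binary Newick tree from a file."""
    return SpeciesTree.from_newick(Path(path).read_text())


def read_profiles(path: str | Path, tree: SpeciesTree | None = None,
                  ascertainment: bool = True,
                  coerce_floats: bool = False) -> ProfileSet:
    """Load a tab-delimited profile table, matching columns to tree leaves.

    All-zero rows are rejected with a warning when ``ascertainment`` is on
    (they are unobservable under the presence-in-≥1-genome rule).  Row order
    is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate family ids: {dups[:5]}")
    if tree is not None:
        missing = set(tree.leaf_names) - set(map(str, df.columns))
        if missing:
            raise ValueError(
                f"profile table lacks columns for tree leaves {sorted(missing)}"
            )
        extra = set(map(str, df.columns)) - set(tree.leaf_names)
        if extra:
            raise ValueError(f"unknown taxon columns {sorted(extra)}")
        df = df[tree.leaf_names]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("profile table contains non-numeric entries")
    flt = arr.astype(float)
    if np.any(flt < 0):
        bad = np.argwhere(flt < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    if not np.allclose(flt, np.round(flt)):
        if not coerce_floats:
            bad = np.argwhere(flt != np.round(flt))[0]
            raise ValueError(
                f"non-integer count at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r} (use coerce_floats to truncate)"
            )
        warnings.warn("non-integer counts truncated toward zero", stacklevel=2)
        flt = np.trunc(flt)
    df = pd.DataFrame(flt.astype(np.int64), index=df.index, columns=df.columns)
    if ascertainment:
        zero = df.sum(axis=1) == 0
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} all-zero families "
                "(unobservable under ascertainment)", stacklevel=2)
            df = df[~zero]
    return ProfileSet.from_dataframe(df)


def write_profiles(data: ProfileSet, path: str | Path) -> None:
    data.to_dataframe().to_csv(path, sep="\t")


# ----------------------------------------------------------------------

def summarize_profiles(data: ProfileSet) -> dict:
    """Dataset summary statistics.

    Per-species mean family size is averaged over the families present
    (count ≥ 1) in that species; family totals sum members across all
    species.
    """
    df = data.to_dataframe()
    present = df > 0
    n_species = present.sum(axis=1)
    totals = df.sum(axis=1).sort_values(ascending=False)
    mean_sizes = {
        sp: float(df.loc[present[sp], sp].mean()) if present[sp].any() else 0.0
        for sp in df.columns
    }
    return {
        "n_families": int(data.n),
        "n_species": len(df.columns),
        "n_in_all_species": int((n_species == len(df.columns)).sum()),
        "n_single_species": int((n_species == 1).sum()),
        "largest_family": str(totals.index[0]) if data.n else None,
        "largest_family_total": int(totals.iloc[0]) if data.n else 0,
        "second_largest_family_total": int(totals.iloc[1]) if data.n > 1 else 0,
        "mean_family_size_per_species": mean_sizes,
    }


# ----------------------------------------------------------------------

def _sig6(x) -> object:
    if isinstance(x, (float, np.floating)):
        return float(f"{x:.6g}")
    return x


def _write_tsv_json(df: pd.DataFrame, stem: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.floating):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(stem.with_suffix(".tsv"), sep="\t")
    records = [
        {str(k): _sig6(v) for k, v in row.items()}
        for row in df.reset_index().to_dict(orient="records")
    ]
    stem.with_suffix(".json").write_text(
        json.dumps(records, indent=1, default=_sig6) + "\n")


def write_results(out_dir: str | Path, tree: SpeciesTree,
                  fits: list[FitResult] | None = None,
                  events: EventSummary | None = None,
                  bootstrap=None) -> list[Path]:
    """Write fit / event / bootstrap outputs as TSVs with JSON mirrors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv_json(df, out / name)
        written.extend([out / f"{name}.tsv", out / f"{name}.json"])

    if fits:
        emit(pd.DataFrame([fr.summary() for fr in fits]).set_index("model"),
             "model_comparison")
        for fr in fits:
            if not np.isfinite(fr.loglik):
                continue
            emit(branch_rates_table(fr.params, tree).set_index("branch"),
                 f"branch_rates_{fr.spec.name}")
            laws = pd.DataFrame({
                "parameter": ["duration", "expansion", "loss", "gain"],
                "categories": list(fr.spec.categories),
                "shape": fr.params.shapes,
                "multipliers": [
                    ",".join(f"{v:.6g}" for v in mult)
                    for mult in fr.params.family_multipliers()
                ],
            }).set_index("parameter")
            emit(laws, f"family_laws_{fr.spec.name}")
            (out / f"fit_{fr.spec.name}.json").write_text(json.dumps({
                **fr.summary(),
                "phi": _sig6(fr.params.phi),
                "trace": [_sig6(v) for v in fr.trace],
            }, indent=1) + "\n")
            written.append(out / f"fit_{fr.spec.name}.json")
    if events is not None:
        emit(events.per_branch, "expected_events")
        emit(events.root_fractions.to_frame("fraction"), "root_fractions")
    if bootstrap is not None:
        long = bootstrap.estimates.stack().rename("value").reset_index()
        long.columns = ["replicate", "estimator", "value"]
        emit(long.set_index("replicate"), "bootstrap_replicates")
        emit(bootstrap.summary.sort_index(), "bootstrap_summary")
        flags = bootstrap.flags if bootstrap.flags is not None else \
            pd.Series(dtype=bool)
        emit(flags.to_frame("flagged"), "bootstrap_flags")
    return written
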