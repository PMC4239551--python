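"""Phylogenetic profiles: per-family member counts on the leaf genomes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import SpeciesTree

__all__ = ["PhyloProfile", "ProfileSet"]


@dataclass(frozen=True)
class PhyloProfile:
    """One family's member counts, keyed by leaf taxon name."""

    family_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ValueError(
                    f"count for {name!r} in family {self.family_id!r} must be a "
                    f"non-negative integer, got {c!r}"
                )

    def vector(self, tree: SpeciesTree) -> np.ndarray:
        missing = set(tree.leaf_names) - set(self.counts)
        if missing:
            raise ValueError(
                f"family {self.family_id!r} lacks counts for leaves {sorted(missing)}"
            )
        return np.array([int(self.counts[n]) for n in tree.leaf_names], dtype=int)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def present_anywhere(self) -> bool:
        return any(c > 0 for c in self.counts.values())


class ProfileSet:
    """An ordered collection of phylogenetic profiles on a fixed leaf set.

    Internally a (n_families × n_leaves) integer matrix with family ids and
    taxon names; convertible to and from a pandas DataFrame (families as
    rows, taxa as columns).
    """

    def __init__(self, counts: np.ndarray, family_ids: list[str],
                 taxa: list[str]):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape != (len(family_ids), len(taxa)):
            raise ValueError("counts must be (n_families, n_taxa)")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if len(set(family_ids)) != len(family_ids):
            dup = pd.Series(family_ids).value_counts()
            raise ValueError(
                f"duplicate family ids: {list(dup[dup > 1].index[:5])}"
            )
        self.counts = counts.astype(np.int64)
        self.family_ids = list(family_ids)
        self.taxa = list(taxa)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of families (the n of BIC = m ln n − 2 lnL)."""
        return len(self.family_ids)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> PhyloProfile:
        return PhyloProfile(self.family_ids[i],
                            dict(zip(self.taxa, self.counts[i].tolist())))

    def __iter__(self):
        return (self[i] for i in range(self.n))

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProfileSet":
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = arr.astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                raise ValueError("profile table contains non-integer counts")
            arr = np.round(as_float).astype(np.int64)
        return cls(arr, [str(i) for i in df.index], [str(c) for c in df.columns])

    @classmethod
    def from_profiles(cls, profiles: list[PhyloProfile],
                      taxa: list[str]) -> "ProfileSet":
        counts = np.array(
            [[int(p.counts[t]) for t in taxa] for p in profiles], dtype=np.int64
        ).reshape(len(profiles), len(taxa))
        return cls(counts, [p.family_id for p in profiles], taxa)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=pd.Index(self.family_ids, name="Family"),
                            columns=self.taxa)

    # ------------------------------------------------------------------
    def matrix_for(self, tree: SpeciesTree) -> np.ndarray:
        """Counts reordered to the tree's post-order leaf columns."""
        missing = set(tree.leaf_names) - set(self.taxa)
        if missing:
            raise ValueError(f"profiles lack tree leaves {sorted(missing)}")
        cols = [self.taxa.index(n) for n in tree.leaf_names]
        return self.counts[:, cols]

    def subset(self, indices: np.ndarray, disambiguate: bool = False) -> "ProfileSet":
        indices = np.asarray(indices, dtype=int)
        ids = [self.family_ids[i] for i in indices]
        if disambiguate:
            seen: dict[str, int] = {}
            out = []
            for fid in ids:
                k = seen.get(fid, 0)
                seen[fid] = k + 1
                out.append(fid if k == 0 else f"{fid}#{k + 1}")
            ids = out
        return ProfileSet(self.counts[indices], ids, self.taxa)
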