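"""Gene-family count tables (families x species, non-negative integers)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FamilyCountTable", "filter_families"]


class FamilyCountTable:
    """Per-species gene counts for a set of gene families.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds family ids (MEROPS-style, e.g. ``S8A``) and whose columns hold
    species ids matching the species-tree tips.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate family ids")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate species ids")
        values = frame.to_numpy()
        if values.size and (
            not np.issubdtype(values.dtype, np.integer)
            and not np.all(np.equal(np.mod(values, 1), 0))
        ):
            raise ValueError("counts must be integers")
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.frame = frame.astype(int)

    @classmethod
    def from_counts(
        cls, family_ids: Sequence[str], species: Sequence[str], counts
    ) -> "FamilyCountTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(family_ids), columns=list(species)))

    # -- accessors ----------------------------------------------------
    @property
    def family_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def species(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_families(self) -> int:
        return len(self.frame)

    def counts(self, order: Sequence[str] | None = None) -> np.ndarray:
        """(n_families, n_species) integer matrix, optionally species-ordered."""
        frame = self.frame if order is None else self.frame[list(order)]
        return frame.to_numpy()

    def max_count(self) -> int:
        return int(self.frame.to_numpy().max(initial=0))

    def validate_against(self, species_tree) -> None:
        missing = set(self.species) - set(species_tree.tip_labels)
        if missing:
            raise ValueError(f"species {sorted(missing)} absent from the species tree")

    # -- I/O ----------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "FamilyCountTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "family_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other) -> bool:
        return isinstance(other, FamilyCountTable) and self.frame.equals(other.frame)


def filter_families(table: FamilyCountTable) -> FamilyCountTable:
    """Keep families informative for birth-death rate estimation.

    A family is retained when it has at least two gene copies in some
    species and is present (count > 0) in at least two species.  Row order
    is preserved; the result may be empty.
    """
    counts = table.counts()
    keep = (counts.max(axis=1) >= 2) & ((counts > 0).sum(axis=1) >= 2)
    return FamilyCountTable(table.frame.loc[keep])
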