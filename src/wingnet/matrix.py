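"""Count-matrix container shared by the gene and miRNA analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Nonnegative integer counts (features x samples) with sample metadata.

    Parameters
    ----------
    counts
        DataFrame of raw counts; rows are features, columns are sample ids.
    meta
        DataFrame indexed by sample id with columns ``form``, ``stage`` and
        ``replicate``; must cover every count column.
    kind
        ``"gene"`` or ``"miRNA"``; the two kinds are normalized and tested
        separately because their library compositions differ.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "miRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        # keep metadata aligned & restricted to the count columns
        self.meta = self.meta.loc[list(self.counts.columns)]

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        ids = [i for i in ids if i in self.counts.columns]
        return ExpressionMatrix(self.counts[ids], self.meta.loc[ids], self.kind)

    def stage_matrix(self, stage: str) -> "ExpressionMatrix":
        ids = self.meta.index[self.meta["stage"] == stage]
        return self.subset_samples(ids)

    def form_samples(self, form: str) -> list[str]:
        return list(self.meta.index[self.meta["form"] == form])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.counts.equals(other.counts)
            and self.meta.equals(other.meta)
        )
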