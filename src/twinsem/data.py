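"""Twin-pair dataset container and delimited-text IO.

One row per pair: ``pair_id, zygosity, age_1, age_2`` followed by
``<trait>_1, <trait>_2`` columns per phenotype.  Missing values are empty
fields on disk and NaN in memory; binary traits are 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import DZ, MZ, PhenotypeSpec

__all__ = ["TwinDataset"]


@dataclass
class TwinDataset:
    """Pair-per-row twin data with declared phenotype scales."""

    df: pd.DataFrame
    phenotypes: tuple[PhenotypeSpec, ...]

    def __post_init__(self):
        self.phenotypes = tuple(self.phenotypes)
        required = ["pair_id", "zygosity", "age_1", "age_2"] + self.value_columns
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        bad = set(self.df["zygosity"].unique()) - {MZ, DZ}
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
        vals = self.df[self.value_columns].to_numpy(dtype=float)
        if np.isnan(vals).all(axis=1).any():
            raise ValueError("every retained pair needs at least one observed value")
        for ph in self.phenotypes:
            if ph.binary:
                col = self.df[[f"{ph.name}_1", f"{ph.name}_2"]].to_numpy(dtype=float)
                obs = col[~np.isnan(col)]
                if not np.isin(obs, (0.0, 1.0)).all():
                    raise ValueError(f"binary trait {ph.name} has values outside 0/1")

    # -- basic views ---------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.phenotypes)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(ph.name for ph in self.phenotypes)

    @property
    def value_columns(self) -> list[str]:
        return [f"{ph.name}_{t}" for t in (1, 2) for ph in self.phenotypes]

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    def zygosity_mask(self, zygosity: str) -> np.ndarray:
        if zygosity not in (MZ, DZ):
            raise ValueError(f"unknown zygosity {zygosity!r}")
        return (self.df["zygosity"] == zygosity).to_numpy()

    def values(self, zygosity: str | None = None) -> np.ndarray:
        """(n, 2p) array ordered twin-1 traits then twin-2 traits."""
        arr = self.df[self.value_columns].to_numpy(dtype=float)
        if zygosity is None:
            return arr
        return arr[self.zygosity_mask(zygosity)]

    def ages(self, zygosity: str | None = None) -> np.ndarray:
        arr = self.df[["age_1", "age_2"]].to_numpy(dtype=float)
        if zygosity is None:
            return arr
        return arr[self.zygosity_mask(zygosity)]

    def subset(self, mask: np.ndarray) -> "TwinDataset":
        return TwinDataset(self.df.loc[mask].reset_index(drop=True), self.phenotypes)

    # -- IO ------------------------------------------------------------
    def to_csv(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False, na_rep="")

    @classmethod
    def read_csv(
        cls,
        path,
        phenotypes: Sequence[PhenotypeSpec],
        sep: str | None = None,
    ) -> "TwinDataset":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        return cls(df, tuple(phenotypes))
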