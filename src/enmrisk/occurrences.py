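"""Georeferenced presence records with provenance and train/test partition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet"]

COLUMNS = ["species", "x", "y", "source", "year"]


@dataclass
class OccurrenceSet:
    """Presence points backed by a :class:`pandas.DataFrame`.

    The frame has columns ``species, x, y, source, year`` plus an optional
    ``partition`` column with values ``"train"``/``"test"`` once
    :func:`enmrisk.preprocess.split_train_test` has run.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("x", "y", "year") else ""
        df["x"] = pd.to_numeric(df["x"], errors="coerce")
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, x, y, species="sp", source="", year=np.nan) -> "OccurrenceSet":
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return cls(
            pd.DataFrame(
                {"species": species, "x": x, "y": y, "source": source, "year": year}
            )
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x, y coordinates."""
        return self.records[["x", "y"]].to_numpy(dtype=float)

    @property
    def has_partition(self) -> bool:
        return "partition" in self.records.columns and self.records["partition"].notna().all()

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.records.loc[np.asarray(mask)].reset_index(drop=True))

    def partition_subset(self, label: str) -> "OccurrenceSet":
        if "partition" not in self.records.columns:
            raise ValueError("occurrence set has no train/test partition")
        return self.subset((self.records["partition"] == label).to_numpy())

    @property
    def train(self) -> "OccurrenceSet":
        return self.partition_subset("train")

    @property
    def test(self) -> "OccurrenceSet":
        return self.partition_subset("test")

    def copy(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records.copy())
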