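"""Core data containers: item banks, person tables and response matrices.

All containers are plain-text serializable (CSV) so that a whole study can be
round-tripped through files.  Responses are stored long-format with missing
entries simply absent; in memory a dense float matrix with NaN marks
missingness.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BLOCKS = ("A", "B", "C", "D")

PERSON_COLUMNS = (
    "id",
    "theta_true",
    "gender",
    "ethnicity",
    "assigned_block",
    "criterion_score",
    "clinical",
    "treated",
)


@dataclass
class ItemBank:
    """Polytomous item bank with per-item step thresholds.

    ``thresholds[i]`` holds the ``n_categories[i] - 1`` step parameters of
    item ``i`` (logits); an item's *location* is the mean of its thresholds.
    """

    ids: np.ndarray
    labels: list[str]
    blocks: np.ndarray
    thresholds: list[np.ndarray]
    retained: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=object)
        self.retained = np.asarray(self.retained, dtype=bool)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        n = len(self.ids)
        if not (len(self.labels) == len(self.blocks) == len(self.thresholds) == len(self.retained) == n):
            raise ValueError("ItemBank fields have inconsistent lengths")
        if len(np.unique(self.ids)) != n:
            raise ValueError("item ids must be unique")
        for t in self.thresholds:
            if t.size < 1 or not np.all(np.isfinite(t)):
                raise ValueError("each item needs >= 1 finite threshold")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([t.size + 1 for t in self.thresholds], dtype=int)

    @property
    def locations(self) -> np.ndarray:
        return np.array([t.mean() for t in self.thresholds])

    def index_of(self, item_id: int) -> int:
        pos = np.flatnonzero(self.ids == item_id)
        if pos.size == 0:
            raise KeyError(f"item id {item_id} not in bank")
        return int(pos[0])

    def subset(self, mask_or_ids) -> "ItemBank":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = np.array([self.index_of(i) for i in arr])
        return ItemBank(
            ids=self.ids[idx],
            labels=[self.labels[i] for i in idx],
            blocks=self.blocks[idx],
            thresholds=[self.thresholds[i].copy() for i in idx],
            retained=self.retained[idx],
        )

    def retained_bank(self) -> "ItemBank":
        return self.subset(self.retained)

    def with_thresholds(self, thresholds: Sequence[np.ndarray]) -> "ItemBank":
        return ItemBank(
            ids=self.ids.copy(),
            labels=list(self.labels),
            blocks=self.blocks.copy(),
            thresholds=[np.asarray(t, float).copy() for t in thresholds],
            retained=self.retained.copy(),
        )

    def copy(self) -> "ItemBank":
        return self.with_thresholds(self.thresholds)

    # --- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        kmax = max(t.size for t in self.thresholds)
        rows = {}
        rows["id"] = self.ids
        rows["label"] = self.labels
        rows["block"] = self.blocks
        rows["n_categories"] = self.n_categories
        for k in range(kmax):
            rows[f"threshold_{k + 1}"] = [
                t[k] if k < t.size else np.nan for t in self.thresholds
            ]
        rows["location"] = self.locations
        rows["retained"] = self.retained
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        thr_cols = sorted(
            (c for c in df.columns if c.startswith("threshold_")),
            key=lambda c: int(c.split("_")[1]),
        )
        thresholds = []
        for _, row in df.iterrows():
            m = int(row["n_categories"]) - 1
            thresholds.append(np.array([row[thr_cols[k]] for k in range(m)], float))
        return cls(
            ids=df["id"].to_numpy(int),
            labels=[str(x) for x in df["label"]],
            blocks=df["block"].to_numpy(object),
            thresholds=thresholds,
            retained=df["retained"].astype(bool).to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PairedBank:
    """An item bank with uniform DIF injected on one item for group==1.

    ``bank_for(0)`` is the base bank, ``bank_for(1)`` has all thresholds of
    ``item_id`` shifted by ``shift`` logits.
    """

    base: ItemBank
    item_id: int
    group: str  # "gender" or "ethnicity"
    shift: float

    def __post_init__(self) -> None:
        if self.group not in ("gender", "ethnicity"):
            raise ValueError("group must be 'gender' or 'ethnicity'")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")
        self.base.index_of(self.item_id)  # raises KeyError if absent

    def bank_for(self, group_value: int) -> ItemBank:
        if group_value == 0 or self.shift == 0.0:
            return self.base
        shifted = [t.copy() for t in self.base.thresholds]
        shifted[self.base.index_of(self.item_id)] = (
            shifted[self.base.index_of(self.item_id)] + self.shift
        )
        return self.base.with_thresholds(shifted)


@dataclass
class ResponseMatrix:
    """Persons x items integer responses; NaN marks structurally missing."""

    values: np.ndarray  # float (n_persons, n_items), NaN = missing
    person_ids: np.ndarray
    item_ids: np.ndarray
    design: str = "complete"  # {"complete", "four_block"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.person_ids = np.asarray(self.person_ids, dtype=int)
        self.item_ids = np.asarray(self.item_ids, dtype=int)
        if self.values.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("values shape inconsistent with id vectors")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def validate_against(self, bank: ItemBank) -> None:
        """Check category ranges and per-person coverage; raise on violation."""
        if not np.array_equal(np.sort(self.item_ids), np.sort(bank.ids)) and not np.all(
            np.isin(self.item_ids, bank.ids)
        ):
            unknown = set(self.item_ids) - set(bank.ids)
            raise ValueError(f"responses reference unknown item ids: {sorted(unknown)}")
        ncat = bank.n_categories
        for j, item_id in enumerate(self.item_ids):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                continue
            m = ncat[bank.index_of(item_id)] - 1
            if obs.min() < 0 or obs.max() > m or not np.allclose(obs, np.round(obs)):
                raise ValueError(f"item {item_id}: responses outside 0..{m}")
        if not self.observed.any(axis=1).all():
            bad = self.person_ids[~self.observed.any(axis=1)]
            raise ValueError(f"persons with zero observed responses: {bad.tolist()}")

    def subset_persons(self, person_ids: Iterable[int]) -> "ResponseMatrix":
        wanted = np.asarray(list(person_ids), int)
        pos = {int(p): i for i, p in enumerate(self.person_ids)}
        idx = np.array([pos[int(p)] for p in wanted])
        return ResponseMatrix(self.values[idx], wanted, self.item_ids.copy(), self.design)

    def subset_items(self, item_ids: Iterable[int]) -> "ResponseMatrix":
        wanted = np.asarray(list(item_ids), int)
        pos = {int(i): j for j, i in enumerate(self.item_ids)}
        idx = np.array([pos[int(i)] for i in wanted])
        return ResponseMatrix(self.values[:, idx], self.person_ids.copy(), wanted, self.design)

    # --- serialization ----------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        p_idx, i_idx = np.nonzero(self.observed)
        return pd.DataFrame(
            {
                "person_id": self.person_ids[p_idx],
                "item_id": self.item_ids[i_idx],
                "response": self.values[p_idx, i_idx].astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(
        cls,
        df: pd.DataFrame,
        design: str = "complete",
        person_ids: np.ndarray | None = None,
        item_ids: np.ndarray | None = None,
    ) -> "ResponseMatrix":
        required = {"person_id", "item_id", "response"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long response table missing columns: {sorted(missing)}")
        if person_ids is None:
            person_ids = np.unique(df["person_id"].to_numpy(int))
        if item_ids is None:
            item_ids = np.unique(df["item_id"].to_numpy(int))
        p_pos = {int(p): i for i, p in enumerate(person_ids)}
        i_pos = {int(i): j for j, i in enumerate(item_ids)}
        unknown_items = set(df["item_id"].astype(int)) - set(i_pos)
        if unknown_items:
            raise ValueError(f"responses reference unknown item ids: {sorted(unknown_items)}")
        unknown_persons = set(df["person_id"].astype(int)) - set(p_pos)
        if unknown_persons:
            raise ValueError(f"responses reference unknown person ids: {sorted(unknown_persons)}")
        values = np.full((len(person_ids), len(item_ids)), np.nan)
        rows = df["person_id"].map(p_pos).to_numpy()
        cols = df["item_id"].map(i_pos).to_numpy()
        values[rows, cols] = df["response"].to_numpy(float)
        return cls(values, np.asarray(person_ids, int), np.asarray(item_ids, int), design)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ResponseMatrix":
        return cls.from_long_frame(pd.read_csv(path), **kwargs)


def validate_persons(df: pd.DataFrame, require_theta: bool = False) -> None:
    if "id" not in df.columns:
        raise ValueError("person table needs an 'id' column")
    if df["id"].duplicated().any():
        raise ValueError("person ids must be unique")
    if require_theta and ("theta_true" not in df.columns or df["theta_true"].isna().any()):
        raise ValueError("person table lacks theta_true values required here")
    for col in ("gender", "ethnicity"):
        if col in df.columns and not df[col].dropna().isin([0, 1]).all():
            raise ValueError(f"column '{col}' must be binary 0/1")
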