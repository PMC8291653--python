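"""Core data containers for competition datasets, submissions and results.

The per-record truth table is held as a :class:`pandas.DataFrame` in the
layout of the public competition files (``id``, ``molecule_name``,
``atom_index_0``, ``atom_index_1``, ``type``, ``scalar_coupling_constant``)
plus a ``split`` column taking values ``train``/``public``/``private``.
A team submission is a :class:`pandas.Series` of predicted coupling
constants (Hz) indexed by record id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: The eight scalar-coupling categories used for grouped scoring.  nJXY
#: denotes a coupling between nuclei X and Y separated by n covalent bonds.
COUPLING_TYPE_LABELS: tuple[str, ...] = (
    "1JHC", "1JHN", "2JHH", "2JHC", "2JHN", "3JHH", "3JHC", "3JHN",
)

SPLITS = ("train", "public", "private")


@dataclass(frozen=True)
class CouplingType:
    """One scalar-coupling category with its value distribution and abundance.

    Parameters
    ----------
    label:
        One of the eight ``nJXY`` category names.
    location_hz, scale_hz:
        Typical offset and spread of the true coupling constant, in Hz.
    relative_frequency:
        Proportion of records belonging to this type (sums to 1 over the
        eight types in a full type table).
    """

    label: str
    location_hz: float
    scale_hz: float
    relative_frequency: float

    def __post_init__(self) -> None:
        if self.label not in COUPLING_TYPE_LABELS:
            raise ConfigurationError(f"unknown coupling type label {self.label!r}")
        if not np.isfinite(self.scale_hz) or self.scale_hz <= 0:
            raise ConfigurationError(
                f"scale_hz for {self.label} must be finite and positive, got {self.scale_hz}"
            )
        if not np.isfinite(self.location_hz):
            raise ConfigurationError(f"location_hz for {self.label} must be finite")
        if not np.isfinite(self.relative_frequency) or self.relative_frequency <= 0:
            raise ConfigurationError(
                f"relative_frequency for {self.label} must be positive"
            )


def validate_type_table(type_table: Mapping[str, CouplingType]) -> None:
    """Check that a type table covers exactly the 8 labels with frequencies summing to 1."""
    if set(type_table) != set(COUPLING_TYPE_LABELS):
        raise ConfigurationError(
            "type table must contain exactly the 8 coupling types; got "
            f"{sorted(type_table)}"
        )
    total = sum(t.relative_frequency for t in type_table.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ConfigurationError(f"relative frequencies must sum to 1, got {total}")


@dataclass
class CouplingDataset:
    """A complete competition truth table with molecule-level splits.

    ``records`` columns: ``id`` (dense 0..N-1), ``molecule_name``,
    ``atom_index_0``, ``atom_index_1``, ``type``, ``scalar_coupling_constant``
    (Hz) and ``split``.
    """

    records: pd.DataFrame
    type_table: dict[str, CouplingType]
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {
            "id", "molecule_name", "atom_index_0", "atom_index_1",
            "type", "scalar_coupling_constant", "split",
        }
        missing = required - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_molecules(self) -> int:
        return self.records["molecule_name"].nunique()

    def split_mask(self, split: str) -> np.ndarray:
        """Boolean mask over records.

        ``split`` is ``train``, ``public``, ``private``, or ``test``/``all``
        (both meaning public+private — submissions only ever cover test
        records).
        """
        col = self.records["split"]
        if split in ("all", "test"):
            return col.isin(("public", "private")).to_numpy()
        if split not in SPLITS:
            raise ConfigurationError(f"unknown split {split!r}")
        return (col == split).to_numpy()

    def record_ids(self, split: str = "test") -> np.ndarray:
        """Record ids in the given split, in record order."""
        return self.records.loc[self.split_mask(split), "id"].to_numpy()

    def truth(self, split: str = "test") -> pd.Series:
        """True coupling constants indexed by record id for the given split."""
        sel = self.records.loc[self.split_mask(split)]
        return pd.Series(
            sel["scalar_coupling_constant"].to_numpy(),
            index=sel["id"].to_numpy(),
            name="scalar_coupling_constant",
        )

    def types(self, split: str = "test") -> pd.Series:
        """Coupling-type labels indexed by record id for the given split."""
        sel = self.records.loc[self.split_mask(split)]
        return pd.Series(sel["type"].to_numpy(), index=sel["id"].to_numpy(), name="type")

    def type_counts(self, split: str | None = None) -> pd.Series:
        """Per-type record counts, over all records or one split."""
        if split is None:
            return self.records["type"].value_counts()
        return self.records.loc[self.split_mask(split), "type"].value_counts()


@dataclass
class SubmissionSet:
    """One team submission: a full prediction vector over the test records."""

    team_id: str
    predictions: pd.Series  # record id -> predicted value (Hz)
    rank: int | None = None
    timestamp_days: float = 0.0
    submission_index: int = 0

    def __post_init__(self) -> None:
        if self.timestamp_days < 0:
            raise ConfigurationError("timestamp_days must be nonnegative")
        self.predictions = self.predictions.astype(float)

    def __len__(self) -> int:
        return len(self.predictions)


@dataclass
class ScoreReport:
    """Grouped log-MAE score breakdown.

    ``score`` is the mean over scored coupling types of the natural log of
    the per-type mean absolute error; ``geometric_mean_error`` is
    ``exp(score)`` in Hz.
    """

    per_type_mae: dict[str, float]
    per_type_log_mae: dict[str, float]
    score: float
    geometric_mean_error: float
    n_types_used: int
    split_scored: str
    per_type_n: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "score": self.score,
            "geometric_mean_error": self.geometric_mean_error,
            "n_types_used": self.n_types_used,
            "split_scored": self.split_scored,
            "per_type_mae": dict(self.per_type_mae),
            "per_type_log_mae": dict(self.per_type_log_mae),
            "per_type_n": dict(self.per_type_n),
        }


@dataclass
class LeaderboardEntry:
    rank: int
    team_id: str
    score: float
    timestamp_days: float


@dataclass
class LeaderboardTrace:
    """Time-ordered submission scores and the running-best (leader) trace."""

    points: pd.DataFrame       # columns timestamp_days, score, team_id
    running_best: pd.DataFrame  # columns timestamp_days, score

    def __len__(self) -> int:
        return len(self.points)
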