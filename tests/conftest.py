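"""Shared builders for handcrafted miniature competitions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from couplingswarm import CouplingDataset, SubmissionSet
from couplingswarm.synthetic import default_type_table


def make_dataset(
    type_labels,
    values=None,
    split="public",
    molecule_size=None,
) -> CouplingDataset:
    """Build a tiny truth table directly from per-record type labels.

    ``split`` may be a single label for all records or a per-record
    sequence.  Molecules are synthetic, ``molecule_size`` records each
    (default: all records in one molecule per split label).
    """
    type_labels = np.asarray(type_labels, dtype=object)
    n = len(type_labels)
    if values is None:
        values = np.linspace(1.0, 2.0, n) * 10.0
    values = np.asarray(values, dtype=float)
    if isinstance(split, str):
        split = np.full(n, split, dtype=object)
    else:
        split = np.asarray(split, dtype=object)
    if molecule_size is None:
        molecules = np.asarray([f"mol_{s}" for s in split], dtype=object)
    else:
        molecules = np.asarray(
            [f"mol_{i // molecule_size:04d}" for i in range(n)], dtype=object)
    records = pd.DataFrame({
        "id": np.arange(n),
        "molecule_name": molecules,
        "atom_index_0": np.arange(n) % 5,
        "atom_index_1": np.arange(n) % 5 + 5,
        "type": type_labels,
        "scalar_coupling_constant": values,
        "split": split,
    })
    return CouplingDataset(records=records, type_table=default_type_table())


def submission_from_errors(
    dataset: CouplingDataset, errors, team_id="team", split="test", **kwargs
) -> SubmissionSet:
    """A submission whose signed prediction errors are given explicitly."""
    truth = dataset.truth(split)
    errors = np.broadcast_to(np.asarray(errors, dtype=float), truth.shape)
    return SubmissionSet(
        team_id=team_id,
        predictions=pd.Series(truth.to_numpy() + errors, index=truth.index),
        **kwargs,
    )


@pytest.fixture
def two_type_dataset() -> CouplingDataset:
    """Four public records: two of type 1JHC, two of type 3JHH."""
    return make_dataset(["1JHC", "1JHC", "3JHH", "3JHH"])
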