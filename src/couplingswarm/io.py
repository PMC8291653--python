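"""Readers and writers for the competition CSV layout.

The on-disk layout mirrors the public competition files so real downloads
are drop-in compatible:

* ``train.csv``: id, molecule_name, atom_index_0, atom_index_1, type,
  scalar_coupling_constant
* ``test.csv``: same minus the constant
* submission files: id, scalar_coupling_constant
* ``truth.csv`` (package addition): the full truth table including the
  ``split`` column, for lossless round-trips.

Comma-separated, header row, UTF-8, "." decimal, no index column.
"""

from __future__ import annotations

import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IncompleteSubmissionError,
    InvalidSubmissionError,
)
from .types import (
    COUPLING_TYPE_LABELS,
    CouplingDataset,
    CouplingType,
    SubmissionSet,
)
from .synthetic import default_type_table

_TRUTH_COLUMNS = ("id", "molecule_name", "atom_index_0", "atom_index_1", "type")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def read_truth(path, type_table: dict[str, CouplingType] | None = None) -> CouplingDataset:
    """Read a truth table (train.csv or truth.csv layout) into a dataset.

    A ``split`` column is honoured if present; otherwise every record is
    labelled ``train``.  Unknown type labels, duplicate ids and
    unparseable numbers are format errors.
    """
    frame = _read_csv(path)
    required = set(_TRUTH_COLUMNS) | {"scalar_coupling_constant"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")

    for col in ("id", "atom_index_0", "atom_index_1", "scalar_coupling_constant"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise FormatError(
                f"{path}: unparseable or missing value in column {col!r} "
                f"at data row {row}")
        frame[col] = numeric
    if frame["id"].duplicated().any():
        dup = int(frame.loc[frame["id"].duplicated(), "id"].iloc[0])
        raise FormatError(f"{path}: duplicate record id {dup}")
    unknown = set(frame["type"].unique()) - set(COUPLING_TYPE_LABELS)
    if unknown:
        raise FormatError(f"{path}: unknown coupling type label(s) {sorted(unknown)}")
    if (frame["atom_index_0"] == frame["atom_index_1"]).any():
        row = int(np.flatnonzero(frame["atom_index_0"] == frame["atom_index_1"])[0])
        raise FormatError(f"{path}: atom indices coincide at data row {row}")

    if "split" not in frame.columns:
        frame["split"] = "train"
    else:
        bad_split = set(frame["split"].unique()) - {"train", "public", "private"}
        if bad_split:
            raise FormatError(f"{path}: unknown split label(s) {sorted(bad_split)}")
    frame["id"] = frame["id"].astype(int)
    frame["atom_index_0"] = frame["atom_index_0"].astype(int)
    frame["atom_index_1"] = frame["atom_index_1"].astype(int)
    return CouplingDataset(
        records=frame.reset_index(drop=True),
        type_table=type_table or default_type_table(),
    )


def read_submission(
    path,
    expected_ids: Sequence[int] | np.ndarray,
    team_id: str | None = None,
    timestamp_days: float = 0.0,
) -> SubmissionSet:
    """Read a two-column submission file and validate coverage.

    Missing ids, unexpected extra ids and non-finite values are reported
    with up to 10 offenders each.
    """
    frame = _read_csv(path)
    missing_cols = {"id", "scalar_coupling_constant"} - set(frame.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing_cols)}")
    ids = pd.to_numeric(frame["id"], errors="coerce")
    if ids.isna().any():
        row = int(np.flatnonzero(ids.isna())[0])
        raise FormatError(f"{path}: unparseable id at data row {row}")
    values = pd.to_numeric(frame["scalar_coupling_constant"], errors="coerce")

    expected = np.asarray(expected_ids)
    got = ids.to_numpy(dtype=int)
    missing = np.setdiff1d(expected, got)
    if missing.size:
        raise IncompleteSubmissionError(
            f"{path}: missing prediction(s) for id(s) {missing[:10].tolist()}"
            + ("..." if missing.size > 10 else ""))
    extra = np.setdiff1d(got, expected)
    if extra.size:
        raise IncompleteSubmissionError(
            f"{path}: unexpected id(s) {extra[:10].tolist()}"
            + ("..." if extra.size > 10 else ""))
    if len(got) != len(set(got)):
        raise FormatError(f"{path}: duplicate submission ids")
    finite = np.isfinite(values.to_numpy(dtype=float))
    if not finite.all():
        bad = got[~finite]
        raise InvalidSubmissionError(
            f"{path}: non-finite prediction(s) at id(s) {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else ""))
    name = team_id if team_id is not None else pathlib.Path(path).stem
    return SubmissionSet(
        team_id=name,
        predictions=pd.Series(values.to_numpy(dtype=float), index=got),
        timestamp_days=timestamp_days,
    )


def write_dataset(dataset: CouplingDataset, outdir) -> dict[str, pathlib.Path]:
    """Write train.csv, test.csv and truth.csv in the competition layout."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = dataset.records
    train = records.loc[records["split"] == "train",
                        list(_TRUTH_COLUMNS) + ["scalar_coupling_constant"]]
    test = records.loc[records["split"].isin(("public", "private")),
                       list(_TRUTH_COLUMNS)]
    truth = records[list(_TRUTH_COLUMNS) + ["scalar_coupling_constant", "split"]]
    paths = {
        "train": outdir / "train.csv",
        "test": outdir / "test.csv",
        "truth": outdir / "truth.csv",
    }
    train.to_csv(paths["train"], index=False)
    test.to_csv(paths["test"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def write_submission(submission: SubmissionSet, path) -> pathlib.Path:
    """Write one submission as the two-column competition CSV."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({
        "id": submission.predictions.index.to_numpy(),
        "scalar_coupling_constant": submission.predictions.to_numpy(),
    })
    frame.to_csv(path, index=False)
    return path


def write_submission_population(
    submissions: Iterable[SubmissionSet], outdir
) -> pathlib.Path:
    """Write one CSV per submission plus a manifest.csv of metadata."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in submissions:
        fname = f"{sub.team_id}_s{sub.submission_index:02d}.csv"
        write_submission(sub, outdir / fname)
        rows.append({
            "file": fname,
            "team_id": sub.team_id,
            "timestamp_days": sub.timestamp_days,
            "submission_index": sub.submission_index,
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_submission_population(
    directory, expected_ids: Sequence[int] | np.ndarray
) -> list[SubmissionSet]:
    """Read every submission in a directory.

    If a ``manifest.csv`` is present its team ids and timestamps are used;
    otherwise each ``*.csv`` is one team's submission named by file stem.
    """
    directory = pathlib.Path(directory)
    manifest = directory / "manifest.csv"
    subs = []
    if manifest.exists():
        meta = _read_csv(manifest)
        for _, row in meta.iterrows():
            sub = read_submission(
                directory / row["file"], expected_ids,
                team_id=str(row["team_id"]),
                timestamp_days=float(row.get("timestamp_days", 0.0)))
            sub.submission_index = int(row.get("submission_index", 0))
            subs.append(sub)
    else:
        for path in sorted(directory.glob("*.csv")):
            subs.append(read_submission(path, expected_ids))
    if not subs:
        raise FormatError(f"no submissions found in {directory}")
    return subs


def read_structures(path) -> pd.DataFrame:
    """Read an atom-coordinates table (molecule_name, atom_index, atom, x, y, z).

    Carried through for compatibility with the competition layout; no
    analysis in this package consumes coordinates.
    """
    frame = _read_csv(path)
    required = {"molecule_name", "atom_index", "atom", "x", "y", "z"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return frame
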