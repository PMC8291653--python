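"""Synthetic competition generator.

Produces a desk-scale replica of the statistical structure of a
crowdsourced scalar-coupling prediction competition:

* a truth table of per-record coupling constants over 8 types with strongly
  unbalanced abundances and type-specific value scales;
* a molecule-level train/test split (default 65/35) and a record-level
  public/private split of the test records (default 29/71), both with exact
  largest-remainder counts;
* a population of team submissions whose errors are lineage-correlated
  (teams in the same "strategy cluster" share an error component) and
  shrink over time following a bi-exponential improvement envelope.

The generator plants ground truth the downstream analyses can be checked
against: for a team with skill ``s`` and unit envelope the per-type MAE
converges to ``s * sigma_t * sqrt(2/pi)``; residual correlation between two
teams is ``rho`` within a cluster and 0 across clusters.

All randomness flows from a single master seed through named substreams
(dataset, cluster-noise, idiosyncratic, timestamps, skills), so datasets
and submissions are byte-identical given the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import biexponential
from .errors import ConfigurationError
from .types import (
    COUPLING_TYPE_LABELS,
    CouplingDataset,
    CouplingType,
    LeaderboardTrace,
    SubmissionSet,
    validate_type_table,
)

_SUBSTREAMS = {"dataset": 0, "cluster-noise": 1, "idiosyncratic": 2,
               "timestamps": 3, "skills": 4}

# Default type table.  The abundance imbalance pins the most frequent type
# (3JHC) to ~33.6x the least frequent (1JHN), matching the real dataset's
# extreme count ratio; the remaining six relative weights and all value
# locations/scales (Hz) are package defaults resembling typical organic
# scalar-coupling magnitudes for each bond-count/nucleus combination.
_DEFAULT_TYPE_SPECS: dict[str, tuple[float, float, float]] = {
    # label: (location_hz, scale_hz, relative weight before normalization)
    "1JHC": (94.0, 18.0, 18.0),
    "1JHN": (47.0, 11.0, 1.0),
    "2JHH": (-10.3, 3.8, 5.0),
    "2JHC": (-0.3, 4.5, 25.0),
    "2JHN": (3.1, 3.7, 3.0),
    "3JHH": (4.8, 3.7, 20.0),
    "3JHC": (3.7, 3.7, 33.56),
    "3JHN": (0.9, 1.3, 6.0),
}


def default_type_table() -> dict[str, CouplingType]:
    """The 8 coupling types with default locations, scales and abundances."""
    total = sum(w for _, _, w in _DEFAULT_TYPE_SPECS.values())
    return {
        label: CouplingType(label, loc, scale, w / total)
        for label, (loc, scale, w) in _DEFAULT_TYPE_SPECS.items()
    }


def largest_remainder_counts(total: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer class counts summing exactly to ``total``.

    Each class gets floor(f * total); leftover units go to the classes with
    the largest fractional remainders (ties broken by class order).
    """
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


@dataclass
class PopulationConfig:
    """Study conditions for one synthetic competition.

    ``improvement_curve`` is (A, B, tau1, tau2, C) in score units/days; the
    error envelope applied to a submission at time t is
    ``exp(s(t) - s(0))`` where s is the bi-exponential, i.e. the envelope
    is 1 at the competition start and shrinks as the curve descends.
    """

    n_molecules: int = 200
    couplings_per_molecule: int = 20
    n_teams: int = 20
    n_clusters: int = 4
    cluster_assignment: dict[int, int] | None = None  # team index -> cluster
    within_cluster_correlation: float = 0.6
    per_type_error_scale: dict[str, float] | None = None  # Hz; default 0.1*scale_hz
    team_skill: dict[int, float] | None = None  # default lognormal draws
    improvement_curve: tuple[float, float, float, float, float] = (
        2.11, 2.97, 50.0, 1.29, -3.59)
    submissions_per_team: int = 5
    duration_days: float = 91.0
    train_fraction: float = 0.65
    public_fraction_of_test: float = 0.29
    seed: int = 0
    type_table: dict[str, CouplingType] = field(default_factory=default_type_table)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError(
                f"train_fraction must be in (0,1), got {self.train_fraction}")
        if not (0.0 < self.public_fraction_of_test < 1.0):
            raise ConfigurationError(
                f"public_fraction_of_test must be in (0,1), got "
                f"{self.public_fraction_of_test}")
        if not (0.0 <= self.within_cluster_correlation < 1.0):
            raise ConfigurationError(
                f"within_cluster_correlation must be in [0,1), got "
                f"{self.within_cluster_correlation}")
        A, B, tau1, tau2, C = self.improvement_curve
        if not (tau1 >= tau2 > 0):
            raise ConfigurationError(
                f"improvement_curve requires tau1 >= tau2 > 0, got "
                f"tau1={tau1}, tau2={tau2}")
        if self.n_molecules < 0 or self.couplings_per_molecule <= 0:
            raise ConfigurationError("molecule/coupling counts must be positive")
        if self.duration_days <= 0:
            raise ConfigurationError("duration_days must be positive")
        validate_type_table(self.type_table)
        if self.per_type_error_scale is not None:
            for label, s in self.per_type_error_scale.items():
                if not np.isfinite(s) or s <= 0:
                    raise ConfigurationError(
                        f"per_type_error_scale[{label!r}] must be finite "
                        f"and positive, got {s}")

    def rng(self, substream: str) -> np.random.Generator:
        """Seeded generator for one named substream of the master seed."""
        key = _SUBSTREAMS[substream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))

    def resolve_clusters(self) -> np.ndarray:
        """Cluster label per team (round-robin unless explicitly assigned)."""
        if self.cluster_assignment is not None:
            labels = np.array(
                [self.cluster_assignment[j] for j in range(self.n_teams)])
        else:
            labels = np.arange(self.n_teams) % self.n_clusters
        if labels.min() < 0 or labels.max() >= self.n_clusters:
            raise ConfigurationError(
                "cluster_assignment labels must lie in [0, n_clusters)")
        return labels

    def resolve_skills(self) -> np.ndarray:
        """Multiplicative skill factor per team (lower = more accurate)."""
        if self.team_skill is not None:
            return np.array([float(self.team_skill[j]) for j in range(self.n_teams)])
        rng = self.rng("skills")
        return np.exp(rng.normal(0.0, 0.5, size=self.n_teams))

    def resolve_error_scales(self) -> dict[str, float]:
        """Base per-type error scale sigma_t in Hz (default 10% of the value spread)."""
        if self.per_type_error_scale is not None:
            missing = set(COUPLING_TYPE_LABELS) - set(self.per_type_error_scale)
            if missing:
                raise ConfigurationError(
                    f"per_type_error_scale missing types: {sorted(missing)}")
            return dict(self.per_type_error_scale)
        return {label: 0.1 * t.scale_hz for label, t in self.type_table.items()}

    def envelope(self, t: np.ndarray | float) -> np.ndarray | float:
        """Error-scale multiplier at time t: exp(s(t) - s(0)), 1 at t=0."""
        A, B, tau1, tau2, C = self.improvement_curve
        s_t = biexponential(t, A, B, tau1, tau2, C)
        s_0 = biexponential(0.0, A, B, tau1, tau2, C)
        return np.exp(np.asarray(s_t) - s_0) if np.ndim(t) else math.exp(s_t - s_0)


def generate_dataset(config: PopulationConfig) -> CouplingDataset:
    """Generate the truth table with molecule-level train/test and
    record-level public/private splits.

    Split counts are exact under largest-remainder rounding: 1000 molecules
    at train_fraction 0.65 give exactly 650 train molecules, and 10,000
    test records at public fraction 0.29 give exactly 2900 public records.
    """
    rng = config.rng("dataset")
    n_mol = config.n_molecules
    per_mol = config.couplings_per_molecule
    n_records = n_mol * per_mol

    labels = list(config.type_table)
    freqs = [config.type_table[l].relative_frequency for l in labels]
    type_counts = largest_remainder_counts(n_records, freqs)
    type_column = np.repeat(np.array(labels, dtype=object), type_counts)
    rng.shuffle(type_column)

    locs = np.array([config.type_table[l].location_hz for l in type_column], dtype=float)
    scales = np.array([config.type_table[l].scale_hz for l in type_column], dtype=float)
    values = locs + scales * rng.standard_normal(n_records)

    molecule_idx = np.repeat(np.arange(n_mol), per_mol)
    within = np.tile(np.arange(per_mol), n_mol) if n_mol else np.array([], dtype=int)

    # Molecule-level train/test split.
    n_train, _ = largest_remainder_counts(
        n_mol, [config.train_fraction, 1.0 - config.train_fraction])
    mol_order = rng.permutation(n_mol)
    train_molecules = np.zeros(n_mol, dtype=bool)
    train_molecules[mol_order[:n_train]] = True
    split = np.where(train_molecules[molecule_idx], "train", "test").astype(object) \
        if n_records else np.array([], dtype=object)

    # Record-level public/private split within the test records.
    test_pos = np.flatnonzero(split == "test")
    n_public, _ = largest_remainder_counts(
        len(test_pos), [config.public_fraction_of_test,
                        1.0 - config.public_fraction_of_test])
    test_order = rng.permutation(len(test_pos))
    split[test_pos] = "private"
    split[test_pos[test_order[:n_public]]] = "public"

    records = pd.DataFrame({
        "id": np.arange(n_records),
        "molecule_name": np.array(
            [f"mol_{m:06d}" for m in molecule_idx], dtype=object),
        "atom_index_0": within,
        "atom_index_1": within + per_mol,  # synthetic labels; never equal
        "type": type_column,
        "scalar_coupling_constant": values,
        "split": split,
    })
    return CouplingDataset(records=records, type_table=dict(config.type_table),
                           seed=config.seed)


def generate_submissions(
    dataset: CouplingDataset, config: PopulationConfig
) -> list[SubmissionSet]:
    """Generate the time-stamped population of correlated team submissions.

    For team j (cluster c, skill s_j), submission at time t, record i of
    type tau:

        prediction_i = truth_i + s_j * envelope(t) * sigma_tau *
                       ( sqrt(rho) * Z_{c,i} + sqrt(1-rho) * eps_{j,i,sub} )

    where Z is a cluster-shared standard normal fixed per (cluster, record)
    and eps is idiosyncratic.  Marginally each residual is
    N(0, (s_j * envelope * sigma_tau)^2); the correlation between two teams'
    residuals is rho within a cluster and 0 across clusters.
    """
    test_ids = dataset.record_ids("test")
    if test_ids.size == 0:
        raise ConfigurationError("dataset has no test records")
    if config.n_teams < 1:
        raise ConfigurationError("n_teams must be >= 1")

    clusters = config.resolve_clusters()
    skills = config.resolve_skills()
    sigma_map = config.resolve_error_scales()

    truth = dataset.truth("test").to_numpy()
    types = dataset.types("test").to_numpy()
    sigma = np.array([sigma_map[t] for t in types])
    n_test = test_ids.size

    z = config.rng("cluster-noise").standard_normal((config.n_clusters, n_test))
    eps_rng = config.rng("idiosyncratic")
    ts_rng = config.rng("timestamps")
    rho = config.within_cluster_correlation
    sqrt_rho, sqrt_1mrho = math.sqrt(rho), math.sqrt(1.0 - rho)

    submissions: list[SubmissionSet] = []
    for j in range(config.n_teams):
        times = np.sort(ts_rng.uniform(0.0, config.duration_days,
                                       size=config.submissions_per_team))
        for s_idx, t in enumerate(times):
            eps = eps_rng.standard_normal(n_test)
            noise = sqrt_rho * z[clusters[j]] + sqrt_1mrho * eps
            preds = truth + skills[j] * config.envelope(float(t)) * sigma * noise
            submissions.append(SubmissionSet(
                team_id=f"team_{j:03d}",
                predictions=pd.Series(preds, index=test_ids),
                timestamp_days=float(t),
                submission_index=s_idx,
            ))
    return submissions


def generate_leaderboard_history(
    submissions: Iterable[SubmissionSet],
    dataset: CouplingDataset,
    split: str = "public",
) -> LeaderboardTrace:
    """Score every submission on a split and build the running-best trace.

    Submissions are ordered by timestamp, with ties broken stably by team
    id then submission index.  The running best is the cumulative minimum
    of score over that order, hence non-increasing.
    """
    from .dynamics import running_best
    from .scoring import score

    rows = sorted(submissions,
                  key=lambda s: (s.timestamp_days, s.team_id, s.submission_index))
    points = pd.DataFrame({
        "timestamp_days": [s.timestamp_days for s in rows],
        "score": [score(s, dataset, split).score for s in rows],
        "team_id": [s.team_id for s in rows],
    })
    return running_best(points)
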