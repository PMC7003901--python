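"""Domain types, validation and tabular I/O for arm-level NMA evidence.

The evidence base is a set of (network meta-analysis) studies, each reporting
event counts for one or more outcomes in one of three aggregate summary
formats:

* format 1 — only each patient's *first* event is counted (competing risks;
  patients are censored at their first event),
* format 2 — number of patients with *at least one* event of each outcome
  (a patient can contribute to several outcomes, once each),
* format 3 — *total* number of events of each outcome, repeats included.

Counts are held in long form: one CSV row per (study, arm, outcome).  A study
either reports an outcome on every arm or not at all; a missing outcome is an
absent row, never a zero count.  Treatments are dense integer codes ``1..T``
with treatment 1 the network reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ArmRecord",
    "StudyRecord",
    "NMADataset",
    "SchemaError",
    "ValidationError",
    "ConnectivityError",
    "IncompleteRecordError",
    "exposure",
    "read_dataset",
    "write_dataset",
]

#: canonical long-format column order
CSV_COLUMNS = [
    "study_id",
    "data_format",
    "arm",
    "treatment",
    "n",
    "person_years",
    "mean_followup",
    "outcome",
    "count",
]

_REL_TOL = 1e-6  # relative tolerance for the T̄ = E/n consistency check


class SchemaError(ValueError):
    """Input table is missing mandatory columns or has malformed values."""


class ValidationError(ValueError):
    """A record violates a structural invariant; message carries coordinates."""


class ConnectivityError(ValidationError):
    """The treatment comparison network is not connected."""


class IncompleteRecordError(ValidationError):
    """Neither person-years nor mean follow-up is available for an arm."""


@dataclass
class ArmRecord:
    """One trial arm: treatment, denominator, follow-up and outcome counts.

    ``person_years`` is the total exposure E (person-years at risk, shared by
    every outcome) and ``mean_followup`` the per-patient mean T̄ = E / n; at
    least one must be present and the other is derived.
    """

    study_id: str
    arm_index: int
    treatment: int
    n_randomized: int
    counts: dict[int, int] = field(default_factory=dict)
    person_years: float | None = None
    mean_followup: float | None = None

    def validate(self) -> None:
        where = f"study {self.study_id!r}, arm {self.arm_index}"
        if self.arm_index < 1:
            raise ValidationError(f"{where}: arm index must be >= 1")
        if self.treatment < 1:
            raise ValidationError(f"{where}: treatment code must be >= 1")
        if self.n_randomized <= 0:
            raise ValidationError(f"{where}: n_randomized must be positive")
        if self.person_years is None and self.mean_followup is None:
            raise IncompleteRecordError(
                f"{where}: need person_years or mean_followup"
            )
        for name, value in (
            ("person_years", self.person_years),
            ("mean_followup", self.mean_followup),
        ):
            if value is not None and (not np.isfinite(value) or value < 0):
                raise ValidationError(f"{where}: {name} must be finite and >= 0")
        if self.person_years is not None and self.mean_followup is not None:
            implied = self.person_years / self.n_randomized
            if not np.isclose(self.mean_followup, implied, rtol=_REL_TOL, atol=0.0):
                raise ValidationError(
                    f"{where}: mean_followup {self.mean_followup} inconsistent "
                    f"with person_years/n = {implied}"
                )
        for m, r in self.counts.items():
            if m < 1:
                raise ValidationError(f"{where}: outcome index {m} must be >= 1")
            if r < 0 or r != int(r):
                raise ValidationError(
                    f"{where}, outcome {m}: count must be a nonnegative integer"
                )

    def with_followup_filled(self) -> "ArmRecord":
        """Return a copy with the absent one of E / T̄ derived from the other."""
        if self.person_years is None:
            return replace(
                self, person_years=self.n_randomized * self.mean_followup
            )
        if self.mean_followup is None:
            return replace(
                self, mean_followup=self.person_years / self.n_randomized
            )
        return self


def exposure(arm: ArmRecord) -> float:
    """Person-years at risk E for an arm, computing n·T̄ when only the mean
    follow-up is stored."""
    if arm.person_years is not None:
        return float(arm.person_years)
    if arm.mean_followup is not None:
        return float(arm.n_randomized * arm.mean_followup)
    raise IncompleteRecordError(
        f"study {arm.study_id!r}, arm {arm.arm_index}: "
        "need person_years or mean_followup"
    )


@dataclass
class StudyRecord:
    """One study: data format, ordered arms, common set of reported outcomes.

    Arms are ordered by ``arm_index``; the first arm's treatment is the
    study-level baseline against which relative effects are expressed.
    """

    study_id: str
    data_format: int
    arms: list[ArmRecord]

    @property
    def reported_outcomes(self) -> tuple[int, ...]:
        return tuple(sorted(self.arms[0].counts)) if self.arms else ()

    @property
    def baseline_treatment(self) -> int:
        return self.arms[0].treatment

    def validate(self) -> None:
        where = f"study {self.study_id!r}"
        if self.data_format not in (1, 2, 3):
            raise ValidationError(
                f"{where}: data_format must be 1, 2 or 3, got {self.data_format}"
            )
        if len(self.arms) < 2:
            raise ValidationError(f"{where}: needs >= 2 arms")
        indices = [a.arm_index for a in self.arms]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValidationError(f"{where}: arm indices must be unique and ordered")
        for arm in self.arms:
            arm.validate()
        outcome_sets = {tuple(sorted(a.counts)) for a in self.arms}
        if len(outcome_sets) > 1:
            raise ValidationError(
                f"{where}: all arms must report the same outcomes "
                f"(outcome missingness is at study level), got {outcome_sets}"
            )
        if self.data_format == 1:
            for arm in self.arms:
                total = sum(arm.counts.values())
                if total > arm.n_randomized:
                    raise ValidationError(
                        f"{where}, arm {arm.arm_index}: format-1 first-event "
                        f"counts sum to {total} > n = {arm.n_randomized}"
                    )
        if self.data_format == 2:
            # per-outcome patient counts cannot exceed the denominator;
            # (a mortality outcome is also a patient count, so same bound)
            for arm in self.arms:
                for m, r in arm.counts.items():
                    if r > arm.n_randomized:
                        raise ValidationError(
                            f"{where}, arm {arm.arm_index}, outcome {m}: "
                            f"count {r} > n = {arm.n_randomized}"
                        )


@dataclass
class NMADataset:
    """The full evidence base handed to the models."""

    studies: list[StudyRecord]
    n_treatments: int
    n_outcomes: int
    outcome_labels: list[str] | None = None
    mortality_outcome: int | None = None

    def validate(self) -> None:
        if not self.studies:
            raise ValidationError("dataset has no studies")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study_id values")
        for study in self.studies:
            study.validate()
            for arm in study.arms:
                if arm.treatment > self.n_treatments:
                    raise ValidationError(
                        f"study {study.study_id!r}: treatment {arm.treatment} "
                        f"exceeds n_treatments = {self.n_treatments}"
                    )
                for m in arm.counts:
                    if m > self.n_outcomes:
                        raise ValidationError(
                            f"study {study.study_id!r}: outcome {m} exceeds "
                            f"n_outcomes = {self.n_outcomes}"
                        )
        if self.mortality_outcome is not None and not (
            1 <= self.mortality_outcome <= self.n_outcomes
        ):
            raise ValidationError(
                f"mortality_outcome {self.mortality_outcome} out of range"
            )
        self._check_connectivity()

    def _check_connectivity(self) -> None:
        graph = nx.Graph()
        graph.add_nodes_from(range(1, self.n_treatments + 1))
        for study in self.studies:
            codes = [a.treatment for a in study.arms]
            for a in codes:
                for b in codes:
                    if a != b:
                        graph.add_edge(a, b)
        if graph.number_of_nodes() > 1 and not nx.is_connected(graph):
            parts = [sorted(c) for c in nx.connected_components(graph)]
            raise ConnectivityError(
                f"treatment network is disconnected: components {parts}"
            )

    @property
    def treatments(self) -> list[int]:
        return sorted({a.treatment for s in self.studies for a in s.arms})


def _to_frame(dataset: NMADataset) -> pd.DataFrame:
    rows = []
    for study in dataset.studies:
        for arm in study.arms:
            for m in sorted(arm.counts):
                rows.append(
                    {
                        "study_id": study.study_id,
                        "data_format": study.data_format,
                        "arm": arm.arm_index,
                        "treatment": arm.treatment,
                        "n": arm.n_randomized,
                        "person_years": arm.person_years,
                        "mean_followup": arm.mean_followup,
                        "outcome": m,
                        "count": arm.counts[m],
                    }
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def read_dataset(
    path,
    *,
    schema: dict[str, str] | None = None,
    mortality_outcome: int | None = None,
    outcome_labels: list[str] | None = None,
    n_treatments: int | None = None,
) -> NMADataset:
    """Read a long-format CSV into a validated :class:`NMADataset`.

    Parameters
    ----------
    schema
        Optional mapping from the file's column names to the canonical names
        in :data:`CSV_COLUMNS`.
    mortality_outcome
        Outcome index modelled as death in format-2 studies (Poisson block
        instead of the binomial/cloglog block).
    """
    frame = pd.read_csv(path)
    if schema:
        frame = frame.rename(columns=schema)
    missing = [
        c
        for c in CSV_COLUMNS
        if c not in frame.columns and c not in ("person_years", "mean_followup")
    ]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for optional in ("person_years", "mean_followup"):
        if optional not in frame.columns:
            frame[optional] = np.nan
    return dataset_from_frame(
        frame,
        mortality_outcome=mortality_outcome,
        outcome_labels=outcome_labels,
        n_treatments=n_treatments,
    )


def dataset_from_frame(
    frame: pd.DataFrame,
    *,
    mortality_outcome: int | None = None,
    outcome_labels: list[str] | None = None,
    n_treatments: int | None = None,
) -> NMADataset:
    """Assemble and validate a dataset from an in-memory long-format table."""
    studies: list[StudyRecord] = []
    for study_id, study_rows in frame.groupby("study_id", sort=False):
        formats = study_rows["data_format"].unique()
        if len(formats) != 1:
            raise ValidationError(
                f"study {study_id!r}: conflicting data_format values {formats}"
            )
        arms = []
        for arm_index, arm_rows in study_rows.groupby("arm", sort=True):
            first = arm_rows.iloc[0]
            for col in ("treatment", "n"):
                if arm_rows[col].nunique() != 1:
                    raise ValidationError(
                        f"study {study_id!r}, arm {arm_index}: "
                        f"inconsistent {col} across outcome rows"
                    )
            counts = {}
            for _, row in arm_rows.iterrows():
                m = int(row["outcome"])
                if m in counts:
                    raise ValidationError(
                        f"study {study_id!r}, arm {arm_index}: "
                        f"duplicate rows for outcome {m}"
                    )
                counts[m] = int(row["count"])
            E = first["person_years"]
            tbar = first["mean_followup"]
            arm = ArmRecord(
                study_id=str(study_id),
                arm_index=int(arm_index),
                treatment=int(first["treatment"]),
                n_randomized=int(first["n"]),
                counts=counts,
                person_years=None if pd.isna(E) else float(E),
                mean_followup=None if pd.isna(tbar) else float(tbar),
            )
            arm.validate()
            arms.append(arm.with_followup_filled())
        studies.append(
            StudyRecord(study_id=str(study_id), data_format=int(formats[0]), arms=arms)
        )
    all_treatments = sorted({a.treatment for s in studies for a in s.arms})
    all_outcomes = sorted({m for s in studies for m in s.reported_outcomes})
    dataset = NMADataset(
        studies=studies,
        n_treatments=n_treatments or max(all_treatments),
        n_outcomes=max(all_outcomes),
        outcome_labels=outcome_labels,
        mortality_outcome=mortality_outcome,
    )
    dataset.validate()
    return dataset


def write_dataset(dataset: NMADataset, path) -> None:
    """Write the dataset back to the canonical long CSV layout.

    Counts and metadata round-trip exactly; follow-up columns are written
    with full float precision.
    """
    _to_frame(dataset).to_csv(path, index=False)
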