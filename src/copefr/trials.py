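"""Predation-trial records, CSV interchange, design enumeration and exclusions.

A *trial* is one Petri-dish observation: a known number of newly hatched
mosquito larvae exposed (or not) to a single copepod predator for a fixed
period, after which survivors are counted.  Two experimental arms are
distinguished: the functional-response arm (``FR``, a gradient of initial
densities) and the predation-efficiency arm (``PE``, a constant density of
24 larvae per dish).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SPECIES",
    "TEMPERATURES",
    "PredationTrial",
    "CopepodRecord",
    "ExperimentDesign",
    "DesignSummary",
    "STUDY_DESIGN",
    "TrialValidationError",
    "SchemaError",
    "read_trials",
    "write_trials",
    "read_copepods",
    "write_copepods",
    "enumerate_design",
    "apply_exclusions",
    "ExclusionRule",
    "insufficient_length",
    "predator_death",
    "double_predator",
]

SPECIES = ("M_albidus", "M_viridis", "none")
TEMPERATURES = (15, 20, 25)

TRIAL_COLUMNS = [
    "trial_id",
    "experiment",
    "species",
    "temperature_C",
    "initial_count",
    "survivors",
    "predator_count",
    "duration_h",
    "arena_volume_mL",
    "copepod_length_mm",
    "excluded",
    "exclusion_reason",
]

COPEPOD_COLUMNS = ["copepod_id", "species", "experiment", "length_mm"]


class TrialValidationError(ValueError):
    """A trial record violates a structural invariant."""


class SchemaError(ValueError):
    """A CSV file does not match the documented column layout."""


@dataclass
class PredationTrial:
    """One Petri-dish observation.

    ``initial_count`` is the number of larvae placed in the arena (N0),
    ``survivors`` the count alive when the predator was removed.
    ``predator_count`` is 0 (control) or 1 (treatment).
    """

    trial_id: str
    experiment: str  # "FR" or "PE"
    species: str  # "M_albidus", "M_viridis" or "none" for controls
    temperature_C: int
    initial_count: int
    survivors: int
    predator_count: int = 1
    duration_h: float = 6.0
    arena_volume_mL: float = 20.0
    copepod_length_mm: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        tid = self.trial_id
        if self.experiment not in ("FR", "PE"):
            raise TrialValidationError(f"{tid}: experiment must be FR or PE")
        if self.species not in SPECIES:
            raise TrialValidationError(f"{tid}: unknown species {self.species!r}")
        if self.temperature_C not in TEMPERATURES:
            raise TrialValidationError(
                f"{tid}: temperature_C must be one of {TEMPERATURES}"
            )
        if self.initial_count < 1:
            raise TrialValidationError(f"{tid}: initial_count must be positive")
        if not 0 <= self.survivors <= self.initial_count:
            raise TrialValidationError(
                f"{tid}: survivors ({self.survivors}) must lie in "
                f"[0, initial_count={self.initial_count}]"
            )
        if self.predator_count not in (0, 1):
            raise TrialValidationError(f"{tid}: predator_count must be 0 or 1")
        if (self.species == "none") != (self.predator_count == 0):
            raise TrialValidationError(
                f"{tid}: species is 'none' iff predator_count is 0"
            )
        if self.duration_h <= 0 or self.arena_volume_mL <= 0:
            raise TrialValidationError(f"{tid}: duration and volume must be positive")
        if self.copepod_length_mm is not None and self.copepod_length_mm <= 0:
            raise TrialValidationError(f"{tid}: copepod_length_mm must be positive")

    @property
    def eaten(self) -> int:
        """Larvae no longer alive at the end of the trial."""
        return self.initial_count - self.survivors


@dataclass
class CopepodRecord:
    """A single measured copepod; mass follows the allometric power law."""

    copepod_id: str
    species: str
    experiment: str
    length_mm: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise TrialValidationError(f"{self.copepod_id}: length_mm must be > 0")
        if self.species not in ("M_albidus", "M_viridis"):
            raise TrialValidationError(f"{self.copepod_id}: bad species")
        if self.experiment not in ("FR", "PE"):
            raise TrialValidationError(f"{self.copepod_id}: bad experiment")

    @property
    def mass_mg(self) -> float:
        from .allometry import length_to_mass

        return length_to_mass(self.length_mm)


@dataclass
class ExperimentDesign:
    """Counts defining both experimental arms.

    Defaults reproduce the published design: densities 1-32 with four
    predator replicates and one control per density, six species x
    temperature combinations, and a predation-efficiency arm of 24 dishes
    of 24 larvae per temperature (8 dishes per group, 3 groups).
    """

    densities: tuple[int, ...] = (1, 2, 4, 8, 16, 24, 32)
    replicates_per_density: int = 4
    controls_per_density: int = 1
    species_list: tuple[str, ...] = ("M_albidus", "M_viridis")
    temperatures_list: tuple[int, ...] = (15, 20, 25)
    pe_larvae_per_dish: int = 24
    pe_dishes_per_group: int = 8
    pe_groups: int = 3

    def __post_init__(self) -> None:
        if not self.densities:
            raise ValueError("densities list must be non-empty")
        if any(d < 1 for d in self.densities):
            raise ValueError("densities must be positive")
        if list(self.densities) != sorted(set(self.densities)):
            raise ValueError("densities must be strictly increasing")
        for name in (
            "replicates_per_density",
            "pe_larvae_per_dish",
            "pe_dishes_per_group",
            "pe_groups",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


STUDY_DESIGN = ExperimentDesign()


@dataclass
class DesignSummary:
    """Grand totals implied by an :class:`ExperimentDesign`."""

    larvae_per_tub: int
    dishes_per_combination: int
    larvae_per_combination: int
    n_combinations: int
    fr_total_larvae: int
    fr_total_dishes: int
    fr_copepods: int
    pe_total_dishes: int
    pe_total_larvae: int
    pe_control_larvae_per_temperature: int
    pe_copepods: int


def enumerate_design(design: ExperimentDesign) -> DesignSummary:
    """Work out dish, larva and predator totals from the design counts.

    For the published design this gives 87 larvae per tub, 435 per
    species x temperature combination, 2,610 larvae and 168 copepods in
    the functional-response arm, and 1,728 larvae (192 controls per
    temperature) in the predation-efficiency arm.
    """
    per_tub = sum(design.densities)
    reps = design.replicates_per_density + design.controls_per_density
    dishes_per_combo = len(design.densities) * reps
    larvae_per_combo = per_tub * reps
    n_combo = len(design.species_list) * len(design.temperatures_list)
    fr_copepods = (
        len(design.densities)
        * design.replicates_per_density
        * n_combo
    )
    pe_dishes = design.pe_dishes_per_group * design.pe_groups * len(
        design.temperatures_list
    )
    pe_larvae = pe_dishes * design.pe_larvae_per_dish
    pe_ctrl_per_temp = design.pe_dishes_per_group * design.pe_larvae_per_dish
    # one of the pe_groups is the control group; the rest hold one predator each
    pe_copepods = (
        (design.pe_groups - 1)
        * design.pe_dishes_per_group
        * len(design.temperatures_list)
    )
    return DesignSummary(
        larvae_per_tub=per_tub,
        dishes_per_combination=dishes_per_combo,
        larvae_per_combination=larvae_per_combo,
        n_combinations=n_combo,
        fr_total_larvae=larvae_per_combo * n_combo,
        fr_total_dishes=dishes_per_combo * n_combo,
        fr_copepods=fr_copepods,
        pe_total_dishes=pe_dishes,
        pe_total_larvae=pe_larvae,
        pe_control_larvae_per_temperature=pe_ctrl_per_temp,
        pe_copepods=pe_copepods,
    )


# ---------------------------------------------------------------------------
# CSV interchange


def _trial_to_row(t: PredationTrial) -> dict:
    row = dataclasses.asdict(t)
    row["copepod_length_mm"] = (
        "" if t.copepod_length_mm is None else repr(t.copepod_length_mm)
    )
    row["exclusion_reason"] = t.exclusion_reason or ""
    row["excluded"] = str(bool(t.excluded))
    return row


def write_trials(trials: Iterable[PredationTrial], path: str | Path) -> None:
    """Write trials to CSV in the documented fixed column order."""
    rows = [_trial_to_row(t) for t in trials]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def read_trials(path: str | Path, schema: str | None = None) -> list[PredationTrial]:
    """Read and validate a ``trials.csv`` file.

    Parameters
    ----------
    path:
        CSV file with the documented header.
    schema:
        Optional arm filter, ``"FR"`` or ``"PE"``; when given, rows from
        the other arm raise a :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    trials: list[PredationTrial] = []
    for _, row in df.iterrows():
        length = row["copepod_length_mm"]
        trial = PredationTrial(
            trial_id=row["trial_id"],
            experiment=row["experiment"],
            species=row["species"],
            temperature_C=int(row["temperature_C"]),
            initial_count=int(row["initial_count"]),
            survivors=int(row["survivors"]),
            predator_count=int(row["predator_count"]),
            duration_h=float(row["duration_h"]),
            arena_volume_mL=float(row["arena_volume_mL"]),
            copepod_length_mm=float(length) if length != "" else None,
            excluded=row["excluded"] == "True",
            exclusion_reason=row["exclusion_reason"] or None,
        )
        if schema is not None and trial.experiment != schema:
            raise SchemaError(
                f"{trial.trial_id}: experiment {trial.experiment} does not match "
                f"requested schema {schema}"
            )
        trials.append(trial)
    return trials


def write_copepods(records: Iterable[CopepodRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "copepod_id": r.copepod_id,
                "species": r.species,
                "experiment": r.experiment,
                "length_mm": repr(r.length_mm),
            }
            for r in records
        ],
        columns=COPEPOD_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_copepods(path: str | Path) -> list[CopepodRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COPEPOD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return [
        CopepodRecord(
            copepod_id=row["copepod_id"],
            species=row["species"],
            experiment=row["experiment"],
            length_mm=float(row["length_mm"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Exclusion rules
#
# Trials excluded from analysis are retained (soft delete) with a reason so
# the exclusion log stays auditable; analysis code filters on ``excluded``.


@dataclass(frozen=True)
class ExclusionRule:
    name: str
    threshold: float | None = None
    trial_ids: tuple[str, ...] = ()


def insufficient_length(threshold: float = 1.2) -> ExclusionRule:
    """Exclude predator trials whose copepod is shorter than ``threshold`` mm.

    Undersized individuals may be males or immatures rather than adult
    non-gravid females.  The default 1.2 mm is the low end of the published
    adult length ranges; the cutoff is configurable because no single value
    is canonical.
    """
    return ExclusionRule("insufficient_length", threshold=threshold)


def predator_death(trial_ids: Sequence[str]) -> ExclusionRule:
    """Exclude trials whose copepod died during the starvation period."""
    return ExclusionRule("predator_death", trial_ids=tuple(trial_ids))


def double_predator(trial_ids: Sequence[str]) -> ExclusionRule:
    """Exclude dishes that accidentally received two predators."""
    return ExclusionRule("double_predator", trial_ids=tuple(trial_ids))


_KNOWN_RULES = {"insufficient_length", "predator_death", "double_predator"}


def apply_exclusions(
    trials: Sequence[PredationTrial], rules: Sequence[ExclusionRule]
) -> tuple[list[PredationTrial], pd.DataFrame]:
    """Flag trials matching any rule; return flagged copies and a log.

    Measurement fields are never mutated; the returned list contains the
    same trials with ``excluded``/``exclusion_reason`` set where a rule
    fired.  The log reports exclusion counts per species x temperature
    group and reason.
    """
    for rule in rules:
        if rule.name not in _KNOWN_RULES:
            raise ValueError(f"unknown exclusion rule: {rule.name!r}")
    out: list[PredationTrial] = []
    log_rows: list[dict] = []
    for t in trials:
        reason = t.exclusion_reason if t.excluded else None
        for rule in rules:
            if reason is not None:
                break
            if rule.name == "insufficient_length":
                if (
                    t.predator_count >= 1
                    and t.copepod_length_mm is not None
                    and t.copepod_length_mm < rule.threshold
                ):
                    reason = "insufficient_length"
            elif t.trial_id in rule.trial_ids:
                reason = rule.name
        flagged = dataclasses.replace(
            t, excluded=reason is not None, exclusion_reason=reason
        )
        out.append(flagged)
        if reason is not None:
            log_rows.append(
                {
                    "species": t.species,
                    "temperature_C": t.temperature_C,
                    "reason": reason,
                    "trial_id": t.trial_id,
                }
            )
    if log_rows:
        log = (
            pd.DataFrame(log_rows)
            .groupby(["species", "temperature_C", "reason"])
            .size()
            .rename("n_excluded")
            .reset_index()
        )
    else:
        log = pd.DataFrame(
            columns=["species", "temperature_C", "reason", "n_excluded"]
        )
    return out, log
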