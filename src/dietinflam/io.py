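"""Reading, validation and writing of the configuration and subject tables.

Three configuration tables drive the scoring engines:

* a **parameter reference** (one row per food parameter: global mean and SD of
  its per-1000-kcal density, and its inflammatory effect score),
* a **TEAC table** (one row per food item: antioxidant content in mmol Trolox
  equivalents per kg, and a coffee flag),
* subject-level **intake tables** (wide CSV: one row per subject, energy plus
  one column per parameter; optionally a parallel food-item gram table).

All tables are delimited text (comma by default, tab via ``sep="\\t"``) with a
header row, UTF-8, ``.`` decimal.  Subjects failing validation are excluded
row-wise and reported in a machine-readable exclusion manifest rather than
aborting the run; structural problems in configuration tables (duplicate
parameters, non-positive SDs, missing columns) are hard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("dietinflam.io")

PARAMETER_REFERENCE_COLUMNS = ("parameter_name", "global_mean", "global_sd", "effect_score")
TEAC_COLUMNS = ("item_name", "teac_content", "is_coffee")

#: Column name for missing categorical covariate levels.  The analysis layer
#: models "unknown" as its own dummy level, so it must survive I/O as a token.
UNKNOWN = "unknown"


class ValidationError(ValueError):
    """A configuration or input table violates a structural invariant."""


@dataclass(frozen=True)
class ParameterRecord:
    """Reference entry for one food parameter."""

    name: str
    global_mean: float
    global_sd: float
    effect_score: float


class ParameterReference:
    """Validated collection of :class:`ParameterRecord`.

    The full schema of the underlying index holds up to 45 food parameters;
    any subset is permitted (the bundled synthetic fixture carries 30).
    """

    MAX_PARAMETERS = 45

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PARAMETER_REFERENCE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(
                f"parameter reference is missing column(s) {missing}; "
                f"expected header {list(PARAMETER_REFERENCE_COLUMNS)}"
            )
        frame = frame.loc[:, list(PARAMETER_REFERENCE_COLUMNS)].copy()
        frame["parameter_name"] = frame["parameter_name"].astype(str)
        dup = frame["parameter_name"][frame["parameter_name"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate parameter name(s): {sorted(set(dup))}")
        for col in ("global_mean", "global_sd", "effect_score"):
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        if not np.isfinite(frame[["global_mean", "global_sd", "effect_score"]].to_numpy()).all():
            raise ValidationError("parameter reference contains non-finite values")
        bad_sd = frame.loc[frame["global_sd"] <= 0, "parameter_name"]
        if len(bad_sd):
            raise ValidationError(f"non-positive global_sd for parameter(s): {list(bad_sd)}")
        if len(frame) > self.MAX_PARAMETERS:
            raise ValidationError(
                f"{len(frame)} parameters exceed the {self.MAX_PARAMETERS}-parameter schema"
            )
        self._frame = frame.set_index("parameter_name", drop=False)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, name: str) -> bool:
        return name in self._frame.index

    def __getitem__(self, name: str) -> ParameterRecord:
        row = self._frame.loc[name]
        return ParameterRecord(name, row["global_mean"], row["global_sd"], row["effect_score"])

    @property
    def names(self) -> list[str]:
        return list(self._frame.index)

    @property
    def global_means(self) -> np.ndarray:
        return self._frame["global_mean"].to_numpy(float)

    @property
    def global_sds(self) -> np.ndarray:
        return self._frame["global_sd"].to_numpy(float)

    @property
    def effect_scores(self) -> np.ndarray:
        return self._frame["effect_score"].to_numpy(float)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.reset_index(drop=True).copy()

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float, float, float]]) -> "ParameterReference":
        return cls(pd.DataFrame(records, columns=list(PARAMETER_REFERENCE_COLUMNS)))


class TeacTable:
    """Validated antioxidant-content lookup (mmol TE per kg of edible food)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TEAC_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(
                f"TEAC table is missing column(s) {missing}; expected header {list(TEAC_COLUMNS)}"
            )
        frame = frame.loc[:, list(TEAC_COLUMNS)].copy()
        frame["item_name"] = frame["item_name"].astype(str)
        dup = frame["item_name"][frame["item_name"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate food item(s) in TEAC table: {sorted(set(dup))}")
        frame["teac_content"] = pd.to_numeric(frame["teac_content"], errors="raise")
        if (frame["teac_content"] < 0).any():
            bad = frame.loc[frame["teac_content"] < 0, "item_name"]
            raise ValidationError(f"negative teac_content for item(s): {list(bad)}")
        frame["is_coffee"] = frame["is_coffee"].astype(bool)
        if frame.empty:
            logger.warning("TEAC table is empty; NEAC scores will be undefined")
        self._frame = frame.set_index("item_name", drop=False)

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, item: str) -> bool:
        return item in self._frame.index

    @property
    def items(self) -> list[str]:
        return list(self._frame.index)

    @property
    def contents(self) -> Mapping[str, float]:
        return self._frame["teac_content"].to_dict()

    @property
    def coffee_items(self) -> set[str]:
        return set(self._frame.loc[self._frame["is_coffee"], "item_name"])

    def to_frame(self) -> pd.DataFrame:
        return self._frame.reset_index(drop=True).copy()

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class SubjectIntake:
    """One subject's daily energy, raw parameter intakes and optional item grams."""

    subject_id: str
    energy_kcal: float
    parameter_intakes: dict[str, float]
    item_grams: dict[str, float] | None = None
    alcohol_g: float = 0.0


@dataclass
class LoadReport:
    """Outcome of loading a subject-level table: exclusions and ignored columns."""

    n_loaded: int = 0
    ignored_columns: list[str] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (subject_id, reason)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["subject_id", "reason"])

    def write_manifest(self, path, sep: str = ",") -> None:
        self.manifest().to_csv(path, sep=sep, index=False)


def load_parameter_reference(path, sep: str = ",") -> ParameterReference:
    """Read and validate a parameter reference table from delimited text."""
    return ParameterReference(pd.read_csv(path, sep=sep))


def load_teac_table(path, sep: str = ",") -> TeacTable:
    """Read and validate a TEAC content table from delimited text."""
    return TeacTable(pd.read_csv(path, sep=sep))


def load_intake_table(
    path, reference: ParameterReference, sep: str = ","
) -> tuple[list[SubjectIntake], LoadReport]:
    """Read a wide subject × parameter intake table.

    Parameter columns are intersected with the reference; unrecognised columns
    are reported in the returned :class:`LoadReport` and ignored.  Rows with
    non-positive energy or any negative intake are excluded (not fatal) and
    listed with reasons in the report.
    """
    frame = pd.read_csv(path, sep=sep)
    required = {"subject_id", "energy_kcal"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"intake table is missing column(s) {sorted(missing)}")
    special = {"subject_id", "energy_kcal", "alcohol_g", "energy_nonalcohol"}
    param_cols = [c for c in frame.columns if c in reference and c not in special]
    ignored = [c for c in frame.columns if c not in special and c not in reference]
    report = LoadReport(ignored_columns=ignored)
    if ignored:
        logger.info("ignoring %d unrecognised column(s): %s", len(ignored), ignored)

    subjects: list[SubjectIntake] = []
    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        energy = float(row["energy_kcal"])
        if not np.isfinite(energy) or energy <= 0:
            report.exclusions.append((sid, f"non-positive energy_kcal ({energy})"))
            continue
        intakes = {c: float(row[c]) for c in param_cols if pd.notna(row[c])}
        negative = [c for c, v in intakes.items() if v < 0]
        if negative:
            report.exclusions.append((sid, f"negative intake for {negative}"))
            continue
        alcohol = float(row["alcohol_g"]) if "alcohol_g" in frame.columns else intakes.get("alcohol", 0.0)
        subjects.append(SubjectIntake(sid, energy, intakes, alcohol_g=alcohol))
    report.n_loaded = len(subjects)
    if report.exclusions:
        logger.info("excluded %d subject(s) while loading %s", report.n_excluded, path)
    return subjects, report


def load_item_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a wide subject × food-item gram table, indexed by subject_id."""
    frame = pd.read_csv(path, sep=sep)
    if "subject_id" not in frame.columns:
        raise ValidationError("item table is missing the subject_id column")
    frame["subject_id"] = frame["subject_id"].astype(str)
    item_cols = [c for c in frame.columns if c != "subject_id"]
    values = frame[item_cols].to_numpy(float)
    if (values < 0).any():
        bad = frame.loc[(values < 0).any(axis=1), "subject_id"]
        raise ValidationError(f"negative gram intake for subject(s): {list(bad)}")
    return frame.set_index("subject_id")


def attach_item_grams(subjects: list[SubjectIntake], items: pd.DataFrame) -> int:
    """Attach per-item gram intakes to subjects in place; return matches."""
    matched = 0
    for subject in subjects:
        if subject.subject_id in items.index:
            subject.item_grams = items.loc[subject.subject_id].to_dict()
            matched += 1
    return matched


def default_parameter_reference() -> ParameterReference:
    """The bundled 30-parameter synthetic placeholder reference."""
    path = resources.files("dietinflam.data").joinpath("synthetic_parameter_reference.csv")
    with resources.as_file(path) as p:
        return load_parameter_reference(p)


def default_teac_table() -> TeacTable:
    """The bundled synthetic placeholder TEAC table."""
    path = resources.files("dietinflam.data").joinpath("synthetic_teac_table.csv")
    with resources.as_file(path) as p:
        return load_teac_table(p)
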