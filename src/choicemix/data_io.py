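"""Read, validate and assemble choice and respondent tables.

The choice table has one row per observed binary choice with *raw*
differenced attribute columns (option 2 minus option 1); the respondent
table has one row per participant with socio-demographic covariates.
``assemble_panel`` joins them, applies the model scaling (cattle per 100
head, small stock per 200, wage per 10,000 KSh), prepends an intercept
column of ones, and prepares covariate matrices for the hierarchical
coefficient means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A value violates its legal set; cites row and column."""


#: legal value sets for the coded difference columns (raw units)
CHOICE_LEVEL_SETS = {
    "choice": {0, 1},
    "access": {-1, 0, 1},
    "cattle": {-100, -60, -40, 0, 40, 60, 100},
    "cons150": {-1, 0, 1},
    "cons75": {-1, 0, 1},
    "cult": {-1, 0, 1},
    "smlstk": {-200, -120, -80, 0, 80, 120, 200},
    "wage": {-10000, -6000, -4000, 0, 4000, 6000, 10000},
}

CHOICE_COLUMNS = ["choice", "access", "cattle", "cons150", "cons75",
                  "cult", "smlstk", "wage", "indiv_id", "choice_id"]

ATTRIBUTE_COLUMNS = ["access", "cattle", "cons150", "cons75", "cult", "smlstk", "wage"]

#: divisor taking raw differences to the model scale, per attribute column
MODEL_SCALES = {"access": 1.0, "cattle": 100.0, "cons150": 1.0, "cons75": 1.0,
                "cult": 1.0, "smlstk": 200.0, "wage": 10000.0}

RESPONDENT_BINARY = ["sexF", "consY", "cattle51plus", "smlstk101plus", "vehicle",
                     "ageset2", "ageset3", "ageset4", "educated", "olmareiHead",
                     "leadership"]
RESPONDENT_NONNEG = ["land", "buildingsMud", "buildingsIron", "hhsize",
                     "settlementYears"]
RESPONDENT_COLUMNS = ["indiv_id", "sexF", "consY", "land", "cattle51plus",
                      "smlstk101plus", "buildingsMud", "buildingsIron", "vehicle",
                      "ageset2", "ageset3", "ageset4", "educated",
                      "settlementYears", "hhsize", "olmareiHead", "leadership"]

#: respondent covariates that are centred and scaled by two sample
#: standard deviations when used as hierarchical predictors
SCALED_COVARIATES = ("land", "settlementYears", "hhsize", "buildingsMud",
                     "buildingsIron")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _check_no_blanks(df: pd.DataFrame, what: str) -> None:
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"{what}: blank cells in rows {rows}; "
                              "missing values are not permitted")


def validate_choice_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory choice table against the schema."""
    _require_columns(df, CHOICE_COLUMNS, "choice table")
    df = df[CHOICE_COLUMNS].reset_index(drop=True)
    _check_no_blanks(df, "choice table")
    for col, legal in CHOICE_LEVEL_SETS.items():
        bad = ~df[col].isin(legal)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"choice table: illegal value {df.loc[row, col]!r} in "
                f"column {col!r} at row {row}")
    cid = df["choice_id"]
    if ((cid < 1) | (cid > 16) | (cid != cid.astype(int))).any():
        raise ValidationError("choice table: choice_id must be an integer in 1..16")
    dup = df.duplicated(subset=["indiv_id", "choice_id"]).to_numpy()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        pair = df.iloc[i][["indiv_id", "choice_id"]].tolist()
        raise ValidationError(f"choice table: duplicate (indiv_id, choice_id) {pair}")
    for col in CHOICE_LEVEL_SETS:
        df[col] = df[col].astype(int)
    df["choice_id"] = df["choice_id"].astype(int)
    return df


def read_choice_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a choice-observation table (comma-separated)."""
    df = pd.read_csv(path)
    return validate_choice_frame(df)


def write_choice_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_choice_frame(df).to_csv(path, index=False)


def validate_respondent_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory respondent table against the schema."""
    _require_columns(df, RESPONDENT_COLUMNS, "respondent table")
    df = df[RESPONDENT_COLUMNS].reset_index(drop=True)
    _check_no_blanks(df, "respondent table")
    if df["indiv_id"].duplicated().any():
        dup = df.loc[df["indiv_id"].duplicated(), "indiv_id"].iloc[0]
        raise ValidationError(f"respondent table: duplicate indiv_id {dup!r}")
    for col in RESPONDENT_BINARY:
        if ~df[col].isin([0, 1]).all():
            row = int(df.index[~df[col].isin([0, 1])][0])
            raise ValidationError(
                f"respondent table: column {col!r} must be 0/1 (row {row})")
    agesets = df[["ageset2", "ageset3", "ageset4"]].sum(axis=1)
    if (agesets > 1).any():
        row = int(df.index[agesets > 1][0])
        raise ValidationError(
            f"respondent table: more than one age-set dummy set at row {row}")
    for col in RESPONDENT_NONNEG:
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0])
            raise ValidationError(
                f"respondent table: negative {col!r} at row {row}")
    return df


def read_respondent_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a respondent-characteristics table."""
    df = pd.read_csv(path)
    return validate_respondent_frame(df)


def write_respondent_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_respondent_frame(df).to_csv(path, index=False)


@dataclass
class ChoicePanel:
    """Model-ready panel: scaled design matrix, response, and covariates.

    ``X`` holds (intercept, access, cattle/100, cons150, cons75, cult,
    smlstk/200, wage/10000) per observed choice; rows are sorted by
    individual. ``respondents`` keeps one validated row per individual in
    the order of ``indiv_ids``. Covariate matrices for the hierarchical
    means are built on demand by :meth:`covariate_matrix`, which centres
    and rescales the count-like covariates by two sample standard
    deviations (binary covariates stay 0/1).
    """

    rows: pd.DataFrame
    respondents: pd.DataFrame
    X: np.ndarray
    y: np.ndarray
    indiv_ids: np.ndarray          # unique ids, panel order
    row_individual: np.ndarray     # per-row index into indiv_ids
    covariate_transforms: dict = field(default_factory=dict)

    coefficient_names = ("intercept", "access", "cattle", "cons150", "cons75",
                         "cult", "smlstk", "wage")

    @property
    def n_individuals(self) -> int:
        return len(self.indiv_ids)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def rows_per_individual(self) -> pd.Series:
        return pd.Series(self.row_individual).value_counts().sort_index()

    def covariate_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        """n_individuals x C matrix of model-scale covariates.

        Count-like covariates (land, settlementYears, hhsize,
        buildingsMud, buildingsIron) are centred and divided by two
        sample standard deviations; the transform used is recorded in
        ``covariate_transforms`` so group profiles can be mapped to the
        same scale later.
        """
        cols = []
        for name in covariates:
            if name not in self.respondents.columns:
                raise SchemaError(f"unknown covariate {name!r}")
            v = self.respondents[name].to_numpy(dtype=float)
            if name in SCALED_COVARIATES:
                center, scale = float(v.mean()), 2.0 * float(v.std(ddof=1))
                if scale == 0:
                    scale = 1.0
                v = (v - center) / scale
                self.covariate_transforms[name] = (center, scale)
            else:
                self.covariate_transforms[name] = (0.0, 1.0)
            cols.append(v)
        if not cols:
            return np.zeros((self.n_individuals, 0))
        return np.column_stack(cols)


def assemble_panel(choices: pd.DataFrame, respondents: pd.DataFrame | None,
                   blocks: dict | None = None,
                   allow_missing_respondents: bool = False) -> ChoicePanel:
    """Join validated tables into a model-ready :class:`ChoicePanel`.

    Raw attribute differences are divided by their model scales and an
    intercept column of ones is prepended. ``blocks`` optionally maps
    choice_id -> block label; when given, each individual's situations
    must come from a single block. Choice rows whose ``indiv_id`` has no
    respondent record raise an error unless ``allow_missing_respondents``
    (covariate-free fits can proceed with a stub respondent table).
    """
    choices = validate_choice_frame(choices)
    if len(choices) == 0:
        raise ValidationError("choice table is empty")
    if respondents is None:
        respondents = pd.DataFrame({"indiv_id": np.sort(choices["indiv_id"].unique())})
        for col in RESPONDENT_COLUMNS[1:]:
            respondents[col] = 0
    respondents = validate_respondent_frame(respondents)

    known = set(respondents["indiv_id"])
    orphans = sorted(set(choices["indiv_id"]) - known)
    if orphans:
        if not allow_missing_respondents:
            raise ValidationError(
                f"choice rows reference unknown indiv_id(s) {orphans[:10]}"
                + ("..." if len(orphans) > 10 else ""))
        choices = choices[choices["indiv_id"].isin(known)]

    choices = choices.sort_values(["indiv_id", "choice_id"], kind="mergesort")
    choices = choices.reset_index(drop=True)
    counts = choices.groupby("indiv_id").size()
    if (counts > 8).any():
        bad = counts.index[counts > 8][0]
        raise ValidationError(f"individual {bad!r} has more than 8 choice rows")
    if blocks is not None:
        per = choices.groupby("indiv_id")["choice_id"].agg(
            lambda s: len({blocks[c] for c in s}))
        if (per > 1).any():
            bad = per.index[per > 1][0]
            raise ValidationError(
                f"individual {bad!r} mixes choice situations from several blocks")

    indiv_ids = choices["indiv_id"].unique()
    respondents = (respondents.set_index("indiv_id").loc[indiv_ids]
                   .reset_index())
    id_pos = {v: k for k, v in enumerate(indiv_ids)}
    row_individual = choices["indiv_id"].map(id_pos).to_numpy()

    scaled = np.column_stack(
        [np.ones(len(choices))]
        + [choices[c].to_numpy(dtype=float) / MODEL_SCALES[c] for c in ATTRIBUTE_COLUMNS])
    y = choices["choice"].to_numpy(dtype=float)
    return ChoicePanel(rows=choices, respondents=respondents, X=scaled, y=y,
                       indiv_ids=indiv_ids, row_individual=row_individual)
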