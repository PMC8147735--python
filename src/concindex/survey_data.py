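"""Respondent-level survey tables: reading, validation, harmonization, pooling.

The in-memory container is a :class:`pandas.DataFrame` with one row per
respondent and a fixed set of standard columns (:data:`STANDARD_COLUMNS`).
Binary survey responses are harmonized to float columns coded ``1.0`` /
``0.0`` / ``NaN`` (yes / no / missing); the four HIV-knowledge items are
coded ``1.0`` for a correct answer and ``0.0`` for an incorrect or
"don't know" answer, which never counts as correct knowledge.

Input files are comma-delimited UTF-8 with a header row; ``NA`` or an
empty cell marks a missing value. A ``column_map`` renames file columns
onto the standard schema so arbitrary export headers can be consumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, MetadataError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Identifier / design columns every respondent table must provide.
ID_COLUMNS = ["country_code", "program", "year_label", "weight", "wealth_index", "age"]

#: The four knowledge items summed into the 0-4 score.
KNOWLEDGE_ITEMS = ["k_condom", "k_single_partner", "k_mosquito", "k_food"]

#: Binary indicator columns (tri-state: 1 / 0 / NaN).
INDICATOR_COLUMNS = ["heard_of_aids", *KNOWLEDGE_ITEMS, "ever_tested", "condom_last"]

STANDARD_COLUMNS = ID_COLUMNS + INDICATOR_COLUMNS

_TRUE_TOKENS = {"1", "1.0", "yes", "y", "correct", "true"}
_FALSE_TOKENS = {"0", "0.0", "no", "n", "incorrect", "dont_know", "dk", "false"}
_NA_TOKENS = {"", "na", "nan", "missing", "."}

ELIGIBLE_AGE_MIN = 15
ELIGIBLE_AGE_MAX = 24


@dataclass
class ValidationReport:
    """Counts of rows read, dropped, and missing responses per indicator."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    missing_by_indicator: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_read": self.n_read,
                "n_kept": self.n_kept,
                "n_dropped": self.n_dropped,
                "dropped": self.dropped,
                "missing_by_indicator": self.missing_by_indicator,
            },
            indent=2,
            sort_keys=True,
        )


def _parse_tristate(series: pd.Series, column: str) -> pd.Series:
    """Map a raw column onto {1.0, 0.0, NaN}; unrecognized tokens raise."""
    tokens = series.astype("string").str.strip().str.lower()
    out = pd.Series(np.nan, index=series.index, dtype=float)
    out[tokens.isin(_TRUE_TOKENS)] = 1.0
    out[tokens.isin(_FALSE_TOKENS)] = 0.0
    bad = ~(tokens.isin(_TRUE_TOKENS) | tokens.isin(_FALSE_TOKENS)
            | tokens.isin(_NA_TOKENS) | tokens.isna())
    if bad.any():
        example = tokens[bad].iloc[0]
        raise ValidationError(
            f"column {column!r}: unrecognized response value {example!r}"
        )
    return out


def read_survey_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a respondent CSV into the standard schema.

    Parameters
    ----------
    path
        CSV file with a header row; ``NA`` or empty cells are missing.
    column_map
        Mapping from standard column names to the file's header names.
        Omitted entries default to the standard name itself.

    Returns
    -------
    (records, report)
        The validated DataFrame (rows failing hard validation — a
        non-positive or missing weight, an unparseable wealth index —
        are dropped, not fixed) and the validation report counting them.

    Raises
    ------
    SchemaError
        If a required column is absent, naming the standard column.
    EmptyInputError
        If the file holds no data rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise EmptyInputError(f"{path}: no data rows")

    column_map = dict(column_map or {})
    report = ValidationReport(n_read=len(raw))
    out = pd.DataFrame(index=raw.index)

    def source(name: str) -> pd.Series:
        file_col = column_map.get(name, name)
        if file_col not in raw.columns:
            raise SchemaError(f"{path}: required column {name!r} "
                              f"(file column {file_col!r}) not found")
        return raw[file_col]

    out["country_code"] = source("country_code").str.strip()
    out["program"] = source("program").str.strip().str.upper()
    out["year_label"] = source("year_label").str.strip()
    out["weight"] = pd.to_numeric(source("weight"), errors="coerce")
    out["wealth_index"] = pd.to_numeric(source("wealth_index"), errors="coerce")
    out["age"] = pd.to_numeric(source("age"), errors="coerce")
    for col in INDICATOR_COLUMNS:
        out[col] = _parse_tristate(source(col), col)

    bad_program = ~out["program"].isin(["MICS", "DHS"])
    bad_weight = out["weight"].isna() | (out["weight"] <= 0)
    bad_wealth = out["wealth_index"].isna()
    bad_age = out["age"].isna()
    for label, mask in [
        ("invalid_program", bad_program),
        ("nonpositive_or_missing_weight", bad_weight & ~bad_program),
        ("unparseable_wealth", bad_wealth & ~bad_program & ~bad_weight),
        ("missing_age", bad_age & ~bad_program & ~bad_weight & ~bad_wealth),
    ]:
        n = int(mask.sum())
        if n:
            report.dropped[label] = n
    keep = ~(bad_program | bad_weight | bad_wealth | bad_age)
    out = out.loc[keep].reset_index(drop=True)
    out["age"] = out["age"].astype(int)
    report.n_kept = len(out)
    for col in INDICATOR_COLUMNS:
        report.missing_by_indicator[col] = int(out[col].isna().sum())
    if report.n_dropped:
        logger.warning("%s: dropped %d of %d rows (%s)",
                       path.name, report.n_dropped, report.n_read,
                       report.dropped)
    return out, report


def write_survey_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the same CSV dialect ``read_survey_table`` consumes.

    Binary/tri-state values round-trip exactly (1 / 0 / NA).
    """
    out = records.loc[:, STANDARD_COLUMNS].copy()
    for col in INDICATOR_COLUMNS:
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, na_rep="NA")


def read_country_meta(path: str | Path) -> pd.DataFrame:
    """Read the country metadata table (pc-GDP-PPP and population shares).

    Columns: ``country_code``, ``pc_gdp_ppp`` (international $, PPP),
    ``pop_share`` (share of the analysis region's female 15-24
    population; must sum to 1 over the table within 1e-9).
    """
    path = Path(path)
    meta = pd.read_csv(path)
    for col in ("country_code", "pc_gdp_ppp", "pop_share"):
        if col not in meta.columns:
            raise SchemaError(f"{path}: required column {col!r} not found")
    if meta.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if meta["country_code"].duplicated().any():
        dup = meta.loc[meta["country_code"].duplicated(), "country_code"].iloc[0]
        raise MetadataError(f"duplicate country_code {dup!r} in metadata")
    if (meta["pc_gdp_ppp"] <= 0).any():
        raise MetadataError("pc_gdp_ppp must be positive for every country")
    total = float(meta["pop_share"].sum())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise MetadataError(f"pop_share must sum to 1 over the analysis set, "
                            f"got {total!r}")
    return meta.reset_index(drop=True)


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Keep respondents aged 15-24 inclusive (the study's eligibility window).

    Idempotent; logs the number excluded and warns on an empty result.
    """
    keep = records["age"].between(ELIGIBLE_AGE_MIN, ELIGIBLE_AGE_MAX)
    excluded = int((~keep).sum())
    if excluded:
        logger.info("filter_eligible: excluded %d respondents outside 15-24",
                    excluded)
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_eligible: no eligible respondents remain")
    return out


def build_knowledge_score(
    records: pd.DataFrame,
    *,
    never_heard_policy: str = "zero",
    missing_item_policy: str = "missing",
) -> pd.Series:
    """Composite 0-4 HIV-knowledge score: the count of correct items.

    The four items are knowing that condom use and a single partner
    prevent transmission, and that mosquito bites and sharing food do
    not. "Don't know" is already coded 0 (incorrect) at read time.

    Parameters
    ----------
    never_heard_policy
        ``"zero"`` (default): a respondent who never heard of AIDS scores
        0 — she cannot hold correct knowledge, and dropping her would
        shrink the knowledge-score N far below the awareness N.
        ``"missing"``: such respondents get a missing score.
        A respondent with *missing* awareness always gets a missing score.
    missing_item_policy
        ``"missing"`` (default): any structurally missing item (question
        not asked) makes the composite missing for that respondent.
        ``"incorrect"``: a missing item scores 0.

    Returns
    -------
    pandas.Series of floats in {0,...,4} with NaN for missing.
    """
    if never_heard_policy not in ("zero", "missing"):
        raise ValueError(f"never_heard_policy: {never_heard_policy!r}")
    if missing_item_policy not in ("missing", "incorrect"):
        raise ValueError(f"missing_item_policy: {missing_item_policy!r}")

    items = records[KNOWLEDGE_ITEMS]
    if missing_item_policy == "incorrect":
        score = items.fillna(0.0).sum(axis=1)
    else:
        score = items.sum(axis=1)
        score[items.isna().any(axis=1)] = np.nan

    heard = records["heard_of_aids"]
    score = score.astype(float).copy()
    if never_heard_policy == "zero":
        score[heard == 0.0] = 0.0
    else:
        score[heard == 0.0] = np.nan
    score[heard.isna()] = np.nan
    score.name = "knowledge_score"
    return score


def pool_surveys(
    record_sets: Sequence[pd.DataFrame] | Iterable[pd.DataFrame],
    *,
    expect_single_country: bool = False,
) -> pd.DataFrame:
    """Concatenate per-survey record sets, retaining program/year labels.

    Weights are deliberately not rescaled here; pooled-weight
    construction happens in :func:`concindex.ranking.normalize_weights`
    so per-survey descriptives stay computable from the pooled frame.
    """
    record_sets = list(record_sets)
    if not record_sets:
        raise EmptyInputError("pool_surveys: no record sets given")
    for df in record_sets:
        missing = [c for c in STANDARD_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"pool_surveys: record set lacks columns {missing}")
        if df.empty:
            logger.warning("pool_surveys: one record set is empty")
    pooled = pd.concat(record_sets, ignore_index=True, sort=False)
    if expect_single_country and pooled["country_code"].nunique() > 1:
        codes = sorted(pooled["country_code"].unique())
        raise ValidationError(
            f"pool_surveys: single-country pool requested but found {codes}"
        )
    return pooled
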