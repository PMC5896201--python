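"""File formats and configuration.

Data travel as UTF-8 CSV with fixed column order (no established
bioinformatics format exists for clonal chimerism tables); report tables are
TSV.  Run configuration is one human-editable YAML file validated key by
key — unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._constants import AGE_GROUPS, FRACTIONS, LINEAGES, STAGES
from .classify import ClassificationCriteria
from .compartment import FractionFrequencies

#: Long-format chimerism schema, in fixed column order.
CHIMERISM_COLUMNS = [
    "clone_id",
    "recipient_id",
    "stage",
    "age_group",
    "fraction",
    "week",
    "lineage",
    "donor_events",
    "total_events",
    "percent",
    "censored_week",
]

CALLS_COLUMNS = [
    "clone_id",
    "age_group",
    "fraction",
    "lineages_primary",
    "lineages_secondary_union",
    "duration_class",
    "cell_type",
    "latent",
    "n_secondaries",
    "flags",
]

_VALID_FRACTIONS = set(FRACTIONS) | {"CD34-KSL", "unknown"}


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


class TableError(ValueError):
    """Schema violation in a data table; carries the error list."""

    def __init__(self, errors: list[dict]):
        self.errors = errors
        first = errors[0]
        super().__init__(
            f"{len(errors)} schema violation(s); first: row "
            f"{first.get('row')}, column {first.get('column')}: {first['error']}"
        )


def validate_table(table: pd.DataFrame | str | Path, schema: str = "chimerism") -> list[dict]:
    """Validate a table against a named schema; returns the error list.

    Each error is ``{"row": <0-based data row or None>, "column": <name>,
    "error": <message>}``.  An empty list means the table is valid.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    errors: list[dict] = []
    if schema == "chimerism":
        required = [c for c in CHIMERISM_COLUMNS if c not in ("donor_events", "total_events", "percent", "censored_week")]
        for col in required:
            if col not in table.columns:
                errors.append({"row": None, "column": col, "error": "missing column"})
        if errors:
            return errors
        has_counts = {"donor_events", "total_events"} <= set(table.columns)
        has_percent = "percent" in table.columns
        if not (has_counts or has_percent):
            errors.append(
                {"row": None, "column": "percent",
                 "error": "need percent and/or donor_events+total_events"}
            )
            return errors
        for i, row in table.iterrows():
            if row["stage"] not in STAGES:
                errors.append({"row": i, "column": "stage",
                               "error": f"unknown stage {row['stage']!r}"})
            if row["lineage"] not in LINEAGES:
                errors.append({"row": i, "column": "lineage",
                               "error": f"unknown lineage {row['lineage']!r}"})
            if row["age_group"] not in AGE_GROUPS:
                errors.append({"row": i, "column": "age_group",
                               "error": f"unknown age_group {row['age_group']!r}"})
            if row["fraction"] not in _VALID_FRACTIONS:
                errors.append({"row": i, "column": "fraction",
                               "error": f"unknown fraction {row['fraction']!r}"})
            try:
                week = float(row["week"])
                if week < 0 or week != int(week):
                    raise ValueError
            except (TypeError, ValueError):
                errors.append({"row": i, "column": "week",
                               "error": f"week must be a non-negative integer, got {row['week']!r}"})
            if has_percent and pd.notna(row.get("percent")):
                pct = float(row["percent"])
                if not 0.0 <= pct <= 100.0:
                    errors.append({"row": i, "column": "percent",
                                   "error": f"percent {pct} outside [0, 100]"})
            if has_counts and pd.notna(row.get("donor_events")) and pd.notna(row.get("total_events")):
                d, t = float(row["donor_events"]), float(row["total_events"])
                if t < 1:
                    errors.append({"row": i, "column": "total_events",
                                   "error": f"total_events {t} < 1"})
                if d < 0 or d > t:
                    errors.append({"row": i, "column": "donor_events",
                                   "error": f"donor_events {d} outside [0, total_events]"})
    elif schema == "calls":
        for col in CALLS_COLUMNS:
            if col not in table.columns:
                errors.append({"row": None, "column": col, "error": "missing column"})
    else:
        raise ValueError(f"unknown schema {schema!r}")
    return errors


def read_chimerism_csv(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate:
        errors = validate_table(df, "chimerism")
        if errors:
            raise TableError(errors)
    return df


def write_chimerism_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CHIMERISM_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_calls_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, keep_default_na=False,
        dtype={"lineages_primary": str, "lineages_secondary_union": str, "flags": str},
    )
    errors = validate_table(df, "calls")
    if errors:
        raise TableError(errors)
    df["latent"] = df["latent"].astype(str).str.lower().isin(("true", "1"))
    return df


def write_calls_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in CALLS_COLUMNS if c in df.columns])


# ---------------------------------------------------------------------------
# configuration

_CRITERIA_KEYS = {
    "threshold_percent",
    "min_positive_timepoints",
    "min_donor_events",
    "terminal_week",
    "lt_secondary_week",
    "hsc_requires_all_five",
}


def criteria_from_dict(d: dict) -> ClassificationCriteria:
    unknown = set(d) - _CRITERIA_KEYS
    if unknown:
        raise ConfigError(f"unknown criteria key(s): {sorted(unknown)}")
    try:
        return ClassificationCriteria(**d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid criteria block: {e}") from e


def freqs_from_dict(age_group: str, d: dict) -> FractionFrequencies:
    unknown = set(d) - {"phsc_per_million", "shares"}
    if unknown:
        raise ConfigError(
            f"unknown fraction_frequencies key(s) for {age_group}: {sorted(unknown)}"
        )
    try:
        return FractionFrequencies(
            age_group=age_group,
            phsc_per_million=float(d["phsc_per_million"]),
            shares={k: float(v) for k, v in dict(d["shares"]).items()},
        )
    except KeyError as e:
        raise ConfigError(f"fraction_frequencies for {age_group} missing key {e}") from e
    except ValueError as e:
        raise ConfigError(f"invalid fraction_frequencies for {age_group}: {e}") from e


@dataclass
class RunConfig:
    """Parsed run configuration."""

    seed: int = 0
    log_level: str = "INFO"
    paths: dict[str, str] = field(default_factory=dict)
    criteria: ClassificationCriteria = field(default_factory=ClassificationCriteria)
    fraction_frequencies: dict[str, FractionFrequencies] = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)


_TOP_KEYS = {"seed", "log_level", "paths", "criteria", "fraction_frequencies", "scenario"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate the YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"seed must be a non-negative integer, got {seed!r}")
    cfg = RunConfig(seed=seed, log_level=str(raw.get("log_level", "INFO")))
    cfg.paths = dict(raw.get("paths", {}))
    if "criteria" in raw:
        cfg.criteria = criteria_from_dict(dict(raw["criteria"]))
    for age, block in dict(raw.get("fraction_frequencies", {})).items():
        if age not in AGE_GROUPS:
            raise ConfigError(f"unknown age group in fraction_frequencies: {age!r}")
        cfg.fraction_frequencies[age] = freqs_from_dict(age, dict(block))
    cfg.scenario = dict(raw.get("scenario", {}))
    return cfg


def scenario_to_dict(scenario) -> dict:
    """Serialise a Scenario preset to a plain config mapping."""
    return {
        "age_group": scenario.age_group,
        "death_probability": scenario.death_probability,
        "jitter_sigma": scenario.jitter_sigma,
        "n_secondaries_range": list(scenario.n_secondaries_range),
        "timepoints_primary": list(scenario.timepoints_primary),
        "timepoints_secondary": list(scenario.timepoints_secondary),
        "fraction_frequencies": {
            "phsc_per_million": scenario.fraction_frequencies.phsc_per_million,
            "shares": dict(scenario.fraction_frequencies.shares),
        },
        "fraction_mixtures": {
            f: dict(m) for f, m in scenario.fraction_mixtures.items()
        },
    }
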