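"""Donor chimerism from flow-cytometry gate counts.

Peripheral-blood chimerism of a donor clone is the percentage of
donor-marker-positive events within a lineage gate.  Gates are finite
(30,000-50,000 leukocytes, 20,000-50,000 platelets, 500,000 erythrocytes per
mouse and timepoint), so the smallest representable chimerism depends on the
gate size; :func:`detection_floor` makes that explicit for reasoning about
reconstitution thresholds such as 0.005%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._constants import LINEAGES


class InvalidGateError(ValueError):
    """Raised for gate counts that cannot arise from a real acquisition."""


@dataclass(frozen=True)
class GateCounts:
    """Raw event counts for one recipient x lineage x week gate.

    Parameters
    ----------
    recipient_id : str
        Recipient mouse identifier.
    week : int
        Weeks post-transplant.
    lineage : str
        One of ``nm, E, P, B, T``.
    total_events : int
        Events acquired in the lineage gate (>= 1).
    donor_events : int
        Donor-marker-positive events within the gate.
    """

    recipient_id: str
    week: int
    lineage: str
    total_events: int
    donor_events: int

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise InvalidGateError(f"unknown lineage code {self.lineage!r}")
        if self.total_events < 1:
            raise InvalidGateError("total_events must be >= 1")
        if not 0 <= self.donor_events <= self.total_events:
            raise InvalidGateError(
                "donor_events must satisfy 0 <= donor_events <= total_events"
            )


@dataclass
class ChimerismSeries:
    """One clone's longitudinal five-lineage chimerism in one recipient.

    ``observations`` maps ``(week, lineage)`` to percent donor chimerism in
    [0, 100]; a missing cell is *unobserved*, never zero.  ``counts``
    optionally backs observations with raw ``GateCounts`` (used by the
    classifier's minimum-event rule).  A censored series (recipient died
    during follow-up) has no observations after ``censored_week``.
    """

    clone_id: str
    recipient_id: str
    stage: str = "primary"
    age_group: str = "young"
    fraction: str = "unknown"
    observations: dict[tuple[int, str], float] = field(default_factory=dict)
    counts: dict[tuple[int, str], GateCounts] = field(default_factory=dict)
    censored: bool = False
    censored_week: int | None = None

    def weeks(self) -> list[int]:
        return sorted({w for w, _ in self.observations})


def compute_chimerism(gate: GateCounts) -> float:
    """Percent donor chimerism, ``100 * donor_events / total_events``."""
    return 100.0 * gate.donor_events / gate.total_events


def detection_floor(total_events: int, min_donor_events: int = 1) -> float:
    """Smallest chimerism representable by >= ``min_donor_events`` events.

    For a 30,000-event leukocyte gate the floor at 2 events is ~0.0067%,
    i.e. above a 0.005% reconstitution threshold — a single stray event can
    clear such a threshold, which is why the classifier can additionally
    require a minimum donor event count when raw counts are available.
    """
    if total_events < 1:
        raise InvalidGateError("total_events must be >= 1")
    if min_donor_events < 1:
        raise ValueError("min_donor_events must be >= 1")
    return 100.0 * min_donor_events / total_events


def assemble_series(gate_table: pd.DataFrame) -> list[ChimerismSeries]:
    """Group a long-format gate/chimerism table into per-recipient series.

    Expects the long-format chimerism schema (see :mod:`clonalhsc.io`):
    one row per (clone_id, recipient_id, week, lineage), with either raw
    ``donor_events``/``total_events``, a pre-computed ``percent``, or both.
    When both are present the counts win; a mismatch beyond 1e-6 percent
    emits a validation warning.

    Raises on duplicated (recipient, week, lineage) keys and unknown
    lineage codes.
    """
    series: list[ChimerismSeries] = []
    if len(gate_table) == 0:
        return series

    bad = set(gate_table["lineage"]) - set(LINEAGES)
    if bad:
        raise InvalidGateError(f"unknown lineage code(s): {sorted(bad)}")
    dup = gate_table.duplicated(subset=["recipient_id", "week", "lineage"])
    if dup.any():
        first = gate_table[dup].iloc[0]
        raise ValueError(
            "duplicated (recipient, week, lineage) key: "
            f"({first['recipient_id']}, {first['week']}, {first['lineage']})"
        )

    has_counts = {"donor_events", "total_events"} <= set(gate_table.columns)
    has_percent = "percent" in gate_table.columns

    for (clone_id, recipient_id), rows in gate_table.groupby(
        ["clone_id", "recipient_id"], sort=True
    ):
        first = rows.iloc[0]
        cens_week = first.get("censored_week")
        censored = pd.notna(cens_week)
        s = ChimerismSeries(
            clone_id=str(clone_id),
            recipient_id=str(recipient_id),
            stage=str(first.get("stage", "primary")),
            age_group=str(first.get("age_group", "young")),
            fraction=str(first.get("fraction", "unknown")),
            censored=bool(censored),
            censored_week=int(cens_week) if censored else None,
        )
        for _, row in rows.iterrows():
            key = (int(row["week"]), str(row["lineage"]))
            counts_ok = (
                has_counts
                and pd.notna(row["donor_events"])
                and pd.notna(row["total_events"])
            )
            if counts_ok:
                gate = GateCounts(
                    recipient_id=str(recipient_id),
                    week=key[0],
                    lineage=key[1],
                    total_events=int(row["total_events"]),
                    donor_events=int(row["donor_events"]),
                )
                pct = compute_chimerism(gate)
                s.counts[key] = gate
                if has_percent and pd.notna(row["percent"]):
                    if abs(float(row["percent"]) - pct) > 1e-6:
                        warnings.warn(
                            f"percent column disagrees with counts for "
                            f"{recipient_id} week {key[0]} {key[1]}: "
                            f"{row['percent']} vs {pct}; using counts",
                            stacklevel=2,
                        )
            elif has_percent and pd.notna(row["percent"]):
                pct = float(row["percent"])
                if not 0.0 <= pct <= 100.0:
                    raise ValueError(
                        f"percent out of [0, 100] for {recipient_id} "
                        f"week {key[0]} {key[1]}: {pct}"
                    )
            else:
                continue  # unobserved cell
            if s.censored and key[0] > s.censored_week:
                raise ValueError(
                    f"censored series {recipient_id} has an observation at "
                    f"week {key[0]} after censored_week {s.censored_week}"
                )
            s.observations[key] = pct
        series.append(s)
    return series


def series_to_frame(series: list[ChimerismSeries]) -> pd.DataFrame:
    """Inverse of :func:`assemble_series`: long-format chimerism table."""
    rows = []
    for s in series:
        for (week, lineage), pct in sorted(s.observations.items()):
            gate = s.counts.get((week, lineage))
            rows.append(
                {
                    "clone_id": s.clone_id,
                    "recipient_id": s.recipient_id,
                    "stage": s.stage,
                    "age_group": s.age_group,
                    "fraction": s.fraction,
                    "week": week,
                    "lineage": lineage,
                    "donor_events": gate.donor_events if gate else None,
                    "total_events": gate.total_events if gate else None,
                    "percent": pct,
                    "censored_week": s.censored_week if s.censored else None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
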