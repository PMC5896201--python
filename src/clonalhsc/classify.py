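"""Functional classification of clones from longitudinal chimerism.

Each transplanted single cell is judged on two axes:

* **lineage output** — which of the five blood lineages (nm, E, P, B, T)
  it reconstituted above a detection threshold in the primary recipient;
* **duration** — short-term (ST: signal lost by the terminal primary bleed),
  long-term (LT: engrafts secondary recipients late), or intermediate-term
  (IT: positive at the terminal primary bleed but not LT).

Lineage set x duration maps onto the functional taxonomy: multipotent HSCs
(myeloid plus lymphoid output), the nested myeloid-restricted chain
Mk ⊂ ME ⊂ CM (suffix RP when short-term, SC when IT/LT), "other" for
patterns fitting no named class, and non-reconstituting for no output at
all.  A clone that is myeloid-restricted in its primary recipient but shows
lymphoid (B and/or T) output after secondary transplantation is relabelled
**latent-HSC** — multipotency that only becomes visible upon
re-transplantation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._constants import (
    CELL_TYPES,
    LINEAGES,
    LYMPHOID_LINEAGES,
    MYELOID_LINEAGES,
)
from .chimerism import ChimerismSeries


class ValidationError(ValueError):
    """Raised when a cohort table violates the classification contract."""


@dataclass(frozen=True)
class ClassificationCriteria:
    """All thresholds and windows governing the classification.

    Parameters
    ----------
    threshold_percent : float
        Reconstitution threshold τ on percent chimerism (default 0.005,
        chosen low to avoid overlooking platelet/erythrocyte output; 0.1 is
        the standard alternative).
    min_positive_timepoints : int
        Weeks a lineage must be at/above τ to count as reconstituted.
    min_donor_events : int
        Minimum donor events backing a positive observation, applied only
        when raw gate counts are available (0.005% of a 30,000-event gate is
        1.5 events; requiring 2 guards against single-event artifacts).
    terminal_week : int
        Last primary bleed; positivity here separates ST from IT/LT.
    lt_secondary_week : int
        Earliest secondary-recipient week whose positivity counts as
        long-term engraftment.
    hsc_requires_all_five : bool
        If True an HSC call needs all five lineages; default False requires
        nm+E+P plus at least one of B/T, since lymphoid acquisition of
        either B or T is treated as multipotency evidence.
    """

    threshold_percent: float = 0.005
    min_positive_timepoints: int = 1
    min_donor_events: int = 2
    terminal_week: int = 24
    lt_secondary_week: int = 16
    hsc_requires_all_five: bool = False

    def __post_init__(self) -> None:
        if self.threshold_percent <= 0:
            raise ValueError("threshold_percent must be > 0")
        if self.min_positive_timepoints < 1:
            raise ValueError("min_positive_timepoints must be >= 1")

    def with_threshold(self, tau: float) -> "ClassificationCriteria":
        return replace(self, threshold_percent=tau)


@dataclass(frozen=True)
class CloneCall:
    """The classifier's verdict for one clone."""

    clone_id: str
    lineages_primary: frozenset[str]
    lineages_secondary_union: frozenset[str] | None
    duration_class: str  # ST | IT | LT | none
    cell_type: str | None
    latent: bool = False
    excluded_dead: bool = False
    flags: tuple[str, ...] = ()
    age_group: str = "young"
    fraction: str = "unknown"
    n_secondaries: int = 0


def _obs_positive(
    series: ChimerismSeries, key: tuple[int, str], criteria: ClassificationCriteria
) -> bool:
    pct = series.observations.get(key)
    if pct is None or pct < criteria.threshold_percent:
        return False
    gate = series.counts.get(key)
    if gate is not None and gate.donor_events < criteria.min_donor_events:
        return False
    return True


def lineage_positivity(
    series: ChimerismSeries, criteria: ClassificationCriteria | None = None
) -> frozenset[str]:
    """Lineages reconstituted in one recipient.

    A lineage is in the set iff it has at least ``min_positive_timepoints``
    observed weeks at or above τ, each backed by at least
    ``min_donor_events`` donor events when raw counts are available.
    """
    criteria = criteria or ClassificationCriteria()
    out = set()
    for lin in LINEAGES:
        n_pos = sum(
            _obs_positive(series, (week, lin), criteria)
            for week in series.weeks()
        )
        if n_pos >= criteria.min_positive_timepoints:
            out.add(lin)
    return frozenset(out)


def _terminal_positive(
    series: ChimerismSeries, criteria: ClassificationCriteria
) -> bool:
    return any(
        _obs_positive(series, (criteria.terminal_week, lin), criteria)
        for lin in LINEAGES
    )


def _late_secondary_positive(
    series: ChimerismSeries, criteria: ClassificationCriteria
) -> bool:
    return any(
        _obs_positive(series, (week, lin), criteria)
        for (week, lin) in series.observations
        if week >= criteria.lt_secondary_week
    )


def duration_call(
    primary: ChimerismSeries,
    secondaries: list[ChimerismSeries],
    criteria: ClassificationCriteria | None = None,
) -> tuple[str, bool]:
    """Duration class for a clone: ``(ST|IT|LT|none, unresolved_flag)``.

    * ``none`` — no lineage reconstituted in the primary recipient.
    * ``ST`` — reconstituted, but no lineage at/above τ at the terminal
      primary week.
    * ``LT`` — positive at the terminal week *and* at least one linked
      secondary recipient shows any lineage at/above τ at a week >=
      ``lt_secondary_week``.
    * ``IT`` — positive at the terminal week but not LT.  When no secondary
      assay exists the LT/IT distinction is unresolvable; such clones are
      reported IT with the unresolved flag set.
    """
    criteria = criteria or ClassificationCriteria()
    for sec in secondaries:
        if sec.clone_id != primary.clone_id:
            raise ValidationError(
                f"secondary series {sec.recipient_id} (clone {sec.clone_id}) "
                f"is not linked to primary clone {primary.clone_id}"
            )
    if not lineage_positivity(primary, criteria):
        return "none", False
    if not _terminal_positive(primary, criteria):
        return "ST", False
    if any(_late_secondary_positive(s, criteria) for s in secondaries):
        return "LT", False
    return "IT", not secondaries


_MYELOID_CHAIN = {
    frozenset({"P"}): "Mk",
    frozenset({"P", "E"}): "ME",
    frozenset({"P", "E", "nm"}): "CM",
}


def cell_type_call(
    lineages_primary: frozenset[str] | set[str],
    duration: str,
    criteria: ClassificationCriteria | None = None,
) -> str:
    """Map a primary lineage set and duration class to a taxonomy label.

    The myeloid-restricted chain is strictly nested (Mk: P only; ME: P+E;
    CM: P+E+nm) with suffix RP for ST and SC for IT/LT duration.  HSC
    requires the full myeloid set plus lymphoid output (one of B/T, or both
    under the strict all-five criterion).  Any other non-empty pattern —
    lymphoid-only, nm without P, E alone, ... — is "other".
    """
    criteria = criteria or ClassificationCriteria()
    lineages = frozenset(lineages_primary)
    unknown = lineages - set(LINEAGES)
    if unknown:
        raise ValidationError(f"unknown lineage code(s): {sorted(unknown)}")
    if not lineages:
        return "non-reconstituting"
    if duration not in ("ST", "IT", "LT"):
        raise ValidationError(
            f"reconstituting clone needs duration ST/IT/LT, got {duration!r}"
        )

    lymphoid = lineages & LYMPHOID_LINEAGES
    if MYELOID_LINEAGES <= lineages:
        full_lymphoid = lymphoid == LYMPHOID_LINEAGES
        if (criteria.hsc_requires_all_five and full_lymphoid) or (
            not criteria.hsc_requires_all_five and lymphoid
        ):
            return f"{duration}-HSC"

    if not lymphoid and lineages in _MYELOID_CHAIN:
        stem = _MYELOID_CHAIN[lineages]
        return f"{duration}-{stem}RP" if duration == "ST" else f"{duration}-{stem}SC"
    return "other"


def latent_call(
    lineages_primary: frozenset[str] | set[str],
    duration: str,
    secondary_union: frozenset[str] | set[str] | None,
    criteria: ClassificationCriteria | None = None,
) -> bool:
    """Latent-HSC test: myeloid-restricted primary output with terminal-week
    persistence (IT/LT) that acquires lymphoid (B and/or T) output in any
    secondary recipient."""
    lineages = frozenset(lineages_primary)
    if not lineages or not lineages <= MYELOID_LINEAGES:
        return False
    if duration not in ("IT", "LT"):
        return False
    if secondary_union is None:
        return False
    return bool(frozenset(secondary_union) & LYMPHOID_LINEAGES)


class CloneClassifier:
    """Configured classifier applying the taxonomy to whole cohorts.

    Parameters
    ----------
    criteria : ClassificationCriteria, optional
        Thresholds and windows; defaults reproduce the standard criteria.
    """

    def __init__(self, criteria: ClassificationCriteria | None = None):
        self.criteria = criteria or ClassificationCriteria()

    # -- single-clone path (readable reference implementation) ------------

    def classify_clone(
        self, primary: ChimerismSeries, secondaries: list[ChimerismSeries]
    ) -> CloneCall:
        c = self.criteria
        if primary.censored:
            return CloneCall(
                clone_id=primary.clone_id,
                lineages_primary=frozenset(),
                lineages_secondary_union=None,
                duration_class="none",
                cell_type=None,
                excluded_dead=True,
                age_group=primary.age_group,
                fraction=primary.fraction,
            )
        lin_primary = lineage_positivity(primary, c)
        duration, unresolved = duration_call(primary, secondaries, c)
        sec_union = (
            frozenset().union(*(lineage_positivity(s, c) for s in secondaries))
            if secondaries
            else None
        )
        cell_type = cell_type_call(lin_primary, duration, c)
        latent = latent_call(lin_primary, duration, sec_union, c)
        if latent:
            cell_type = "latent-HSC"
        flags = ("LT/IT-unresolved",) if unresolved else ()
        return CloneCall(
            clone_id=primary.clone_id,
            lineages_primary=lin_primary,
            lineages_secondary_union=sec_union,
            duration_class=duration,
            cell_type=cell_type,
            latent=latent,
            flags=flags,
            age_group=primary.age_group,
            fraction=primary.fraction,
            n_secondaries=len(secondaries),
        )

    # -- cohort path (vectorised) -----------------------------------------

    def classify_cohort(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Classify every surviving clone in a long-format cohort table.

        Dead-flagged primaries (non-null ``censored_week``) are excluded
        before classification.  Returns one row per surviving clone, sorted
        by clone_id; the result is invariant to input row order.
        """
        c = self.criteria
        required = {"clone_id", "recipient_id", "stage", "week", "lineage", "percent"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValidationError(f"cohort table lacks column(s): {sorted(missing)}")
        if len(cohort) == 0:
            return _empty_calls_frame()

        df = cohort.copy()
        df["clone_id"] = df["clone_id"].astype(str)

        prim = df[df["stage"] == "primary"]
        sec = df[df["stage"] == "secondary"]
        all_clones = set(df["clone_id"])
        primary_clones = set(prim["clone_id"])
        orphan = set(sec["clone_id"]) - primary_clones
        if orphan:
            raise ValidationError(
                f"secondary series lacking a linked primary: {sorted(orphan)[:5]}"
            )

        observed = df["percent"].notna()
        if "donor_events" in df.columns:
            observed |= df["donor_events"].notna()
        obs_clones = set(df.loc[observed & (df["stage"] == "primary"), "clone_id"])
        censored = prim["censored_week"].notna() if "censored_week" in prim else None
        dead_clones = (
            set(prim.loc[censored, "clone_id"]) if censored is not None else set()
        )
        ghost = all_clones - obs_clones - dead_clones
        if ghost:
            raise ValidationError(
                "clone(s) with zero observed timepoints and no censoring flag: "
                f"{sorted(ghost)[:5]}"
            )

        pos = df["percent"].fillna(-1.0) >= c.threshold_percent
        if "donor_events" in df.columns:
            ev = df["donor_events"]
            pos &= ev.isna() | (ev >= c.min_donor_events)

        pdf = df[(df["stage"] == "primary") & pos]
        sdf = df[(df["stage"] == "secondary") & pos]

        # lineage sets per clone (primary) and per recipient (secondary)
        prim_counts = pdf.groupby(["clone_id", "lineage"])["week"].nunique()
        prim_sets: dict[str, set[str]] = {}
        for (clone, lin), n in prim_counts.items():
            if n >= c.min_positive_timepoints:
                prim_sets.setdefault(clone, set()).add(lin)

        sec_counts = sdf.groupby(["clone_id", "recipient_id", "lineage"])[
            "week"
        ].nunique()
        sec_union: dict[str, set[str]] = {}
        for (clone, _rec, lin), n in sec_counts.items():
            if n >= c.min_positive_timepoints:
                sec_union.setdefault(clone, set()).add(lin)

        terminal_pos = set(pdf.loc[pdf["week"] == c.terminal_week, "clone_id"])
        late_sec_pos = set(sdf.loc[sdf["week"] >= c.lt_secondary_week, "clone_id"])

        sec_all = df[df["stage"] == "secondary"]
        n_secondaries = sec_all.groupby("clone_id")["recipient_id"].nunique()
        meta_cols = [c_ for c_ in ("age_group", "fraction") if c_ in prim.columns]
        meta = prim.drop_duplicates("clone_id").set_index("clone_id")

        rows = []
        for clone in sorted(primary_clones - dead_clones):
            lin_primary = frozenset(prim_sets.get(clone, set()))
            n_sec = int(n_secondaries.get(clone, 0))
            has_sec = n_sec > 0
            union = frozenset(sec_union.get(clone, set())) if has_sec else None
            unresolved = False
            if not lin_primary:
                duration = "none"
            elif clone not in terminal_pos:
                duration = "ST"
            elif clone in late_sec_pos:
                duration = "LT"
            else:
                duration = "IT"
                unresolved = not has_sec
            cell_type = cell_type_call(lin_primary, duration, c)
            latent = latent_call(lin_primary, duration, union, c)
            if latent:
                cell_type = "latent-HSC"
            m = meta.loc[clone] if clone in meta.index else {}
            rows.append(
                {
                    "clone_id": clone,
                    "age_group": m.get("age_group", "unknown")
                    if "age_group" in meta_cols
                    else "unknown",
                    "fraction": m.get("fraction", "unknown")
                    if "fraction" in meta_cols
                    else "unknown",
                    "lineages_primary": _join(lin_primary),
                    "lineages_secondary_union": _join(union)
                    if union is not None
                    else "",
                    "duration_class": duration,
                    "cell_type": cell_type,
                    "latent": latent,
                    "n_secondaries": n_sec,
                    "flags": "LT/IT-unresolved" if unresolved else "",
                }
            )
        out = pd.DataFrame(rows, columns=_CALL_COLUMNS)
        return out.reset_index(drop=True)


_CALL_COLUMNS = [
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


def _empty_calls_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=_CALL_COLUMNS)


def _join(lineages: frozenset[str] | set[str]) -> str:
    return "|".join(lin for lin in LINEAGES if lin in lineages)


def split_lineages(joined: str) -> frozenset[str]:
    """Inverse of the ``nm|E|P`` encoding used in calls tables."""
    return frozenset(joined.split("|")) if joined else frozenset()


def classify_cohort(
    cohort: pd.DataFrame, criteria: ClassificationCriteria | None = None
) -> pd.DataFrame:
    """Functional interface to :meth:`CloneClassifier.classify_cohort`."""
    return CloneClassifier(criteria).classify_cohort(cohort)


def threshold_sensitivity(
    cohort: pd.DataFrame,
    thresholds: list[float],
    criteria: ClassificationCriteria | None = None,
) -> dict:
    """Re-classify a cohort under each threshold and compare.

    Returns a dict with ``compositions`` (threshold -> cell-type counts over
    the full taxonomy) and ``agreement`` (DataFrame of pairwise fractions of
    clones whose cell_type is unchanged between thresholds).
    """
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    base = criteria or ClassificationCriteria()
    calls = {}
    for tau in thresholds:
        res = classify_cohort(cohort, base.with_threshold(tau))
        calls[tau] = res.set_index("clone_id")["cell_type"]
    compositions = {
        tau: s.value_counts().reindex(CELL_TYPES, fill_value=0)
        for tau, s in calls.items()
    }
    agreement = pd.DataFrame(
        np.nan, index=[str(t) for t in thresholds], columns=[str(t) for t in thresholds]
    )
    for t1 in thresholds:
        for t2 in thresholds:
            a, b = calls[t1].sort_index(), calls[t2].sort_index()
            agreement.loc[str(t1), str(t2)] = float((a == b).mean()) if len(a) else 1.0
    return {"compositions": compositions, "agreement": agreement}
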