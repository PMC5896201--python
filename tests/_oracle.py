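"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: classification is done by
enumerating raw table rows with plain dict/set logic, and the per-million
estimator by summing per-clone weights.  They are only run on small inputs.
"""

from __future__ import annotations

import math

LINEAGES = ("nm", "E", "P", "B", "T")


def _is_nan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return x is None


def _pos(row, tau, min_events):
    pct = row.get("percent")
    if _is_nan(pct) or float(pct) < tau:
        return False
    ev = row.get("donor_events")
    if not _is_nan(ev) and float(ev) < min_events:
        return False
    return True


def _lineage_set(rows, tau, min_events, min_tp):
    out = set()
    for lin in LINEAGES:
        weeks = {r["week"] for r in rows if r["lineage"] == lin and _pos(r, tau, min_events)}
        if len(weeks) >= min_tp:
            out.add(lin)
    return out


def oracle_classify(
    cohort,
    tau=0.005,
    min_events=2,
    min_tp=1,
    terminal=24,
    lt_week=16,
    strict_hsc=False,
):
    """Classify every surviving clone by direct enumeration.

    Returns {clone_id: dict} with lineage sets, duration, cell type and
    latent flag.
    """
    rows = cohort.to_dict("records")
    clones: dict[str, dict] = {}
    for r in rows:
        c = clones.setdefault(str(r["clone_id"]), {"primary": [], "secondary": {}})
        if r["stage"] == "primary":
            c["primary"].append(r)
        else:
            c["secondary"].setdefault(str(r["recipient_id"]), []).append(r)

    out = {}
    for clone_id, grp in sorted(clones.items()):
        prim = grp["primary"]
        if any(not _is_nan(r.get("censored_week")) for r in prim):
            continue  # dead, excluded
        lin_primary = _lineage_set(prim, tau, min_events, min_tp)
        terminal_pos = any(
            _pos(r, tau, min_events) for r in prim if r["week"] == terminal
        )
        sec_sets = {
            rec: _lineage_set(rws, tau, min_events, min_tp)
            for rec, rws in grp["secondary"].items()
        }
        union = set().union(*sec_sets.values()) if sec_sets else None
        late_pos = any(
            _pos(r, tau, min_events)
            for rws in grp["secondary"].values()
            for r in rws
            if r["week"] >= lt_week
        )

        if not lin_primary:
            duration = "none"
        elif not terminal_pos:
            duration = "ST"
        elif late_pos:
            duration = "LT"
        else:
            duration = "IT"

        cell_type = _cell_type(lin_primary, duration, strict_hsc)
        latent = (
            bool(lin_primary)
            and lin_primary <= {"nm", "E", "P"}
            and duration in ("IT", "LT")
            and union is not None
            and bool(union & {"B", "T"})
        )
        if latent:
            cell_type = "latent-HSC"
        out[clone_id] = {
            "lineages_primary": frozenset(lin_primary),
            "lineages_secondary_union": frozenset(union) if union is not None else None,
            "duration_class": duration,
            "cell_type": cell_type,
            "latent": latent,
        }
    return out


def _cell_type(lineages, duration, strict_hsc):
    s = set(lineages)
    if not s:
        return "non-reconstituting"
    suffix = {"ST": "RP", "IT": "SC", "LT": "SC"}[duration]
    has_myeloid_core = {"nm", "E", "P"} <= s
    if has_myeloid_core:
        if strict_hsc and {"B", "T"} <= s:
            return duration + "-HSC"
        if not strict_hsc and ({"B", "T"} & s):
            return duration + "-HSC"
    if "B" in s or "T" in s:
        return "other"
    if s == {"P"}:
        return f"{duration}-Mk{suffix}"
    if s == {"P", "E"}:
        return f"{duration}-ME{suffix}"
    if s == {"P", "E", "nm"}:
        return f"{duration}-CM{suffix}"
    return "other"


def oracle_per_million(calls, N, shares):
    """Per-clone weight sum: each clone adds N * s_f / n_f to its type."""
    n_f: dict[str, int] = {}
    for r in calls.to_dict("records"):
        n_f[r["fraction"]] = n_f.get(r["fraction"], 0) + 1
    out: dict[str, float] = {}
    for r in calls.to_dict("records"):
        f = r["fraction"]
        w = N * shares.get(f, 0.0) / n_f[f]
        out[r["cell_type"]] = out.get(r["cell_type"], 0.0) + w
    return out
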