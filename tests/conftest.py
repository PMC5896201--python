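import pandas as pd
import pytest

from clonalhsc.classify import ClassificationCriteria
from clonalhsc.simulate import paper_scenarios


@pytest.fixture(scope="session")
def criteria():
    return ClassificationCriteria()


@pytest.fixture(scope="session")
def presets():
    return paper_scenarios()


def make_clone_rows(
    clone_id,
    primary,
    secondaries=(),
    age_group="young",
    fraction="F1",
    censored_week=None,
):
    """Hand-build long-format cohort rows.

    ``primary`` and each secondary map (week, lineage) -> percent (optionally
    (percent, donor_events, total_events)); unmentioned cells at the same
    weeks default to 0 percent so the clone has observed timepoints.
    """
    rows = []

    def emit(obs, stage, recipient):
        weeks = sorted({w for w, _ in obs})
        for week in weeks:
            for lin in ("nm", "E", "P", "B", "T"):
                val = obs.get((week, lin), 0.0)
                if isinstance(val, tuple):
                    pct, donor, total = val
                else:
                    pct, donor, total = val, None, None
                rows.append(
                    {
                        "clone_id": clone_id,
                        "recipient_id": recipient,
                        "stage": stage,
                        "age_group": age_group,
                        "fraction": fraction,
                        "week": week,
                        "lineage": lin,
                        "donor_events": donor,
                        "total_events": total,
                        "percent": pct,
                        "censored_week": censored_week if stage == "primary" else None,
                    }
                )

    emit(primary, "primary", f"{clone_id}-p")
    for j, sec in enumerate(secondaries):
        emit(sec, "secondary", f"{clone_id}-s{j}")
    return rows


def frame(rows):
    df = pd.DataFrame(rows)
    df["censored_week"] = df["censored_week"].astype("Float64")
    return df
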