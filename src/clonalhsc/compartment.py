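"""Compartment composition and absolute frequency estimation.

Single-cell transplants sample the phenotypic HSC (pHSC) compartment via its
sorted fractions F1/F2/F3.  Writing ``p_{t|f}`` for the proportion of clones
of functional type ``t`` among the ``n_f`` assayed clones of fraction ``f``,
``s_f`` for the share of the pHSC compartment in fraction ``f`` and ``N``
for pHSC cells per 10^6 nucleated bone-marrow cells, the absolute frequency
of type ``t`` is

    F_t = N * sum_f s_f * p_{t|f}          (cells per 10^6 BM cells)

with within-compartment composition ``pi_t = F_t / (N * sum_f s_f)``.
Conservation holds exactly: ``sum_t F_t = N * sum_f s_f`` (= N when the
fraction shares cover the whole compartment).  Uncertainty comes from a
within-fraction multinomial bootstrap over clones; young/aged composition is
compared with a Pearson chi-square test.

The module is organised statsmodels-style: build a
:class:`ClonalCompartmentModel` from a calls table plus fraction
frequencies, ``fit()`` it, and read estimates, intervals and ``summary()``
off the :class:`CompartmentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import CELL_TYPES, FRACTIONS


@dataclass(frozen=True)
class FractionFrequencies:
    """Flow-cytometry frequencies anchoring the absolute scale.

    Parameters
    ----------
    age_group : str
        ``young`` or ``aged``.
    phsc_per_million : float
        Phenotypic HSC (CD34-KSL) cells per 10^6 nucleated BM cells.
    shares : dict
        Proportion of the pHSC compartment in each sorted fraction
        (keys F1, F2, F3); may sum to < 1 when a quadrant is unassayed.
    """

    age_group: str
    phsc_per_million: float
    shares: dict[str, float]

    def __post_init__(self) -> None:
        if self.phsc_per_million <= 0:
            raise ValueError("phsc_per_million must be > 0")
        unknown = set(self.shares) - set(FRACTIONS)
        if unknown:
            raise ValueError(f"unknown fraction key(s): {sorted(unknown)}")
        for f, s in self.shares.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"share {f}={s} outside [0, 1]")
        if sum(self.shares.values()) > 1.0 + 1e-9:
            raise ValueError("fraction shares must sum to <= 1")

    @property
    def total_share(self) -> float:
        return float(sum(self.shares.values()))


@dataclass
class CompartmentEstimate:
    """Point estimates for one age group."""

    counts: pd.DataFrame  # cell type x fraction clone counts
    p_table: pd.DataFrame  # p_{t|f}
    composition: pd.Series  # pi_t
    per_million: pd.Series  # F_t
    freqs: FractionFrequencies


def composition(
    calls: pd.DataFrame,
    by_fraction: bool = True,
    fractions: list[str] | tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-fraction cell-type proportions ``p_{t|f} = n_{t,f} / n_f``.

    ``calls`` is a classifier output table restricted to fractionated clones
    (fraction in F1/F2/F3).  All taxonomy labels appear as rows, zero-count
    types included.  ``fractions`` names the fractions a composition is
    required for (default: those present in ``calls``); a required fraction
    with no clones is an error — it cannot be given a composition.
    """
    bad = set(calls["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(
            f"calls contain non-fraction label(s) {sorted(bad)}; restrict to "
            f"{FRACTIONS} before estimating composition"
        )
    counts = count_table(calls)
    if fractions is None:
        fractions = [f for f in FRACTIONS if f in set(calls["fraction"])]
    counts = counts[list(fractions)]
    n_f = counts.sum(axis=0)
    empty = [f for f in fractions if n_f[f] == 0]
    if empty:
        raise ValueError(f"fraction(s) with zero clones: {empty}")
    p = counts / n_f
    return p if by_fraction else p.mean(axis=1).to_frame("pooled")


def count_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Cell type x fraction clone counts over the full taxonomy."""
    counts = (
        calls.groupby(["cell_type", "fraction"]).size().unstack(fill_value=0)
    )
    return counts.reindex(
        index=list(CELL_TYPES), columns=list(FRACTIONS), fill_value=0
    ).astype(int)


def estimate_per_million(
    p_table: pd.DataFrame, freqs: FractionFrequencies
) -> CompartmentEstimate:
    """Absolute frequencies ``F_t = N * sum_f s_f * p_{t|f}`` and
    within-compartment composition ``pi_t``."""
    weighted = {f: s for f, s in freqs.shares.items() if s > 0}
    missing = set(weighted) - set(p_table.columns)
    if missing:
        raise ValueError(f"p_table lacks fraction column(s): {sorted(missing)}")
    N = freqs.phsc_per_million
    shares = pd.Series(weighted, dtype=float)
    per_million = N * (p_table[shares.index] * shares).sum(axis=1)
    total = N * freqs.total_share
    pi = per_million / total
    counts = pd.DataFrame(
        0, index=p_table.index, columns=p_table.columns, dtype=int
    )
    return CompartmentEstimate(
        counts=counts,
        p_table=p_table,
        composition=pi,
        per_million=per_million,
        freqs=freqs,
    )


def fold_change(young: float, aged: float) -> float | str:
    """Aged/young ratio rounded half-away-from-zero to 1 decimal; ``"n/a"``
    when the young frequency is zero."""
    if young < 0 or aged < 0:
        raise ValueError("frequencies must be non-negative")
    if young == 0:
        return "n/a"
    ratio = float(aged) / float(young)
    return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def aggregate_groups(
    table: pd.DataFrame, grouping: dict[str, tuple[str, ...] | list[str]]
) -> pd.DataFrame:
    """Sum member frequencies per group and age, with group fold changes.

    ``table`` has taxonomy rows and ``young``/``aged`` columns; ``grouping``
    maps group name -> member row labels.  A row label may belong to at most
    one group and must exist in the table.
    """
    seen: dict[str, str] = {}
    for group, members in grouping.items():
        for label in members:
            if label not in table.index:
                raise KeyError(f"unknown row label {label!r} in group {group!r}")
            if label in seen:
                raise ValueError(
                    f"row label {label!r} assigned to both {seen[label]!r} "
                    f"and {group!r}"
                )
            seen[label] = group
    rows = []
    for group, members in grouping.items():
        young = float(table.loc[list(members), "young"].sum())
        aged = float(table.loc[list(members), "aged"].sum())
        rows.append(
            {
                "group": group,
                "young": young,
                "aged": aged,
                "fold": fold_change(young, aged),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def bootstrap_ci(
    calls: pd.DataFrame,
    freqs: FractionFrequencies,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for each ``F_t``.

    Clones are resampled with replacement *within* each fraction (clone
    labels within a fraction are exchangeable, so this is a multinomial
    draw of the count vector), ``F_t`` recomputed per replicate, and the
    central ``level`` interval reported.  Fractions with fewer than two
    clones leave the interval flagged unreliable.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = count_table(calls)
    fractions = [f for f in FRACTIONS if freqs.shares.get(f, 0.0) > 0]
    n_f = counts.sum(axis=0)
    empty = [f for f in fractions if n_f[f] == 0]
    if empty:
        raise ValueError(f"fraction(s) with zero clones: {empty}")
    unreliable = bool((n_f[fractions] < 2).any())

    N = freqs.phsc_per_million
    k = len(counts.index)
    F_rep = np.zeros((B, k))
    for f in fractions:
        share = freqs.shares[f]
        p_hat = counts[f].to_numpy() / n_f[f]
        draws = rng.multinomial(int(n_f[f]), p_hat, size=B)  # B x k
        F_rep += N * share * draws / n_f[f]
    alpha = 1.0 - level
    lo = np.quantile(F_rep, alpha / 2, axis=0)
    hi = np.quantile(F_rep, 1 - alpha / 2, axis=0)
    out = pd.DataFrame({"lower": lo, "upper": hi}, index=counts.index)
    out.attrs["unreliable"] = unreliable
    out.attrs["B"] = B
    out.attrs["level"] = level
    return out


def composition_chisq(
    young_counts: pd.Series | np.ndarray, aged_counts: pd.Series | np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square comparing young vs aged functional composition.

    Categories empty in both groups are dropped (they carry no information
    and would inflate the nominal df); df = k - 1 for the remaining k
    categories.  Returns ``(statistic, df, p)``.
    """
    y = np.asarray(young_counts, dtype=float)
    a = np.asarray(aged_counts, dtype=float)
    if y.shape != a.shape:
        raise ValueError("count vectors must share categories")
    if y.sum() <= 0 or a.sum() <= 0:
        raise ValueError("each group needs a positive total count")
    keep = (y + a) > 0
    table = np.vstack([y[keep], a[keep]])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


class ClonalCompartmentModel:
    """Compartment-frequency model for one age group.

    Parameters
    ----------
    calls : pandas.DataFrame
        Classifier output (one row per surviving clone).  Clones whose
        fraction is not F1/F2/F3 (e.g. unfractionated CD34-KSL transplants)
        are excluded from frequency estimation — the absolute scale is
        anchored to the sorted-fraction shares — and counted in
        ``n_unfractionated``.
    freqs : FractionFrequencies
        Compartment size and fraction shares for the age group.

    Examples
    --------
    >>> model = ClonalCompartmentModel(calls, freqs)
    >>> res = model.fit(bootstrap=1000, seed=0)
    >>> res.per_million["LT-HSC"]      # cells per 10^6 BM cells
    >>> print(res.summary())
    """

    def __init__(self, calls: pd.DataFrame, freqs: FractionFrequencies):
        in_fraction = calls["fraction"].isin(FRACTIONS)
        self.calls = calls[in_fraction].reset_index(drop=True)
        self.n_unfractionated = int((~in_fraction).sum())
        self.freqs = freqs
        if len(self.calls) == 0:
            raise ValueError("no fractionated clones to estimate from")

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        freqs: FractionFrequencies,
        criteria=None,
    ) -> "ClonalCompartmentModel":
        """Classify a long-format chimerism cohort, then build the model."""
        from .classify import classify_cohort

        calls = classify_cohort(cohort, criteria)
        return cls(calls, freqs)

    def fit(
        self,
        bootstrap: int | None = 1000,
        seed: int | None = None,
        level: float = 0.95,
    ) -> "CompartmentResults":
        required = [f for f in FRACTIONS if self.freqs.shares.get(f, 0.0) > 0]
        p = composition(self.calls, fractions=required)
        est = estimate_per_million(p, self.freqs)
        est.counts = count_table(self.calls)
        ci = (
            bootstrap_ci(self.calls, self.freqs, B=bootstrap, seed=seed, level=level)
            if bootstrap
            else None
        )
        return CompartmentResults(self, est, ci)


class CompartmentResults:
    """Fitted compartment estimates for one age group.

    Attributes
    ----------
    counts : DataFrame
        Clone counts, cell type x fraction.
    p_table : DataFrame
        Per-fraction composition ``p_{t|f}``.
    composition : Series
        Within-compartment composition ``pi_t`` (sums to 1).
    per_million : Series
        Absolute frequency ``F_t`` per 10^6 BM cells
        (sums to ``N * sum_f s_f``).
    """

    def __init__(
        self,
        model: ClonalCompartmentModel,
        estimate: CompartmentEstimate,
        ci: pd.DataFrame | None,
    ):
        self.model = model
        self.estimate = estimate
        self.counts = estimate.counts
        self.p_table = estimate.p_table
        self.composition = estimate.composition
        self.per_million = estimate.per_million
        self._ci = ci
        self.n_clones = int(len(model.calls))

    def conf_int(self) -> pd.DataFrame:
        if self._ci is None:
            raise ValueError("model was fitted without bootstrap; refit with "
                             "bootstrap=B to obtain intervals")
        return self._ci

    def summary(self) -> str:
        freqs = self.model.freqs
        lines = [
            "Clonal compartment estimate",
            "===========================",
            f"age group:          {freqs.age_group}",
            f"clones (F1/F2/F3):  {self.n_clones}"
            + (
                f"  (+{self.model.n_unfractionated} unfractionated, excluded)"
                if self.model.n_unfractionated
                else ""
            ),
            f"pHSC per 10^6 BM:   {freqs.phsc_per_million:g}",
            "fraction shares:    "
            + ", ".join(f"{f}={s:g}" for f, s in freqs.shares.items()),
            "",
        ]
        tbl = pd.DataFrame(
            {
                "count": self.counts.sum(axis=1),
                "pi": self.composition.round(4),
                "per_1e6_BM": self.per_million.round(2),
            }
        )
        if self._ci is not None:
            tbl["ci_lower"] = self._ci["lower"].round(2)
            tbl["ci_upper"] = self._ci["upper"].round(2)
        lines.append(tbl.to_string())
        lines.append("")
        lines.append(
            f"total per 10^6 BM:  {self.per_million.sum():.2f} "
            f"(= N x total fraction share {freqs.total_share:g})"
        )
        return "\n".join(lines)

    def plot_composition(self, ax=None):
        """Horizontal bar chart of the within-compartment composition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        comp = self.composition[self.composition.index[::-1]]
        ax.barh(comp.index, comp.to_numpy())
        ax.set_xlabel("share of pHSC compartment")
        ax.set_title(f"{self.model.freqs.age_group} functional composition")
        return ax


def aging_table(
    young: CompartmentResults,
    aged: CompartmentResults,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Frequency table across ages with fold changes.

    Rows = taxonomy labels; columns ``young``, ``aged`` (per 10^6 BM cells)
    and ``fold`` (aged/young to 1 decimal, ``"n/a"`` when young is 0).
    When ``groups`` is given, grouped sums are appended as extra rows.
    """
    table = pd.DataFrame(
        {"young": young.per_million, "aged": aged.per_million}
    )
    table["fold"] = [
        fold_change(y, a) for y, a in zip(table["young"], table["aged"])
    ]
    if groups:
        grouped = aggregate_groups(table[["young", "aged"]], groups)
        table = pd.concat([table, grouped])
    return table
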