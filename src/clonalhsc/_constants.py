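"""Shared vocabulary: lineages, taxonomy labels, timepoint schedules."""

#: Five peripheral-blood lineages: neutrophils/monocytes, erythrocytes,
#: platelets, B cells, T cells.
LINEAGES: tuple[str, ...] = ("nm", "E", "P", "B", "T")

MYELOID_LINEAGES: frozenset[str] = frozenset({"nm", "E", "P"})
LYMPHOID_LINEAGES: frozenset[str] = frozenset({"B", "T"})

#: Functional taxonomy, in report order.  Myeloid-restricted repopulating
#: cells take the RP suffix when short-term and the SC (stem cell) suffix
#: when intermediate-/long-term.
CELL_TYPES: tuple[str, ...] = (
    "LT-HSC",
    "IT-HSC",
    "ST-HSC",
    "latent-HSC",
    "LT-CMSC",
    "IT-CMSC",
    "ST-CMRP",
    "LT-MESC",
    "IT-MESC",
    "ST-MERP",
    "LT-MkSC",
    "IT-MkSC",
    "ST-MkRP",
    "other",
    "non-reconstituting",
)

FRACTIONS: tuple[str, ...] = ("F1", "F2", "F3")
AGE_GROUPS: tuple[str, ...] = ("young", "aged")
STAGES: tuple[str, ...] = ("primary", "secondary")

#: Primary-recipient bleed schedule (weeks post-transplant); weeks 12 and 20
#: are optional in the assay design and downstream code never requires them.
PRIMARY_WEEKS: tuple[int, ...] = (2, 3, 4, 8, 12, 16, 20, 24)

#: Secondary-recipient bleed schedule; the final 21-22 week window is
#: encoded as week 21.
SECONDARY_WEEKS: tuple[int, ...] = (4, 12, 16, 20, 21)

#: Lineage -> gate-size range (leukocyte gates for nm/B/T, platelet gate for
#: P, fixed erythrocyte gate).
GATE_SIZE_RANGES: dict[str, tuple[int, int]] = {
    "nm": (30_000, 50_000),
    "B": (30_000, 50_000),
    "T": (30_000, 50_000),
    "P": (20_000, 50_000),
    "E": (500_000, 500_000),
}
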