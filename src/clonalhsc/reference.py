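"""Published per-10^6-BM-cell frequencies of each functional cell type.

These are the reported point estimates from the large-scale single-cell
transplantation study of young (8-12 week) and aged (20-24 month) mouse
phenotypic HSCs, used as *inputs*: the synthetic presets are calibrated to
them and the fold-change arithmetic is recomputed from them.  Fold changes
are never stored here — they are always derived from the frequency pairs.
"""

from __future__ import annotations

import pandas as pd

from ._constants import CELL_TYPES

# label -> (young, aged) cells per 10^6 nucleated BM cells
_PUBLISHED: dict[str, tuple[float, float]] = {
    "LT-HSC": (7.3, 21.0),
    "IT-HSC": (5.6, 49.9),
    "ST-HSC": (10.8, 52.4),
    "latent-HSC": (0.0, 82.0),  # printed as "LT-latent-HSC"
    "LT-CMSC": (0.3, 0.0),
    "IT-CMSC": (1.7, 34.2),
    "ST-CMRP": (9.2, 75.1),
    "LT-MESC": (0.3, 0.0),
    "IT-MESC": (0.3, 9.1),
    "ST-MERP": (1.3, 19.1),
    "LT-MkSC": (0.0, 0.0),
    "IT-MkSC": (1.2, 20.4),
    "ST-MkRP": (6.7, 35.1),
    "other": (2.3, 10.8),
    "non-reconstituting": (20.3, 316.0),
}

#: Rows whose printed fold value is arithmetically consistent with the
#: printed frequency pair under half-away-from-zero rounding to 1 decimal.
#: The four IT rows are not (e.g. IT-HSC prints 9.0 but 49.9/5.6 = 8.9);
#: their published folds presumably derive from unrounded frequencies.
CONSISTENT_FOLD_ROWS: tuple[str, ...] = (
    "LT-HSC",
    "ST-HSC",
    "ST-CMRP",
    "ST-MERP",
    "ST-MkRP",
    "other",
    "non-reconstituting",
)

#: Standard row groupings for aggregate fold changes.
GROUPS: dict[str, tuple[str, ...]] = {
    "HSC": ("LT-HSC", "IT-HSC", "ST-HSC"),
    "ST-MyRP": ("ST-CMRP", "ST-MERP", "ST-MkRP"),
}


def published_frequencies() -> pd.DataFrame:
    """Reported frequencies per 10^6 BM cells; rows = taxonomy, columns
    ``young``/``aged``."""
    df = pd.DataFrame.from_dict(
        _PUBLISHED, orient="index", columns=["young", "aged"]
    )
    return df.reindex(list(CELL_TYPES))


def published_totals() -> dict[str, float]:
    """Column sums: the implied phenotypic-HSC compartment size per age
    (young 67.3, aged 725.1 per 10^6 BM cells; ~10-fold expansion)."""
    df = published_frequencies()
    return {"young": float(df["young"].sum()), "aged": float(df["aged"].sum())}
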