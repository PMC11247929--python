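"""Monosynaptic rabies-tracing quantification.

Starter cells co-express the helper (GFP) and rabies (mCherry); input
cells are mCherry+ GFP-.  Brain-wide connectivity is summarized as the
percentage of input cells per (region, hemisphere) out of all input cells,
with a strict >1% reporting filter; local connectivity as the per-layer
fraction of ipsilateral inputs inside the injected region (VISp).
"""

from __future__ import annotations

import pandas as pd

from .errors import EmptyTracingError, InvalidArgumentError

__all__ = [
    "validate_table",
    "starter_mask",
    "input_mask",
    "input_fractions",
    "starter_layer_distribution",
    "local_layer_fractions",
]

REQUIRED_COLUMNS = ("cell_id", "region", "hemisphere", "layer", "gfp", "mcherry")
LAYERS = ("L1", "L2/3", "L4", "L5", "L6", "none")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and value domains of a traced-cell table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"missing columns: {missing}")
    if not set(table["hemisphere"]).issubset({"ipsi", "contra"}):
        raise InvalidArgumentError("hemisphere must be ipsi/contra")
    if not set(table["layer"]).issubset(set(LAYERS)):
        raise InvalidArgumentError(f"layer must be one of {LAYERS}")
    if not set(table["gfp"]).issubset({0, 1}) or not set(table["mcherry"]).issubset({0, 1}):
        raise InvalidArgumentError("gfp/mcherry must be 0/1 flags")
    return table


def starter_mask(table: pd.DataFrame):
    """Starter cells: GFP+ and mCherry+."""
    return (table["gfp"] == 1) & (table["mcherry"] == 1)


def input_mask(table: pd.DataFrame):
    """Presynaptic input cells: mCherry+ and GFP-."""
    return (table["mcherry"] == 1) & (table["gfp"] == 0)


def input_fractions(table: pd.DataFrame, report_threshold_pct: float = 1.0,
                    include_starters: bool = False) -> pd.DataFrame:
    """Input-cell percentage per (region, hemisphere).

    The denominator counts input cells only (starters excluded, unless
    ``include_starters``).  ``reported`` is True strictly above the
    threshold (a region at exactly 1.0% is not reported).
    """
    validate_table(table)
    sel = input_mask(table)
    if include_starters:
        sel = sel | starter_mask(table)
    cells = table[sel]
    if cells.empty:
        raise EmptyTracingError("no input cells in the table")
    counts = (cells.groupby(["region", "hemisphere"], observed=True)
              .size().rename("count").reset_index())
    counts["percent"] = 100.0 * counts["count"] / counts["count"].sum()
    counts["reported"] = counts["percent"] > report_threshold_pct
    return counts.sort_values("percent", ascending=False, ignore_index=True)


def starter_layer_distribution(table: pd.DataFrame) -> pd.Series:
    """Fraction of starter cells per cortical layer (sums to 1)."""
    validate_table(table)
    starters = table[starter_mask(table)]
    if starters.empty:
        raise EmptyTracingError("no starter cells in the table")
    counts = starters.groupby("layer", observed=True).size()
    return counts / counts.sum()


def local_layer_fractions(table: pd.DataFrame,
                          local_region: str = "VISp") -> pd.Series:
    """Per-layer fraction of local inputs (ipsilateral, in local_region).

    Normalized to the total ipsilateral mCherry+ GFP- count inside
    ``local_region``; contralateral cells are excluded.
    """
    validate_table(table)
    sel = (input_mask(table)
           & (table["region"] == local_region)
           & (table["hemisphere"] == "ipsi"))
    local = table[sel]
    if local.empty:
        raise EmptyTracingError(f"no local input cells in {local_region}")
    counts = local.groupby("layer", observed=True).size()
    return counts / counts.sum()
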