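"""Reproduction helpers for externally deposited isotope spreadsheets.

The deposited data file's exact column layout is not machine-readable in
advance, so the import is driven by a configurable column mapping with
permissive defaults: the reader scans all sheets for columns matching
the canonical names (case/space-insensitive) and falls back to any
mapping supplied by the caller.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import TrophicEnrichment
from .trophic import nested_anova

_CANONICAL = {
    "d15N": re.compile(r"(d|delta|δ)\s*15\s*n", re.I),
    "category": re.compile(r"(category|taxon|species|group|organism)", re.I),
    "site": re.compile(r"(site|location)", re.I),
    "habitat_status": re.compile(r"(status|habitat|treatment|condition)", re.I),
}


def _match_columns(df: pd.DataFrame) -> dict[str, str] | None:
    out = {}
    for canon, pat in _CANONICAL.items():
        hits = [c for c in df.columns if isinstance(c, str) and pat.search(c)]
        if not hits:
            return None
        out[canon] = hits[0]
    return out


def load_deposited_consumers(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sheet: str | int | None = None,
) -> pd.DataFrame:
    """Extract (category, site, habitat_status, d15N) rows from a deposited
    XLSX, scanning sheets until a usable layout is found."""
    sheets = pd.read_excel(path, sheet_name=sheet)
    if isinstance(sheets, pd.DataFrame):
        sheets = {"sheet": sheets}
    for name, df in sheets.items():
        mapping = column_map or _match_columns(df)
        if mapping is None:
            continue
        out = df[[mapping[k] for k in
                  ("category", "site", "habitat_status", "d15N")]].copy()
        out.columns = ["category", "site", "habitat_status", "d15N"]
        out = out.dropna(subset=["d15N"])
        out["d15N"] = pd.to_numeric(out["d15N"], errors="coerce")
        out = out.dropna(subset=["d15N"])
        if len(out):
            return out
    raise ValueError(f"{path}: no sheet matches the expected column layout; "
                     "supply an explicit column_map")


def trophic_f_stats_from_deposited(
    path: str | Path,
    tef: TrophicEnrichment,
    consumer_pattern: str = "armases",
    baseline_pattern: str = "melampus",
    lam: float = 2.0,
    column_map: dict[str, str] | None = None,
) -> tuple[float, float]:
    """Per-crab trophic positions and nested-ANOVA F statistics from a
    deposited spreadsheet.

    TP = lam + (crab δ15N − site mean baseline δ15N) / Δδ15N; the ANOVA
    tests habitat treatment (over the residual mean square) and site
    nested within treatment. Returns (F_treatment, F_site_within).
    """
    df = load_deposited_consumers(path, column_map=column_map)
    cat = df["category"].astype(str).str.lower()
    crabs = df[cat.str.contains(consumer_pattern)].copy()
    snails = df[cat.str.contains(baseline_pattern)]
    if crabs.empty or snails.empty:
        raise ValueError("could not locate consumer and/or baseline rows")
    base = snails.groupby("site")["d15N"].mean()
    crabs["tp"] = lam + (crabs["d15N"] - crabs["site"].map(base)) \
        / tef.delta_d15N_mean
    table = nested_anova(crabs, denominator="residual")
    return float(table.loc[0, "F"]), float(table.loc[1, "F"])
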