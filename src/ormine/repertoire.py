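"""Per-species OR repertoire tables, normalizations and summary statistics.

Aggregates classified OR records into a species x counts table: functional
counts per family, sub-7TM and pseudogene counts, totals and fractions.
Two "fraction functional" conventions are computed side by side because
both occur in the literature: relative to functional + pseudogene only
(``fraction_functional_fp``), and relative to the full repertoire
including sub-7TM sequences (``fraction_functional``). Class I is the
ancient families 51/52/55/56.

Family proportions (count / total functional) can optionally be rescaled
so every family column has mean 1, which gives small and large families
the same weight in downstream ordination and model fitting.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import (
    ORRecord,
    STATUS_FUNCTIONAL,
    STATUS_PSEUDOGENE,
    STATUS_REMOVED,
    STATUS_SUB7TM,
)
from .families import CLASS_I, FAMILIES, UNASSIGNED

__all__ = [
    "summarize",
    "repertoire_from_counts",
    "normalize_families",
    "table_stats",
    "family_columns",
]

_VALID_STATUS = {STATUS_FUNCTIONAL, STATUS_SUB7TM, STATUS_PSEUDOGENE, STATUS_REMOVED}


def family_columns() -> list[str]:
    return [f"fam_{f}" for f in FAMILIES]


def summarize(records_by_species: Mapping[str, Iterable[ORRecord]]) -> pd.DataFrame:
    """Aggregate classified records into a per-species repertoire table.

    Rows are species (sorted); columns are the 13 per-family functional
    counts, ``fam_unassigned``, ``sub7tm``, ``pseudogene``,
    ``removed_nonor``, totals and fractions. ``n_total`` counts
    functional + sub7TM + pseudogene (non-OR removals are bookkept but
    excluded from repertoire totals).
    """
    rows = {}
    for species in sorted(records_by_species):
        counts = {c: 0 for c in family_columns()}
        counts["fam_unassigned"] = 0
        sub7 = pseudo = removed = 0
        for rec in records_by_species[species]:
            if rec.status not in _VALID_STATUS:
                raise ValueError(
                    f"record {rec.id!r}: unknown status {rec.status!r}"
                )
            if rec.status == STATUS_FUNCTIONAL:
                fam = rec.family_id if rec.family_id in FAMILIES else UNASSIGNED
                key = f"fam_{fam}" if fam != UNASSIGNED else "fam_unassigned"
                counts[key] += 1
            elif rec.status == STATUS_SUB7TM:
                sub7 += 1
            elif rec.status == STATUS_PSEUDOGENE:
                pseudo += 1
            else:
                removed += 1
        counts["sub7tm"] = sub7
        counts["pseudogene"] = pseudo
        counts["removed_nonor"] = removed
        rows[species] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        return pd.DataFrame(
            columns=family_columns()
            + ["fam_unassigned", "sub7tm", "pseudogene", "removed_nonor"]
        )
    return _derive(table)


def repertoire_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Ingest a pre-counted per-species table (e.g. a published supplement).

    Expects the 13 ``fam_<id>`` columns plus ``pseudogene``; ``sub7tm``,
    ``fam_unassigned`` and ``removed_nonor`` default to zero. Derived
    totals and fractions are (re)computed.
    """
    table = counts.copy()
    missing = [c for c in family_columns() + ["pseudogene"] if c not in table]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    for col in ("sub7tm", "fam_unassigned", "removed_nonor"):
        if col not in table:
            table[col] = 0
    return _derive(table)


def _derive(table: pd.DataFrame) -> pd.DataFrame:
    fam_cols = family_columns()
    table = table.copy()
    table["n_func"] = table[fam_cols].sum(axis=1) + table["fam_unassigned"]
    table["n_total"] = table["n_func"] + table["sub7tm"] + table["pseudogene"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["fraction_functional"] = table["n_func"] / table["n_total"]
        fp = table["n_func"] + table["pseudogene"]
        table["fraction_functional_fp"] = table["n_func"] / fp
        class1 = table[[f"fam_{f}" for f in CLASS_I]].sum(axis=1)
        table["class1_fraction"] = class1 / table["n_func"]
    table.index.name = "species"
    return table.sort_index()


def normalize_families(
    table: pd.DataFrame, rescale_columns: bool = False
) -> pd.DataFrame:
    """Per-species family proportions, optionally column-rescaled to mean 1.

    Proportions are functional counts divided by the species' total
    functional count, so each row of the un-rescaled matrix sums to ~1
    (exactly 1 when no functional gene is family-unassigned). With
    ``rescale_columns`` every family column is divided by its mean, giving
    each family equal weight.
    """
    fam_cols = family_columns()
    zero = table.index[table["n_func"] <= 0]
    if len(zero):
        raise ValueError(
            f"species with no functional genes: {', '.join(map(str, zero))}"
        )
    props = table[fam_cols].div(table["n_func"], axis=0)
    props.columns = [c.removeprefix("fam_") for c in fam_cols]
    if rescale_columns:
        means = props.mean(axis=0)
        if (means <= 0).any():
            bad = means.index[means <= 0].tolist()
            raise ValueError(f"family with zero counts everywhere: {bad}")
        props = props.div(means, axis=1)
    return props


def table_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Median / mean / min / max and arg-extreme species per numeric column.

    The median of an even-length column is the mean of the two central
    values (the usual mid-mean convention).
    """
    if len(table) == 0:
        raise ValueError("empty repertoire table")
    num = table.select_dtypes(include=[np.number])
    out = pd.DataFrame(
        {
            col: {
                "median": num[col].median(),
                "mean": num[col].mean(),
                "min": num[col].min(),
                "max": num[col].max(),
                "argmin": num[col].idxmin(),
                "argmax": num[col].idxmax(),
            }
            for col in num.columns
        }
    )
    return out.reindex(["median", "mean", "min", "max", "argmin", "argmax"])
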