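"""Spatial thinning of occurrence records on a reference grid.

Thinning keeps at most one record per grid cell — per species when run at
species level, ignoring species labels at genus level — which is the
standard guard against inflated sample sizes from clustered herbarium
records.  The retained record in a cell is the first in input order; the
choice of survivor is the only permutation-sensitive aspect, never the
count.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .grids import GridSpec, OccurrenceSet

logger = logging.getLogger("nichekit")

Level = Literal["genus", "species"]


def thin_occurrences(
    occ: OccurrenceSet, spec: GridSpec, level: Level = "species"
) -> OccurrenceSet:
    """Keep at most one record per (species,) grid cell.

    Points outside the grid extent are dropped with a warning count.
    Idempotent: thinning an already-thinned set returns it unchanged.
    """
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    if level not in ("genus", "species"):
        raise ValueError(f"unknown thinning level {level!r}")
    frame = occ.frame
    lon, lat = occ.lonlat()
    inside = np.asarray(spec.contains(lon, lat))
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("thinning: dropped %d point(s) outside the grid extent", n_outside)
        frame = frame[inside].reset_index(drop=True)
        lon, lat = lon[inside], lat[inside]
        if len(frame) == 0:
            raise ValueError("no occurrences inside the grid extent")
    row, col = spec.cell_of(lon, lat)
    cell = row * spec.ncols + col
    if level == "species":
        keep = ~pd.DataFrame({"sp": frame["species"].to_numpy(), "cell": cell}).duplicated()
    else:
        keep = ~pd.Series(cell).duplicated()
    return OccurrenceSet(frame[keep.to_numpy()].reset_index(drop=True))


def thinning_report(before: OccurrenceSet, after: OccurrenceSet) -> pd.DataFrame:
    """Per-species before/after record counts with a totals row.

    Species absent after thinning are still listed with count 0.
    """
    b = before.frame["species"].value_counts()
    a = after.frame["species"].value_counts()
    species = list(dict.fromkeys(before.frame["species"]))
    rows = [
        {
            "species": sp,
            "before": int(b.get(sp, 0)),
            "after": int(a.get(sp, 0)),
            "removed": int(b.get(sp, 0)) - int(a.get(sp, 0)),
        }
        for sp in species
    ]
    rows.append(
        {
            "species": "Total",
            "before": len(before),
            "after": len(after),
            "removed": len(before) - len(after),
        }
    )
    return pd.DataFrame(rows)
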