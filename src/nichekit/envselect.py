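"""Environmental-variable screening.

The screening pipeline mirrors common practice in distribution modelling:
(1) sample every candidate layer at the occurrence points, (2) drop
variables the initial model assigns zero contribution, (3) remove one
member of every highly correlated pair (|Pearson r| >= 0.80 by default),
keeping the higher-contribution variable unless an explicit
ecological-importance override says otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvStack, OccurrenceSet

logger = logging.getLogger("nichekit")

DEFAULT_CORR_THRESHOLD = 0.80


@dataclass
class VariableTable:
    """Layer values sampled at occurrence points (rows = points)."""

    frame: pd.DataFrame
    n_dropped_nodata: int = 0
    n_dropped_outside: int = 0

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def extract_at_points(stack: EnvStack, occ: OccurrenceSet) -> VariableTable:
    """Sample every layer at each occurrence point (nearest-cell lookup).

    A point takes the value of the cell containing it (half-open cell
    intervals).  Points outside the extent, or hitting nodata in any layer,
    are excluded with counts.
    """
    lon, lat = occ.lonlat()
    inside = np.asarray(stack.spec.contains(lon, lat))
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("extract: %d point(s) outside the grid extent excluded", n_outside)
    lon, lat = lon[inside], lat[inside]
    row, col = stack.spec.cell_of(lon, lat)
    data = {name: stack[name].values[row, col] for name in stack.names}
    valid = np.ones(len(lon), dtype=bool)
    for name in stack.names:
        valid &= stack[name].valid[row, col]
    n_nodata = int((~valid).sum())
    if n_nodata:
        logger.warning("extract: %d point(s) hitting nodata excluded", n_nodata)
    frame = pd.DataFrame(data)[valid].reset_index(drop=True)
    return VariableTable(frame, n_dropped_nodata=n_nodata, n_dropped_outside=n_outside)


def drop_zero_contribution(
    variables: list[str], contributions: dict[str, float]
) -> list[str]:
    """Retain variables whose model contribution is strictly positive."""
    missing = [v for v in variables if v not in contributions]
    if missing:
        raise ValueError(f"contributions missing for {missing}")
    kept = [v for v in variables if contributions[v] > 0]
    if not kept:
        logger.warning("all variables have zero contribution")
    return kept


def correlation_matrix(table: VariableTable) -> pd.DataFrame:
    """Full Pearson correlation matrix of the sampled variables."""
    return table.frame.corr(method="pearson")


def pearson_filter(
    table: VariableTable,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    keep: set[str] | None = None,
    rank: dict[str, float] | None = None,
) -> list[str]:
    """Greedy pairwise elimination of highly correlated variables.

    Pairs with |r| >= threshold are visited in descending |r| (ties broken
    by variable-name pair).  At each offending pair the lower-contribution
    member is removed — unless it is in *keep* (an ecological-importance
    override), in which case the partner is removed instead.  A pair whose
    members are both in *keep* survives.  The result has no correlated pair
    outside *keep*.
    """
    if len(table) < 3:
        raise ValueError("pearson_filter needs at least 3 rows")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    keep = set(keep or ())
    rank = rank or {}
    variables = table.variables
    unknown = keep - set(variables)
    if unknown:
        raise ValueError(f"keep names not in table: {sorted(unknown)}")
    corr = correlation_matrix(table)

    pairs = []
    for a, b in itertools.combinations(variables, 2):
        r = corr.loc[a, b]
        if np.isfinite(r) and abs(r) >= threshold:
            pairs.append((abs(r), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    removed: set[str] = set()
    for absr, a, b in pairs:
        if a in removed or b in removed:
            continue
        ra, rb = rank.get(a, 0.0), rank.get(b, 0.0)
        # lower-contribution member is the default victim; on a tie the
        # lexicographically later name goes
        if ra < rb or (ra == rb and a > b):
            victim, partner = a, b
        else:
            victim, partner = b, a
        if victim in keep and partner in keep:
            logger.info("pearson_filter: |r|=%.3f pair (%s, %s) both kept by override", absr, a, b)
            continue
        if victim in keep:
            victim, partner = partner, victim
        removed.add(victim)
        logger.info("pearson_filter: removed %s (|r|=%.3f with %s)", victim, absr, partner)
    return [v for v in variables if v not in removed]


def combine_replicate_contributions(tables: list[dict[str, float]]) -> dict[str, float]:
    """Arithmetic mean of per-replicate percent contributions."""
    if not tables:
        raise ValueError("no replicate contribution tables")
    keys = tables[0].keys()
    return {k: float(np.mean([t[k] for t in tables])) for k in keys}
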