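"""Emergent range measurements.

The corridor geometry makes the range front a scalar: the edge is the row of
the furthest-forward habitat patch holding a breeding population (two-sex
runs require at least one individual of each sex — a patch that cannot
produce offspring is not occupied in this sense).  Spread rate is the number
of extra rows colonised per five-year window divided by five, averaged over
consecutive non-overlapping windows; quasi-equilibrium asks whether core
proportional occupancy has stopped declining over the back half of a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "breeding_patch",
    "range_edge",
    "spread_rate",
    "spread_windows",
    "quasi_equilibrium",
    "neighbourhood_stats",
    "extinction_stats",
]


def breeding_patch(n_f, n_m, two_sex: bool) -> np.ndarray:
    """Which patches hold a population capable of producing offspring.

    Counts individuals of any age: a juvenile pair present at the year-end
    census breeds the following year.
    """
    n_f = np.asarray(n_f)
    n_m = np.asarray(n_m)
    if two_sex:
        return (n_f >= 1) & (n_m >= 1)
    return n_f >= 1


def range_edge(breeding: np.ndarray, patch_rows: np.ndarray) -> int:
    """Row of the furthest-forward breeding patch; -1 if none (extinct)."""
    breeding = np.asarray(breeding, dtype=bool)
    if not breeding.any():
        return -1
    return int(np.asarray(patch_rows)[breeding].max())


def spread_windows(
    edges: pd.Series,
    horizon_years: int,
    window: int = 5,
    extinct: pd.Series | None = None,
) -> list[float]:
    """Per-window advance of the range edge, in rows per generation.

    ``edges`` is indexed by year (year 0 = initial state).  Windows are the
    consecutive non-overlapping [t, t+window] intervals with t + window <=
    horizon; a window is only used if both endpoints exist and the run is
    not extinct at either.
    """
    edges = pd.Series(edges)
    rates: list[float] = []
    for t in range(0, horizon_years - window + 1, window):
        t1 = t + window
        if t not in edges.index or t1 not in edges.index:
            break
        if extinct is not None and (bool(extinct.get(t, True)) or bool(extinct.get(t1, True))):
            break
        rates.append(float(edges.loc[t1] - edges.loc[t]) / window)
    return rates


def spread_rate(
    edges: pd.Series,
    horizon_years: int,
    window: int = 5,
    extinct: pd.Series | None = None,
) -> float:
    """Overall spread rate: mean of the per-window rates (`spread_windows`).

    NaN when no full window is available (extinction before year ``window``).
    """
    rates = spread_windows(edges, horizon_years, window, extinct)
    if not rates:
        return float("nan")
    return float(np.mean(rates))


def quasi_equilibrium(
    occupancy: pd.Series,
    y_from: int = 20,
    y_to: int = 50,
    extinct: bool = False,
) -> bool:
    """mean(delta p) + SE(delta p) > 0 over years [y_from, y_to].

    ``occupancy`` is the core proportional-occupancy series indexed by year
    (positional index = year when a RangeIndex).  Extinct runs never qualify.
    The inequality is strict, so a perfectly flat series does not qualify.
    """
    if extinct:
        return False
    occ = pd.Series(occupancy).to_numpy(dtype=float)
    if len(occ) <= y_from + 1:
        return False
    seg = occ[y_from : y_to + 1]
    dp = np.diff(seg)
    if dp.size == 0:
        return False
    se = dp.std(ddof=1) / np.sqrt(dp.size) if dp.size > 1 else 0.0
    return bool(dp.mean() + se > 0.0)


def neighbourhood_stats(
    breeding: np.ndarray,
    patch_rows: np.ndarray,
    n_females: np.ndarray,
    n_unmated: np.ndarray,
    edge_row: int,
    section_rows: int = 10,
) -> pd.DataFrame:
    """Occupancy and mating failure by 10-row section behind the range edge.

    Sections tile the occupied range backwards from the edge: section 0
    covers the ``section_rows`` rows ending at the edge, section 1 the next
    block toward the core, and so on down to row 0 — re-anchored at the edge
    every year so a section's relative position in the occupied range stays
    constant.  Per section: occupancy P = breeding / habitat patches, and
    the proportion of this year's reproductive-age females that went
    unmated (NaN when the section holds no females).
    """
    if edge_row < 0:
        raise ValueError("neighbourhood_stats needs a defined range edge")
    patch_rows = np.asarray(patch_rows)
    breeding = np.asarray(breeding, dtype=bool)
    n_females = np.asarray(n_females)
    n_unmated = np.asarray(n_unmated)
    rows_out = []
    section = 0
    hi = edge_row
    while hi >= 0:
        lo = hi - section_rows + 1
        sel = (patch_rows >= lo) & (patch_rows <= hi)
        n_patches = int(sel.sum())
        if n_patches > 0:
            fem = int(n_females[sel].sum())
            unm = int(n_unmated[sel].sum())
            rows_out.append(
                {
                    "section_index": section,
                    "row_hi": hi,
                    "row_lo": max(lo, 0),
                    "n_patches": n_patches,
                    "n_breeding": int(breeding[sel].sum()),
                    "occupancy": breeding[sel].sum() / n_patches,
                    "females": fem,
                    "unmated": unm,
                    "prop_unmated": unm / fem if fem > 0 else np.nan,
                }
            )
        section += 1
        hi = lo - 1
    return pd.DataFrame(rows_out)


def extinction_stats(table: pd.DataFrame) -> pd.Series:
    """Proportion of runs extinct before the horizon, by mating system."""
    return table.groupby("mating_system")["extinct"].mean()
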