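"""Juvenile dispersal: stochastic stepwise movement and settlement rules.

Movement follows a stochastic movement simulator (SMS) scheme: a disperser
moves cell to cell on the raster, choosing among its (on-grid) eight
neighbours with probability proportional to

    DP^(-turn) * 1 / effective_cost(candidate cell, heading)

where ``turn`` is the heading change in multiples of 45 degrees and DP the
directional persistence (DP = 3 makes a 90-degree turn 9 times, and a
reversal 81 times, less likely than continuing straight).  The effective
cost of a candidate cell is the arithmetic mean of per-cell movement costs
(habitat 1, matrix 10) over the cells the disperser perceives in that
direction — by default the 45-degree wedge of cells within the perceptual
range around the candidate, alternatively just the straight ray of cells —
truncated at the hard grid border.  Each step carries a fixed mortality
risk and there is
no cap on the number of steps, so realized dispersal distances are emergent.

Settlement is evaluated every time a disperser steps onto a habitat cell
other than its natal patch:

* ``habitat_only`` — settle unconditionally;
* ``mate_search`` — settle only if an opposite-sex conspecific already
  occupies the patch (a resident or an earlier settler); two opposite-sex
  dispersers reaching an empty patch in the same global tick settle together;
* ``density_dependent`` — settle with the logistic probability
  P_s = 1 / (1 + exp(-(b*N_f - beta_s) * alpha_s)), decreasing in the
  patch's current female count N_f when alpha_s < 0;
* ``mate_search_and_dd`` — both conditions.

`disperse_cohort` advances all of a year's emigrants one step per global
tick in randomized order, with settlement seen against up-to-the-moment
occupancy, which gives the simultaneous-arrival semantics a well-defined
meaning.  The hot loop lives in a numba kernel; this module also provides a
plain-Python single-disperser `step` used as the reference implementation in
the test-suite cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _sms_kernel
from .landscape import GridLandscape

__all__ = [
    "MovementParams",
    "SettlementRule",
    "DisperserState",
    "STRATEGIES",
    "DIR_OFFSETS",
    "emigrate",
    "directional_weight",
    "cost_grid",
    "perceptual_offsets",
    "effective_cost",
    "effective_cost_grid",
    "step_probabilities",
    "step",
    "settlement_prob_dd",
    "check_settlement",
    "disperse_cohort",
]

# eight compass directions, clockwise from "up the corridor" (decreasing row)
DIR_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=np.int64,
)

STRATEGIES = ("habitat_only", "mate_search", "density_dependent", "mate_search_and_dd")


@dataclass(frozen=True)
class MovementParams:
    """``pr_aggregation`` selects how per-cell costs within the perceptual
    range combine into one effective cost per direction: ``"sector"`` (the
    default) averages every cell within PR whose bearing falls in the
    45-degree wedge centred on the direction, as in the reference stochastic
    movement simulator; ``"line"`` averages the PR cells along the straight
    ray only — a simpler variant that makes single habitat cells much more
    attractive and so shortens emergent dispersal distances."""

    emigration_prob: float = 0.5
    perceptual_range: int = 5
    directional_persistence: float = 3.0
    step_mortality: float = 0.005
    cost_habitat: float = 1.0
    cost_matrix: float = 10.0
    pr_aggregation: str = "sector"
    max_ticks: int = 1_000_000

    def __post_init__(self) -> None:
        if self.pr_aggregation not in ("sector", "line"):
            raise ValueError("pr_aggregation must be 'sector' or 'line'")
        if not 0.0 <= self.emigration_prob <= 1.0:
            raise ValueError("emigration_prob must lie in [0, 1]")
        if self.perceptual_range < 1:
            raise ValueError("perceptual_range must be >= 1")
        if self.directional_persistence < 1.0:
            raise ValueError("directional_persistence must be >= 1")
        if not 0.0 <= self.step_mortality < 1.0:
            raise ValueError("step_mortality must lie in [0, 1)")
        if self.cost_habitat < 1.0 or self.cost_matrix < 1.0:
            raise ValueError("movement costs must be >= 1")


@dataclass(frozen=True)
class SettlementRule:
    """``density_measure`` selects the patch count N entering the settlement
    logistic: ``"all"`` (default) uses every current occupant relative to
    the 2/b two-sex carrying capacity, as when density is assessed against
    total patch population; ``"females"`` counts females only, mirroring the
    survival equation's weighting."""

    strategy: str = "habitat_only"
    beta_s: float = 0.75
    alpha_s: float = -10.0
    density_measure: str = "all"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown settlement strategy {self.strategy!r}; "
                f"expected one of {STRATEGIES}"
            )
        if self.density_measure not in ("all", "females"):
            raise ValueError("density_measure must be 'all' or 'females'")

    @property
    def needs_mate(self) -> bool:
        return self.strategy in ("mate_search", "mate_search_and_dd")

    @property
    def density_dependent(self) -> bool:
        return self.strategy in ("density_dependent", "mate_search_and_dd")


@dataclass
class DisperserState:
    """Mutable state of one disperser in transit."""

    row: int
    col: int
    natal_patch: int
    sex: int = 0  # 0 female, 1 male
    heading: int = -1  # -1 = no previous heading (first step)
    steps: int = 0
    status: str = "moving"  # {"moving", "settled", "dead"}


def emigrate(age: int, emigration_prob: float, rng: np.random.Generator) -> bool:
    """Bernoulli emigration decision; only age-0 juveniles may emigrate."""
    if age != 0:
        raise ValueError("only juveniles (age 0) can emigrate")
    return bool(rng.uniform() < emigration_prob)


def directional_weight(turn: int, dp: float) -> float:
    """Relative weight DP^(-turn) for a heading change of ``turn`` x 45 deg."""
    if turn not in (0, 1, 2, 3, 4):
        raise ValueError("turn must be in 0..4 (multiples of 45 degrees)")
    if dp < 1.0:
        raise ValueError("directional persistence must be >= 1")
    return float(dp ** (-turn))


def cost_grid(landscape: GridLandscape, params: MovementParams) -> np.ndarray:
    """Per-cell movement cost raster (habitat vs matrix)."""
    return np.where(
        landscape.habitat_mask, params.cost_habitat, params.cost_matrix
    ).astype(np.float64)


def perceptual_offsets(params: MovementParams) -> list:
    """Cell offsets aggregated per direction, relative to the candidate cell.

    ``line``: the candidate cell plus the next PR-1 cells along the ray.
    ``sector``: the candidate cell plus every cell within Chebyshev distance
    PR-1 of it whose bearing falls in the 45-degree wedge centred on the
    direction (integer offsets never land exactly on a wedge boundary).
    """
    pr = params.perceptual_range
    out: list[list[tuple[int, int]]] = [[] for _ in range(8)]
    if params.pr_aggregation == "line":
        for d, (dr, dc) in enumerate(DIR_OFFSETS):
            out[d] = [(k * int(dr), k * int(dc)) for k in range(pr)]
        return out
    dir_ang = [math.atan2(float(dr), float(dc)) for dr, dc in DIR_OFFSETS]
    for d in range(8):
        out[d].append((0, 0))
    for orr in range(-(pr - 1), pr):
        for occ in range(-(pr - 1), pr):
            if orr == 0 and occ == 0:
                continue
            ang = math.atan2(float(orr), float(occ))
            best = min(
                range(8),
                key=lambda d: abs(
                    math.remainder(ang - dir_ang[d], 2.0 * math.pi)
                ),
            )
            out[best].append((orr, occ))
    return out


def effective_cost(
    cell: tuple[int, int],
    heading: int,
    landscape: GridLandscape,
    params: MovementParams,
) -> float:
    """Effective cost of candidate ``cell`` when approached along ``heading``.

    The arithmetic mean of per-cell costs over the perceptual-range
    neighbourhood of the candidate cell in the heading direction
    (`perceptual_offsets`), truncated at the hard grid border, so near a
    border fewer cells contribute.  The candidate cell itself always
    contributes, hence the result is defined for every on-grid candidate.
    """
    cost = cost_grid(landscape, params)
    r, c = cell
    if not (0 <= r < landscape.n_rows and 0 <= c < landscape.n_cols):
        raise ValueError("candidate cell is off-grid")
    total, count = 0.0, 0
    for orr, occ in perceptual_offsets(params)[heading]:
        rr, cc = r + orr, c + occ
        if not (0 <= rr < landscape.n_rows and 0 <= cc < landscape.n_cols):
            continue
        total += cost[rr, cc]
        count += 1
    return total / count


def effective_cost_grid(
    landscape: GridLandscape, params: MovementParams
) -> np.ndarray:
    """Precompute `effective_cost` for every (candidate cell, heading).

    Returns shape (n_rows, n_cols, 8).  Computed once per landscape and
    shared by the reference `step` and the compiled cohort kernel.
    """
    cost = cost_grid(landscape, params)
    R, C = cost.shape
    eff = np.empty((R, C, 8), dtype=np.float64)
    offsets = perceptual_offsets(params)
    for d in range(8):
        total = np.zeros((R, C))
        count = np.zeros((R, C))
        for orr, occ in offsets[d]:
            r0, r1 = max(0, -orr), min(R, R - orr)
            c0, c1 = max(0, -occ), min(C, C - occ)
            total[r0:r1, c0:c1] += cost[r0 + orr : r1 + orr, c0 + occ : c1 + occ]
            count[r0:r1, c0:c1] += 1.0
        eff[:, :, d] = total / count
    return eff


def step_probabilities(
    row: int,
    col: int,
    heading: int,
    effcost: np.ndarray,
    dp: float,
) -> np.ndarray:
    """Normalized move probabilities over the 8 directions (0 if off-grid)."""
    R, C, _ = effcost.shape
    w = np.zeros(8)
    for d, (dr, dc) in enumerate(DIR_OFFSETS):
        nr, nc = row + dr, col + dc
        if not (0 <= nr < R and 0 <= nc < C):
            continue
        if heading < 0:
            dwt = 1.0
        else:
            turn = abs(d - heading)
            turn = 8 - turn if turn > 4 else turn
            dwt = dp ** (-turn)
        w[d] = dwt / effcost[nr, nc, d]
    tot = w.sum()
    if tot <= 0:
        return w
    return w / tot


def step(
    state: DisperserState,
    landscape: GridLandscape,
    params: MovementParams,
    rng: np.random.Generator,
    effcost: np.ndarray | None = None,
) -> DisperserState:
    """Advance one disperser by one step (reference implementation).

    Per-step mortality is resolved before the move; otherwise the disperser
    picks a neighbour from `step_probabilities` and moves there.
    """
    if state.status != "moving":
        raise ValueError("step() requires a moving disperser")
    if effcost is None:
        effcost = effective_cost_grid(landscape, params)
    if rng.uniform() < params.step_mortality:
        return replace(state, status="dead")
    probs = step_probabilities(
        state.row, state.col, state.heading, effcost, params.directional_persistence
    )
    if probs.sum() <= 0:  # no legal neighbour; cannot occur on 2D grids >= 2x2
        return replace(state, status="dead")
    d = rng.choice(8, p=probs)
    dr, dc = DIR_OFFSETS[d]
    return replace(
        state,
        row=state.row + int(dr),
        col=state.col + int(dc),
        heading=int(d),
        steps=state.steps + 1,
    )


def settlement_prob_dd(n_f, b: float, beta_s: float = 0.75, alpha_s: float = -10.0):
    """Logistic settlement probability P_s = 1/(1 + exp(-(b*N_f - beta_s)*alpha_s))."""
    n_f = np.asarray(n_f, dtype=np.float64)
    if np.any(n_f < 0):
        raise ValueError("female count must be non-negative")
    ps = 1.0 / (1.0 + np.exp(-(b * n_f - beta_s) * alpha_s))
    if ps.ndim == 0:
        return float(ps)
    return ps


def check_settlement(
    sex: int,
    natal_patch: int,
    patch: int,
    n_f: int,
    n_m: int,
    rule: SettlementRule,
    b: float,
    rng: np.random.Generator,
) -> bool:
    """Settlement decision on entering habitat patch ``patch``.

    ``n_f``/``n_m`` are the patch's current occupants (previous-year
    residents plus already-settled dispersers).  The natal patch is never a
    legal settlement target.
    """
    if patch == natal_patch:
        return False
    if rule.needs_mate:
        mate_present = (n_m if sex == 0 else n_f) > 0
        if not mate_present:
            return False
    if rule.density_dependent:
        dens = n_f + n_m if rule.density_measure == "all" else n_f
        ps = settlement_prob_dd(dens, b, rule.beta_s, rule.alpha_s)
        return bool(rng.uniform() < ps)
    return True


def disperse_cohort(
    natal_patch: np.ndarray,
    sex: np.ndarray,
    landscape: GridLandscape,
    params: MovementParams,
    rule: SettlementRule,
    occupant_f: np.ndarray,
    occupant_m: np.ndarray,
    b: float,
    seed: int,
    effcost: np.ndarray | None = None,
):
    """Run one year's emigrants to settlement or death.

    All dispersers advance one step per global tick in uniformly random
    order; settlement is checked after each individual's step against
    occupancy updated within the tick, and at tick end any patch holding
    unsettled dispersers of both sexes settles them (the simultaneous-arrival
    rule for the mate-search strategies).

    Parameters
    ----------
    natal_patch, sex : int arrays, one entry per disperser (sex 0=F, 1=M).
    occupant_f, occupant_m : per-patch occupant counts at the start of
        dispersal (residents); updated in place as settlers arrive, so on
        return they hold residents + settlers.
    seed : int
        Seed for the kernel's private RNG stream.

    Returns
    -------
    dict of arrays: fate ("settled"/"died_transit"), settle_patch (-1 when
    dead), settle_row, steps, rows_displaced.
    """
    natal_patch = np.asarray(natal_patch, dtype=np.int64)
    sex = np.asarray(sex, dtype=np.int8)
    n = natal_patch.size
    patch_rows = landscape.patch_rows
    patch_cols = landscape.patch_cols
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return {
            "fate": np.empty(0, dtype=object),
            "settle_patch": empty,
            "settle_row": empty,
            "steps": empty,
            "rows_displaced": empty,
            "natal_row": empty,
        }
    if effcost is None:
        effcost = effective_cost_grid(landscape, params)
    dpw = params.directional_persistence ** -np.arange(5, dtype=np.float64)
    natal_row = patch_rows[natal_patch].astype(np.int64)
    natal_col = patch_cols[natal_patch].astype(np.int64)
    dens_all = rule.density_measure == "all"
    pdens = occupant_f + occupant_m if dens_all else occupant_f.copy()
    status, settle_patch, steps, final_row, ticks = _sms_kernel.run_cohort(
        np.int64(seed) & 0x7FFFFFFF,
        landscape.patch_id.astype(np.int32),
        effcost,
        DIR_OFFSETS[:, 0].copy(),
        DIR_OFFSETS[:, 1].copy(),
        dpw,
        natal_row,
        natal_col,
        natal_patch,
        sex,
        occupant_f,
        occupant_m,
        pdens,
        np.int64(1 if dens_all else 0),
        STRATEGIES.index(rule.strategy),
        float(b),
        float(rule.beta_s),
        float(rule.alpha_s),
        float(params.step_mortality),
        int(params.max_ticks),
    )
    if np.any(status == 0):
        raise RuntimeError(
            f"dispersal did not terminate within {params.max_ticks} ticks "
            f"({int((status == 0).sum())} dispersers still in transit)"
        )
    settled = status == 1
    settle_row = np.where(settled, final_row, -1)
    fate = np.where(settled, "settled", "died_transit").astype(object)
    rows_displaced = np.where(settled, np.abs(settle_row - natal_row), -1)
    return {
        "fate": fate,
        "settle_patch": settle_patch,
        "settle_row": settle_row,
        "steps": steps,
        "rows_displaced": rows_displaced,
        "natal_row": natal_row,
    }
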