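"""Annual-cycle scheduler, replicate runner and factorial experiment driver.

One model year (= one generation in all rate reporting) runs three phases:

1. mating and reproduction in every patch (harmonic-mean mating function,
   Bernoulli mating trials, Poisson litters);
2. juvenile emigration, stepwise movement and settlement;
3. female-density-dependent survival applied to everyone in their
   end-of-dispersal patch, then aging (max age 3).

A run is deterministic given ``(config, replicate)``: every stochastic
stream (landscape, initialization, demography, movement) is derived from the
master seed, a stable scenario hash and the replicate index through numpy
``SeedSequence``.  Replicates share one landscape realization per replicate
index across scenarios so that scenario contrasts are paired.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .demography import (
    DemographyParams,
    FEMALE_ONLY,
    MAX_AGE,
    MatingSystem,
    MONOGAMOUS,
    POLYGYNOUS,
    apply_survival_and_aging,
    assign_reproduction,
    produce_offspring,
)
from .dispersal import (
    MovementParams,
    SettlementRule,
    disperse_cohort,
    effective_cost_grid,
)
from .landscape import GridLandscape, InitSpec, generate_landscape, sample_initial_population

__all__ = [
    "SimConfig",
    "SimResult",
    "ExperimentDesign",
    "annual_cycle",
    "run_simulation",
    "run_experiment",
    "experiment1_design",
    "experiment2_design",
]

_LANDSCAPE_TAG = 0x1A5D
_MATING = {"female_only": FEMALE_ONLY, "monogamous": MONOGAMOUS, "polygynous": POLYGYNOUS}


@dataclass(frozen=True)
class SimConfig:
    """Full parameter set for one scenario."""

    n_cols: int = 20
    n_rows: int = 1000
    habitat_fraction: float = 0.07
    init: InitSpec = field(default_factory=InitSpec)
    mating: MatingSystem = field(default_factory=lambda: POLYGYNOUS)
    demography: DemographyParams = field(default_factory=DemographyParams)
    movement: MovementParams = field(default_factory=MovementParams)
    settlement: SettlementRule = field(default_factory=SettlementRule)
    years: int = 50
    replicates: int = 5
    master_seed: int = 0
    scenario_id: str = "default"

    def __post_init__(self) -> None:
        if self.init.core_rows > self.n_rows:
            raise ValueError("core_rows exceeds n_rows")
        if self.settlement.needs_mate and not self.mating.two_sex:
            raise ValueError(
                "mate-search settlement requires a two-sex mating system"
            )
        if self.years < 1 or self.replicates < 1:
            raise ValueError("years and replicates must be >= 1")

    def seed_for(self, replicate: int, stream: str) -> np.random.SeedSequence:
        """Independent substream for (scenario, replicate, stream)."""
        sc = zlib.crc32(self.scenario_id.encode()) & 0x7FFFFFFF
        st = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.SeedSequence([self.master_seed, sc, replicate, st])

    def landscape_seed(self, replicate: int) -> np.random.SeedSequence:
        # shared across scenarios: paired landscapes per replicate
        return np.random.SeedSequence([self.master_seed, _LANDSCAPE_TAG, replicate])


@dataclass
class SimResult:
    """Outputs of one replicate run."""

    config: SimConfig
    replicate: int
    landscape: GridLandscape
    range_series: pd.DataFrame  # year, edge_row, core_occupancy, extinct, n_total
    extinct: bool
    extinction_year: int | None
    dispersal: pd.DataFrame | None = None
    neighbourhoods: pd.DataFrame | None = None
    populations: pd.DataFrame | None = None


class _State:
    """Per-patch count state: adults[patch, sex, age-1] for ages 1..MAX_AGE."""

    __slots__ = ("adults", "year")

    def __init__(self, n_patches: int):
        self.adults = np.zeros((n_patches, 2, MAX_AGE), dtype=np.int64)
        self.year = 0

    @property
    def females(self) -> np.ndarray:
        return self.adults[:, 0, :].sum(axis=1)

    @property
    def males(self) -> np.ndarray:
        return self.adults[:, 1, :].sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.adults.sum())


def annual_cycle(
    state: _State,
    config: SimConfig,
    landscape: GridLandscape,
    rng_demog: np.random.Generator,
    rng_move: np.random.Generator,
    effcost: np.ndarray,
    record_dispersal: bool = False,
):
    """Advance the state by one year; returns (year_record, extras).

    ``year_record`` carries the per-patch reproduction census (adult females,
    unmated females) taken before dispersal, plus the dispersal outcome
    arrays when requested.  An empty (extinct) state only advances the year
    counter.
    """
    two_sex = config.mating.two_sex
    demo = config.demography
    extras: dict = {}
    f = state.females
    m = state.males
    n_repro, n_unmated = assign_reproduction(f, m, config.mating, rng_demog)
    jf, jm = produce_offspring(n_repro, demo, two_sex, rng_demog)
    # emigration: each juvenile independently leaves with fixed probability
    ef = rng_demog.binomial(jf, config.movement.emigration_prob)
    em = rng_demog.binomial(jm, config.movement.emigration_prob)
    stay_f = jf - ef
    stay_m = jm - em
    n_emig = int(ef.sum() + em.sum())
    settled_f = np.zeros_like(jf)
    settled_m = np.zeros_like(jm)
    if n_emig > 0:
        pids = np.arange(landscape.n_patches)
        natal = np.concatenate([np.repeat(pids, ef), np.repeat(pids, em)])
        sex = np.concatenate(
            [np.zeros(int(ef.sum()), np.int8), np.ones(int(em.sum()), np.int8)]
        )
        occ_f = (f + stay_f).astype(np.int64)
        occ_m = (m + stay_m).astype(np.int64)
        out = disperse_cohort(
            natal,
            sex,
            landscape,
            config.movement,
            config.settlement,
            occ_f,
            occ_m,
            demo.b,
            seed=int(rng_move.integers(2**31)),
            effcost=effcost,
        )
        ok = out["settle_patch"] >= 0
        settled_f = np.bincount(
            out["settle_patch"][ok & (sex == 0)], minlength=landscape.n_patches
        )
        settled_m = np.bincount(
            out["settle_patch"][ok & (sex == 1)], minlength=landscape.n_patches
        )
        # dispersal ledger: every emigrant either settled or died in transit
        n_transit_deaths = int((~ok).sum())
        assert int(settled_f.sum() + settled_m.sum()) + n_transit_deaths == n_emig
        if record_dispersal:
            extras["dispersal"] = {**out, "sex": sex}
    else:
        n_transit_deaths = 0
    start_count = state.total
    juveniles = np.stack([stay_f + settled_f, stay_m + settled_m], axis=1)
    pre_survival = start_count + int(juveniles.sum())
    state.adults = apply_survival_and_aging(state.adults, juveniles, demo, rng_demog)
    state.year += 1
    # yearly conservation: end = start + births - transit deaths - mortality
    # (survival Bernoulli losses and the max-age removals)
    births = int(jf.sum() + jm.sum())
    assert pre_survival == start_count + births - n_transit_deaths
    assert state.total <= pre_survival
    record = {
        "n_adult_f": f,
        "n_adult_m": m,
        "n_reproducing_f": n_repro,
        "n_unmated_f": n_unmated,
        "n_emigrants": n_emig,
    }
    return record, extras


def run_simulation(
    config: SimConfig,
    replicate: int,
    landscape: GridLandscape | None = None,
    record_dispersal: bool = False,
    record_neighbourhoods: bool = False,
    record_populations: bool = False,
) -> SimResult:
    """Run one replicate for ``config.years`` years or until extinction.

    The metapopulation is extinct once no patch holds a breeding population
    (for two-sex runs: at least one individual of each sex); extinction is
    absorbing because only newborn juveniles disperse.
    """
    if landscape is None:
        landscape = generate_landscape(
            config.n_cols,
            config.n_rows,
            config.habitat_fraction,
            np.random.default_rng(config.landscape_seed(replicate)),
        )
    rng_init = np.random.default_rng(config.seed_for(replicate, "init"))
    rng_demog = np.random.default_rng(config.seed_for(replicate, "demography"))
    rng_move = np.random.default_rng(config.seed_for(replicate, "movement"))
    effcost = effective_cost_grid(landscape, config.movement)
    two_sex = config.mating.two_sex
    patch_rows = landscape.patch_rows
    core = patch_rows < config.init.core_rows

    state = _State(landscape.n_patches)
    founders = sample_initial_population(landscape, config.init, two_sex, rng_init)
    state.adults[:, :, 0] = founders  # founders are age-1 adults

    series = []
    disp_frames = []
    nbhd_frames = []
    pop_frames = []

    def census(year: int) -> tuple[bool, dict]:
        fem = state.females
        mal = state.males
        breeding = metrics.breeding_patch(fem, mal, two_sex)
        extinct = not breeding.any()
        edge = metrics.range_edge(breeding, patch_rows) if not extinct else -1
        occ = float(breeding[core].sum() / core.sum())
        series.append(
            {
                "year": year,
                "edge_row": edge,
                "core_occupancy": occ,
                "extinct": extinct,
                "n_total": state.total,
            }
        )
        return extinct, {"breeding": breeding, "edge": edge}

    extinct, _ = census(0)
    extinction_year: int | None = 0 if extinct else None
    for year in range(1, config.years + 1):
        if extinct:
            break
        record, extras = annual_cycle(
            state,
            config,
            landscape,
            rng_demog,
            rng_move,
            effcost,
            record_dispersal=record_dispersal,
        )
        extinct, cinfo = census(year)
        if extinct and extinction_year is None:
            extinction_year = year
        if record_dispersal and "dispersal" in extras:
            d = extras["dispersal"]
            disp_frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "replicate": replicate,
                        "sex": np.where(d["sex"] == 0, "F", "M"),
                        "natal_row": d["natal_row"],
                        "fate": d["fate"],
                        "settle_patch": d["settle_patch"],
                        "settle_row": d["settle_row"],
                        "steps": d["steps"],
                        "rows_displaced": d["rows_displaced"],
                    }
                )
            )
        if record_neighbourhoods and not extinct:
            nb = metrics.neighbourhood_stats(
                cinfo["breeding"],
                patch_rows,
                record["n_adult_f"],
                record["n_unmated_f"],
                cinfo["edge"],
            )
            nb.insert(0, "replicate", replicate)
            nb.insert(0, "year", year)
            nbhd_frames.append(nb)
        if record_populations:
            occ_mask = (record["n_adult_f"] > 0) | (record["n_adult_m"] > 0)
            pop_frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "replicate": replicate,
                        "patch_id": np.nonzero(occ_mask)[0],
                        "row": patch_rows[occ_mask],
                        "n_adult_f": record["n_adult_f"][occ_mask],
                        "n_adult_m": record["n_adult_m"][occ_mask],
                        "n_reproducing_f": record["n_reproducing_f"][occ_mask],
                        "n_unmated_f": record["n_unmated_f"][occ_mask],
                    }
                )
            )
    range_series = pd.DataFrame(series)
    return SimResult(
        config=config,
        replicate=replicate,
        landscape=landscape,
        range_series=range_series,
        extinct=bool(range_series["extinct"].iloc[-1]),
        extinction_year=extinction_year,
        dispersal=pd.concat(disp_frames, ignore_index=True) if disp_frames else None,
        neighbourhoods=pd.concat(nbhd_frames, ignore_index=True)
        if nbhd_frames
        else None,
        populations=pd.concat(pop_frames, ignore_index=True) if pop_frames else None,
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """A fully factorial scenario grid plus shared run settings."""

    name: str
    scenarios: tuple  # of dicts: mating_system, habitat_quality, fecundity, strategy
    years: int
    replicates: int
    n_rows: int = 1000
    n_cols: int = 20
    habitat_fraction: float = 0.07
    core_rows: int | None = None  # default: n_rows // 2
    spread_horizon: int | None = None  # default: years

    def config_for(self, scenario: dict, master_seed: int) -> SimConfig:
        hq = scenario["habitat_quality"]
        rule = SettlementRule(strategy=scenario.get("strategy", "habitat_only"))
        sid = "{}|{}|hq{}|f{}|{}".format(
            self.name,
            scenario["mating_system"],
            hq,
            scenario["fecundity"],
            rule.strategy,
        )
        return SimConfig(
            n_cols=self.n_cols,
            n_rows=self.n_rows,
            habitat_fraction=self.habitat_fraction,
            init=InitSpec(core_rows=self.core_rows or self.n_rows // 2),
            mating=_MATING[scenario["mating_system"]],
            demography=DemographyParams(
                fecundity=float(scenario["fecundity"]), b=1.0 / hq
            ),
            settlement=rule,
            years=self.years,
            replicates=self.replicates,
            master_seed=master_seed,
            scenario_id=sid,
        )


def experiment1_design(
    years: int = 50,
    replicates: int = 5,
    n_rows: int = 1000,
    habitat_qualities=(2, 4, 6, 8, 10, 12, 14),
    fecundities=(2.0, 3.0, 4.0),
) -> ExperimentDesign:
    """Mating system x habitat quality x fecundity, habitat-only settlement."""
    scenarios = tuple(
        {
            "mating_system": ms,
            "habitat_quality": hq,
            "fecundity": fec,
            "strategy": "habitat_only",
        }
        for ms in ("female_only", "polygynous", "monogamous")
        for hq in habitat_qualities
        for fec in fecundities
    )
    return ExperimentDesign(
        name="exp1", scenarios=scenarios, years=years, replicates=replicates,
        n_rows=n_rows,
    )


def experiment2_design(
    years: int = 50,
    replicates: int = 5,
    n_rows: int = 1000,
    habitat_qualities=(8, 10, 12, 14),
    fecundity: float = 3.0,
    mating_systems=("polygynous", "monogamous"),
    strategies=("habitat_only", "mate_search", "density_dependent", "mate_search_and_dd"),
) -> ExperimentDesign:
    """Two-sex mating system x settlement strategy x habitat quality."""
    scenarios = tuple(
        {
            "mating_system": ms,
            "habitat_quality": hq,
            "fecundity": fecundity,
            "strategy": st,
        }
        for ms in mating_systems
        for st in strategies
        for hq in habitat_qualities
    )
    return ExperimentDesign(
        name="exp2",
        scenarios=scenarios,
        years=years,
        replicates=replicates,
        n_rows=n_rows,
        spread_horizon=min(30, years),
    )


def _run_cell(design, scenario, rep, master_seed, landscape_cache):
    config = design.config_for(scenario, master_seed)
    key = rep
    if key not in landscape_cache:
        landscape_cache[key] = generate_landscape(
            config.n_cols,
            config.n_rows,
            config.habitat_fraction,
            np.random.default_rng(config.landscape_seed(rep)),
        )
    result = run_simulation(config, rep, landscape=landscape_cache[key])
    horizon = design.spread_horizon or design.years
    edges = result.range_series.set_index("year")["edge_row"]
    extinct_flags = result.range_series.set_index("year")["extinct"]
    windows = metrics.spread_windows(edges, horizon_years=horizon, extinct=extinct_flags)
    rate = float(np.mean(windows)) if windows else float("nan")
    occ = result.range_series["core_occupancy"]
    qe = metrics.quasi_equilibrium(
        occ, y_from=min(20, design.years // 2), y_to=design.years,
        extinct=result.extinct,
    )
    final_occ = 0.0 if result.extinct else float(occ.iloc[-1])
    return {
        "experiment": design.name,
        "mating_system": scenario["mating_system"],
        "habitat_quality": scenario["habitat_quality"],
        "fecundity": scenario["fecundity"],
        "strategy": scenario.get("strategy", "habitat_only"),
        "replicate": rep,
        "core_occupancy": final_occ,
        "quasi_equilibrium": qe,
        "spread_rate": rate,
        "window_rates": ";".join(f"{r:g}" for r in windows),
        "extinct": result.extinct,
        "extinction_year": result.extinction_year
        if result.extinction_year is not None
        else -1,
    }


def run_experiment(
    design: ExperimentDesign,
    master_seed: int,
    out_dir=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario x replicate cell; returns the tidy response table.

    With ``out_dir`` set, each completed cell is written to
    ``out_dir/cells/<scenario>_<rep>.csv`` and valid rows found there are
    reused instead of re-running (corrupt files trigger a re-run).
    """
    import sys
    from pathlib import Path

    cells_dir = None
    if out_dir is not None:
        cells_dir = Path(out_dir) / "cells"
        cells_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    landscape_cache: dict = {}
    for si, scenario in enumerate(design.scenarios):
        for rep in range(design.replicates):
            tag = "{}_{}_hq{}_f{}_{}_r{}".format(
                design.name,
                scenario["mating_system"],
                scenario["habitat_quality"],
                scenario["fecundity"],
                scenario.get("strategy", "habitat_only"),
                rep,
            )
            cell_path = cells_dir / f"{tag}.csv" if cells_dir else None
            if cell_path is not None and cell_path.exists():
                try:
                    cached = pd.read_csv(cell_path)
                    required = {"mating_system", "replicate", "core_occupancy",
                                "spread_rate", "extinct"}
                    if len(cached) != 1 or not required.issubset(cached.columns):
                        raise ValueError("incomplete cell row")
                    row = cached.iloc[0].to_dict()
                    rows.append(row)
                    continue
                except Exception:
                    print(f"warning: re-running corrupt cell {tag}", file=sys.stderr)
            row = _run_cell(design, scenario, rep, master_seed, landscape_cache)
            rows.append(row)
            if cell_path is not None:
                pd.DataFrame([row]).to_csv(cell_path, index=False)
            if progress:
                print(
                    f"[{si + 1}/{len(design.scenarios)}] {tag}: "
                    f"rate={row['spread_rate']:.2f} occ={row['core_occupancy']:.2f} "
                    f"extinct={row['extinct']}",
                    file=sys.stderr,
                )
    if not rows:
        return pd.DataFrame(
            columns=[
                "experiment", "mating_system", "habitat_quality", "fecundity",
                "strategy", "replicate", "core_occupancy", "quasi_equilibrium",
                "spread_rate", "window_rates", "extinct", "extinction_year",
            ]
        )
    table = pd.DataFrame(rows)
    table["window_rates"] = table["window_rates"].astype(str)
    return table
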