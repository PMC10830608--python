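"""Parameter files, raster/CSV readers-writers, and test fixtures.

The native configuration format is a plain INI-style text file whose
sections mirror the model components::

    [landscape]
    n_cols = 20
    n_rows = 1000
    habitat_fraction = 0.07

    [demography]
    habitat_quality = 10    ; 1/b, females/patch -- must be supplied
    fecundity = 3.0

    [mating]
    system = polygynous     ; female_only | polygynous | monogamous

    [movement]
    emigration_prob = 0.5

    [settlement]
    strategy = habitat_only

    [simulation]
    years = 50
    replicates = 5
    master_seed = 1

Any omitted key falls back to the model's standard constant; unknown keys
are rejected so typos cannot silently revert a parameter to its default.
Landscapes serialize as ESRI-ASCII integer rasters (0 = matrix, 1 = habitat,
plus a patch-id raster), founders as CSV.
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import DemographyParams, MatingSystem
from .dispersal import MovementParams, SettlementRule
from .engine import SimConfig
from .landscape import GridLandscape, InitSpec

__all__ = [
    "load_config",
    "save_config",
    "config_echo",
    "write_ascii_raster",
    "read_ascii_raster",
    "write_landscape",
    "read_landscape",
    "landscape_from_mask",
    "make_fixture",
    "FIXTURES",
]

_SCHEMA = {
    "landscape": {"n_cols": int, "n_rows": int, "habitat_fraction": float,
                  "cell_size": float},
    "init": {"core_rows": int, "init_fraction_of_habitat": float,
             "lambda_init": float, "lambda_is_rate": bool},
    "demography": {"habitat_quality": float, "fecundity": float,
                   "sigma0_adult": float, "sigma0_juvenile": float,
                   "sex_ratio_at_birth": float, "fecundity_doubling_two_sex": bool},
    "mating": {"system": str, "harem_size": int},
    "movement": {"emigration_prob": float, "perceptual_range": int,
                 "directional_persistence": float, "step_mortality": float,
                 "cost_habitat": float, "cost_matrix": float,
                 "pr_aggregation": str, "max_ticks": int},
    "settlement": {"strategy": str, "beta_s": float, "alpha_s": float,
                   "density_measure": str},
    "simulation": {"years": int, "replicates": int, "master_seed": int,
                   "scenario_id": str},
}

_MATING_SYSTEMS = {
    "female_only": ("female_only", 100),
    "polygynous": ("two_sex", 100),
    "monogamous": ("two_sex", 1),
}


def _parse(parser: configparser.ConfigParser) -> dict:
    values: dict = {}
    for section in parser.sections():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        values[section] = {}
        for key, raw in parser[section].items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            typ = _SCHEMA[section][key]
            try:
                if typ is bool:
                    values[section][key] = raw.strip().lower() in ("1", "true", "yes", "on")
                else:
                    values[section][key] = typ(raw)
            except ValueError as exc:
                raise ValueError(f"bad value for {section}.{key}: {raw!r}") from exc
    return values


def load_config(path) -> SimConfig:
    """Parse and validate a parameter file into a `SimConfig`.

    Habitat quality (1/b) has no universal default and must be supplied;
    everything else falls back to the standard constants.
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    v = _parse(parser)
    demo = dict(v.get("demography", {}))
    if "habitat_quality" not in demo:
        raise ValueError("demography.habitat_quality (1/b) must be supplied")
    hq = demo.pop("habitat_quality")
    if hq <= 0:
        raise ValueError("demography.habitat_quality must be positive")
    mating_in = v.get("mating", {})
    system = mating_in.get("system", "polygynous")
    if system not in _MATING_SYSTEMS:
        raise ValueError(
            f"mating.system must be one of {sorted(_MATING_SYSTEMS)}, got {system!r}"
        )
    mode, default_h = _MATING_SYSTEMS[system]
    harem = mating_in.get("harem_size", default_h)
    land = v.get("landscape", {})
    sim = v.get("simulation", {})
    n_rows = land.get("n_rows", 1000)
    init_in = dict(v.get("init", {}))
    init_in.setdefault("core_rows", n_rows // 2)
    try:
        return SimConfig(
            n_cols=land.get("n_cols", 20),
            n_rows=n_rows,
            habitat_fraction=land.get("habitat_fraction", 0.07),
            init=InitSpec(**init_in),
            mating=MatingSystem(mode=mode, harem_size=harem),
            demography=DemographyParams(b=1.0 / hq, **demo),
            movement=MovementParams(**v.get("movement", {})),
            settlement=SettlementRule(**v.get("settlement", {})),
            years=sim.get("years", 50),
            replicates=sim.get("replicates", 5),
            master_seed=sim.get("master_seed", 0),
            scenario_id=sim.get("scenario_id", "default"),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def config_echo(config: SimConfig) -> str:
    """Every resolved parameter, exactly once, as config-file text."""
    parser = configparser.ConfigParser()
    parser["landscape"] = {
        "n_cols": config.n_cols,
        "n_rows": config.n_rows,
        "habitat_fraction": config.habitat_fraction,
    }
    parser["init"] = {
        "core_rows": config.init.core_rows,
        "init_fraction_of_habitat": config.init.init_fraction_of_habitat,
        "lambda_init": config.init.lambda_init,
        "lambda_is_rate": config.init.lambda_is_rate,
    }
    parser["demography"] = {
        "habitat_quality": config.demography.habitat_quality,
        "fecundity": config.demography.fecundity,
        "sigma0_adult": config.demography.sigma0_adult,
        "sigma0_juvenile": config.demography.sigma0_juvenile,
        "sex_ratio_at_birth": config.demography.sex_ratio_at_birth,
        "fecundity_doubling_two_sex": config.demography.fecundity_doubling_two_sex,
    }
    parser["mating"] = {
        "system": config.mating.label,
        "harem_size": config.mating.harem_size,
    }
    parser["movement"] = {
        "emigration_prob": config.movement.emigration_prob,
        "perceptual_range": config.movement.perceptual_range,
        "directional_persistence": config.movement.directional_persistence,
        "step_mortality": config.movement.step_mortality,
        "cost_habitat": config.movement.cost_habitat,
        "cost_matrix": config.movement.cost_matrix,
        "pr_aggregation": config.movement.pr_aggregation,
        "max_ticks": config.movement.max_ticks,
    }
    parser["settlement"] = {
        "strategy": config.settlement.strategy,
        "beta_s": config.settlement.beta_s,
        "alpha_s": config.settlement.alpha_s,
        "density_measure": config.settlement.density_measure,
    }
    parser["simulation"] = {
        "years": config.years,
        "replicates": config.replicates,
        "master_seed": config.master_seed,
        "scenario_id": config.scenario_id,
    }
    buf = _io.StringIO()
    parser.write(buf)
    return buf.getvalue()


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(config_echo(config))


def write_ascii_raster(path, grid: np.ndarray, cell_size: float = 100.0,
                       nodata: int = -9999) -> None:
    """ESRI-ASCII integer raster (ncols/nrows/xllcorner/.../NODATA header)."""
    grid = np.asarray(grid)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(str(int(x)) for x in row) for row in grid)
    Path(path).write_text(header + body + "\n")


def read_ascii_raster(path) -> tuple[np.ndarray, float, int]:
    lines = Path(path).read_text().splitlines()
    meta = {}
    for ln in lines[:6]:
        k, v = ln.split(maxsplit=1)
        meta[k.lower()] = float(v)
    grid = np.array(
        [[int(x) for x in ln.split()] for ln in lines[6:] if ln.strip()],
        dtype=np.int64,
    )
    assert grid.shape == (int(meta["nrows"]), int(meta["ncols"]))
    return grid, meta["cellsize"], int(meta["nodata_value"])


def write_landscape(out_dir, landscape: GridLandscape) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_raster(out / "landscape.asc", landscape.habitat_mask.astype(int),
                       landscape.cell_size)
    write_ascii_raster(out / "patches.asc", landscape.patch_id, landscape.cell_size)


def read_landscape(in_dir) -> GridLandscape:
    in_dir = Path(in_dir)
    mask, cell_size, _ = read_ascii_raster(in_dir / "landscape.asc")
    pid, _, _ = read_ascii_raster(in_dir / "patches.asc")
    return GridLandscape(
        n_cols=mask.shape[1],
        n_rows=mask.shape[0],
        habitat_mask=mask.astype(bool),
        patch_id=pid.astype(np.int32),
        cell_size=cell_size,
    )


def write_founders(path, landscape: GridLandscape, founders: np.ndarray) -> None:
    """founders.csv: patch_id,row,col,sex,age,count (populated patches only)."""
    rows = []
    pr, pc = landscape.patch_rows, landscape.patch_cols
    for pid in np.nonzero(founders.sum(axis=1))[0]:
        for sex, label in ((0, "F"), (1, "M")):
            if founders[pid, sex] > 0:
                rows.append(
                    {"patch_id": pid, "row": pr[pid], "col": pc[pid],
                     "sex": label, "age": 1, "count": founders[pid, sex]}
                )
    pd.DataFrame(rows, columns=["patch_id", "row", "col", "sex", "age", "count"]).to_csv(
        path, index=False
    )


def landscape_from_mask(mask: np.ndarray, cell_size: float = 100.0) -> GridLandscape:
    """Build a landscape from an explicit habitat mask (row-major patch ids)."""
    mask = np.asarray(mask, dtype=bool)
    pid = np.full(mask.shape, -1, dtype=np.int32)
    pid[mask] = np.arange(int(mask.sum()), dtype=np.int32)
    return GridLandscape(
        n_cols=mask.shape[1], n_rows=mask.shape[0], habitat_mask=mask,
        patch_id=pid, cell_size=cell_size,
    )


def _fixture_two_patch_pair():
    """One adult female and one adult male in adjacent patches, 20x5 grid."""
    mask = np.zeros((20, 5), dtype=bool)
    cells = [(3, 2), (5, 2), (9, 1), (9, 3), (14, 2), (17, 2)]
    for r, c in cells:
        mask[r, c] = True
    land = landscape_from_mask(mask)
    occupants = np.zeros((land.n_patches, 2), dtype=np.int64)
    occupants[0, 0] = 1  # female in patch 0 (row 3)
    occupants[1, 1] = 1  # male in patch 1 (row 5)
    return {"landscape": land, "occupants": occupants}


def _fixture_edge_ladder():
    """Breeding patches at known rows for exact range-edge checks."""
    mask = np.zeros((30, 5), dtype=bool)
    rows = [2, 7, 12, 19, 26]
    for i, r in enumerate(rows):
        mask[r, i % 5] = True
    land = landscape_from_mask(mask)
    breeding = np.array([True, True, False, True, False])
    return {"landscape": land, "breeding": breeding, "expected_edge": 19}


def _fixture_strip_costs():
    """A single-column strip whose costs are (1,10,10,10,10) going north."""
    mask = np.zeros((10, 1), dtype=bool)
    mask[2, 0] = True  # habitat cell; the rest is matrix
    land = landscape_from_mask(mask)
    return {"landscape": land, "expected_mean_cost": 8.2, "cell": (2, 0)}


FIXTURES = {
    "two_patch_pair": _fixture_two_patch_pair,
    "edge_ladder": _fixture_edge_ladder,
    "strip_costs": _fixture_strip_costs,
}


def make_fixture(name: str) -> dict:
    """Deterministic miniature worlds for unit tests."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
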