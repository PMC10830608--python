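"""Corridor landscape generation and founder populations.

The model world is a long, narrow grid of 100 m cells (default 20 columns x
1000 rows) with hard, non-periodic borders.  A fixed fraction of cells
(default 7%) is suitable breeding habitat; every suitable cell is its own
single-cell habitat patch, and the remaining cells form an unsuitable matrix
through which dispersers can move but never settle.

Founder populations occupy half of the habitat cells in the "core" (the first
``core_rows`` rows); the number of founders of each sex in each populated
patch is a zero-truncated Poisson draw.  Range expansion then proceeds toward
increasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GridLandscape",
    "InitSpec",
    "generate_landscape",
    "ztpois_mean",
    "ztpois_rate_for_mean",
    "ztpois_sample",
    "sample_initial_population",
]


@dataclass(frozen=True)
class GridLandscape:
    """A corridor raster of single-cell habitat patches in a hostile matrix.

    Attributes
    ----------
    n_cols, n_rows : int
        Grid dimensions.  Rows index the corridor's long axis; row 0 is the
        populated (core) end and expansion proceeds toward higher rows.
    cell_size : float
        Cell edge length in metres (1 row = ``cell_size`` metres).
    habitat_mask : ndarray of bool, shape (n_rows, n_cols)
        True where the cell is suitable breeding habitat.
    patch_id : ndarray of int32, shape (n_rows, n_cols)
        Unique id (0..n_patches-1) for every habitat cell; -1 in the matrix.
    """

    n_cols: int
    n_rows: int
    habitat_mask: np.ndarray
    patch_id: np.ndarray
    cell_size: float = 100.0
    seed: int | None = None

    @property
    def n_patches(self) -> int:
        return int(self.habitat_mask.sum())

    @property
    def patch_rows(self) -> np.ndarray:
        """Row index of each patch, ordered by patch id."""
        rows, cols = np.nonzero(self.habitat_mask)
        order = np.argsort(self.patch_id[rows, cols])
        return rows[order].astype(np.int64)

    @property
    def patch_cols(self) -> np.ndarray:
        rows, cols = np.nonzero(self.habitat_mask)
        order = np.argsort(self.patch_id[rows, cols])
        return cols[order].astype(np.int64)


@dataclass(frozen=True)
class InitSpec:
    """How founder populations are placed.

    ``lambda_init`` is by default the rate parameter of the Poisson before
    zero truncation (so the realized mean is lambda / (1 - e^-lambda)); set
    ``lambda_is_rate=False`` to interpret it as the target post-truncation
    mean instead.
    """

    core_rows: int = 500
    init_fraction_of_habitat: float = 0.5
    lambda_init: float = 2.0
    sexes_independent: bool = True
    lambda_is_rate: bool = True

    def rate(self) -> float:
        if self.lambda_is_rate:
            return self.lambda_init
        return ztpois_rate_for_mean(self.lambda_init)


def generate_landscape(
    n_cols: int,
    n_rows: int,
    habitat_fraction: float,
    seed: int | np.random.Generator | None = None,
) -> GridLandscape:
    """Place exactly ``round(habitat_fraction * n_cells)`` habitat cells.

    Cells are chosen uniformly at random without replacement, so replicate
    landscapes differ only in the configuration, never the amount, of
    habitat.  Each habitat cell receives a distinct patch id (assigned in
    row-major order).
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError(f"grid dimensions must be positive, got {n_cols}x{n_rows}")
    if not 0.0 < habitat_fraction < 1.0:
        raise ValueError(
            f"habitat_fraction must lie strictly in (0, 1), got {habitat_fraction}"
        )
    rng = np.random.default_rng(seed)
    n_cells = n_cols * n_rows
    n_habitat = int(round(habitat_fraction * n_cells))
    if n_habitat < 1:
        raise ValueError("habitat_fraction too small: zero habitat cells")
    flat = rng.choice(n_cells, size=n_habitat, replace=False)
    mask = np.zeros(n_cells, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n_rows, n_cols)
    pid = np.full((n_rows, n_cols), -1, dtype=np.int32)
    pid[mask] = np.arange(n_habitat, dtype=np.int32)
    return GridLandscape(
        n_cols=n_cols,
        n_rows=n_rows,
        habitat_mask=mask,
        patch_id=pid,
        seed=seed if isinstance(seed, int) else None,
    )


def ztpois_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lambda / (1 - e^-lambda)."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    return lam / -np.expm1(-lam)


def ztpois_rate_for_mean(mean: float) -> float:
    """Invert `ztpois_mean`: the rate whose truncated distribution has `mean`."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    return float(optimize.brentq(lambda l: ztpois_mean(l) - mean, 1e-9, 10 * mean))


def ztpois_sample(
    lam: float,
    rng: np.random.Generator,
    size: int | tuple[int, ...] | None = None,
) -> np.ndarray | int:
    """Draw from the zero-truncated Poisson, P(k) ∝ lam^k / k! for k >= 1.

    Uses exact inverse-CDF sampling through the untruncated Poisson quantile
    function, so the support is {1, 2, ...} for any positive rate.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    p0 = np.exp(-lam)
    u = rng.uniform(size=size)
    k = stats.poisson.ppf(p0 + u * (1.0 - p0), lam)
    k = np.maximum(k, 1.0)  # guard the u -> 0 float edge
    if size is None:
        return int(k)
    return k.astype(np.int64)


def sample_initial_population(
    landscape: GridLandscape,
    spec: InitSpec,
    two_sex: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample founder counts per patch.

    Exactly ``floor(init_fraction * n_core_patches)`` habitat patches inside
    the core rows are populated (chosen uniformly without replacement).  Each
    populated patch receives one zero-truncated Poisson draw per sex (two-sex
    mode) or a single female draw (female-only mode).  Founders are adults of
    age 1.

    Returns
    -------
    ndarray of int64, shape (n_patches, 2)
        Column 0 = founding females, column 1 = founding males, indexed by
        patch id.  Male column is all zero in female-only mode.
    """
    if spec.core_rows > landscape.n_rows:
        raise ValueError(
            f"core_rows ({spec.core_rows}) exceeds landscape rows ({landscape.n_rows})"
        )
    rows = landscape.patch_rows
    core_pids = np.nonzero(rows < spec.core_rows)[0]
    n_init = int(spec.init_fraction_of_habitat * core_pids.size)
    chosen = rng.choice(core_pids, size=n_init, replace=False)
    lam = spec.rate()
    counts = np.zeros((landscape.n_patches, 2), dtype=np.int64)
    counts[chosen, 0] = ztpois_sample(lam, rng, size=n_init)
    if two_sex:
        counts[chosen, 1] = ztpois_sample(lam, rng, size=n_init)
    return counts
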