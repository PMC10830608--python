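"""Compiled inner loop for the stepwise movement simulator.

One global tick advances every still-moving disperser by one step in a
freshly shuffled order; settlement is evaluated immediately after each move
against occupancy updated within the tick.  Strategy codes match the order
of `matewave.dispersal.STRATEGIES`:

    0 habitat_only, 1 mate_search, 2 density_dependent, 3 mate_search_and_dd.

The kernel keeps its own numba RNG stream, seeded per cohort call, so cohort
results are reproducible independent of surrounding numpy Generator state.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def run_cohort(
    seed,
    patch_grid,  # (R, C) int32, patch id or -1 in matrix
    effcost,  # (R, C, 8) float64
    dr8,
    dc8,  # direction offsets, int64[8]
    dpw,  # DP^-turn weights, float64[5]
    natal_row,
    natal_col,
    natal_patch,
    sex,  # int8, 0 female / 1 male
    pf,
    pm,  # per-patch occupant counts, int64; updated in place
    pdens,  # per-patch count entering the settlement logistic; updated too
    dens_all,  # 1: settlers of both sexes increment pdens, 0: females only
    strategy,
    b,
    beta_s,
    alpha_s,
    step_mort,
    max_ticks,
):
    np.random.seed(seed)
    n = natal_row.size
    R, C = patch_grid.shape
    row = natal_row.copy()
    col = natal_col.copy()
    heading = np.full(n, -1, np.int64)
    steps = np.zeros(n, np.int64)
    status = np.zeros(n, np.int8)  # 0 moving, 1 settled, 2 dead
    settle_patch = np.full(n, -1, np.int64)
    had_mate = np.zeros(n, np.uint8)  # failed a density draw with mate present
    active = np.arange(n)
    n_active = n
    n_patches = pf.size
    tmpf = np.zeros(n_patches, np.int64)
    tmpm = np.zeros(n_patches, np.int64)
    touched = np.empty(n, np.int64)
    w = np.empty(8, np.float64)
    needs_mate = strategy == 1 or strategy == 3
    tick = 0
    while n_active > 0 and tick < max_ticks:
        tick += 1
        # compact the active list, then Fisher-Yates shuffle it
        na = 0
        for k in range(n_active):
            i = active[k]
            if status[i] == 0:
                active[na] = i
                na += 1
        n_active = na
        for k in range(na - 1, 0, -1):
            j = np.random.randint(0, k + 1)
            t = active[k]
            active[k] = active[j]
            active[j] = t
        for k in range(na):
            i = active[k]
            had_mate[i] = 0
            if np.random.random() < step_mort:
                status[i] = 2
                continue
            r = row[i]
            c = col[i]
            h = heading[i]
            tot = 0.0
            for d in range(8):
                nr = r + dr8[d]
                nc = c + dc8[d]
                if nr < 0 or nr >= R or nc < 0 or nc >= C:
                    w[d] = 0.0
                    continue
                if h < 0:
                    dwt = 1.0
                else:
                    t8 = d - h
                    if t8 < 0:
                        t8 = -t8
                    if t8 > 4:
                        t8 = 8 - t8
                    dwt = dpw[t8]
                w[d] = dwt / effcost[nr, nc, d]
                tot += w[d]
            if tot <= 0.0:  # no legal neighbour (degenerate 1-cell grid)
                status[i] = 2
                continue
            u = np.random.random() * tot
            acc = 0.0
            d = 7
            for dd in range(8):
                acc += w[dd]
                if u < acc:
                    d = dd
                    break
            row[i] = r + dr8[d]
            col[i] = c + dc8[d]
            heading[i] = d
            steps[i] += 1
            p = patch_grid[row[i], col[i]]
            if p >= 0 and p != natal_patch[i]:
                settle = False
                if strategy == 0:
                    settle = True
                elif strategy == 1:
                    if sex[i] == 0:
                        settle = pm[p] > 0
                    else:
                        settle = pf[p] > 0
                elif strategy == 2:
                    ps = 1.0 / (1.0 + np.exp(-(b * pdens[p] - beta_s) * alpha_s))
                    settle = np.random.random() < ps
                else:
                    mate = pm[p] > 0 if sex[i] == 0 else pf[p] > 0
                    if mate:
                        ps = 1.0 / (1.0 + np.exp(-(b * pdens[p] - beta_s) * alpha_s))
                        if np.random.random() < ps:
                            settle = True
                        else:
                            had_mate[i] = 1
                if settle:
                    status[i] = 1
                    settle_patch[i] = p
                    if sex[i] == 0:
                        pf[p] += 1
                    else:
                        pm[p] += 1
                    if dens_all == 1 or sex[i] == 0:
                        pdens[p] += 1
        if needs_mate:
            # simultaneous-arrival rule: a patch holding unsettled dispersers
            # of both sexes at tick end settles them together
            nt = 0
            for i in active[:na]:
                if status[i] != 0:
                    continue
                p = patch_grid[row[i], col[i]]
                if p >= 0 and p != natal_patch[i]:
                    if tmpf[p] == 0 and tmpm[p] == 0:
                        touched[nt] = p
                        nt += 1
                    if sex[i] == 0:
                        tmpf[p] += 1
                    else:
                        tmpm[p] += 1
            if nt > 0:
                for i in active[:na]:
                    if status[i] != 0:
                        continue
                    p = patch_grid[row[i], col[i]]
                    if p < 0 or p == natal_patch[i]:
                        continue
                    if tmpf[p] >= 1 and tmpm[p] >= 1:
                        ok = True
                        if strategy == 3:
                            if had_mate[i] == 1:
                                ok = False  # already failed this tick's density draw
                            else:
                                ps = 1.0 / (
                                    1.0 + np.exp(-(b * pdens[p] - beta_s) * alpha_s)
                                )
                                ok = np.random.random() < ps
                        if ok:
                            status[i] = 1
                            settle_patch[i] = p
                            if sex[i] == 0:
                                pf[p] += 1
                            else:
                                pm[p] += 1
                            if dens_all == 1 or sex[i] == 0:
                                pdens[p] += 1
                for k in range(nt):
                    tmpf[touched[k]] = 0
                    tmpm[touched[k]] = 0
        # n_active is the candidate-list length; compaction happens at the
        # top of the next tick.  Drop to 0 only when nobody is still moving.
        n_active = 0
        for k in range(na):
            if status[active[k]] == 0:
                n_active = na
                break
    return status, settle_patch, steps, row, tick
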