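"""Numba-compiled grid engine.

The whole-world timestep is the hot path of the simulator, so it is
implemented here as ``@njit`` kernels over flat preallocated arrays:
per-site genome rows (``codes``/``phis`` with a length column), cached
census/fitness columns, and a flat fragment store for the eDNA pool.
The semantics mirror the reference operators in :mod:`tecoevo.genome`,
:mod:`tecoevo.mutation`, :mod:`tecoevo.transposition` and
:mod:`tecoevo.edna`; consistency between the two layers is covered by
tests.

All randomness uses numba's internal ``np.random`` state, seeded once per
world through :func:`seed_rng`, which makes a run fully deterministic for
a given seed (single-threaded).

Parameter vector layout (``P``, float64) — see index constants below.
Per-step lineage events (deaths with lysed-TE counts, births, new
infections) are written to caller-provided buffers so the Python layer
can do lineage bookkeeping without touching the hot loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NONCODING = 0
TE_CODE = 127

# indices into the parameter vector P
P_D = 0          # baseline death probability d
P_U = 1          # fragment uptake probability u
P_J = 2          # transposition opportunity rate j
P_DIFF = 3       # fragment diffusion probability D
P_Q = 4          # fragment degradation probability q
P_B = 5          # insertion damage probability b
P_C = 6          # per-TE fitness penalty c
P_EPS = 7        # competition regulariser epsilon
P_NFUNC = 8      # number of essential functions
P_SDUP = 9       # single duplication rate
P_SDEL = 10      # single deletion rate
P_INACT = 11     # inactivation rate
P_LARGE = 12     # large-scale event rate
P_PHIMUT = 13    # phi-mutation probability per TE replication
P_PHISTEP = 14   # phi-mutation step size
P_MODE = 15      # 0 spatial, 1 mixed_cells, 2 mixed_edna
P_REPRO = 16     # 0 asexual_hgt, 1 sexual, 2 clonal
NPARAMS = 17

MODE_SPATIAL = 0
MODE_MIXED_CELLS = 1
MODE_MIXED_EDNA = 2
REPRO_ASEXUAL = 0
REPRO_SEXUAL = 1
REPRO_CLONAL = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _clamp01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def _offer_phi_mut(phi, P):
    """One phi-mutation offer: +-phi_step with prob phi_mut, clamped."""
    if P[P_PHIMUT] > 0.0 and np.random.random() < P[P_PHIMUT]:
        if np.random.random() < 0.5:
            phi = phi + P[P_PHISTEP]
        else:
            phi = phi - P[P_PHISTEP]
        return _clamp01(phi)
    return phi


@njit(cache=True)
def refresh_cell(i, codes, phis, glen, P, fitness, viable, te_cnt, ess_cnt, nc_cnt, phi_sum):
    """Recompute the cached census, viability and fitness of cell ``i``."""
    nf = int(P[P_NFUNC])
    present = np.int64(0)
    te = 0
    nc = 0
    ps = 0.0
    for k in range(glen[i]):
        c = codes[i, k]
        if c == NONCODING:
            nc += 1
        elif c == TE_CODE:
            te += 1
            ps += phis[i, k]
        else:
            present |= np.int64(1) << np.int64(c - 1)
    te_cnt[i] = te
    nc_cnt[i] = nc
    ess_cnt[i] = glen[i] - te - nc
    phi_sum[i] = ps
    ok = present == (np.int64(1) << np.int64(nf)) - np.int64(1)
    viable[i] = ok
    if ok:
        f = 1.0 - P[P_C] * te
        fitness[i] = f if f > 0.0 else 0.0
    else:
        fitness[i] = 0.0


@njit(cache=True)
def refresh_all(occ, codes, phis, glen, P, fitness, viable, te_cnt, ess_cnt, nc_cnt, phi_sum):
    for i in range(occ.shape[0]):
        if occ[i]:
            refresh_cell(i, codes, phis, glen, P, fitness, viable, te_cnt,
                         ess_cnt, nc_cnt, phi_sum)


@njit(cache=True)
def _insert_te_row(i, pos, phi, b, codes, phis, glen):
    """Insert a TE copy into cell ``i`` at ``pos`` with damage prob ``b``.

    Mirrors the reference ``insert_te``: length +1, displaced coding
    element inactivated with probability ``b``.  Returns False if the
    genome row is at capacity (the event is skipped).
    """
    lmax = codes.shape[1]
    L = glen[i]
    if L + 1 > lmax:
        return False
    for k in range(L - 1, pos - 1, -1):
        codes[i, k + 1] = codes[i, k]
        phis[i, k + 1] = phis[i, k]
    codes[i, pos] = TE_CODE
    phis[i, pos] = phi
    glen[i] = L + 1
    if pos < L:
        target = codes[i, pos + 1]
        if target != NONCODING:
            if b >= 1.0 or np.random.random() < b:
                codes[i, pos + 1] = NONCODING
                phis[i, pos + 1] = 0.0
    return True


@njit(cache=True)
def _lyse_cell(i, site, codes, phis, glen,
               f_site, f_len, f_codes, f_phis, f_te, f_count, f_dropped):
    """Fragment cell ``i``'s genome into the pool at ``site``.

    Cut lengths iid uniform on [3, 8] left to right; the terminal
    remainder (possibly < 3) is kept.  Returns the number of TEs lysed
    into the pool.
    """
    L = glen[i]
    start = 0
    te_out = 0
    while start < L:
        cut = 3 + np.random.randint(0, 6)
        if cut > L - start:
            cut = L - start
        k = f_count[0]
        if k < f_site.shape[0]:
            f_site[k] = site
            f_len[k] = cut
            nte = 0
            for e in range(cut):
                f_codes[k, e] = codes[i, start + e]
                f_phis[k, e] = phis[i, start + e]
                if codes[i, start + e] == TE_CODE:
                    nte += 1
            f_te[k] = nte
            te_out += nte
            f_count[0] = k + 1
        else:
            f_dropped[0] += 1
            for e in range(cut):
                if codes[i, start + e] == TE_CODE:
                    te_out += 1
        start += cut
    return te_out


@njit(cache=True)
def _scan_mutate(wcodes, wphis, wfresh, L, P):
    """The left-to-right replication mutation scan on a working buffer.

    Events per position in fixed order (large-scale, single dup, single
    del, inactivation); at most one fires; fresh copies are skipped.
    Growth past buffer capacity skips the growing event.  Ends with one
    phi-mutation offer per TE present.  Returns the new length.
    """
    lmax = wcodes.shape[0]
    ls = P[P_LARGE]
    sd = P[P_SDUP]
    sdel = P[P_SDEL]
    inact = P[P_INACT]
    i = 0
    while i < L:
        if wfresh[i] != 0:
            i += 1
            continue
        r = np.random.random()
        if r < ls:
            kind = np.random.randint(0, 3)
            hi = L // 2 - 1
            if hi < 1:
                hi = 1
            seg = 1 + np.random.randint(0, hi)
            end = i + seg
            if end > L:
                end = L
            m = end - i
            if kind == 0:  # tandem duplication of [i, end)
                if L + m <= lmax:
                    for k in range(L - 1, end - 1, -1):
                        wcodes[k + m] = wcodes[k]
                        wphis[k + m] = wphis[k]
                        wfresh[k + m] = wfresh[k]
                    for k in range(m):
                        wcodes[end + k] = wcodes[i + k]
                        wphis[end + k] = wphis[i + k]
                        wfresh[end + k] = 1
                    L += m
                i += 1
            elif kind == 1:  # deletion of [i, end)
                for k in range(end, L):
                    wcodes[k - m] = wcodes[k]
                    wphis[k - m] = wphis[k]
                    wfresh[k - m] = wfresh[k]
                L -= m
                # cursor stays: the next un-scanned element shifted onto i
            else:  # inversion of [i, end)
                a = i
                z = end - 1
                while a < z:
                    tc = wcodes[a]
                    wcodes[a] = wcodes[z]
                    wcodes[z] = tc
                    tp = wphis[a]
                    wphis[a] = wphis[z]
                    wphis[z] = tp
                    tf = wfresh[a]
                    wfresh[a] = wfresh[z]
                    wfresh[z] = tf
                    a += 1
                    z -= 1
                i += 1
        elif r < ls + sd:  # single tandem duplication
            if L + 1 <= lmax:
                for k in range(L - 1, i, -1):
                    wcodes[k + 1] = wcodes[k]
                    wphis[k + 1] = wphis[k]
                    wfresh[k + 1] = wfresh[k]
                wcodes[i + 1] = wcodes[i]
                wphis[i + 1] = wphis[i]
                wfresh[i + 1] = 1
                L += 1
            i += 1
        elif r < ls + sd + sdel:  # single deletion
            for k in range(i + 1, L):
                wcodes[k - 1] = wcodes[k]
                wphis[k - 1] = wphis[k]
                wfresh[k - 1] = wfresh[k]
            L -= 1
        elif r < ls + sd + sdel + inact:  # inactivation
            wcodes[i] = NONCODING
            wphis[i] = 0.0
            i += 1
        else:
            i += 1
    # host-genome replication replicates every TE: one phi-offer each
    if P[P_PHIMUT] > 0.0:
        for k in range(L):
            if wcodes[k] == TE_CODE:
                wphis[k] = _offer_phi_mut(wphis[k], P)
    return L


@njit(cache=True)
def _death_phase(t, occ, codes, phis, glen, P, viable, lineage, depth,
                 f_site, f_len, f_codes, f_phis, f_te, f_count, f_dropped,
                 ev_death_lin, ev_death_te, ev_death_depth, ev_death_t):
    """Non-viable cells plus a fraction ``d`` of viable cells die and lyse."""
    nd = 0
    for i in range(occ.shape[0]):
        if not occ[i]:
            continue
        if viable[i]:
            die = np.random.random() < P[P_D]
        else:
            die = True
        if die:
            te_out = _lyse_cell(i, i, codes, phis, glen,
                                f_site, f_len, f_codes, f_phis, f_te,
                                f_count, f_dropped)
            ev_death_lin[nd] = lineage[i]
            ev_death_te[nd] = te_out
            ev_death_depth[nd] = depth[i]
            ev_death_t[nd] = t
            nd += 1
            occ[i] = False
            glen[i] = 0
            lineage[i] = -1
            depth[i] = 0
    return nd


@njit(cache=True)
def _geom_skip(p):
    """Failures before the next success of a Bernoulli(p) sequence.

    Sampling hit positions by geometric skips is exactly equivalent to a
    per-element Bernoulli draw but costs one RNG call per *event*, which
    keeps the (large) eDNA pool phases cheap.
    """
    if p >= 1.0:
        return 0
    if p <= 0.0:
        return np.int64(1) << 60
    u = np.random.random()
    return np.int64(np.floor(np.log1p(-u) / np.log1p(-p)))


@njit(cache=True)
def _pull_fragment(k, n, f_site, f_len, f_codes, f_phis, f_te):
    """Swap-remove: move fragment ``n`` into slot ``k``."""
    if k != n:
        f_site[k] = f_site[n]
        f_len[k] = f_len[n]
        f_te[k] = f_te[n]
        for e in range(f_len[n]):
            f_codes[k, e] = f_codes[n, e]
            f_phis[k, e] = f_phis[n, e]


@njit(cache=True)
def _edna_phase(nbr, P, f_site, f_len, f_codes, f_phis, f_te, f_count):
    """Degrade each fragment with prob q, else diffuse with prob D.

    Both processes are sampled by geometric skips.  Degradation walks
    from the top of the pool downwards so that swap-removal never pulls
    an element into the already-processed range.
    """
    q = P[P_Q]
    dd = P[P_DIFF]
    n = f_count[0]
    k = n - 1 - _geom_skip(q)
    while k >= 0:
        n -= 1
        _pull_fragment(k, n, f_site, f_len, f_codes, f_phis, f_te)
        k -= 1 + _geom_skip(q)
    f_count[0] = n
    k = _geom_skip(dd)
    while k < n:
        f_site[k] = nbr[f_site[k], np.random.randint(0, 8)]
        k += 1 + _geom_skip(dd)


@njit(cache=True)
def _competition_phase(occ, codes, phis, glen, P, fitness, viable,
                       te_cnt, ess_cnt, nc_cnt, phi_sum,
                       lineage, depth, nbr, occ_snap,
                       wcodes, wphis, wfresh,
                       next_lin, ev_birth_lin, ev_inf_lin):
    """Fill empty sites by fitness-proportional Moore competition.

    All empty sites compete against the same post-death occupancy
    snapshot, so a daughter never reproduces in the step of its birth.
    Winner i is drawn with probability f_i / (sum f + eps); the epsilon
    slack leaves the site empty.
    """
    n = occ.shape[0]
    eps = P[P_EPS]
    repro = int(P[P_REPRO])
    for i in range(n):
        occ_snap[i] = occ[i]
    nb = 0
    ninf = 0
    for i in range(n):
        if occ_snap[i]:
            continue
        ftot = 0.0
        for a in range(8):
            s = nbr[i, a]
            if occ_snap[s]:
                ftot += fitness[s]
        if ftot <= 0.0:
            continue
        r = np.random.random() * (ftot + eps)
        w = -1
        acc = 0.0
        for a in range(8):
            s = nbr[i, a]
            if occ_snap[s]:
                acc += fitness[s]
                if r < acc:
                    w = s
                    break
        if w < 0:
            continue  # epsilon branch: nobody wins
        p2 = -1
        if repro == REPRO_SEXUAL:
            # the mate is drawn purely fitness-proportionally: epsilon
            # regulates colonisation of the site, not mate choice
            ftot2 = ftot - fitness[w]
            if ftot2 > 0.0:
                r2 = np.random.random() * ftot2
                acc2 = 0.0
                for a in range(8):
                    s = nbr[i, a]
                    if occ_snap[s] and s != w:
                        acc2 += fitness[s]
                        if r2 < acc2:
                            p2 = s
                            break
            # p2 == -1 (no living mate of positive fitness):
            # fall back to a clonal copy of the first parent
        # build the child genome into the working buffer
        lmax = wcodes.shape[0]
        if repro == REPRO_SEXUAL and p2 >= 0:
            h1 = glen[w] // 2
            h2 = glen[p2] // 2
            L = 0
            for k in range(h1):
                if L < lmax:
                    wcodes[L] = codes[w, k]
                    wphis[L] = phis[w, k]
                    wfresh[L] = 0
                    L += 1
            for k in range(h2, glen[p2]):
                if L < lmax:
                    wcodes[L] = codes[p2, k]
                    wphis[L] = phis[p2, k]
                    wfresh[L] = 0
                    L += 1
        else:
            L = glen[w]
            for k in range(L):
                wcodes[k] = codes[w, k]
                wphis[k] = phis[w, k]
                wfresh[k] = 0
        L = _scan_mutate(wcodes, wphis, wfresh, L, P)
        glen[i] = L
        for k in range(L):
            codes[i, k] = wcodes[k]
            phis[i, k] = wphis[k]
        occ[i] = True
        if lineage[w] >= 0:
            lineage[i] = lineage[w]
            depth[i] = depth[w] + 1
            ev_birth_lin[nb] = lineage[w]
            nb += 1
        else:
            lineage[i] = -1
            depth[i] = 0
        refresh_cell(i, codes, phis, glen, P, fitness, viable, te_cnt,
                     ess_cnt, nc_cnt, phi_sum)
        if te_cnt[i] > 0 and lineage[i] < 0:
            # TEs crossed in from parent 2: the child founds a new lineage
            lineage[i] = next_lin[0]
            depth[i] = 0
            ev_inf_lin[ninf] = next_lin[0]
            ninf += 1
            next_lin[0] += 1
    return nb, ninf


@njit(cache=True)
def _uptake_phase(occ, codes, phis, glen, P, fitness, viable,
                  te_cnt, ess_cnt, nc_cnt, phi_sum, lineage, depth,
                  f_site, f_len, f_codes, f_phis, f_te, f_count,
                  next_lin, ev_inf_lin, ninf0):
    """Fragment uptake and TE integration for living cells."""
    u = P[P_U]
    b = P[P_B]
    ninf = ninf0
    n = f_count[0]
    # thinning: candidate uptake events at rate u over the whole pool,
    # realised only where a living cell sits; walked from the top so the
    # swap-removal of consumed fragments stays exact
    k = n - 1 - _geom_skip(u)
    while k >= 0:
        s = f_site[k]
        if occ[s]:
            changed = False
            for e in range(f_len[k]):
                if f_codes[k, e] == TE_CODE:
                    phi = f_phis[k, e]
                    if np.random.random() < phi:
                        pos = np.random.randint(0, glen[s] + 1)
                        newphi = _offer_phi_mut(phi, P)
                        if _insert_te_row(s, pos, newphi, b, codes, phis, glen):
                            changed = True
            if changed:
                refresh_cell(s, codes, phis, glen, P, fitness, viable,
                             te_cnt, ess_cnt, nc_cnt, phi_sum)
                if te_cnt[s] > 0 and lineage[s] < 0:
                    lineage[s] = next_lin[0]
                    depth[s] = 0
                    ev_inf_lin[ninf] = next_lin[0]
                    ninf += 1
                    next_lin[0] += 1
            # consumed: swap-remove from the (already processed) top
            n -= 1
            _pull_fragment(k, n, f_site, f_len, f_codes, f_phis, f_te)
        k -= 1 + _geom_skip(u)
    f_count[0] = n
    return ninf


@njit(cache=True)
def _transposition_phase(occ, codes, phis, glen, P, fitness, viable,
                         te_cnt, ess_cnt, nc_cnt, phi_sum, tbuf):
    """Within-genome replication: TE phis snapshotted at phase entry per
    cell; each replicates with prob phi*j; new copies wait a step."""
    j = P[P_J]
    b = P[P_B]
    if j <= 0.0:
        return
    n = occ.shape[0]
    for i in range(n):
        if not occ[i] or te_cnt[i] == 0:
            continue
        nt = 0
        for k in range(glen[i]):
            if codes[i, k] == TE_CODE:
                tbuf[nt] = phis[i, k]
                nt += 1
        changed = False
        for k in range(nt):
            if np.random.random() < tbuf[k] * j:
                pos = np.random.randint(0, glen[i] + 1)
                newphi = _offer_phi_mut(tbuf[k], P)
                if _insert_te_row(i, pos, newphi, b, codes, phis, glen):
                    changed = True
        if changed:
            refresh_cell(i, codes, phis, glen, P, fitness, viable, te_cnt,
                         ess_cnt, nc_cnt, phi_sum)


@njit(cache=True)
def _mix_cells(occ, codes, phis, glen, fitness, viable, te_cnt, ess_cnt,
               nc_cnt, phi_sum, lineage, depth, perm):
    """Scatter every cell to a random site (well-mixed control)."""
    n = occ.shape[0]
    for i in range(n):
        perm[i] = i
    for i in range(n - 1, 0, -1):
        jj = np.random.randint(0, i + 1)
        t = perm[i]
        perm[i] = perm[jj]
        perm[jj] = t
    # cycle-safe scatter via temporaries; only occupancy needs clearing —
    # every other slot is written before it can be read (guarded by occ2)
    lmax = codes.shape[1]
    occ2 = np.zeros(n, dtype=np.bool_)
    glen2 = np.empty(n, dtype=glen.dtype)
    codes2 = np.empty((n, lmax), dtype=codes.dtype)
    phis2 = np.empty((n, lmax), dtype=phis.dtype)
    lin2 = np.full(n, -1, dtype=lineage.dtype)
    dep2 = np.empty(n, dtype=depth.dtype)
    fit2 = np.empty(n, dtype=fitness.dtype)
    via2 = np.empty(n, dtype=np.bool_)
    te2 = np.empty(n, dtype=te_cnt.dtype)
    es2 = np.empty(n, dtype=ess_cnt.dtype)
    nc2 = np.empty(n, dtype=nc_cnt.dtype)
    ph2 = np.empty(n, dtype=phi_sum.dtype)
    for i in range(n):
        if occ[i]:
            d = perm[i]
            occ2[d] = True
            glen2[d] = glen[i]
            for k in range(glen[i]):
                codes2[d, k] = codes[i, k]
                phis2[d, k] = phis[i, k]
            lin2[d] = lineage[i]
            dep2[d] = depth[i]
            fit2[d] = fitness[i]
            via2[d] = viable[i]
            te2[d] = te_cnt[i]
            es2[d] = ess_cnt[i]
            nc2[d] = nc_cnt[i]
            ph2[d] = phi_sum[i]
    for d in range(n):
        if occ2[d]:
            occ[d] = True
            glen[d] = glen2[d]
            for k in range(glen2[d]):
                codes[d, k] = codes2[d, k]
                phis[d, k] = phis2[d, k]
            lineage[d] = lin2[d]
            depth[d] = dep2[d]
            fitness[d] = fit2[d]
            viable[d] = via2[d]
            te_cnt[d] = te2[d]
            ess_cnt[d] = es2[d]
            nc_cnt[d] = nc2[d]
            phi_sum[d] = ph2[d]
        else:
            occ[d] = False
            glen[d] = 0
            lineage[d] = -1
            depth[d] = 0


@njit(cache=True)
def step(t, occ, codes, phis, glen, P, fitness, viable,
         te_cnt, ess_cnt, nc_cnt, phi_sum, lineage, depth, nbr,
         f_site, f_len, f_codes, f_phis, f_te, f_count, f_dropped,
         occ_snap, wcodes, wphis, wfresh, tbuf, perm, next_lin,
         ev_death_lin, ev_death_te, ev_death_depth, ev_death_t,
         ev_birth_lin, ev_inf_lin):
    """One full world timestep.

    Phase order: (1) death and lysis, (2) eDNA degradation/diffusion,
    (3) synchronous competition/reproduction for empty sites, (4) uptake
    and integration (asexual-HGT mode only), (5) lifetime transposition,
    (6) caches refreshed as cells change, (7) well-mixed shuffling if
    configured.  Returns (n_deaths, n_births, n_infections) as sizes of
    the filled event buffers.
    """
    nd = _death_phase(t, occ, codes, phis, glen, P, viable, lineage, depth,
                      f_site, f_len, f_codes, f_phis, f_te, f_count, f_dropped,
                      ev_death_lin, ev_death_te, ev_death_depth, ev_death_t)
    _edna_phase(nbr, P, f_site, f_len, f_codes, f_phis, f_te, f_count)
    nb, ninf = _competition_phase(occ, codes, phis, glen, P, fitness, viable,
                                  te_cnt, ess_cnt, nc_cnt, phi_sum,
                                  lineage, depth, nbr, occ_snap,
                                  wcodes, wphis, wfresh,
                                  next_lin, ev_birth_lin, ev_inf_lin)
    repro = int(P[P_REPRO])
    if repro == REPRO_ASEXUAL:
        ninf = _uptake_phase(occ, codes, phis, glen, P, fitness, viable,
                             te_cnt, ess_cnt, nc_cnt, phi_sum, lineage, depth,
                             f_site, f_len, f_codes, f_phis, f_te, f_count,
                             next_lin, ev_inf_lin, ninf)
    _transposition_phase(occ, codes, phis, glen, P, fitness, viable,
                         te_cnt, ess_cnt, nc_cnt, phi_sum, tbuf)
    mode = int(P[P_MODE])
    if mode == MODE_MIXED_CELLS:
        _mix_cells(occ, codes, phis, glen, fitness, viable, te_cnt, ess_cnt,
                   nc_cnt, phi_sum, lineage, depth, perm)
    elif mode == MODE_MIXED_EDNA:
        n = occ.shape[0]
        for k in range(f_count[0]):
            f_site[k] = np.random.randint(0, n)
    return nd, nb, ninf
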