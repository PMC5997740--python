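"""Numba-jitted inner loops.

Every stochastic kernel takes a ``numpy.random.Generator`` so that a single
seeded generator drives an entire replicate, whether a draw happens inside or
outside jitted code.  The public operations in :mod:`pennaxy.genome` and the
engine phases both call these kernels — there is one implementation of each
primitive.

Dialect codes (kept as plain ints for numba):
  mutation:  0 = Bernoulli(M) for exactly one uniform site, 1 = Poisson(M) sites
  crossover: 0 = Poisson(C) distinct boundaries, 1 = Bernoulli(C) single boundary
"""

import numpy as np
from numba import njit

MUT_BERNOULLI = 0
MUT_POISSON = 1
CROSS_POISSON = 0
CROSS_BERNOULLI = 1

REGIME_OFF = 0
REGIME_ON = 1
REGIME_EVOLVING = 2


@njit(cache=True)
def mutate_chrom(bits, mean, dialect, rng):
    """In-place replication mutation on one chromosome copy.

    A hit on an already-defective site is consumed without effect (no
    reversions, no resampling).
    """
    n = bits.shape[0]
    if dialect == MUT_BERNOULLI:
        if rng.random() < mean:
            bits[rng.integers(0, n)] = 1
    else:
        k = rng.poisson(mean)
        for _ in range(k):
            bits[rng.integers(0, n)] = 1


@njit(cache=True)
def crossover_pair(a, b, mean, dialect, rng):
    """In-place reciprocal exchange between two homologous copies.

    Crossover points fall on distinct intergenic boundaries 1..n-1.  Position 0
    is never exchanged, so ``b`` keeps its own chromosome start: for the male
    sex pair the product held in ``b`` is the Y-labelled one.  Returns the
    number of crossover points applied.
    """
    n = a.shape[0]
    if dialect == CROSS_POISSON:
        k = int(rng.poisson(mean))
    else:
        k = 1 if rng.random() < mean else 0
    if k <= 0 or n < 2:
        return 0
    if k > n - 1:
        k = n - 1
    pts = np.empty(k, np.int64)
    m = 0
    while m < k:  # rejection sampling of distinct boundaries; k << n in practice
        p = rng.integers(1, n)
        dup = False
        for i in range(m):
            if pts[i] == p:
                dup = True
                break
        if not dup:
            pts[m] = p
            m += 1
    pts.sort()
    swapped = False
    pi = 0
    for j in range(n):
        while pi < k and pts[pi] == j:
            swapped = not swapped
            pi += 1
        if swapped:
            t = a[j]
            a[j] = b[j]
            b[j] = t
    return k


@njit(cache=True)
def exchange_at(a, b, points):
    """Deterministic reciprocal exchange at given sorted boundaries (tests/oracles)."""
    n = a.shape[0]
    swapped = False
    pi = 0
    for j in range(n):
        while pi < points.shape[0] and points[pi] == j:
            swapped = not swapped
            pi += 1
        if swapped:
            t = a[j]
            a[j] = b[j]
            b[j] = t


@njit(cache=True)
def gamete_from_rows(row0, row1, starts, lengths, mut, rec, sex_idx,
                     parent_is_male, xy_rate, mut_dialect, cross_dialect,
                     buf_a, buf_b, out, rng):
    """Produce one gamete from a parent's two genome rows into ``out``.

    row0 is the maternally inherited copy (X for the sex pair), row1 the
    paternal one (Y in males).  Returns 1 if the gamete carries a Y product
    (only possible for a male parent), else 0.
    """
    carries_y = 0
    nch = starts.shape[0]
    for c in range(nch):
        s = starts[c]
        e = s + lengths[c]
        for j in range(s, e):
            buf_a[j] = row0[j]
            buf_b[j] = row1[j]
        mutate_chrom(buf_a[s:e], mut[c], mut_dialect, rng)
        mutate_chrom(buf_b[s:e], mut[c], mut_dialect, rng)
        cmean = rec[c]
        if c == sex_idx and parent_is_male == 1:
            cmean = xy_rate
        crossover_pair(buf_a[s:e], buf_b[s:e], cmean, cross_dialect, rng)
        if rng.random() < 0.5:
            for j in range(s, e):
                out[j] = buf_a[j]
        else:
            for j in range(s, e):
                out[j] = buf_b[j]
            if c == sex_idx and parent_is_male == 1:
                carries_y = 1
    return carries_y


@njit(cache=True)
def zygote_year_defects(g0, g1, starts, lengths, kpy, L, out):
    """Per-activation-year homozygous defect counts of a zygote into ``out`` (len L)."""
    for y in range(L):
        out[y] = 0
    for c in range(starts.shape[0]):
        s = starts[c]
        k = kpy[c]
        for y in range(L):
            base = s + y * k
            for t in range(k):
                j = base + t
                if g0[j] == 1 and g1[j] == 1:
                    out[y] += 1


@njit(cache=True)
def popcount_range(row, s, e):
    tot = 0
    for j in range(s, e):
        if row[j] == 1:
            tot += 1
    return tot


@njit(cache=True)
def mutate_modifier_k(value, step, rng):
    """One father-to-son transmission of the X-Y recombination modifier.

    Zero is absorbing; otherwise +/- step with equal probability, clamped at 0.
    """
    if value <= 0.0:
        return 0.0
    if rng.random() < 0.5:
        return value + step
    nv = value - step
    if nv < 0.0:
        nv = 0.0
    return nv


@njit(cache=True)
def aging_k(occ, sex, age, cum, partner, year_def, L, b, T):
    """One ageing sweep: increment ages, disclose this year's loci, apply deaths.

    Loci activating in years < b were already counted prenatally, so ages
    1..b-1 disclose nothing new.  Death at age L (old age) or cum >= T
    (genetic death); dead cells are vacated immediately and widowed partners
    unbonded.  Returns the number of deaths.
    """
    deaths = 0
    n = occ.shape[0]
    for i in range(n):
        if not occ[i]:
            continue
        a = age[i] + 1
        age[i] = a
        dead = False
        if a >= L:
            dead = True
        else:
            if a >= b:
                cum[i] += year_def[i, a]
            if cum[i] >= T:
                dead = True
        if dead:
            occ[i] = False
            p = partner[i]
            if p >= 0:
                partner[p] = -1
                partner[i] = -1
            deaths += 1
    return deaths


@njit(cache=True)
def _pick_male(nbr_row, full_scan, self_cell, occ, sex, age, R,
               need_unpaired, partner, rng):
    """Uniform pick among eligible males in a neighborhood (or the whole pool)."""
    k = 0
    if full_scan:
        for c in range(occ.shape[0]):
            if c == self_cell:
                continue
            if occ[c] and sex[c] == 1 and age[c] >= R:
                if (not need_unpaired) or partner[c] < 0:
                    k += 1
    else:
        for t in range(nbr_row.shape[0]):
            c = nbr_row[t]
            if occ[c] and sex[c] == 1 and age[c] >= R:
                if (not need_unpaired) or partner[c] < 0:
                    k += 1
    if k == 0:
        return -1
    r = rng.integers(0, k)
    if full_scan:
        for c in range(occ.shape[0]):
            if c == self_cell:
                continue
            if occ[c] and sex[c] == 1 and age[c] >= R:
                if (not need_unpaired) or partner[c] < 0:
                    if r == 0:
                        return c
                    r -= 1
    else:
        for t in range(nbr_row.shape[0]):
            c = nbr_row[t]
            if occ[c] and sex[c] == 1 and age[c] >= R:
                if (not need_unpaired) or partner[c] < 0:
                    if r == 0:
                        return c
                    r -= 1
    return -1


@njit(cache=True)
def _pick_free_cell(nbr_row, full_scan, self_cell, occ, rng):
    k = 0
    if full_scan:
        for c in range(occ.shape[0]):
            if c != self_cell and not occ[c]:
                k += 1
    else:
        for t in range(nbr_row.shape[0]):
            if not occ[nbr_row[t]]:
                k += 1
    if k == 0:
        return -1
    r = rng.integers(0, k)
    if full_scan:
        for c in range(occ.shape[0]):
            if c != self_cell and not occ[c]:
                if r == 0:
                    return c
                r -= 1
    else:
        for t in range(nbr_row.shape[0]):
            c = nbr_row[t]
            if not occ[c]:
                if r == 0:
                    return c
                r -= 1
    return -1


@njit(cache=True)
def reproduction_k(order, occ, sex, age, cum, xymod, partner,
                   genome, year_def, cnt_s0, cnt_s1, cnt_c0, cnt_c1,
                   nbr_p, nbr_c, partner_full, child_full,
                   starts, lengths, kpy, mut, rec, sex_idx, cmp_idx,
                   L, b, R, T, B, faithful, regime, xy_table_rate,
                   modifier_step, mut_dialect, cross_dialect, rng):
    """One reproduction sweep over reproductive females in the given order.

    Each female draws Poisson(B) conception attempts and stops at the first
    success.  One attempt: partner search -> free-cell search -> gamete
    formation -> zygote -> prenatal check of the first b activation years.
    Returns (births, attempts).
    """
    total = genome.shape[2]
    buf_a = np.empty(total, np.uint8)
    buf_b = np.empty(total, np.uint8)
    gam_m = np.empty(total, np.uint8)
    gam_p = np.empty(total, np.uint8)
    tmp_yd = np.empty(L, np.int32)
    ss = starts[sex_idx]
    se = ss + lengths[sex_idx]
    cs = starts[cmp_idx]
    ce = cs + lengths[cmp_idx]
    births = 0
    attempts = 0
    for fi in range(order.shape[0]):
        f = order[fi]
        if not occ[f]:  # defensive; deaths precede reproduction
            continue
        n_att = rng.poisson(B)
        for _ in range(n_att):
            attempts += 1
            # (1) partner
            if faithful:
                m = partner[f]
                if m < 0:
                    m = _pick_male(nbr_p[f], partner_full, f, occ, sex, age, R,
                                   True, partner, rng)
                    if m >= 0:
                        partner[f] = m
                        partner[m] = f
                if m < 0:
                    continue
            else:
                m = _pick_male(nbr_p[f], partner_full, f, occ, sex, age, R,
                               False, partner, rng)
                if m < 0:
                    continue
            # (2) free place for the child, centred on the mother
            cell = _pick_free_cell(nbr_c[f], child_full, f, occ, rng)
            if cell < 0:
                continue
            # (3) gametes
            if regime == REGIME_OFF:
                xy_rate = 0.0
            elif regime == REGIME_ON:
                xy_rate = xy_table_rate
            else:
                xy_rate = xymod[m]
            gamete_from_rows(genome[f, 0], genome[f, 1], starts, lengths, mut,
                             rec, sex_idx, 0, 0.0, mut_dialect, cross_dialect,
                             buf_a, buf_b, gam_m, rng)
            carries_y = gamete_from_rows(genome[m, 0], genome[m, 1], starts,
                                         lengths, mut, rec, sex_idx, 1, xy_rate,
                                         mut_dialect, cross_dialect,
                                         buf_a, buf_b, gam_p, rng)
            # (4)+(5) zygote and prenatal check of years [0, b)
            zygote_year_defects(gam_m, gam_p, starts, lengths, kpy, L, tmp_yd)
            prenatal = 0
            for y in range(b):
                prenatal += tmp_yd[y]
            if prenatal >= T:
                continue
            # success: place the newborn
            occ[cell] = True
            sex[cell] = carries_y
            age[cell] = 0
            cum[cell] = prenatal
            partner[cell] = -1
            for j in range(total):
                genome[cell, 0, j] = gam_m[j]
                genome[cell, 1, j] = gam_p[j]
            for y in range(L):
                year_def[cell, y] = tmp_yd[y]
            cnt_s0[cell] = popcount_range(gam_m, ss, se)
            cnt_s1[cell] = popcount_range(gam_p, ss, se)
            cnt_c0[cell] = popcount_range(gam_m, cs, ce)
            cnt_c1[cell] = popcount_range(gam_p, cs, ce)
            if carries_y == 1:
                if regime == REGIME_EVOLVING:
                    xymod[cell] = mutate_modifier_k(xymod[m], modifier_step, rng)
                elif regime == REGIME_ON:
                    xymod[cell] = xy_table_rate
                else:
                    xymod[cell] = 0.0
            else:
                xymod[cell] = 0.0
            births += 1
            break
    return births, attempts
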