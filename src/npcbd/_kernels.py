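"""Numba inner loops for the Brownian-dynamics engine.

Everything here operates on the flat array representation produced by
:func:`npcbd.forcefield.flatten`.  The kernel advances the overdamped
Langevin dynamics, maintains a Verlet neighbor list (rebuilt on a fixed
cadence and whenever accumulated displacement threatens the skin),
applies the per-bead rejection of overstretched WLC segments and of
moves into the rigid NE slab or out of the simulation box, and keeps the
per-step transport bookkeeping (kap-FG contacts, events, track samples).

All quantities are in reduced units: kT, nm, 0.1 ns.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# status codes returned by run_chunk
STATUS_OK = 0  # all requested steps done
STATUS_LOADED = 1  # cargo fully loaded into the basket (t_end)
STATUS_FAULT = 2  # non-finite force encountered


@njit(cache=True)
def _excluded(excl, n, i, j):
    a, b = (i, j) if i < j else (j, i)
    key = a * n + b
    lo, hi = 0, len(excl)
    while lo < hi:
        mid = (lo + hi) // 2
        if excl[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < len(excl) and excl[lo] == key


@njit(cache=True)
def build_pairs(pos, offsets, group, excl, cut_ff, cut_rep, skin,
                pair_i, pair_j):
    """O(N^2) Verlet-list build with per-class cutoffs; returns the
    number of pairs stored.

    Pairs of cohesive (central) FG beads use the long hydrophobic
    cutoff; every other pair only needs the short repulsive cutoff, so
    the list stays small even though the largest cutoff is 10 nm.
    """
    n = pos.shape[0]
    count = 0
    cap = pair_i.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if group[i] == 2 and group[j] == 2:
                cut = cut_ff
            else:
                cut = cut_rep
            th = cut + offsets[i] + offsets[j] + skin
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if dx * dx + dy * dy < th * th:
                if _excluded(excl, n, i, j):
                    continue
                if count >= cap:
                    return -1
                pair_i[count] = i
                pair_j[count] = j
                count += 1
    return count


@njit(cache=True)
def build_fg_near(pos, cargo_index, fg_idx, cut_kf, skin, fg_near):
    """FG beads within the kap-FG cutoff (+skin) of the cargo center;
    returns the count.  The spot arc lies on the cargo surface, so the
    reach from the center is cut_kf + R; R is folded into ``skin`` by
    the caller."""
    count = 0
    cx = pos[cargo_index, 0]
    cy = pos[cargo_index, 1]
    th = cut_kf + skin
    for m in range(fg_idx.shape[0]):
        j = fg_idx[m]
        dx = pos[j, 0] - cx
        dy = pos[j, 1] - cy
        if dx * dx + dy * dy < th * th:
            fg_near[count] = j
            count += 1
    return count


@njit(cache=True)
def compute_forces(pos, F, offsets, group,
                   bond_i, bond_j, bond_k, bond_r0,
                   ang_i, ang_j, ang_k, ang_kt, ang_t0,
                   wlc_i, wlc_j, wlc_Ls, l_p,
                   pair_i, pair_j, n_pairs,
                   eps_ff, xi_ff, cut_ff,
                   eps_kf, xi_kf, cut_kf,
                   eps_rep, sigma_rep, cut_rep,
                   cargo_index, spot_off, fg_near, n_fg_near):
    """Total conservative forces into F; returns False on degenerate input."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
    # harmonic bonds
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        fmag = -bond_k[b] * (r - bond_r0[b])  # -dE/dr
        ux = dx / r
        uy = dy / r
        F[i, 0] -= fmag * ux
        F[i, 1] -= fmag * uy
        F[j, 0] += fmag * ux
        F[j, 1] += fmag * uy
    # cosine bending
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        nu = math.sqrt(ux * ux + uy * uy)
        nv = math.sqrt(vx * vx + vy * vy)
        if nu < 1e-12 or nv < 1e-12:
            return False
        c = (ux * vx + uy * vy) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        if ang_t0[a] == math.pi:
            # sin(theta - pi)/sin(theta) = -1 exactly (straight WLC)
            g = -ang_kt[a]
        else:
            theta = math.acos(c)
            s = math.sqrt(max(1.0 - c * c, 1e-24))
            g = ang_kt[a] * math.sin(theta - ang_t0[a]) / s
        dcix = (vx / nv - c * ux / nu) / nu
        dciy = (vy / nv - c * uy / nu) / nu
        dckx = (ux / nu - c * vx / nv) / nv
        dcky = (uy / nu - c * vy / nv) / nv
        F[i, 0] += g * dcix
        F[i, 1] += g * dciy
        F[k, 0] += g * dckx
        F[k, 1] += g * dcky
        F[j, 0] -= g * (dcix + dckx)
        F[j, 1] -= g * (dciy + dcky)
    # WLC tensions
    for w in range(wlc_i.shape[0]):
        i = wlc_i[w]
        j = wlc_j[w]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        x = r / wlc_Ls[w]
        if x >= 1.0:
            return False
        t = (1.0 / l_p) * (0.25 / ((1.0 - x) * (1.0 - x)) - 0.25 + x)
        ux = dx / r
        uy = dy / r
        F[i, 0] += t * ux
        F[i, 1] += t * uy
        F[j, 0] -= t * ux
        F[j, 1] -= t * uy
    # nonbonded pair terms
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        cohesive = group[i] == 2 and group[j] == 2
        cut = cut_ff if cohesive else cut_rep
        th = cut + offsets[i] + offsets[j]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        r2 = dx * dx + dy * dy
        if r2 >= th * th:
            continue
        r = math.sqrt(r2)
        if r < 1e-12:
            continue
        r_eff = r - offsets[i] - offsets[j]
        if r_eff < 0.0:
            r_eff = 0.0
        fmag = 0.0
        if r_eff < cut_rep:
            fmag += (eps_rep / sigma_rep) * math.exp(-r_eff / sigma_rep)
        if cohesive and r_eff < cut_ff:
            fmag += -(eps_ff / xi_ff) * math.exp(-r_eff / xi_ff)
        if fmag != 0.0:
            ux = dx / r
            uy = dy / r
            F[i, 0] -= fmag * ux
            F[i, 1] -= fmag * uy
            F[j, 0] += fmag * ux
            F[j, 1] += fmag * uy
    # kap binding spots x nearby FG motifs
    if cargo_index >= 0:
        cut2 = cut_kf * cut_kf
        for sp in range(spot_off.shape[0]):
            sx = pos[cargo_index, 0] + spot_off[sp, 0]
            sy = pos[cargo_index, 1] + spot_off[sp, 1]
            for m in range(n_fg_near):
                j = fg_near[m]
                dx = pos[j, 0] - sx
                dy = pos[j, 1] - sy
                r2 = dx * dx + dy * dy
                if r2 >= cut2:
                    continue
                r = math.sqrt(r2)
                if r < 1e-12:
                    continue
                fmag = -(eps_kf / xi_kf) * math.exp(-r / xi_kf)
                ux = dx / r
                uy = dy / r
                F[cargo_index, 0] -= fmag * ux
                F[cargo_index, 1] -= fmag * uy
                F[j, 0] += fmag * ux
                F[j, 1] += fmag * uy
    return True


@njit(cache=True)
def _wall_violation(x, y, off, x_ne, y_ne_top, y_ne_bot, x_box, y_top, y_bot):
    """True if a bead (clearance ``off``) is inside the NE slab or out of
    the box."""
    ax = abs(x)
    if ax + off > x_box or y + off > y_top or y - off < y_bot:
        return True
    # distance from (ax, y) to the slab region {u >= x_ne, y_ne_bot<=v<=y_ne_top}
    ddx = x_ne - ax
    if ddx < 0.0:
        ddx = 0.0
    ddy = 0.0
    if y < y_ne_bot:
        ddy = y_ne_bot - y
    elif y > y_ne_top:
        ddy = y - y_ne_top
    dist = math.sqrt(ddx * ddx + ddy * ddy)
    if off > 0.0:
        return dist < off
    return dist == 0.0


@njit(cache=True)
def run_chunk(pos, mobile, D_red, offsets, group,
              bond_i, bond_j, bond_k, bond_r0,
              ang_i, ang_j, ang_k, ang_kt, ang_t0,
              wlc_i, wlc_j, wlc_Ls, l_p,
              excl,
              eps_ff, xi_ff, cut_ff,
              eps_kf, xi_kf, cut_kf,
              eps_rep, sigma_rep, cut_rep,
              cargo_index, spot_off, fg_idx, fg_slot, filament_fg,
              x_ne, y_ne_top, y_ne_bot, x_box, y_top, y_bot,
              y_chan_bot, y_exit, cargo_radius,
              dt, f_max, n_steps, noise, amp,
              rebuild_every, skin, contact_radius,
              start_step, t_start_in, sample_stride,
              runlen, act_sp, act_slot, track, engaged_track,
              episodes, acc, facc):
    """Advance ``n_steps`` Brownian-dynamics steps.

    Returns (status, steps_done, t_start, t_end, n_track_samples).
    Steps are counted globally from ``start_step``; ``t_start``/``t_end``
    are global step indices (-1 when the event has not occurred).
    ``runlen`` (per-pair contact run lengths), the active-pair list
    (``act_sp``/``act_slot``), ``acc`` and ``facc`` persist across
    chunks.

    Occupancy counts a spot as engaged while >= 1 FG motif lies within
    the kap-FG interaction cutoff; bond episodes use the tighter
    geometric ``contact_radius``.

    ``noise`` is an (n_steps, n, 2) array of standard normals drawn by
    the caller (one numpy Generator stream per run, so trajectories are
    independent of how steps are split into chunks) and ``amp`` the
    per-bead noise amplitude sqrt(2 D dt).

    acc layout: 0 engaged steps, 1 engaged-spot sum, 2 episode count,
    3 episode step sum, 4 longest episode, 5 episodes recorded,
    6 active-pair count, 7 active-list overflow flag.
    facc layout: 0 running max WLC extension fraction (sampled).
    """
    n = pos.shape[0]
    n_spots = spot_off.shape[0]
    t_start = t_start_in
    t_end = -1

    cap = 64 * n + 1024
    pair_i = np.empty(cap, np.int64)
    pair_j = np.empty(cap, np.int64)
    n_pairs = build_pairs(pos, offsets, group, excl, cut_ff, cut_rep, skin,
                          pair_i, pair_j)
    if n_pairs < 0:
        return STATUS_FAULT, 0, t_start, t_end, 0
    fg_near = np.empty(max(fg_idx.shape[0], 1), np.int64)
    near_skin = cargo_radius + skin
    n_near = 0
    if cargo_index >= 0:
        n_near = build_fg_near(pos, cargo_index, fg_idx, cut_kf, near_skin,
                               fg_near)

    F = np.empty((n, 2))
    prev = np.empty((n, 2))
    ref = pos.copy()  # positions at last list rebuild
    revert = np.empty(n, np.bool_)
    ep_cap = episodes.shape[0]
    act_cap = act_sp.shape[0]
    cr2 = contact_radius * contact_radius
    kf2 = cut_kf * cut_kf

    n_track = 0
    steps_done = 0
    status = STATUS_OK

    for step in range(n_steps):
        gstep = start_step + step
        # neighbor-list maintenance (fixed cadence + displacement guard)
        need = step % rebuild_every == 0 and step > 0
        if not need:
            maxd2 = 0.0
            for i in range(n):
                if mobile[i]:
                    dx = pos[i, 0] - ref[i, 0]
                    dy = pos[i, 1] - ref[i, 1]
                    d2 = dx * dx + dy * dy
                    if d2 > maxd2:
                        maxd2 = d2
            if 4.0 * maxd2 > skin * skin:
                need = True
        if need:
            n_pairs = build_pairs(pos, offsets, group, excl, cut_ff, cut_rep,
                                  skin, pair_i, pair_j)
            if n_pairs < 0:
                status = STATUS_FAULT
                break
            if cargo_index >= 0:
                n_near = build_fg_near(pos, cargo_index, fg_idx, cut_kf,
                                       near_skin, fg_near)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]

        ok = compute_forces(pos, F, offsets, group,
                            bond_i, bond_j, bond_k, bond_r0,
                            ang_i, ang_j, ang_k, ang_kt, ang_t0,
                            wlc_i, wlc_j, wlc_Ls, l_p,
                            pair_i, pair_j, n_pairs,
                            eps_ff, xi_ff, cut_ff,
                            eps_kf, xi_kf, cut_kf,
                            eps_rep, sigma_rep, cut_rep,
                            cargo_index, spot_off, fg_near, n_near)
        if not ok:
            status = STATUS_FAULT
            break

        # overdamped Langevin proposal: x += F*D*dt + N(0, 2 D dt)
        for i in range(n):
            prev[i, 0] = pos[i, 0]
            prev[i, 1] = pos[i, 1]
            if not mobile[i]:
                continue
            if not (math.isfinite(F[i, 0]) and math.isfinite(F[i, 1])):
                status = STATUS_FAULT
                break
            pos[i, 0] += F[i, 0] * D_red[i] * dt + amp[i] * noise[step, i, 0]
            pos[i, 1] += F[i, 1] * D_red[i] * dt + amp[i] * noise[step, i, 1]
        if status == STATUS_FAULT:
            break

        # Oettinger-style per-bead rejection + rigid boundaries
        resolved = False
        for _it in range(8):
            any_viol = False
            for i in range(n):
                revert[i] = False
            for w in range(wlc_i.shape[0]):
                i = wlc_i[w]
                j = wlc_j[w]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                lim = f_max * wlc_Ls[w]
                if dx * dx + dy * dy >= lim * lim:
                    revert[i] = True
                    revert[j] = True
                    any_viol = True
            for i in range(n):
                if mobile[i] and not revert[i]:
                    if _wall_violation(pos[i, 0], pos[i, 1], offsets[i],
                                       x_ne, y_ne_top, y_ne_bot,
                                       x_box, y_top, y_bot):
                        revert[i] = True
                        any_viol = True
            if not any_viol:
                resolved = True
                break
            for i in range(n):
                if revert[i] and mobile[i]:
                    pos[i, 0] = prev[i, 0]
                    pos[i, 1] = prev[i, 1]
        if not resolved:
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] = prev[i, 0]
                    pos[i, 1] = prev[i, 1]

        # kap-FG bookkeeping: engagement (cutoff) and bonds (contact)
        engaged_spots = 0
        if cargo_index >= 0 and n_spots > 0:
            for sp in range(n_spots):
                sx = pos[cargo_index, 0] + spot_off[sp, 0]
                sy = pos[cargo_index, 1] + spot_off[sp, 1]
                spot_engaged = False
                for m in range(n_near):
                    j = fg_near[m]
                    dx = pos[j, 0] - sx
                    dy = pos[j, 1] - sy
                    r2 = dx * dx + dy * dy
                    if r2 >= kf2:
                        continue
                    spot_engaged = True
                    if t_start < 0 and filament_fg[j]:
                        t_start = gstep
                    if r2 < cr2:
                        slot = fg_slot[j]
                        if runlen[sp, slot] == 0:
                            if acc[6] < act_cap:
                                act_sp[acc[6]] = sp
                                act_slot[acc[6]] = slot
                                acc[6] += 1
                            else:
                                acc[7] = 1
                        runlen[sp, slot] += 1
                if spot_engaged:
                    engaged_spots += 1
            if engaged_spots > 0:
                acc[0] += 1
                acc[1] += engaged_spots
            # close episodes for active pairs that left contact this step
            k = 0
            while k < acc[6]:
                sp = act_sp[k]
                slot = act_slot[k]
                j = fg_idx[slot]
                sx = pos[cargo_index, 0] + spot_off[sp, 0]
                sy = pos[cargo_index, 1] + spot_off[sp, 1]
                dx = pos[j, 0] - sx
                dy = pos[j, 1] - sy
                if dx * dx + dy * dy >= cr2:
                    L = runlen[sp, slot]
                    acc[2] += 1
                    acc[3] += L
                    if L > acc[4]:
                        acc[4] = L
                    if acc[5] < ep_cap:
                        episodes[acc[5]] = L
                        acc[5] += 1
                    runlen[sp, slot] = 0
                    acc[6] -= 1
                    act_sp[k] = act_sp[acc[6]]
                    act_slot[k] = act_slot[acc[6]]
                else:
                    k += 1

        sampling = gstep % sample_stride == 0
        if sampling:
            # running max WLC extension fraction (rejection invariant)
            for w in range(wlc_i.shape[0]):
                i = wlc_i[w]
                j = wlc_j[w]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                frac = math.sqrt(dx * dx + dy * dy) / wlc_Ls[w]
                if frac > facc[0]:
                    facc[0] = frac

        if cargo_index >= 0:
            cy = pos[cargo_index, 1]
            if (cy + cargo_radius < y_chan_bot) and (cy - cargo_radius > y_exit):
                t_end = gstep
            if sampling or t_end >= 0:
                track[n_track, 0] = gstep
                track[n_track, 1] = pos[cargo_index, 0]
                track[n_track, 2] = pos[cargo_index, 1]
                engaged_track[n_track] = engaged_spots
                n_track += 1
            if t_end >= 0:
                steps_done = step + 1
                status = STATUS_LOADED
                break
        steps_done = step + 1

    return status, steps_done, t_start, t_end, n_track
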