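"""Numba kernels for the Brownian-dynamics engine.

Two hot paths live here: the per-trajectory propagation loop (forces from a
trilinear potential grid, Ermak–McCammon translation/rotation updates,
excluded-volume rejection, encounter detection) and the batch update of the
energy-ranked, RMSD-deduplicated recorded set.  Both have pure-Python
counterparts in :mod:`lhdock.bd` that serve as independent oracles in the
test suite; the kernels must implement exactly the same rules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# propagation exit statuses
NOISE_EXHAUSTED = 0
ESCAPED = 1
MAX_STEPS = 2
ABORTED_LARGE_STEP = 3


@njit(cache=False, inline="always")
def _quat_to_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=False, inline="always")
def _rotvec_to_quat(phi, q):
    angle = np.sqrt(phi[0] ** 2 + phi[1] ** 2 + phi[2] ** 2)
    if angle < 1e-12:
        q[0] = 1.0
        q[1] = 0.5 * phi[0]
        q[2] = 0.5 * phi[1]
        q[3] = 0.5 * phi[2]
    else:
        s = np.sin(0.5 * angle) / angle
        q[0] = np.cos(0.5 * angle)
        q[1] = s * phi[0]
        q[2] = s * phi[1]
        q[3] = s * phi[2]
    n = np.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
    q[0] /= n
    q[1] /= n
    q[2] /= n
    q[3] /= n


@njit(cache=False, inline="always")
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=False)
def eval_field(
    pos, R, site_ref, site_q,
    phi, g_origin, g_h,
    tail_pref, kappa, src_center,
    out_force, out_torque,
):
    """Energy (kT), force (kT/Å) and torque (kT) at a pose.

    Sites inside the grid use the analytic gradient of the trilinear
    interpolant; sites outside use the DH monopole tail of the source.
    """
    nx, ny, nz = phi.shape
    energy = 0.0
    out_force[:] = 0.0
    out_torque[:] = 0.0
    inv_h = 1.0 / g_h
    for s in range(site_ref.shape[0]):
        wx = R[0, 0] * site_ref[s, 0] + R[0, 1] * site_ref[s, 1] + R[0, 2] * site_ref[s, 2] + pos[0]
        wy = R[1, 0] * site_ref[s, 0] + R[1, 1] * site_ref[s, 1] + R[1, 2] * site_ref[s, 2] + pos[1]
        wz = R[2, 0] * site_ref[s, 0] + R[2, 1] * site_ref[s, 1] + R[2, 2] * site_ref[s, 2] + pos[2]
        fx = (wx - g_origin[0]) * inv_h
        fy = (wy - g_origin[1]) * inv_h
        fz = (wz - g_origin[2]) * inv_h
        q = site_q[s]
        if 0.0 <= fx <= nx - 1.0 and 0.0 <= fy <= ny - 1.0 and 0.0 <= fz <= nz - 1.0:
            ix = int(fx)
            iy = int(fy)
            iz = int(fz)
            if ix > nx - 2:
                ix = nx - 2
            if iy > ny - 2:
                iy = ny - 2
            if iz > nz - 2:
                iz = nz - 2
            tx = fx - ix
            ty = fy - iy
            tz = fz - iz
            c000 = phi[ix, iy, iz]
            c100 = phi[ix + 1, iy, iz]
            c010 = phi[ix, iy + 1, iz]
            c110 = phi[ix + 1, iy + 1, iz]
            c001 = phi[ix, iy, iz + 1]
            c101 = phi[ix + 1, iy, iz + 1]
            c011 = phi[ix, iy + 1, iz + 1]
            c111 = phi[ix + 1, iy + 1, iz + 1]
            c00 = c000 * (1 - tx) + c100 * tx
            c10 = c010 * (1 - tx) + c110 * tx
            c01 = c001 * (1 - tx) + c101 * tx
            c11 = c011 * (1 - tx) + c111 * tx
            c0 = c00 * (1 - ty) + c10 * ty
            c1 = c01 * (1 - ty) + c11 * ty
            val = c0 * (1 - tz) + c1 * tz
            gx = (((c100 - c000) * (1 - ty) + (c110 - c010) * ty) * (1 - tz)
                  + ((c101 - c001) * (1 - ty) + (c111 - c011) * ty) * tz) * inv_h
            gy = ((c10 - c00) * (1 - tz) + (c11 - c01) * tz) * inv_h
            gz = (c1 - c0) * inv_h
        else:
            rx = wx - src_center[0]
            ry = wy - src_center[1]
            rz = wz - src_center[2]
            r = np.sqrt(rx * rx + ry * ry + rz * rz)
            if r < 1e-6:
                r = 1e-6
            val = tail_pref * np.exp(-kappa * r) / r
            dphi = -val * (kappa + 1.0 / r) / r
            gx = dphi * rx
            gy = dphi * ry
            gz = dphi * rz
        energy += q * val
        ffx = -q * gx
        ffy = -q * gy
        ffz = -q * gz
        out_force[0] += ffx
        out_force[1] += ffy
        out_force[2] += ffz
        ax = wx - pos[0]
        ay = wy - pos[1]
        az = wz - pos[2]
        out_torque[0] += ay * ffz - az * ffy
        out_torque[1] += az * ffx - ax * ffz
        out_torque[2] += ax * ffy - ay * ffx
    return energy


@njit(cache=False, inline="always")
def _overlaps(pos, R, probe_ref, occ, e_origin, e_inv_h):
    mx, my, mz = occ.shape
    for a in range(probe_ref.shape[0]):
        wx = R[0, 0] * probe_ref[a, 0] + R[0, 1] * probe_ref[a, 1] + R[0, 2] * probe_ref[a, 2] + pos[0]
        wy = R[1, 0] * probe_ref[a, 0] + R[1, 1] * probe_ref[a, 1] + R[1, 2] * probe_ref[a, 2] + pos[1]
        wz = R[2, 0] * probe_ref[a, 0] + R[2, 1] * probe_ref[a, 1] + R[2, 2] * probe_ref[a, 2] + pos[2]
        ix = int(np.rint((wx - e_origin[0]) * e_inv_h))
        iy = int(np.rint((wy - e_origin[1]) * e_inv_h))
        iz = int(np.rint((wz - e_origin[2]) * e_inv_h))
        if 0 <= ix < mx and 0 <= iy < my and 0 <= iz < mz:
            if occ[ix, iy, iz]:
                return True
    return False


@njit(cache=False)
def propagate_segment(
    pos, quat,
    site_ref, site_q,
    phi, g_origin, g_h,
    tail_pref, kappa, src_center,
    occ, e_origin, e_h,
    probe_ref,
    D_t, D_r, dt,
    stop2, enc_c2c2, enc_dyad2, skip2,
    nuc_center, dyad_point,
    noise,
    max_disp, max_retries,
    step_start, max_steps,
    ev_step, ev_energy, ev_pos, ev_quat,
):
    """Advance one trajectory until the noise buffer runs out or it exits.

    Returns (status, step, n_events, noise_used).  ``pos``/``quat`` are
    updated in place so the caller can refill noise and resume.
    """
    R = np.empty((3, 3))
    Rtrial = np.empty((3, 3))
    force = np.empty(3)
    torque = np.empty(3)
    dq = np.empty(4)
    qtrial = np.empty(4)
    pos_trial = np.empty(3)
    e_inv_h = 1.0 / e_h
    sig_t = np.sqrt(2.0 * D_t * dt)
    sig_r = np.sqrt(2.0 * D_r * dt)
    phi_vec = np.empty(3)

    step = step_start
    n_events = 0
    used = 0
    m = noise.shape[0]
    _quat_to_mat(quat, R)
    energy = eval_field(pos, R, site_ref, site_q, phi, g_origin, g_h,
                        tail_pref, kappa, src_center, force, torque)
    while True:
        # one BD step (reject-and-redraw on overlap)
        accepted = False
        retries = 0
        while retries < max_retries:
            if used >= m:
                return NOISE_EXHAUSTED, step, n_events, used
            drx = D_t * force[0] * dt + sig_t * noise[used, 0]
            dry = D_t * force[1] * dt + sig_t * noise[used, 1]
            drz = D_t * force[2] * dt + sig_t * noise[used, 2]
            phi_vec[0] = D_r * torque[0] * dt + sig_r * noise[used, 3]
            phi_vec[1] = D_r * torque[1] * dt + sig_r * noise[used, 4]
            phi_vec[2] = D_r * torque[2] * dt + sig_r * noise[used, 5]
            used += 1
            if drx * drx + dry * dry + drz * drz > max_disp * max_disp:
                return ABORTED_LARGE_STEP, step, n_events, used
            _rotvec_to_quat(phi_vec, dq)
            _quat_mul(dq, quat, qtrial)
            n = np.sqrt(qtrial[0] ** 2 + qtrial[1] ** 2 + qtrial[2] ** 2 + qtrial[3] ** 2)
            qtrial /= n
            pos_trial[0] = pos[0] + drx
            pos_trial[1] = pos[1] + dry
            pos_trial[2] = pos[2] + drz
            dcx = pos_trial[0] - nuc_center[0]
            dcy = pos_trial[1] - nuc_center[1]
            dcz = pos_trial[2] - nuc_center[2]
            if dcx * dcx + dcy * dcy + dcz * dcz < skip2:
                _quat_to_mat(qtrial, Rtrial)
                if _overlaps(pos_trial, Rtrial, probe_ref, occ, e_origin, e_inv_h):
                    retries += 1
                    continue
            accepted = True
            break
        if accepted:
            pos[0] = pos_trial[0]
            pos[1] = pos_trial[1]
            pos[2] = pos_trial[2]
            quat[0] = qtrial[0]
            quat[1] = qtrial[1]
            quat[2] = qtrial[2]
            quat[3] = qtrial[3]
        step += 1
        _quat_to_mat(quat, R)
        energy = eval_field(pos, R, site_ref, site_q, phi, g_origin, g_h,
                            tail_pref, kappa, src_center, force, torque)
        dcx = pos[0] - nuc_center[0]
        dcy = pos[1] - nuc_center[1]
        dcz = pos[2] - nuc_center[2]
        c2c2 = dcx * dcx + dcy * dcy + dcz * dcz
        if c2c2 >= stop2:
            return ESCAPED, step, n_events, used
        if c2c2 < enc_c2c2:
            ddx = pos[0] - dyad_point[0]
            ddy = pos[1] - dyad_point[1]
            ddz = pos[2] - dyad_point[2]
            if ddx * ddx + ddy * ddy + ddz * ddz < enc_dyad2:
                ev_step[n_events] = step
                ev_energy[n_events] = energy
                ev_pos[n_events, 0] = pos[0]
                ev_pos[n_events, 1] = pos[1]
                ev_pos[n_events, 2] = pos[2]
                ev_quat[n_events, 0] = quat[0]
                ev_quat[n_events, 1] = quat[1]
                ev_quat[n_events, 2] = quat[2]
                ev_quat[n_events, 3] = quat[3]
                n_events += 1
        if step >= max_steps:
            return MAX_STEPS, step, n_events, used


# ---------------------------------------------------------------------------
# Recorded-set batch update


@njit(cache=False, inline="always")
def _cell_index(p, grid_lo, inv_cell, gdims):
    cx = int((p[0] - grid_lo[0]) * inv_cell)
    cy = int((p[1] - grid_lo[1]) * inv_cell)
    cz = int((p[2] - grid_lo[2]) * inv_cell)
    if cx < 0:
        cx = 0
    if cy < 0:
        cy = 0
    if cz < 0:
        cz = 0
    if cx >= gdims[0]:
        cx = gdims[0] - 1
    if cy >= gdims[1]:
        cy = gdims[1] - 1
    if cz >= gdims[2]:
        cz = gdims[2] - 1
    return (cx * gdims[1] + cy) * gdims[2] + cz, cx, cy, cz


@njit(cache=False, inline="always")
def _unlink(i, cell_head, cell_next, cell_of):
    c = cell_of[i]
    j = cell_head[c]
    if j == i:
        cell_head[c] = cell_next[i]
        return
    while cell_next[j] != i:
        j = cell_next[j]
    cell_next[j] = cell_next[i]


@njit(cache=False)
def process_events(
    ev_pos, ev_quat, ev_energy, ev_traj, ev_step,
    r_pos, r_quat, r_rot, r_rotS, r_energy, r_count, r_traj, r_step,
    cell_head, cell_next, cell_of,
    grid_lo, inv_cell, gdims,
    S, trS, natoms, dedup2, capacity,
    state,
):
    """Apply the recording/substitution/counting rules to an event batch.

    A candidate within the deduplication RMSD of an existing record either
    substitutes it (if lower in energy, inheriting its count + 1) or
    increments the count of the closest such record; otherwise it is added
    as a new record, evicting the least favorable one when the archive is
    at capacity and the candidate is more favorable.  ``state`` holds
    (number of records, total encounters seen).
    """
    Rc = np.empty((3, 3))
    RcS = np.empty((3, 3))
    inv_n = 1.0 / natoms
    for e in range(ev_pos.shape[0]):
        state[1] += 1
        px = ev_pos[e, 0]
        py = ev_pos[e, 1]
        pz = ev_pos[e, 2]
        _quat_to_mat(ev_quat[e], Rc)
        energy = ev_energy[e]
        # closest record within the dedup RMSD (ties: lower energy, lower slot)
        best_i = -1
        best_r2 = 1e300
        cid, cx, cy, cz = _cell_index(ev_pos[e], grid_lo, inv_cell, gdims)
        for ox in range(-1, 2):
            nxc = cx + ox
            if nxc < 0 or nxc >= gdims[0]:
                continue
            for oy in range(-1, 2):
                nyc = cy + oy
                if nyc < 0 or nyc >= gdims[1]:
                    continue
                for oz in range(-1, 2):
                    nzc = cz + oz
                    if nzc < 0 or nzc >= gdims[2]:
                        continue
                    c = (nxc * gdims[1] + nyc) * gdims[2] + nzc
                    i = cell_head[c]
                    while i != -1:
                        dx = px - r_pos[i, 0]
                        dy = py - r_pos[i, 1]
                        dz = pz - r_pos[i, 2]
                        dp2 = dx * dx + dy * dy + dz * dz
                        if dp2 <= dedup2:
                            rot = 0.0
                            for k in range(3):
                                for l in range(3):
                                    rot += Rc[k, l] * r_rotS[i, 3 * k + l]
                            r2 = dp2 + (2.0 * trS - 2.0 * rot) * inv_n
                            if r2 <= dedup2:
                                if (r2 < best_r2
                                        or (r2 == best_r2 and best_i != -1
                                            and (r_energy[i] < r_energy[best_i]
                                                 or (r_energy[i] == r_energy[best_i]
                                                     and i < best_i)))):
                                    best_r2 = r2
                                    best_i = i
                        i = cell_next[i]
        if best_i == -1:
            n = state[0]
            slot = -1
            if n < capacity:
                slot = n
                state[0] = n + 1
            else:
                worst = 0
                for i in range(1, n):
                    if r_energy[i] > r_energy[worst]:
                        worst = i
                if energy < r_energy[worst]:
                    _unlink(worst, cell_head, cell_next, cell_of)
                    slot = worst
            if slot >= 0:
                r_pos[slot, 0] = px
                r_pos[slot, 1] = py
                r_pos[slot, 2] = pz
                for k in range(4):
                    r_quat[slot, k] = ev_quat[e, k]
                for k in range(3):
                    for l in range(3):
                        r_rot[slot, 3 * k + l] = Rc[k, l]
                for k in range(3):
                    for l in range(3):
                        acc = 0.0
                        for m2 in range(3):
                            acc += Rc[k, m2] * S[m2, l]
                        r_rotS[slot, 3 * k + l] = acc
                r_energy[slot] = energy
                r_count[slot] = 1
                r_traj[slot] = ev_traj[e]
                r_step[slot] = ev_step[e]
                c2, _, _, _ = _cell_index(r_pos[slot], grid_lo, inv_cell, gdims)
                cell_of[slot] = c2
                cell_next[slot] = cell_head[c2]
                cell_head[c2] = slot
        else:
            if energy < r_energy[best_i]:
                # substitution: the better pose replaces its neighbor and
                # inherits the occurrence count
                _unlink(best_i, cell_head, cell_next, cell_of)
                r_pos[best_i, 0] = px
                r_pos[best_i, 1] = py
                r_pos[best_i, 2] = pz
                for k in range(4):
                    r_quat[best_i, k] = ev_quat[e, k]
                for k in range(3):
                    for l in range(3):
                        r_rot[best_i, 3 * k + l] = Rc[k, l]
                for k in range(3):
                    for l in range(3):
                        acc = 0.0
                        for m2 in range(3):
                            acc += Rc[k, m2] * S[m2, l]
                        r_rotS[best_i, 3 * k + l] = acc
                r_energy[best_i] = energy
                r_count[best_i] += 1
                r_traj[best_i] = ev_traj[e]
                r_step[best_i] = ev_step[e]
                c2, _, _, _ = _cell_index(r_pos[best_i], grid_lo, inv_cell, gdims)
                cell_of[best_i] = c2
                cell_next[best_i] = cell_head[c2]
                cell_head[c2] = best_i
            else:
                r_count[best_i] += 1
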