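"""Numba kernels for the single-molecule Metropolis Monte Carlo sampler.

The topology is packed into flat arrays by :mod:`cgmotor.sampler`; kernels
work entirely in nm / kJ mol^-1 / radians.  Moves are single-bead
displacements attempted in a fixed cyclic order over the mobile (real)
beads; beads tied to a constrained bond are moved by resampling the bond
direction at fixed length, so constraints hold exactly at every step.
Virtual sites that depend on a moved bead are rebuilt before the local
energy difference is evaluated.

All randomness flows through one ``numpy.random.Generator`` passed in by
the caller, so identical configurations give bit-identical chains.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STUCK = 1

#: consecutive-rejection count that declares a chain stuck
STUCK_LIMIT = 10_000


@njit(cache=False)
def _bond_e(t, coords, b_i, b_j, b_r0, b_k, b_cons):
    if b_cons[t]:
        return 0.0
    d = coords[b_j[t]] - coords[b_i[t]]
    r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    dr = r - b_r0[t]
    return 0.5 * b_k[t] * dr * dr


@njit(cache=False)
def _angle_e(t, coords, a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs):
    u = coords[a_i[t]] - coords[a_j[t]]
    v = coords[a_k[t]] - coords[a_j[t]]
    nu = np.sqrt(u[0] * u[0] + u[1] * u[1] + u[2] * u[2])
    nv = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    c = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = np.arccos(c)
    x = th - a_th0[t]
    if a_form[t] == 0:
        return 0.5 * a_kf[t] * x * x
    e = 0.0
    xp = 1.0
    for n in range(5):
        e += a_coeffs[t, n] * xp
        xp *= x
    return e


@njit(cache=False)
def _dih_e(t, coords, d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp):
    b1 = coords[d_j[t]] - coords[d_i[t]]
    b2 = coords[d_k[t]] - coords[d_j[t]]
    b3 = coords[d_l[t]] - coords[d_k[t]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
    m = np.cross(n1, n2)
    y = (m[0] * b2[0] + m[1] * b2[1] + m[2] * b2[2]) / nb2
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    phi = np.arctan2(y, x)
    return d_kp[t] * (1.0 + np.cos(d_n[t] * phi - d_phi0[t]))


@njit(cache=False)
def _place_vsites_for(b, coords, bead_vs_ptr, bead_vs_idx,
                      vs_site, vs_ptr, vs_cons, vs_w):
    for p in range(bead_vs_ptr[b], bead_vs_ptr[b + 1]):
        v = bead_vs_idx[p]
        s = vs_site[v]
        coords[s, 0] = 0.0
        coords[s, 1] = 0.0
        coords[s, 2] = 0.0
        for q in range(vs_ptr[v], vs_ptr[v + 1]):
            c = vs_cons[q]
            w = vs_w[q]
            coords[s, 0] += w * coords[c, 0]
            coords[s, 1] += w * coords[c, 1]
            coords[s, 2] += w * coords[c, 2]


@njit(cache=False)
def _local_energy(b, coords,
                  bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
                  bead_dh_ptr, bead_dh_idx,
                  b_i, b_j, b_r0, b_k, b_cons,
                  a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                  d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp):
    e = 0.0
    for p in range(bead_bond_ptr[b], bead_bond_ptr[b + 1]):
        e += _bond_e(bead_bond_idx[p], coords, b_i, b_j, b_r0, b_k, b_cons)
    for p in range(bead_ang_ptr[b], bead_ang_ptr[b + 1]):
        e += _angle_e(bead_ang_idx[p], coords, a_i, a_j, a_k, a_th0, a_kf,
                      a_form, a_coeffs)
    for p in range(bead_dh_ptr[b], bead_dh_ptr[b + 1]):
        e += _dih_e(bead_dh_idx[p], coords, d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)
    return e


@njit(cache=False)
def total_energy(coords, n_bonds, n_angles, n_dihterms,
                 b_i, b_j, b_r0, b_k, b_cons,
                 a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                 d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp):
    e = 0.0
    for t in range(n_bonds):
        e += _bond_e(t, coords, b_i, b_j, b_r0, b_k, b_cons)
    for t in range(n_angles):
        e += _angle_e(t, coords, a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs)
    for t in range(n_dihterms):
        e += _dih_e(t, coords, d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)
    return e


@njit(cache=False)
def _propose(b, coords, sigma, rng, cons_partner, cons_r0):
    """Displace bead b in place; constrained beads pivot about their partner."""
    p = cons_partner[b]
    if p < 0:
        coords[b, 0] += sigma * rng.standard_normal()
        coords[b, 1] += sigma * rng.standard_normal()
        coords[b, 2] += sigma * rng.standard_normal()
    else:
        r0 = cons_r0[b]
        ux = coords[b, 0] - coords[p, 0]
        uy = coords[b, 1] - coords[p, 1]
        uz = coords[b, 2] - coords[p, 2]
        nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
        s = sigma / r0
        ux = ux / nrm + s * rng.standard_normal()
        uy = uy / nrm + s * rng.standard_normal()
        uz = uz / nrm + s * rng.standard_normal()
        nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
        coords[b, 0] = coords[p, 0] + r0 * ux / nrm
        coords[b, 1] = coords[p, 1] + r0 * uy / nrm
        coords[b, 2] = coords[p, 2] + r0 * uz / nrm


@njit(cache=False)
def run_chain(coords, rng, n_steps, stride, burn_in, sigma_init, beta, adapt,
              mobile, cons_partner, cons_r0,
              b_i, b_j, b_r0, b_k, b_cons,
              a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
              d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp,
              vs_site, vs_ptr, vs_cons, vs_w,
              bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
              bead_dh_ptr, bead_dh_idx, bead_vs_ptr, bead_vs_idx,
              frames):
    """Metropolis chain; records ``frames`` every ``stride`` steps after
    ``burn_in``.  Returns (status, final_sigma, n_accepted)."""
    n_mobile = mobile.shape[0]
    n_vs = vs_site.shape[0]
    sigma = sigma_init
    n_acc = 0
    consec_rej = 0
    win_try = 0
    win_acc = 0
    frame_idx = 0
    old_b = np.empty(3)
    old_vs = np.empty((n_vs, 3))

    for step in range(n_steps):
        b = mobile[step % n_mobile]
        e_old = _local_energy(
            b, coords, bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
            bead_dh_ptr, bead_dh_idx, b_i, b_j, b_r0, b_k, b_cons,
            a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
            d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)
        old_b[:] = coords[b]
        for p in range(bead_vs_ptr[b], bead_vs_ptr[b + 1]):
            old_vs[bead_vs_idx[p]] = coords[vs_site[bead_vs_idx[p]]]

        _propose(b, coords, sigma, rng, cons_partner, cons_r0)
        _place_vsites_for(b, coords, bead_vs_ptr, bead_vs_idx,
                          vs_site, vs_ptr, vs_cons, vs_w)
        e_new = _local_energy(
            b, coords, bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
            bead_dh_ptr, bead_dh_idx, b_i, b_j, b_r0, b_k, b_cons,
            a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
            d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)

        de = e_new - e_old
        accept = de <= 0.0 or rng.random() < np.exp(-beta * de)
        if accept:
            n_acc += 1
            win_acc += 1
            consec_rej = 0
        else:
            coords[b] = old_b
            for p in range(bead_vs_ptr[b], bead_vs_ptr[b + 1]):
                coords[vs_site[bead_vs_idx[p]]] = old_vs[bead_vs_idx[p]]
            consec_rej += 1
            if consec_rej >= STUCK_LIMIT:
                return STATUS_STUCK, sigma, n_acc
        win_try += 1

        # move-size adaptation during burn-in only (target 40% +- 10%)
        if adapt and step < burn_in and win_try >= 200:
            rate = win_acc / win_try
            if rate < 0.3:
                sigma *= 0.9
            elif rate > 0.5:
                sigma *= 1.1
            if sigma < 1e-4:
                sigma = 1e-4
            elif sigma > 1.0:
                sigma = 1.0
            win_try = 0
            win_acc = 0

        if step >= burn_in and (step - burn_in) % stride == stride - 1:
            if frame_idx < frames.shape[0]:
                frames[frame_idx] = coords
                frame_idx += 1

    return STATUS_OK, sigma, n_acc


@njit(cache=False)
def _rotation_energy(coords, rotor, ref_rel, k_rot):
    """Isotropic restraint to a rotating reference, centred on the group's
    instantaneous centroid (pivot-free), no mass weighting."""
    n = rotor.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for m in range(n):
        cx += coords[rotor[m], 0]
        cy += coords[rotor[m], 1]
        cz += coords[rotor[m], 2]
    cx /= n
    cy /= n
    cz /= n
    e = 0.0
    for m in range(n):
        dx = ref_rel[m, 0] - (coords[rotor[m], 0] - cx)
        dy = ref_rel[m, 1] - (coords[rotor[m], 1] - cy)
        dz = ref_rel[m, 2] - (coords[rotor[m], 2] - cz)
        e += dx * dx + dy * dy + dz * dz
    return 0.5 * k_rot * e


@njit(cache=False)
def run_rotation(coords, rng, n_sweeps, stride, sigma, beta,
                 mobile, in_rotor, cons_partner, cons_r0,
                 b_i, b_j, b_r0, b_k, b_cons,
                 a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                 d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp,
                 vs_site, vs_ptr, vs_cons, vs_w,
                 bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
                 bead_dh_ptr, bead_dh_idx, bead_vs_ptr, bead_vs_idx,
                 rotor, ref_rel0, axis, rate, dt, k_rot,
                 frames, ref_angles):
    """Chain under the bonded potential plus an enforced-rotation restraint
    whose reference rotates rigidly about ``axis`` at ``rate`` rad/ps; one
    sweep (one attempted move per mobile bead) advances time by ``dt`` ps.
    Records a frame and the reference angle every ``stride`` sweeps."""
    n_mobile = mobile.shape[0]
    n_rotor = rotor.shape[0]
    n_vs = vs_site.shape[0]
    old_b = np.empty(3)
    old_vs = np.empty((n_vs, 3))
    ref_rel = np.empty((n_rotor, 3))
    frame_idx = 0
    n_acc = 0

    ux, uy, uz = axis[0], axis[1], axis[2]
    for sweep in range(n_sweeps):
        theta = rate * dt * sweep
        ct = np.cos(theta)
        st = np.sin(theta)
        # Rodrigues rotation of the initial relative reference positions
        for m in range(n_rotor):
            px, py, pz = ref_rel0[m, 0], ref_rel0[m, 1], ref_rel0[m, 2]
            dot = ux * px + uy * py + uz * pz
            crx = uy * pz - uz * py
            cry = uz * px - ux * pz
            crz = ux * py - uy * px
            ref_rel[m, 0] = px * ct + crx * st + ux * dot * (1.0 - ct)
            ref_rel[m, 1] = py * ct + cry * st + uy * dot * (1.0 - ct)
            ref_rel[m, 2] = pz * ct + crz * st + uz * dot * (1.0 - ct)

        for im in range(n_mobile):
            b = mobile[im]
            e_old = _local_energy(
                b, coords, bead_bond_ptr, bead_bond_idx, bead_ang_ptr,
                bead_ang_idx, bead_dh_ptr, bead_dh_idx,
                b_i, b_j, b_r0, b_k, b_cons,
                a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)
            if in_rotor[b]:
                e_old += _rotation_energy(coords, rotor, ref_rel, k_rot)
            old_b[:] = coords[b]
            for p in range(bead_vs_ptr[b], bead_vs_ptr[b + 1]):
                old_vs[bead_vs_idx[p]] = coords[vs_site[bead_vs_idx[p]]]

            _propose(b, coords, sigma, rng, cons_partner, cons_r0)
            _place_vsites_for(b, coords, bead_vs_ptr, bead_vs_idx,
                              vs_site, vs_ptr, vs_cons, vs_w)
            e_new = _local_energy(
                b, coords, bead_bond_ptr, bead_bond_idx, bead_ang_ptr,
                bead_ang_idx, bead_dh_ptr, bead_dh_idx,
                b_i, b_j, b_r0, b_k, b_cons,
                a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp)
            if in_rotor[b]:
                e_new += _rotation_energy(coords, rotor, ref_rel, k_rot)

            de = e_new - e_old
            if de <= 0.0 or rng.random() < np.exp(-beta * de):
                n_acc += 1
            else:
                coords[b] = old_b
                for p in range(bead_vs_ptr[b], bead_vs_ptr[b + 1]):
                    coords[vs_site[bead_vs_idx[p]]] = old_vs[bead_vs_idx[p]]

        if sweep % stride == stride - 1:
            if frame_idx < frames.shape[0]:
                frames[frame_idx] = coords
                ref_angles[frame_idx] = theta
                frame_idx += 1

    return n_acc
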