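"""Numba inner loops for the Langevin docking engine.

The force routine mirrors :func:`cgdock.energy.forces` term by term (the two
are cross-checked in the test suite); the integrator is a BAOAB-splitting
Langevin scheme with unit masses.  Excluded-volume pairs go through a
Verlet-style active list (skin 1.5 A, rebuilt every 50 steps — far more than
safe at the default timestep) since the short-ranged core is inert for
almost every pair almost all of the time.  All randomness comes from
numba's per-thread NumPy legacy RNG, seeded explicitly per replica, so
trajectories are reproducible independent of scheduling.
"""

import numpy as np
from numba import njit

NLIST_STRIDE = 50
NLIST_SKIN = 1.5


@njit(cache=True)
def _rebuild_rep_list(pos, rep_pairs, cutoff2, active):
    n_active = 0
    for p in range(rep_pairs.shape[0]):
        i, j = rep_pairs[p, 0], rep_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx * dx + dy * dy + dz * dz < cutoff2:
            active[n_active] = p
            n_active += 1
    return n_active


@njit(cache=True)
def compute_forces(pos, f,
                   bonds, bond_r0, bond_k,
                   contacts, contact_r0, eps_go, lj1210,
                   rep_pairs, rep_active, n_rep_active, sigma_rep, eps_rep,
                   elec_pairs, elec_coeff, lam,
                   wall_center, wall_radius, wall_k):
    f[:] = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        g = -2.0 * bond_k[b] * (r - bond_r0[b]) / r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    for c in range(contacts.shape[0]):
        i, j = contacts[c, 0], contacts[c, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        x2 = contact_r0[c] * contact_r0[c] / r2
        x4 = x2 * x2
        x10 = x4 * x4 * x2
        if lj1210:
            dudr_r = eps_go * 60.0 * x10 * (1.0 - x2) / r2       # (dU/dr)/r
        else:
            # sigma = r0 / 2^(1/6): sigma^2/r^2 = x2 / 2^(1/3)
            s2r = x2 / 1.2599210498948732
            s6 = s2r * s2r * s2r
            dudr_r = 4.0 * eps_go * (-12.0 * s6 * s6 + 6.0 * s6) / r2
        g = -dudr_r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    s2 = sigma_rep * sigma_rep
    for a in range(n_rep_active):
        p = rep_active[a]
        i, j = rep_pairs[p, 0], rep_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= s2:
            continue
        x2 = s2 / r2
        x4 = x2 * x2
        g = 12.0 * eps_rep * x4 * x4 * x4 / r2
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    for p in range(elec_pairs.shape[0]):
        i, j = elec_pairs[p, 0], elec_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u = elec_coeff[p] * np.exp(-r / lam) / r
        g = u * (1.0 / r + 1.0 / lam) / r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    if wall_k > 0.0:
        for i in range(pos.shape[0]):
            dx = pos[i, 0] - wall_center[0]
            dy = pos[i, 1] - wall_center[1]
            dz = pos[i, 2] - wall_center[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > wall_radius:
                g = -2.0 * wall_k * (r - wall_radius) / r
                f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz


@njit(cache=True)
def integrate_baoab(pos, vel, n_steps, save_stride, n_keep, dt, gamma, kT, seed,
                    bonds, bond_r0, bond_k,
                    contacts, contact_r0, eps_go, lj1210,
                    rep_pairs, sigma_rep, eps_rep,
                    elec_pairs, elec_coeff, lam,
                    wall_center, wall_radius, wall_k,
                    frames_out, ke_out):
    """BAOAB Langevin dynamics; keeps the last ``n_keep`` saved frames.

    Returns 0 on success, 1 on numerical blow-up (non-finite coordinates at
    a save point).  ``frames_out`` is (n_keep, n_beads, 3); ``ke_out`` holds
    the kinetic energy at each kept frame.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros_like(pos)
    rep_active = np.empty(rep_pairs.shape[0], dtype=np.int64)
    list_cut2 = (sigma_rep + NLIST_SKIN) ** 2
    n_rep_active = _rebuild_rep_list(pos, rep_pairs, list_cut2, rep_active)
    compute_forces(pos, f, bonds, bond_r0, bond_k, contacts, contact_r0, eps_go,
                   lj1210, rep_pairs, rep_active, n_rep_active, sigma_rep, eps_rep,
                   elec_pairs, elec_coeff, lam, wall_center, wall_radius, wall_k)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    total_saves = n_steps // save_stride
    first_kept = total_saves - n_keep
    save_idx = 0
    for step in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
                pos[i, d] += 0.5 * dt * vel[i, d]
        if (step + 1) % NLIST_STRIDE == 0:
            n_rep_active = _rebuild_rep_list(pos, rep_pairs, list_cut2, rep_active)
        compute_forces(pos, f, bonds, bond_r0, bond_k, contacts, contact_r0, eps_go,
                       lj1210, rep_pairs, rep_active, n_rep_active, sigma_rep, eps_rep,
                       elec_pairs, elec_coeff, lam, wall_center, wall_radius, wall_k)
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d]
        if (step + 1) % save_stride == 0:
            if save_idx >= first_kept:
                k = save_idx - first_kept
                ke = 0.0
                ok = True
                for i in range(n):
                    for d in range(3):
                        frames_out[k, i, d] = pos[i, d]
                        ke += 0.5 * vel[i, d] * vel[i, d]
                        if not np.isfinite(pos[i, d]):
                            ok = False
                ke_out[k] = ke
                if not ok:
                    return 1
            save_idx += 1
    return 0
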