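"""Numba kernels for Kern-Frenkel Monte Carlo.

All kernels operate on plain arrays:

* ``pos`` (N, 3) particle centers, ``quat`` (N, 4) unit quaternions (w, x,
  y, z), ``spec`` (N,) species indices;
* design arrays: ``npatch`` (S,) patch counts, ``pvec`` (S, Pmax, 3) body-
  frame patch unit vectors, ``ptype`` (S, Pmax) global patch-type indices,
  ``eps`` (n_types, n_types) bonding energies;
* Kern-Frenkel geometry as scalars ``sigma2``, ``rc2`` (= (sigma+delta)^2),
  ``costh``.

Boxes are cubic and periodic; energies are in units of the reference bond
energy, temperatures in the same units (k_B = 1).  Hard-core overlaps are
represented by the finite penalty ``BIG`` so that trial-energy arithmetic
stays NaN-free; any state with E >= BIG/2 is rejected.

Randomness comes from numba's internal per-thread RNG, seeded explicitly
via ``seed_rng`` before every kernel chunk by the Python driver.
"""

import numpy as np
from numba import njit

BIG = 1.0e30


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _rot(qw, qx, qy, qz, vx, vy, vz):
    # rotate body-frame vector v by unit quaternion q
    tx = 2.0 * (qy * vz - qz * vy)
    ty = 2.0 * (qz * vx - qx * vz)
    tz = 2.0 * (qx * vy - qy * vx)
    rx = vx + qw * tx + (qy * tz - qz * ty)
    ry = vy + qw * ty + (qz * tx - qx * tz)
    rz = vz + qw * tz + (qx * ty - qy * tx)
    return rx, ry, rz


@njit(cache=False, inline="always")
def _rand_unit_quat():
    # Shoemake's uniform random rotation
    u1 = np.random.random()
    u2 = np.random.random()
    u3 = np.random.random()
    a = np.sqrt(1.0 - u1)
    b = np.sqrt(u1)
    return (
        a * np.sin(2.0 * np.pi * u2),
        a * np.cos(2.0 * np.pi * u2),
        b * np.sin(2.0 * np.pi * u3),
        b * np.cos(2.0 * np.pi * u3),
    )


@njit(cache=False, inline="always")
def _perturb_quat(qw, qx, qy, qz, max_angle):
    # small rotation about a random axis composed onto q
    gx = np.random.standard_normal()
    gy = np.random.standard_normal()
    gz = np.random.standard_normal()
    gn = np.sqrt(gx * gx + gy * gy + gz * gz)
    if gn < 1e-12:
        return qw, qx, qy, qz
    ang = (2.0 * np.random.random() - 1.0) * max_angle
    s = np.sin(0.5 * ang) / gn
    c = np.cos(0.5 * ang)
    dw, dx, dy, dz = c, s * gx, s * gy, s * gz
    # q' = dq * q
    nw = dw * qw - dx * qx - dy * qy - dz * qz
    nx = dw * qx + dx * qw + dy * qz - dz * qy
    ny = dw * qy - dx * qz + dy * qw + dz * qx
    nz = dw * qz + dx * qy - dy * qx + dz * qw
    n = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    return nw / n, nx / n, ny / n, nz / n


@njit(cache=False)
def pair_energy_kernel(
    dx, dy, dz, qi, qj, si, sj, npatch, pvec, ptype, eps, sigma2, rc2, costh
):
    """Kern-Frenkel pair energy for separation r_j - r_i (already min-imaged)."""
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < sigma2:
        return BIG
    if r2 >= rc2:
        return 0.0
    inv = 1.0 / np.sqrt(r2)
    ux, uy, uz = dx * inv, dy * inv, dz * inv
    e = 0.0
    for a in range(npatch[si]):
        pax, pay, paz = _rot(
            qi[0], qi[1], qi[2], qi[3], pvec[si, a, 0], pvec[si, a, 1], pvec[si, a, 2]
        )
        if ux * pax + uy * pay + uz * paz > costh:
            ta = ptype[si, a]
            for b in range(npatch[sj]):
                if eps[ta, ptype[sj, b]] > 0.0:
                    pbx, pby, pbz = _rot(
                        qj[0],
                        qj[1],
                        qj[2],
                        qj[3],
                        pvec[sj, b, 0],
                        pvec[sj, b, 1],
                        pvec[sj, b, 2],
                    )
                    if -(ux * pbx + uy * pby + uz * pbz) > costh:
                        e -= eps[ta, ptype[sj, b]]
    return e


@njit(cache=False)
def particle_energy(
    i, xi, yi, zi, qi, si, pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh
):
    """Energy of a (possibly trial) particle at (xi, yi, zi, qi, si) with all
    particles j != i currently in the box."""
    e = 0.0
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        dz = pos[j, 2] - zi
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        e += pair_energy_kernel(
            dx, dy, dz, qi, quat[j], si, spec[j], npatch, pvec, ptype, eps, sigma2, rc2, costh
        )
        if e >= 0.5 * BIG:
            return BIG
    return e


@njit(cache=False)
def total_energy(pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh):
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
            e += pair_energy_kernel(
                dx, dy, dz, quat[i], quat[j], spec[i], spec[j],
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if e >= 0.5 * BIG:
                return BIG
    return e


# ---------------------------------------------------------------------------
# single-box elementary moves (operate in place, return (accepted, dE))


@njit(cache=False)
def _try_displace(
    pos, quat, spec, n, L, beta, maxd, npatch, pvec, ptype, eps, sigma2, rc2, costh
):
    i = int(np.random.random() * n)
    e_old = particle_energy(
        i, pos[i, 0], pos[i, 1], pos[i, 2], quat[i], spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    xi = pos[i, 0] + (np.random.random() - 0.5) * maxd
    yi = pos[i, 1] + (np.random.random() - 0.5) * maxd
    zi = pos[i, 2] + (np.random.random() - 0.5) * maxd
    xi -= L * np.floor(xi / L)
    yi -= L * np.floor(yi / L)
    zi -= L * np.floor(zi / L)
    e_new = particle_energy(
        i, xi, yi, zi, quat[i], spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    de = e_new - e_old
    if de <= 0.0 or np.random.random() < np.exp(-beta * de):
        pos[i, 0], pos[i, 1], pos[i, 2] = xi, yi, zi
        return True, de
    return False, 0.0


@njit(cache=False)
def _try_rotate(
    pos, quat, spec, n, L, beta, maxang, npatch, pvec, ptype, eps, sigma2, rc2, costh
):
    i = int(np.random.random() * n)
    e_old = particle_energy(
        i, pos[i, 0], pos[i, 1], pos[i, 2], quat[i], spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    qn = np.empty(4)
    qn[0], qn[1], qn[2], qn[3] = _perturb_quat(
        quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3], maxang
    )
    e_new = particle_energy(
        i, pos[i, 0], pos[i, 1], pos[i, 2], qn, spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    de = e_new - e_old
    if de <= 0.0 or np.random.random() < np.exp(-beta * de):
        quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3] = qn[0], qn[1], qn[2], qn[3]
        return True, de
    return False, 0.0


@njit(cache=False, inline="always")
def _sample_cone(ux, uy, uz, costh):
    # uniform direction within the cone of half-width acos(costh) about u
    c = costh + np.random.random() * (1.0 - costh)
    s = np.sqrt(max(0.0, 1.0 - c * c))
    ph = 2.0 * np.pi * np.random.random()
    # orthonormal frame around u
    if abs(ux) < 0.9:
        e1x, e1y, e1z = 0.0, -uz, uy
    else:
        e1x, e1y, e1z = -uz, 0.0, ux
    nrm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / nrm, e1y / nrm, e1z / nrm
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    cp, sp = np.cos(ph), np.sin(ph)
    dx = c * ux + s * (cp * e1x + sp * e2x)
    dy = c * uy + s * (cp * e1y + sp * e2y)
    dz = c * uz + s * (cp * e1z + sp * e2z)
    return dx, dy, dz


@njit(cache=False, inline="always")
def _quat_mul(aw, ax, ay, az, bw, bx, by, bz):
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


@njit(cache=False)
def _orientation_with_patch_along(pb, dx, dy, dz):
    """Unit quaternion rotating body-frame patch vector pb onto world
    direction d, with a uniform random spin about d."""
    vx, vy, vz = pb[0], pb[1], pb[2]
    dot = vx * dx + vy * dy + vz * dz
    if dot < -1.0 + 1e-12:
        # antiparallel: rotate pi about any axis perpendicular to v
        if abs(vx) < 0.9:
            ax, ay, az = 0.0, -vz, vy
        else:
            ax, ay, az = -vz, 0.0, vx
        nrm = np.sqrt(ax * ax + ay * ay + az * az)
        qw, qx, qy, qz = 0.0, ax / nrm, ay / nrm, az / nrm
    else:
        cx = vy * dz - vz * dy
        cy = vz * dx - vx * dz
        cz = vx * dy - vy * dx
        qw, qx, qy, qz = 1.0 + dot, cx, cy, cz
        nrm = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw, qx, qy, qz = qw / nrm, qx / nrm, qy / nrm, qz / nrm
    ang = 2.0 * np.pi * np.random.random()
    c = np.cos(0.5 * ang)
    s = np.sin(0.5 * ang)
    sw, sx, sy, sz = c, s * dx, s * dy, s * dz
    return _quat_mul(sw, sx, sy, sz, qw, qx, qy, qz)


@njit(cache=False, inline="always")
def _back_aligned_count(q, si, dx, dy, dz, npatch, pvec, costh):
    """Number of patches of a particle at j->k direction (dx,dy,dz) (unit)
    pointing back at j within the patch cone."""
    cnt = 0
    for b in range(npatch[si]):
        px, py, pz = _rot(
            q[0], q[1], q[2], q[3], pvec[si, b, 0], pvec[si, b, 1], pvec[si, b, 2]
        )
        if -(px * dx + py * dy + pz * dz) > costh:
            cnt += 1
    return cnt


@njit(cache=False)
def _try_avb(
    pos, quat, spec, n, L, beta, sigma, rc, npatch, pvec, ptype, eps, sigma2, rc2, costh
):
    """Symmetric AVBMC in/out move on the radial bonding shell of a random
    target particle j, with orientation-biased insertion.

    The "in" region of j is the spherical shell sigma <= r < sigma + delta
    around j (volume V_in); "out" is the rest of the box.  In-moves place
    the particle uniformly in the shell and draw its orientation so that a
    uniformly chosen patch points back at j within the patch cone (uniform
    spin about that axis); out-moves place it uniformly outside with a
    uniform random orientation.  The proposal-density ratio of the biased
    orientation — Gamma_k * (1 - cos θmax)/2 divided by the number of
    back-aligned patches — enters the acceptance explicitly, so the pair
    of moves satisfies detailed balance exactly.  Without the bias the
    alignment probability of a narrow patch makes bond formation
    prohibitively rare.
    """
    if n < 2:
        return False, 0.0
    j = int(np.random.random() * n)
    sj = spec[j]
    V = L * L * L
    # in-region: union of j's patch cone-shells (volume Gamma_j * v_shell *
    # (1 - cos θmax)/2); cones are disjoint for well-separated patches
    vshell = 4.0 * np.pi / 3.0 * (rc**3 - sigma**3)
    vin = npatch[sj] * vshell * (1.0 - costh) / 2.0
    n_in = 0
    for k in range(n):
        if k == j:
            continue
        dx = pos[k, 0] - pos[j, 0]
        dy = pos[k, 1] - pos[j, 1]
        dz = pos[k, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            ri = 1.0 / np.sqrt(r2)
            if _back_aligned_count(
                quat[j], sj, -dx * ri, -dy * ri, -dz * ri, npatch, pvec, costh
            ) > 0:
                n_in += 1
    n_out = n - 1 - n_in
    to_in = np.random.random() < 0.5
    if to_in:
        if n_out == 0:
            return False, 0.0
        # choose the m-th "out" particle
        m = int(np.random.random() * n_out)
    else:
        if n_in == 0:
            return False, 0.0
        m = int(np.random.random() * n_in)
    k_sel = -1
    count = 0
    for k in range(n):
        if k == j:
            continue
        dx = pos[k, 0] - pos[j, 0]
        dy = pos[k, 1] - pos[j, 1]
        dz = pos[k, 2] - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        inside = False
        if r2 < rc2:
            ri = 1.0 / np.sqrt(r2)
            inside = _back_aligned_count(
                quat[j], sj, -dx * ri, -dy * ri, -dz * ri, npatch, pvec, costh
            ) > 0
        if inside == to_in:
            continue
        if count == m:
            k_sel = k
            break
        count += 1
    if k_sel < 0:
        return False, 0.0
    i = k_sel
    si = spec[i]
    afac = npatch[si] * (1.0 - costh) / 2.0  # biased-orientation density factor
    e_old = particle_energy(
        i, pos[i, 0], pos[i, 1], pos[i, 2], quat[i], spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    qn = np.empty(4)
    if to_in:
        # uniform point in the cone-shell of a uniformly chosen patch of j
        a = int(np.random.random() * npatch[sj])
        pax, pay, paz = _rot(
            quat[j, 0], quat[j, 1], quat[j, 2], quat[j, 3],
            pvec[sj, a, 0], pvec[sj, a, 1], pvec[sj, a, 2],
        )
        ux, uy, uz = _sample_cone(pax, pay, paz, costh)  # j -> k direction
        r = (sigma**3 + np.random.random() * (rc**3 - sigma**3)) ** (1.0 / 3.0)
        xi = pos[j, 0] + r * ux
        yi = pos[j, 1] + r * uy
        zi = pos[j, 2] + r * uz
        # orientation biased so a random patch of k points back at j
        b = int(np.random.random() * npatch[si])
        ddx, ddy, ddz = _sample_cone(-ux, -uy, -uz, costh)
        qw, qx, qy, qz = _orientation_with_patch_along(pvec[si, b], ddx, ddy, ddz)
        qn[0], qn[1], qn[2], qn[3] = qw, qx, qy, qz
        cnt = _back_aligned_count(qn, si, ux, uy, uz, npatch, pvec, costh)
        if cnt < 1:
            cnt = 1
        # out-proposals are uniform over the whole box (rejected inside the
        # in-region), so the out-state proposal density is 1/V, not 1/(V-vin)
        pref = n_out * vin / ((n_in + 1.0) * V) * afac / cnt
    else:
        # current orientation must be proposable by the reverse in-move
        dxo = pos[i, 0] - pos[j, 0]
        dyo = pos[i, 1] - pos[j, 1]
        dzo = pos[i, 2] - pos[j, 2]
        dxo -= L * np.rint(dxo / L)
        dyo -= L * np.rint(dyo / L)
        dzo -= L * np.rint(dzo / L)
        ro = np.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
        cnt_old = _back_aligned_count(
            quat[i], si, dxo / ro, dyo / ro, dzo / ro, npatch, pvec, costh
        )
        if cnt_old == 0:
            return False, 0.0
        # uniform point in the box, rejected only if it lands back inside
        # the angular in-region of j
        xi = np.random.random() * L
        yi = np.random.random() * L
        zi = np.random.random() * L
        dx = xi - pos[j, 0]
        dy = yi - pos[j, 1]
        dz = zi - pos[j, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        r2n = dx * dx + dy * dy + dz * dz
        if r2n < rc2 and r2n > 0.0:
            ri = 1.0 / np.sqrt(r2n)
            if _back_aligned_count(
                quat[j], sj, -dx * ri, -dy * ri, -dz * ri, npatch, pvec, costh
            ) > 0:
                return False, 0.0
        qn[0], qn[1], qn[2], qn[3] = _rand_unit_quat()
        pref = n_in * V / ((n_out + 1.0) * vin) * cnt_old / afac
    xi -= L * np.floor(xi / L)
    yi -= L * np.floor(yi / L)
    zi -= L * np.floor(zi / L)
    e_new = particle_energy(
        i, xi, yi, zi, qn, spec[i],
        pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
    )
    if e_new >= 0.5 * BIG:
        return False, 0.0
    de = e_new - e_old
    if np.random.random() < pref * np.exp(-beta * de):
        pos[i, 0], pos[i, 1], pos[i, 2] = xi, yi, zi
        quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3] = qn[0], qn[1], qn[2], qn[3]
        return True, de
    return False, 0.0


# ---------------------------------------------------------------------------
# ensemble chunk drivers


@njit(cache=False)
def run_nvt_chunk(
    pos, quat, spec, n, L, T, e0, n_moves,
    p_rot, p_avb, maxd, maxang, sigma, rc,
    npatch, pvec, ptype, eps, sigma2, rc2, costh, seed,
):
    """n_moves of translate/rotate/AVB at fixed (N, V, T). Returns
    (energy, n_accepted)."""
    np.random.seed(seed)
    beta = 1.0 / T
    e = e0
    acc = 0
    for _ in range(n_moves):
        u = np.random.random()
        if u < p_avb:
            ok, de = _try_avb(
                pos, quat, spec, n, L, beta, sigma, rc,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
        elif u < p_avb + p_rot:
            ok, de = _try_rotate(
                pos, quat, spec, n, L, beta, maxang,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
        else:
            ok, de = _try_displace(
                pos, quat, spec, n, L, beta, maxd,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
        if ok:
            e += de
            acc += 1
    return e, acc


@njit(cache=False)
def run_npt_chunk(
    pos, quat, spec, n, L, T, P, e0, n_moves,
    p_rot, p_avb, p_vol, maxd, maxang, max_lnv, sigma, rc,
    npatch, pvec, ptype, eps, sigma2, rc2, costh, seed,
):
    """n_moves at fixed (N, P, T) with log-volume moves. Returns
    (energy, L, n_accepted, n_vol_accepted)."""
    np.random.seed(seed)
    beta = 1.0 / T
    e = e0
    acc = 0
    accv = 0
    for _ in range(n_moves):
        u = np.random.random()
        if u < p_vol:
            V = L * L * L
            lnv = np.log(V) + (np.random.random() - 0.5) * max_lnv
            Vn = np.exp(lnv)
            s = (Vn / V) ** (1.0 / 3.0)
            Ln = L * s
            for i in range(n):
                pos[i, 0] *= s
                pos[i, 1] *= s
                pos[i, 2] *= s
            en = total_energy(
                pos, quat, spec, n, Ln, npatch, pvec, ptype, eps, sigma2, rc2, costh
            )
            arg = -beta * (en - e) - beta * P * (Vn - V) + (n + 1.0) * np.log(Vn / V)
            if en < 0.5 * BIG and (arg >= 0.0 or np.random.random() < np.exp(arg)):
                e = en
                L = Ln
                accv += 1
            else:
                inv = 1.0 / s
                for i in range(n):
                    pos[i, 0] *= inv
                    pos[i, 1] *= inv
                    pos[i, 2] *= inv
        elif u < p_vol + p_avb:
            ok, de = _try_avb(
                pos, quat, spec, n, L, beta, sigma, rc,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
                acc += 1
        elif u < p_vol + p_avb + p_rot:
            ok, de = _try_rotate(
                pos, quat, spec, n, L, beta, maxang,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
                acc += 1
        else:
            ok, de = _try_displace(
                pos, quat, spec, n, L, beta, maxd,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
                acc += 1
    return e, L, acc, accv


@njit(cache=False)
def run_gcmc_chunk(
    pos, quat, spec, n, cap, L, T, mu, e0, n_moves,
    p_rot, p_avb, p_exch, maxd, maxang, sigma, rc,
    npatch, pvec, ptype, eps, sigma2, rc2, costh, seed,
):
    """Grand-canonical chunk: displacement/rotation/AVB plus insertion and
    deletion with per-species chemical potentials ``mu``.  Returns
    (n, energy, n_ins_acc, n_del_acc)."""
    np.random.seed(seed)
    beta = 1.0 / T
    V = L * L * L
    nspecies = len(mu)
    e = e0
    ins = 0
    dels = 0
    for _ in range(n_moves):
        u = np.random.random()
        if u < p_exch:
            s = int(np.random.random() * nspecies)
            ns = 0
            for k in range(n):
                if spec[k] == s:
                    ns += 1
            if np.random.random() < 0.5:
                # insertion
                if n >= cap:
                    continue
                xi = np.random.random() * L
                yi = np.random.random() * L
                zi = np.random.random() * L
                qn = np.empty(4)
                qn[0], qn[1], qn[2], qn[3] = _rand_unit_quat()
                de = particle_energy(
                    n, xi, yi, zi, qn, s,
                    pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                if de >= 0.5 * BIG:
                    continue
                arg = beta * mu[s] - beta * de + np.log(V / (ns + 1.0))
                if arg >= 0.0 or np.random.random() < np.exp(arg):
                    pos[n, 0], pos[n, 1], pos[n, 2] = xi, yi, zi
                    quat[n, 0], quat[n, 1], quat[n, 2], quat[n, 3] = (
                        qn[0], qn[1], qn[2], qn[3],
                    )
                    spec[n] = s
                    n += 1
                    e += de
                    ins += 1
            else:
                # deletion
                if ns == 0:
                    continue
                m = int(np.random.random() * ns)
                i = -1
                count = 0
                for k in range(n):
                    if spec[k] == s:
                        if count == m:
                            i = k
                            break
                        count += 1
                de = -particle_energy(
                    i, pos[i, 0], pos[i, 1], pos[i, 2], quat[i], spec[i],
                    pos, quat, spec, n, L, npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                arg = -beta * mu[s] - beta * de + np.log(ns / V)
                if arg >= 0.0 or np.random.random() < np.exp(arg):
                    # swap-delete
                    pos[i, 0], pos[i, 1], pos[i, 2] = pos[n - 1, 0], pos[n - 1, 1], pos[n - 1, 2]
                    quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3] = (
                        quat[n - 1, 0], quat[n - 1, 1], quat[n - 1, 2], quat[n - 1, 3],
                    )
                    spec[i] = spec[n - 1]
                    n -= 1
                    e += de
                    dels += 1
        elif u < p_exch + p_avb and n >= 2:
            ok, de = _try_avb(
                pos, quat, spec, n, L, beta, sigma, rc,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
        elif u < p_exch + p_avb + p_rot and n >= 1:
            ok, de = _try_rotate(
                pos, quat, spec, n, L, beta, maxang,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
        elif n >= 1:
            ok, de = _try_displace(
                pos, quat, spec, n, L, beta, maxd,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            if ok:
                e += de
    return n, e, ins, dels


@njit(cache=False)
def run_gibbs_chunk(
    pos_a, quat_a, spec_a, na, La,
    pos_b, quat_b, spec_b, nb, Lb,
    T, ea0, eb0, n_moves,
    p_rot, p_avb, p_vol, p_transfer, p_swap,
    maxd, maxang, max_dzeta, sigma, rc,
    npatch, pvec, ptype, eps, sigma2, rc2, costh, seed,
):
    """Gibbs-ensemble chunk over two boxes.

    Moves: intra-box displacement/rotation/AVB, volume exchange in
    ln(Va/Vb) at fixed total volume, species-preserving particle transfer
    with orientation resampling, and identity swaps (one particle per box
    of different species exchange species labels, equivalent to a
    simultaneous A/B counter-transfer).  N_total and V_total are conserved
    exactly.  Returns (na, La, ea, nb, Lb, eb, acc_transfer, acc_vol,
    acc_swap).
    """
    np.random.seed(seed)
    beta = 1.0 / T
    ea = ea0
    eb = eb0
    acc_tr = 0
    acc_v = 0
    acc_sw = 0
    vtot = La**3 + Lb**3
    for _ in range(n_moves):
        u = np.random.random()
        if u < p_vol:
            Va = La**3
            Vb = Lb**3
            zeta = np.log(Va / Vb) + (np.random.random() - 0.5) * max_dzeta
            ez = np.exp(zeta)
            Van = vtot * ez / (1.0 + ez)
            Vbn = vtot - Van
            sa = (Van / Va) ** (1.0 / 3.0)
            sb = (Vbn / Vb) ** (1.0 / 3.0)
            Lan = La * sa
            Lbn = Lb * sb
            for i in range(na):
                pos_a[i, 0] *= sa
                pos_a[i, 1] *= sa
                pos_a[i, 2] *= sa
            for i in range(nb):
                pos_b[i, 0] *= sb
                pos_b[i, 1] *= sb
                pos_b[i, 2] *= sb
            ean = total_energy(
                pos_a, quat_a, spec_a, na, Lan, npatch, pvec, ptype, eps, sigma2, rc2, costh
            )
            ebn = total_energy(
                pos_b, quat_b, spec_b, nb, Lbn, npatch, pvec, ptype, eps, sigma2, rc2, costh
            )
            arg = (
                -beta * (ean - ea + ebn - eb)
                + (na + 1.0) * np.log(Van / Va)
                + (nb + 1.0) * np.log(Vbn / Vb)
            )
            if (
                ean < 0.5 * BIG
                and ebn < 0.5 * BIG
                and (arg >= 0.0 or np.random.random() < np.exp(arg))
            ):
                La, Lb, ea, eb = Lan, Lbn, ean, ebn
                acc_v += 1
            else:
                inva = 1.0 / sa
                invb = 1.0 / sb
                for i in range(na):
                    pos_a[i, 0] *= inva
                    pos_a[i, 1] *= inva
                    pos_a[i, 2] *= inva
                for i in range(nb):
                    pos_b[i, 0] *= invb
                    pos_b[i, 1] *= invb
                    pos_b[i, 2] *= invb
        elif u < p_vol + p_transfer:
            a_to_b = np.random.random() < 0.5
            if a_to_b:
                if na == 0:
                    continue
                i = int(np.random.random() * na)
                e_rem = particle_energy(
                    i, pos_a[i, 0], pos_a[i, 1], pos_a[i, 2], quat_a[i], spec_a[i],
                    pos_a, quat_a, spec_a, na, La,
                    npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                xi = np.random.random() * Lb
                yi = np.random.random() * Lb
                zi = np.random.random() * Lb
                qn = np.empty(4)
                qn[0], qn[1], qn[2], qn[3] = _rand_unit_quat()
                e_ins = particle_energy(
                    nb, xi, yi, zi, qn, spec_a[i],
                    pos_b, quat_b, spec_b, nb, Lb,
                    npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                if e_ins >= 0.5 * BIG:
                    continue
                arg = -beta * (e_ins - e_rem) + np.log(
                    na * Lb**3 / ((nb + 1.0) * La**3)
                )
                if arg >= 0.0 or np.random.random() < np.exp(arg):
                    pos_b[nb, 0], pos_b[nb, 1], pos_b[nb, 2] = xi, yi, zi
                    quat_b[nb, 0], quat_b[nb, 1], quat_b[nb, 2], quat_b[nb, 3] = (
                        qn[0], qn[1], qn[2], qn[3],
                    )
                    spec_b[nb] = spec_a[i]
                    nb += 1
                    eb += e_ins
                    ea -= e_rem
                    pos_a[i, 0], pos_a[i, 1], pos_a[i, 2] = (
                        pos_a[na - 1, 0], pos_a[na - 1, 1], pos_a[na - 1, 2],
                    )
                    quat_a[i, 0], quat_a[i, 1], quat_a[i, 2], quat_a[i, 3] = (
                        quat_a[na - 1, 0], quat_a[na - 1, 1],
                        quat_a[na - 1, 2], quat_a[na - 1, 3],
                    )
                    spec_a[i] = spec_a[na - 1]
                    na -= 1
                    acc_tr += 1
            else:
                if nb == 0:
                    continue
                i = int(np.random.random() * nb)
                e_rem = particle_energy(
                    i, pos_b[i, 0], pos_b[i, 1], pos_b[i, 2], quat_b[i], spec_b[i],
                    pos_b, quat_b, spec_b, nb, Lb,
                    npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                xi = np.random.random() * La
                yi = np.random.random() * La
                zi = np.random.random() * La
                qn = np.empty(4)
                qn[0], qn[1], qn[2], qn[3] = _rand_unit_quat()
                e_ins = particle_energy(
                    na, xi, yi, zi, qn, spec_b[i],
                    pos_a, quat_a, spec_a, na, La,
                    npatch, pvec, ptype, eps, sigma2, rc2, costh,
                )
                if e_ins >= 0.5 * BIG:
                    continue
                arg = -beta * (e_ins - e_rem) + np.log(
                    nb * La**3 / ((na + 1.0) * Lb**3)
                )
                if arg >= 0.0 or np.random.random() < np.exp(arg):
                    pos_a[na, 0], pos_a[na, 1], pos_a[na, 2] = xi, yi, zi
                    quat_a[na, 0], quat_a[na, 1], quat_a[na, 2], quat_a[na, 3] = (
                        qn[0], qn[1], qn[2], qn[3],
                    )
                    spec_a[na] = spec_b[i]
                    na += 1
                    ea += e_ins
                    eb -= e_rem
                    pos_b[i, 0], pos_b[i, 1], pos_b[i, 2] = (
                        pos_b[nb - 1, 0], pos_b[nb - 1, 1], pos_b[nb - 1, 2],
                    )
                    quat_b[i, 0], quat_b[i, 1], quat_b[i, 2], quat_b[i, 3] = (
                        quat_b[nb - 1, 0], quat_b[nb - 1, 1],
                        quat_b[nb - 1, 2], quat_b[nb - 1, 3],
                    )
                    spec_b[i] = spec_b[nb - 1]
                    nb -= 1
                    acc_tr += 1
        elif u < p_vol + p_transfer + p_swap:
            if na == 0 or nb == 0:
                continue
            i = int(np.random.random() * na)
            j = int(np.random.random() * nb)
            si, sj = spec_a[i], spec_b[j]
            if si == sj:
                continue
            ea_old = particle_energy(
                i, pos_a[i, 0], pos_a[i, 1], pos_a[i, 2], quat_a[i], si,
                pos_a, quat_a, spec_a, na, La,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            ea_new = particle_energy(
                i, pos_a[i, 0], pos_a[i, 1], pos_a[i, 2], quat_a[i], sj,
                pos_a, quat_a, spec_a, na, La,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            eb_old = particle_energy(
                j, pos_b[j, 0], pos_b[j, 1], pos_b[j, 2], quat_b[j], sj,
                pos_b, quat_b, spec_b, nb, Lb,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            eb_new = particle_energy(
                j, pos_b[j, 0], pos_b[j, 1], pos_b[j, 2], quat_b[j], si,
                pos_b, quat_b, spec_b, nb, Lb,
                npatch, pvec, ptype, eps, sigma2, rc2, costh,
            )
            de = (ea_new - ea_old) + (eb_new - eb_old)
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                spec_a[i] = sj
                spec_b[j] = si
                ea += ea_new - ea_old
                eb += eb_new - eb_old
                acc_sw += 1
        else:
            in_a = np.random.random() < 0.5 * (1.0 + (na - nb) / max(na + nb, 1))
            # choose box proportionally to particle number for uniform per-
            # particle attempt rates
            if in_a and na == 0:
                in_a = False
            if (not in_a) and nb == 0:
                continue
            v = np.random.random()
            if in_a:
                if v < p_avb:
                    ok, de = _try_avb(
                        pos_a, quat_a, spec_a, na, La, beta, sigma, rc,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                elif v < p_avb + p_rot:
                    ok, de = _try_rotate(
                        pos_a, quat_a, spec_a, na, La, beta, maxang,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                else:
                    ok, de = _try_displace(
                        pos_a, quat_a, spec_a, na, La, beta, maxd,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                if ok:
                    ea += de
            else:
                if v < p_avb:
                    ok, de = _try_avb(
                        pos_b, quat_b, spec_b, nb, Lb, beta, sigma, rc,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                elif v < p_avb + p_rot:
                    ok, de = _try_rotate(
                        pos_b, quat_b, spec_b, nb, Lb, beta, maxang,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                else:
                    ok, de = _try_displace(
                        pos_b, quat_b, spec_b, nb, Lb, beta, maxd,
                        npatch, pvec, ptype, eps, sigma2, rc2, costh,
                    )
                if ok:
                    eb += de
    return na, La, ea, nb, Lb, eb, acc_tr, acc_v, acc_sw
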