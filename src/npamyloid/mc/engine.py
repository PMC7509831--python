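"""Numba kernels for the bead-chain / nanoparticle Metropolis Monte Carlo engine.

The engine operates on flat numpy arrays so that the whole production loop can
be jitted.  All randomness flows through an explicit xoshiro256++ state (a
4-word uint64 array), which makes every trajectory bit-reproducible for a
given seed and lets the Python-level move API and the fused run kernel share
one stream.

Conventions
-----------
* positions are stored *unwrapped*; every pair interaction uses the
  minimum-image distance, so representatives may drift outside the box.
* a hydrogen bond is an unordered inter-chain bead pair; the registry is kept
  symmetrically in ``partner``/``bond_count`` (swap-delete on removal).
* move types: 0 = pivot, 1 = crankshaft, 2 = kink-jump, 3 = translation.
* a proposal that moves no bead (pivot at a chain end, degenerate crankshaft
  axis) is a null move: accepted, changes nothing.
"""

import numpy as np
from numba import njit

U64 = np.uint64

TWO_PI = 6.283185307179586

# ---------------------------------------------------------------------------
# RNG: xoshiro256++ seeded through splitmix64
# ---------------------------------------------------------------------------


@njit(cache=True)
def rng_new(seed):
    state = np.empty(4, dtype=np.uint64)
    z = U64(seed)
    for i in range(4):
        z = z + U64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> U64(30))) * U64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> U64(27))) * U64(0x94D049BB133111EB)
        state[i] = t ^ (t >> U64(31))
    return state


@njit(cache=True)
def rng_u64(state):
    s0 = state[0]
    s1 = state[1]
    s2 = state[2]
    s3 = state[3]
    tmp = s0 + s3
    result = ((tmp << U64(23)) | (tmp >> U64(41))) + s0
    t = s1 << U64(17)
    s2 = s2 ^ s0
    s3 = s3 ^ s1
    s1 = s1 ^ s2
    s0 = s0 ^ s3
    s2 = s2 ^ t
    s3 = (s3 << U64(45)) | (s3 >> U64(19))
    state[0] = s0
    state[1] = s1
    state[2] = s2
    state[3] = s3
    return result


@njit(cache=True)
def rng_uniform(state):
    """Uniform double in [0, 1)."""
    return (rng_u64(state) >> U64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def rng_below(state, n):
    """Uniform integer in [0, n). Modulo bias is < 2**-50 for the n used here."""
    return int(rng_u64(state) % U64(n))


@njit(cache=True)
def rng_normal(state):
    u1 = rng_uniform(state)
    u2 = rng_uniform(state)
    if u1 < 1e-300:
        u1 = 1e-300
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(TWO_PI * u2)


@njit(cache=True)
def _unit_vector(state):
    while True:
        x = rng_normal(state)
        y = rng_normal(state)
        z = rng_normal(state)
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            inv = 1.0 / np.sqrt(n2)
            return x * inv, y * inv, z * inv


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mi(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def _dist2(ax, ay, az, bx, by, bz, box):
    dx = _mi(ax - bx, box)
    dy = _mi(ay - by, box)
    dz = _mi(az - bz, box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _cell_index(x, y, z, box, nc):
    i = int(((x % box) / box) * nc)
    j = int(((y % box) / box) * nc)
    k = int(((z % box) / box) * nc)
    if i >= nc:
        i = nc - 1
    if j >= nc:
        j = nc - 1
    if k >= nc:
        k = nc - 1
    return (i * nc + j) * nc + k


@njit(cache=True)
def _cell_insert(head, nxt, prv, cell_of, b, c):
    cell_of[b] = c
    first = head[c]
    nxt[b] = first
    prv[b] = -1
    if first >= 0:
        prv[first] = b
    head[c] = b


@njit(cache=True)
def _cell_remove(head, nxt, prv, cell_of, b):
    p = prv[b]
    n = nxt[b]
    if p >= 0:
        nxt[p] = n
    else:
        head[cell_of[b]] = n
    if n >= 0:
        prv[n] = p


@njit(cache=True)
def build_cells(pos, box, nc, head, nxt, prv, cell_of):
    head[:] = -1
    for b in range(pos.shape[0]):
        c = _cell_index(pos[b, 0], pos[b, 1], pos[b, 2], box, nc)
        _cell_insert(head, nxt, prv, cell_of, b, c)


@njit(cache=True)
def _np_energy_at(x, y, z, box, nc, np_cell_count, np_cell_list,
                  np_x, np_y, np_z, np_r, np_eps, np_shell, np_occ):
    """Square-well nanoparticle energy at a point.

    Returns (energy, occlusion, overlap).  ``occlusion`` is the number of
    bonding faces blocked by the most occluding shell containing the point
    (0 when free); ``overlap`` means the point lies inside a hard sphere,
    in which case the other fields are meaningless.
    """
    e = 0.0
    occ = 0
    if np_x.shape[0] == 0:
        return e, occ, False
    c = _cell_index(x, y, z, box, nc)
    for t in range(np_cell_count[c]):
        k = np_cell_list[c, t]
        d2 = _dist2(x, y, z, np_x[k], np_y[k], np_z[k], box)
        r = np_r[k]
        if d2 < r * r:
            return 0.0, 0, True
        ro = r + np_shell[k]
        if d2 < ro * ro:
            e -= np_eps[k]
            if np_occ[k] > occ:
                occ = np_occ[k]
    return e, occ, False


# ---------------------------------------------------------------------------
# Move proposal
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rotate_about(px, py, pz, ox, oy, oz, kx, ky, kz, c, s):
    """Rodrigues rotation of point p about axis k through origin o."""
    vx = px - ox
    vy = py - oy
    vz = pz - oz
    dot = kx * vx + ky * vy + kz * vz
    cx = ky * vz - kz * vy
    cy = kz * vx - kx * vz
    cz = kx * vy - ky * vx
    rx = vx * c + cx * s + kx * dot * (1.0 - c)
    ry = vy * c + cy * s + ky * dot * (1.0 - c)
    rz = vz * c + cz * s + kz * dot * (1.0 - c)
    return ox + rx, oy + ry, oz + rz


@njit(cache=True)
def propose_kernel(pos, n_chains, chain_length, bead_diameter, weights_cum,
                   state, moved_idx, new_pos):
    """Draw one move; fill moved_idx/new_pos; return (mtype, chain, n_moved)."""
    chain = rng_below(state, n_chains)
    base = chain * chain_length
    u = rng_uniform(state)
    if u < weights_cum[0]:
        mtype = 0
    elif u < weights_cum[1]:
        mtype = 1
    elif u < weights_cum[2]:
        mtype = 2
    else:
        mtype = 3
    n_moved = 0

    if mtype == 0:  # pivot: rigid rotation of a random tail about a random bead
        j = rng_below(state, chain_length)
        side = rng_below(state, 2)
        kx, ky, kz = _unit_vector(state)
        ang = (rng_uniform(state) * 2.0 - 1.0) * np.pi
        c = np.cos(ang)
        s = np.sin(ang)
        ox = pos[base + j, 0]
        oy = pos[base + j, 1]
        oz = pos[base + j, 2]
        if side == 0:
            lo = base + j + 1
            hi = base + chain_length
        else:
            lo = base
            hi = base + j
        for b in range(lo, hi):
            x, y, z = _rotate_about(pos[b, 0], pos[b, 1], pos[b, 2],
                                    ox, oy, oz, kx, ky, kz, c, s)
            moved_idx[n_moved] = b
            new_pos[n_moved, 0] = x
            new_pos[n_moved, 1] = y
            new_pos[n_moved, 2] = z
            n_moved += 1

    elif mtype == 1:  # crankshaft: rotate interior bead about neighbor axis
        i = base + 1 + rng_below(state, chain_length - 2)
        ang = (rng_uniform(state) * 2.0 - 1.0) * np.pi
        ax = pos[i + 1, 0] - pos[i - 1, 0]
        ay = pos[i + 1, 1] - pos[i - 1, 1]
        az = pos[i + 1, 2] - pos[i - 1, 2]
        n2 = ax * ax + ay * ay + az * az
        if n2 > 1e-18:
            inv = 1.0 / np.sqrt(n2)
            kx = ax * inv
            ky = ay * inv
            kz = az * inv
            c = np.cos(ang)
            s = np.sin(ang)
            x, y, z = _rotate_about(pos[i, 0], pos[i, 1], pos[i, 2],
                                    pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2],
                                    kx, ky, kz, c, s)
            moved_idx[0] = i
            new_pos[0, 0] = x
            new_pos[0, 1] = y
            new_pos[0, 2] = z
            n_moved = 1

    elif mtype == 2:  # kink-jump: uniform point on the bond-preserving circle
        i = base + 1 + rng_below(state, chain_length - 2)
        phi = rng_uniform(state) * TWO_PI
        ax = pos[i - 1, 0]
        ay = pos[i - 1, 1]
        az = pos[i - 1, 2]
        wx = pos[i + 1, 0] - ax
        wy = pos[i + 1, 1] - ay
        wz = pos[i + 1, 2] - az
        m2 = wx * wx + wy * wy + wz * wz
        if m2 > 1e-18:
            m = np.sqrt(m2)
            ux = wx / m
            uy = wy / m
            uz = wz / m
            d1x = pos[i, 0] - ax
            d1y = pos[i, 1] - ay
            d1z = pos[i, 2] - az
            d1sq = d1x * d1x + d1y * d1y + d1z * d1z
            d2x = pos[i + 1, 0] - pos[i, 0]
            d2y = pos[i + 1, 1] - pos[i, 1]
            d2z = pos[i + 1, 2] - pos[i, 2]
            d2sq = d2x * d2x + d2y * d2y + d2z * d2z
            t = (d1sq - d2sq + m2) / (2.0 * m)
            r2 = d1sq - t * t
            r = np.sqrt(r2) if r2 > 0.0 else 0.0
            # orthonormal frame perpendicular to u
            if abs(ux) < 0.9:
                e1x = 1.0 - ux * ux
                e1y = -ux * uy
                e1z = -ux * uz
            else:
                e1x = -uy * ux
                e1y = 1.0 - uy * uy
                e1z = -uy * uz
            n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= n1
            e1y /= n1
            e1z /= n1
            e2x = uy * e1z - uz * e1y
            e2y = uz * e1x - ux * e1z
            e2z = ux * e1y - uy * e1x
            cp = np.cos(phi)
            sp = np.sin(phi)
            moved_idx[0] = i
            new_pos[0, 0] = ax + t * ux + r * (cp * e1x + sp * e2x)
            new_pos[0, 1] = ay + t * uy + r * (cp * e1y + sp * e2y)
            new_pos[0, 2] = az + t * uz + r * (cp * e1z + sp * e2z)
            n_moved = 1

    else:  # translation of the whole chain
        dx = (rng_uniform(state) * 2.0 - 1.0) * bead_diameter
        dy = (rng_uniform(state) * 2.0 - 1.0) * bead_diameter
        dz = (rng_uniform(state) * 2.0 - 1.0) * bead_diameter
        for j in range(chain_length):
            b = base + j
            moved_idx[n_moved] = b
            new_pos[n_moved, 0] = pos[b, 0] + dx
            new_pos[n_moved, 1] = pos[b, 1] + dy
            new_pos[n_moved, 2] = pos[b, 2] + dz
            n_moved += 1

    return mtype, chain, n_moved


# ---------------------------------------------------------------------------
# Move evaluation (does not mutate state) and commit
# ---------------------------------------------------------------------------


@njit(cache=True)
def evaluate_kernel(pos, chain_length, box, nc, head, nxt,
                    eps_hb, hb_cutoff, bead_diameter, max_bonds,
                    partner, bond_count,
                    np_cell_count, np_cell_list, np_x, np_y, np_z, np_r,
                    np_eps, np_shell, np_occ,
                    moved_idx, n_moved, new_pos,
                    moved_flag, breaks, forms, cand_d, cand_b, cand_j,
                    dcnt, touched, e_scratch):
    """Energy change and bond changes of a proposal.

    Returns (dE, n_break, n_form, reject).  ``reject`` flags hard-core
    overlap (excluded volume or nanoparticle interior); dE is then +inf.
    Bond bookkeeping follows the rule set: bonds of moved beads stretched
    beyond the cutoff break; new inter-chain bonds form for moved beads
    within the cutoff, nearest-distance first, respecting per-bead valence
    reduced by surface occlusion (an adsorbed bead loses ``np_occ`` bonding
    faces for *new* bonds).  All moved beads belong to one chain, so bonds
    never connect two moved beads.
    """
    hb2 = hb_cutoff * hb_cutoff
    bd2 = bead_diameter * bead_diameter * (1.0 - 1e-12)
    for m in range(n_moved):
        moved_flag[moved_idx[m]] = True

    reject = False
    dE_np = 0.0
    ncand = 0
    # pass 1: overlap + nanoparticle energy + bond candidates
    for m in range(n_moved):
        b = moved_idx[m]
        qx = new_pos[m, 0]
        qy = new_pos[m, 1]
        qz = new_pos[m, 2]
        e_new, occ_new, ov = _np_energy_at(qx, qy, qz, box, nc,
                                           np_cell_count, np_cell_list,
                                           np_x, np_y, np_z, np_r, np_eps,
                                           np_shell, np_occ)
        if ov:
            reject = True
            break
        e_old, _occ_old, _ = _np_energy_at(pos[b, 0], pos[b, 1], pos[b, 2],
                                           box, nc, np_cell_count,
                                           np_cell_list, np_x, np_y, np_z,
                                           np_r, np_eps, np_shell, np_occ)
        dE_np += e_new - e_old
        e_scratch[m] = float(occ_new)

        chain_b = b // chain_length
        # moved-vs-moved excluded volume (same chain): direct loop
        for m2 in range(m):
            b2 = moved_idx[m2]
            if abs(b - b2) == 1:
                continue
            d2 = _dist2(qx, qy, qz, new_pos[m2, 0], new_pos[m2, 1],
                        new_pos[m2, 2], box)
            if d2 < bd2:
                reject = True
                break
        if reject:
            break

        # cell scan against unmoved beads
        ci = int(((qx % box) / box) * nc)
        cj = int(((qy % box) / box) * nc)
        ck = int(((qz % box) / box) * nc)
        if ci >= nc:
            ci = nc - 1
        if cj >= nc:
            cj = nc - 1
        if ck >= nc:
            ck = nc - 1
        if nc >= 3:
            olo = -1
            ohi = 2
        else:
            olo = 0
            ohi = nc
        for oi in range(olo, ohi):
            for oj in range(olo, ohi):
                for ok in range(olo, ohi):
                    cc = ((((ci + oi) % nc) * nc + ((cj + oj) % nc)) * nc
                          + ((ck + ok) % nc))
                    j = head[cc]
                    while j >= 0:
                        if moved_flag[j]:
                            j = nxt[j]
                            continue
                        same_chain = (j // chain_length) == chain_b
                        if same_chain and abs(j - b) == 1:
                            j = nxt[j]
                            continue
                        d2 = _dist2(qx, qy, qz, pos[j, 0], pos[j, 1],
                                    pos[j, 2], box)
                        if d2 < bd2:
                            reject = True
                            break
                        if (not same_chain) and d2 <= hb2 and eps_hb > 0.0:
                            # skip pairs already bonded
                            bonded = False
                            for t in range(bond_count[b]):
                                if partner[b, t] == j:
                                    bonded = True
                                    break
                            if not bonded and ncand < cand_d.shape[0]:
                                cand_d[ncand] = d2
                                cand_b[ncand] = b
                                cand_j[ncand] = j
                                ncand += 1
                        j = nxt[j]
                    if reject:
                        break
                if reject:
                    break
            if reject:
                break
        if reject:
            break

    if reject:
        for m in range(n_moved):
            moved_flag[moved_idx[m]] = False
        return np.inf, 0, 0, True

    # pass 2: broken bonds (partners are never moved — single-chain moves)
    n_break = 0
    for m in range(n_moved):
        b = moved_idx[m]
        for t in range(bond_count[b]):
            p = partner[b, t]
            d2 = _dist2(new_pos[m, 0], new_pos[m, 1], new_pos[m, 2],
                        pos[p, 0], pos[p, 1], pos[p, 2], box)
            if d2 > hb2:
                breaks[n_break, 0] = b
                breaks[n_break, 1] = p
                n_break += 1

    # pass 3: greedy bond formation, nearest first
    n_touch = 0
    for k in range(n_break):
        for side in range(2):
            bb = breaks[k, side]
            if dcnt[bb] == 0:
                touched[n_touch] = bb
                n_touch += 1
            dcnt[bb] -= 1

    n_form = 0
    if ncand > 0:
        # insertion sort by (distance, bead index, partner index)
        for a in range(1, ncand):
            d = cand_d[a]
            bi = cand_b[a]
            ji = cand_j[a]
            w = a - 1
            while w >= 0 and (cand_d[w] > d or
                              (cand_d[w] == d and
                               (cand_b[w] > bi or
                                (cand_b[w] == bi and cand_j[w] > ji)))):
                cand_d[w + 1] = cand_d[w]
                cand_b[w + 1] = cand_b[w]
                cand_j[w + 1] = cand_j[w]
                w -= 1
            cand_d[w + 1] = d
            cand_b[w + 1] = bi
            cand_j[w + 1] = ji

        for a in range(ncand):
            b = cand_b[a]
            j = cand_j[a]
            slot = -1
            for m in range(n_moved):
                if moved_idx[m] == b:
                    slot = m
                    break
            occ_b = int(e_scratch[slot])
            if bond_count[b] + dcnt[b] >= max_bonds - occ_b:
                continue
            _e, occ_j, _ = _np_energy_at(pos[j, 0], pos[j, 1], pos[j, 2],
                                         box, nc, np_cell_count,
                                         np_cell_list, np_x, np_y, np_z,
                                         np_r, np_eps, np_shell, np_occ)
            if bond_count[j] + dcnt[j] >= max_bonds - occ_j:
                continue
            forms[n_form, 0] = b
            forms[n_form, 1] = j
            n_form += 1
            for bb in (b, j):
                if dcnt[bb] == 0:
                    touched[n_touch] = bb
                    n_touch += 1
                dcnt[bb] += 1

    for m in range(n_moved):
        moved_flag[moved_idx[m]] = False
    for t in range(n_touch):
        dcnt[touched[t]] = 0

    dE = eps_hb * (n_break - n_form) + dE_np
    return dE, n_break, n_form, False


@njit(cache=True)
def _bond_remove(partner, bond_count, a, b):
    for t in range(bond_count[a]):
        if partner[a, t] == b:
            partner[a, t] = partner[a, bond_count[a] - 1]
            bond_count[a] -= 1
            return


@njit(cache=True)
def commit_kernel(pos, box, nc, head, nxt, prv, cell_of, partner, bond_count,
                  moved_idx, n_moved, new_pos, breaks, n_break, forms, n_form):
    for k in range(n_break):
        a = breaks[k, 0]
        b = breaks[k, 1]
        _bond_remove(partner, bond_count, a, b)
        _bond_remove(partner, bond_count, b, a)
    for k in range(n_form):
        a = forms[k, 0]
        b = forms[k, 1]
        partner[a, bond_count[a]] = b
        bond_count[a] += 1
        partner[b, bond_count[b]] = a
        bond_count[b] += 1
    for m in range(n_moved):
        b = moved_idx[m]
        pos[b, 0] = new_pos[m, 0]
        pos[b, 1] = new_pos[m, 1]
        pos[b, 2] = new_pos[m, 2]
        c = _cell_index(pos[b, 0], pos[b, 1], pos[b, 2], box, nc)
        if c != cell_of[b]:
            _cell_remove(head, nxt, prv, cell_of, b)
            _cell_insert(head, nxt, prv, cell_of, b, c)


@njit(cache=True)
def metropolis_kernel(delta_energy, state):
    if delta_energy <= 0.0:
        return True
    return rng_uniform(state) < np.exp(-delta_energy)


@njit(cache=True)
def full_energy_kernel(pos, eps_hb, partner, bond_count, box, nc,
                       np_cell_count, np_cell_list, np_x, np_y, np_z,
                       np_r, np_eps, np_shell, np_occ):
    e = 0.0
    n = pos.shape[0]
    for b in range(n):
        for t in range(bond_count[b]):
            if partner[b, t] > b:
                e -= eps_hb
        eb, _, _ = _np_energy_at(pos[b, 0], pos[b, 1], pos[b, 2], box, nc,
                                 np_cell_count, np_cell_list,
                                 np_x, np_y, np_z, np_r, np_eps, np_shell,
                                 np_occ)
        e += eb
    return e


# ---------------------------------------------------------------------------
# Cluster bookkeeping
# ---------------------------------------------------------------------------


@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt_i = parent[i]
        parent[i] = root
        i = nxt_i
    return root


@njit(cache=True)
def record_clusters(pos, partner, bond_count, chain_length, n_chains,
                    merge_np, box, nc, np_cell_count, np_cell_list,
                    np_x, np_y, np_z, np_r, np_eps, np_shell, out_row):
    """Connected-component sizes of the chain graph, written into out_row.

    Chains are linked iff they share at least one inter-chain hydrogen bond;
    with ``merge_np`` chains adsorbed on the same nanoparticle are also
    merged.  Returns the number of clusters.
    """
    n_np = np_x.shape[0]
    n_nodes = n_chains + (n_np if merge_np else 0)
    parent = np.arange(n_nodes)
    n_beads = n_chains * chain_length
    for b in range(n_beads):
        for t in range(bond_count[b]):
            p = partner[b, t]
            if p > b:
                ra = _uf_find(parent, b // chain_length)
                rb = _uf_find(parent, p // chain_length)
                if ra != rb:
                    parent[rb] = ra
    if merge_np and n_np > 0:
        for b in range(n_beads):
            c = _cell_index(pos[b, 0], pos[b, 1], pos[b, 2], box, nc)
            for t in range(np_cell_count[c]):
                k = np_cell_list[c, t]
                d2 = _dist2(pos[b, 0], pos[b, 1], pos[b, 2],
                            np_x[k], np_y[k], np_z[k], box)
                ro = np_r[k] + np_shell[k]
                if d2 < ro * ro:
                    ra = _uf_find(parent, b // chain_length)
                    rb = _uf_find(parent, n_chains + k)
                    if ra != rb:
                        parent[rb] = ra
    counts = np.zeros(n_nodes, dtype=np.int64)
    for ch in range(n_chains):
        counts[_uf_find(parent, ch)] += 1
    out_row[:] = 0
    n_clusters = 0
    for r in range(n_nodes):
        if counts[r] > 0:
            out_row[n_clusters] = counts[r]
            n_clusters += 1
    return n_clusters


# ---------------------------------------------------------------------------
# Fused step / run kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def step_kernel(pos, n_chains, chain_length, box, nc, head, nxt, prv, cell_of,
                eps_hb, hb_cutoff, bead_diameter, max_bonds,
                weights_cum, partner, bond_count,
                np_cell_count, np_cell_list, np_x, np_y, np_z, np_r, np_eps,
                np_shell, np_occ, state,
                moved_idx, new_pos, moved_flag, breaks, forms,
                cand_d, cand_b, cand_j, dcnt, touched, e_scratch):
    """One attempted move. Returns (accepted, dE_committed)."""
    _mtype, _chain, n_moved = propose_kernel(
        pos, n_chains, chain_length, bead_diameter, weights_cum, state,
        moved_idx, new_pos)
    if n_moved == 0:
        return True, 0.0
    dE, n_break, n_form, reject = evaluate_kernel(
        pos, chain_length, box, nc, head, nxt,
        eps_hb, hb_cutoff, bead_diameter, max_bonds,
        partner, bond_count, np_cell_count, np_cell_list,
        np_x, np_y, np_z, np_r, np_eps, np_shell, np_occ,
        moved_idx, n_moved, new_pos,
        moved_flag, breaks, forms, cand_d, cand_b, cand_j, dcnt, touched,
        e_scratch)
    if reject:
        return False, 0.0
    if not metropolis_kernel(dE, state):
        return False, 0.0
    commit_kernel(pos, box, nc, head, nxt, prv, cell_of, partner, bond_count,
                  moved_idx, n_moved, new_pos, breaks, n_break, forms, n_form)
    return True, dE


@njit(cache=True)
def run_kernel(pos, n_chains, chain_length, box, nc, head, nxt, prv, cell_of,
               eps_hb, hb_cutoff, bead_diameter, max_bonds,
               weights_cum, partner, bond_count,
               np_cell_count, np_cell_list, np_x, np_y, np_z, np_r, np_eps,
               np_shell, np_occ, state,
               n_relax, n_production, n_analysis, stride, merge_np,
               check_interval, energy_io, snap_sizes):
    """Relaxation + production run with cluster snapshots.

    ``energy_io`` holds the running total energy (in/out, length 1).
    ``snap_sizes`` is (n_snapshots, n_chains); rows are zero-padded cluster
    sizes collected every ``stride`` attempted moves over the final
    ``n_analysis`` steps.  Returns (n_accepted, max_energy_drift).
    """
    Lc = chain_length
    moved_idx = np.empty(Lc, dtype=np.int64)
    new_pos = np.empty((Lc, 3), dtype=np.float64)
    moved_flag = np.zeros(pos.shape[0], dtype=np.bool_)
    breaks = np.empty((Lc * max_bonds, 2), dtype=np.int64)
    forms = np.empty((512, 2), dtype=np.int64)
    cand_d = np.empty(512, dtype=np.float64)
    cand_b = np.empty(512, dtype=np.int64)
    cand_j = np.empty(512, dtype=np.int64)
    dcnt = np.zeros(pos.shape[0], dtype=np.int64)
    touched = np.empty(1200, dtype=np.int64)
    e_scratch = np.empty(Lc, dtype=np.float64)

    total = n_relax + n_production
    analysis_start = total - n_analysis
    energy = energy_io[0]
    n_accept = 0
    max_drift = 0.0
    snap = 0
    for step in range(total):
        acc, dE = step_kernel(
            pos, n_chains, chain_length, box, nc, head, nxt, prv, cell_of,
            eps_hb, hb_cutoff, bead_diameter, max_bonds,
            weights_cum, partner, bond_count,
            np_cell_count, np_cell_list, np_x, np_y, np_z, np_r, np_eps,
            np_shell, np_occ, state,
            moved_idx, new_pos, moved_flag, breaks, forms,
            cand_d, cand_b, cand_j, dcnt, touched, e_scratch)
        if acc:
            energy += dE
            n_accept += 1
        if check_interval > 0 and (step + 1) % check_interval == 0:
            e_full = full_energy_kernel(pos, eps_hb, partner, bond_count,
                                        box, nc, np_cell_count, np_cell_list,
                                        np_x, np_y, np_z, np_r, np_eps,
                                        np_shell, np_occ)
            drift = abs(e_full - energy)
            if drift > max_drift:
                max_drift = drift
        if step >= analysis_start and (step - analysis_start) % stride == 0:
            if snap < snap_sizes.shape[0]:
                record_clusters(pos, partner, bond_count, chain_length,
                                n_chains, merge_np, box, nc,
                                np_cell_count, np_cell_list,
                                np_x, np_y, np_z, np_r, np_eps, np_shell,
                                snap_sizes[snap])
                snap += 1
    energy_io[0] = energy
    return n_accept, max_drift
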