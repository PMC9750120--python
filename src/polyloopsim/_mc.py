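"""Numba kernel for Metropolis single-bead Monte Carlo on the bead-spring chain.

Energy terms (units of kT, lengths in nm):

* chain bonds: ``bond_k * (d - bond_rest)**2`` with hard limits
  ``[bond_min, bond_max]`` (moves leaving the range are rejected),
* bending: ``bend_k * (1 - cos theta)`` per consecutive triplet,
* excluded volume: hard rejection below ``hardcore`` (skipped when
  ``hardcore == 0``),
* loop bonds (extruder legs): ``loop_k * (d - bond_rest)**2`` with no
  range limit, so a freshly advanced leg is a stretched spring that the
  following sweeps contract.

One sweep is ``n`` single-bead trial displacements, each uniform in a
cube of half-width ``max_disp``.  The kernel is seeded per call for
reproducibility; ``cache=True`` persists the compiled code on disk.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _pair_bond_energy(k, d, rest):
    dd = d - rest
    return k * dd * dd


@njit(cache=True)
def _dist(a, b):
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    dz = a[2] - b[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _bend_energy(a, b, c, bend_k):
    v1x = b[0] - a[0]
    v1y = b[1] - a[1]
    v1z = b[2] - a[2]
    v2x = c[0] - b[0]
    v2y = c[1] - b[1]
    v2z = c[2] - b[2]
    n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
    n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    cos_t = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
    return bend_k * (1.0 - cos_t)


@njit(cache=True)
def _local_energy(pos, m, p, loop_a, loop_b, bond_k, bond_rest, bend_k, loop_k):
    """Energy of all terms that involve bead m, with bead m at position p."""
    n = pos.shape[0]
    e = 0.0
    if m > 0:
        e += _pair_bond_energy(bond_k, _dist(p, pos[m - 1]), bond_rest)
    if m < n - 1:
        e += _pair_bond_energy(bond_k, _dist(p, pos[m + 1]), bond_rest)
    if bend_k > 0.0:
        # angles centered at m-1, m, m+1 involve bead m
        if m >= 2:
            e += _bend_energy(pos[m - 2], pos[m - 1], p, bend_k)
        if 1 <= m <= n - 2:
            e += _bend_energy(pos[m - 1], p, pos[m + 1], bend_k)
        if m <= n - 3:
            e += _bend_energy(p, pos[m + 1], pos[m + 2], bend_k)
    for l in range(loop_a.shape[0]):
        if loop_a[l] == m:
            e += _pair_bond_energy(loop_k, _dist(p, pos[loop_b[l]]), bond_rest)
        elif loop_b[l] == m:
            e += _pair_bond_energy(loop_k, _dist(p, pos[loop_a[l]]), bond_rest)
    return e


@njit(cache=True)
def run_sweeps(
    pos,
    loop_a,
    loop_b,
    bond_k,
    bond_rest,
    bond_min,
    bond_max,
    bend_k,
    hardcore,
    loop_k,
    max_disp,
    temperature,
    n_sweeps,
    seed,
):
    """Run ``n_sweeps`` Metropolis sweeps in place; return accepted-move count."""
    np.random.seed(seed)
    n = pos.shape[0]
    hard2 = hardcore * hardcore
    accepted = 0
    new = np.empty(3)
    for _ in range(n_sweeps):
        for _trial in range(n):
            m = np.random.randint(0, n)
            new[0] = pos[m, 0] + (np.random.random() * 2.0 - 1.0) * max_disp
            new[1] = pos[m, 1] + (np.random.random() * 2.0 - 1.0) * max_disp
            new[2] = pos[m, 2] + (np.random.random() * 2.0 - 1.0) * max_disp
            # hard constraints first: chain-bond range, then excluded volume
            ok = True
            if m > 0:
                d = _dist(new, pos[m - 1])
                if d < bond_min or d > bond_max:
                    ok = False
            if ok and m < n - 1:
                d = _dist(new, pos[m + 1])
                if d < bond_min or d > bond_max:
                    ok = False
            if ok and hard2 > 0.0:
                for q in range(n):
                    if q == m:
                        continue
                    dx = new[0] - pos[q, 0]
                    dy = new[1] - pos[q, 1]
                    dz = new[2] - pos[q, 2]
                    if dx * dx + dy * dy + dz * dz < hard2:
                        ok = False
                        break
            if not ok:
                continue
            e_old = _local_energy(
                pos, m, pos[m], loop_a, loop_b, bond_k, bond_rest, bend_k, loop_k
            )
            e_new = _local_energy(
                pos, m, new, loop_a, loop_b, bond_k, bond_rest, bend_k, loop_k
            )
            d_e = e_new - e_old
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / temperature):
                pos[m, 0] = new[0]
                pos[m, 1] = new[1]
                pos[m, 2] = new[2]
                accepted += 1
    return accepted
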