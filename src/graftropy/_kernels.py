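"""Compiled inner loops for Rosenbluth chain growth.

The ensemble sampler marks chain sites in a flat occupancy byte array of the
whole box (reset lazily by unmarking the visited sites after each chain), so
self-avoidance, box bounds, and surface blocking are all O(1) per candidate
move.  A self-contained xorshift64* generator keeps seeded runs
bit-reproducible independent of the host RNG state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True, inline="always")
def _splitmix64(state: np.uint64) -> np.uint64:
    z = state + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _next_u64(state: np.ndarray) -> np.uint64:
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * _MULT


@njit(cache=True, inline="always")
def _rand_below(state: np.ndarray, n: np.int64) -> np.int64:
    r = _next_u64(state) >> np.uint64(32)
    return np.int64((r * np.uint64(n)) >> np.uint64(32))


@njit(cache=True)
def grow_ensemble(
    heights: np.ndarray,  # (L, L) int32 surface altitudes in box frame
    use_surface: bool,
    box: np.int64,
    start_x: np.int64,
    start_y: np.int64,
    start_z: np.int64,
    per_chain_anchor: bool,
    rx0: np.int64,
    rx1: np.int64,
    ry0: np.int64,
    ry1: np.int64,
    moves: np.ndarray,  # (24, 3) int64
    n_segments: np.int64,
    n_samples: np.int64,
    seed: np.uint64,
    max_dead_fraction: np.float64,
    store_sites: bool,
):
    """Grow ``n_samples`` successful Rosenbluth chains of ``n_segments``.

    Returns ``(k, sites, anchors, n_dead, ok)`` where ``k`` is the
    ``(n_samples, n_segments-1)`` matrix of per-step free-site counts,
    ``sites`` the site trajectories (only filled when ``store_sites``),
    ``anchors`` the start site of each chain, ``n_dead`` the number of
    discarded dead-ended chains, and ``ok`` is False when the dead-end rate
    exceeded ``max_dead_fraction`` (pathological environment).
    """
    n_moves = moves.shape[0]
    n_steps = n_segments - 1
    occ = np.zeros(box * box * box, dtype=np.uint8)
    k_out = np.zeros((n_samples, n_steps), dtype=np.uint8)
    if store_sites:
        sites_out = np.zeros((n_samples, n_segments, 3), dtype=np.int16)
    else:
        sites_out = np.zeros((1, 1, 3), dtype=np.int16)
    anchors = np.zeros((n_samples, 3), dtype=np.int16)
    chain = np.zeros((n_segments, 3), dtype=np.int64)
    cand = np.zeros(n_moves, dtype=np.int64)

    state = np.empty(1, dtype=np.uint64)
    state[0] = _splitmix64(seed) | np.uint64(1)

    n_dead = np.int64(0)
    done = np.int64(0)
    min_attempts = np.int64(200)
    while done < n_samples:
        attempts = done + n_dead
        if attempts > min_attempts and attempts * (1.0 - max_dead_fraction) > n_samples:
            if n_dead > max_dead_fraction * attempts:
                return k_out, sites_out, anchors, n_dead, False
        # --- choose the start site -------------------------------------
        if per_chain_anchor:
            ok_anchor = False
            for _ in range(1000):
                ax = rx0 + _rand_below(state, rx1 - rx0 + 1)
                ay = ry0 + _rand_below(state, ry1 - ry0 + 1)
                az = np.int64(heights[ax, ay]) + 1
                if 0 <= az < box:
                    ok_anchor = True
                    break
            if not ok_anchor:
                return k_out, sites_out, anchors, n_dead, False
            x, y, z = ax, ay, az
        else:
            x, y, z = start_x, start_y, start_z
        # --- grow one chain --------------------------------------------
        chain[0, 0], chain[0, 1], chain[0, 2] = x, y, z
        occ[(x * box + y) * box + z] = 1
        length = np.int64(1)
        dead = False
        for i in range(n_steps):
            nf = np.int64(0)
            for m in range(n_moves):
                nx = x + moves[m, 0]
                ny = y + moves[m, 1]
                nz = z + moves[m, 2]
                if nx < 0 or nx >= box or ny < 0 or ny >= box or nz < 0 or nz >= box:
                    continue
                if use_surface and nz < heights[nx, ny]:
                    continue
                if occ[(nx * box + ny) * box + nz] != 0:
                    continue
                cand[nf] = m
                nf += 1
            if nf == 0:
                dead = True
                break
            k_out[done, i] = np.uint8(nf)
            m = cand[_rand_below(state, nf)]
            x += moves[m, 0]
            y += moves[m, 1]
            z += moves[m, 2]
            chain[length, 0], chain[length, 1], chain[length, 2] = x, y, z
            occ[(x * box + y) * box + z] = 1
            length += 1
        # --- unmark and commit -----------------------------------------
        for j in range(length):
            occ[(chain[j, 0] * box + chain[j, 1]) * box + chain[j, 2]] = 0
        if dead:
            n_dead += 1
            for i in range(n_steps):
                k_out[done, i] = 0
            continue
        anchors[done, 0] = np.int16(chain[0, 0])
        anchors[done, 1] = np.int16(chain[0, 1])
        anchors[done, 2] = np.int16(chain[0, 2])
        if store_sites:
            for j in range(n_segments):
                sites_out[done, j, 0] = np.int16(chain[j, 0])
                sites_out[done, j, 1] = np.int16(chain[j, 1])
                sites_out[done, j, 2] = np.int16(chain[j, 2])
        done += 1
    return k_out, sites_out, anchors, n_dead, True
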