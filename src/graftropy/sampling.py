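"""Static Rosenbluth–Rosenbluth growth of self-avoiding chains.

A chain of ``N`` segments is grown site by site: at every step the set of
*free* neighbour sites (inside the box, not occupied by the chain, not
inside the solid) is enumerated, one is picked uniformly at random, and the
count ``k_i`` is recorded.  The product of the ``k_i`` is the Rosenbluth
weight of the conformation — an unbiased estimator of the number of
self-avoiding walks.  Chains that run into a dead end (``k_i = 0``) are
discarded whole and regrown with fresh randomness.

Two growth paths are provided: :func:`grow_chain` is a transparent
pure-Python implementation used for single conformations and property
checks; :func:`sample_ensemble` drives the compiled kernel for large
ensembles.  :func:`enumerate_exact` exhaustively counts all conformations of
short chains and serves as the independent oracle for estimator tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .lattice import LatticeConfig, MoveSet, generate_move_set
from .surfaces import AnchorSpec, HeightField, reduce_surface

#: Soft cap on chain length; longer chains are allowed but warn.
MAX_SEGMENTS = 100


@dataclass
class Environment:
    """Everything a growing chain can collide with.

    ``heights`` is an optional ``(box_edge, box_edge)`` integer altitude map
    *in box coordinates* (sites with ``z < heights[x, y]`` are solid);
    ``start`` is the first-segment site.  When ``anchor_region`` is set the
    ensemble sampler draws a fresh uniform anchor from that inclusive
    ``(x0, x1, y0, y1)`` window for every chain (the "random altitude"
    grafting mode); ``start`` is then ignored by the ensemble path.
    """

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    moves: MoveSet = field(default_factory=generate_move_set)
    heights: Optional[np.ndarray] = None
    start: Optional[tuple[int, int, int]] = None
    anchor_region: Optional[tuple[int, int, int, int]] = None
    label: str = "free"

    def __post_init__(self) -> None:
        if self.heights is not None:
            self.heights = np.ascontiguousarray(self.heights, dtype=np.int32)
            e = self.lattice.box_edge
            if self.heights.shape != (e, e):
                raise ValueError(
                    f"heights shape {self.heights.shape} != box {(e, e)}"
                )
        if self.start is None and self.anchor_region is None:
            self.start = self.lattice.origin
        if self.start is not None and self.heights is not None:
            x, y, z = self.start
            if z < int(self.heights[x, y]):
                raise ValueError("anchor site lies inside the solid")


@dataclass
class GrowthRecord:
    """One grown chain: sites, per-step free-site counts, and log-weight."""

    sites: list[tuple[int, int, int]]
    k: list[int]
    log_weight: float


@dataclass
class DeadEnd:
    """Marker for a chain that ran out of free sites at ``step``."""

    step: int


@dataclass
class EnsembleStats:
    """A sampled ensemble of successful chains.

    ``k`` is the ``(n, N-1)`` matrix of free-site counts; ``sites`` the
    optional ``(n, N, 3)`` trajectories; ``anchors`` the start site of every
    chain (informative in the per-chain random-anchor mode).
    """

    n_target: int
    n_dead: int
    k: np.ndarray
    anchors: np.ndarray
    sites: Optional[np.ndarray] = None
    seed: Optional[int] = None
    label: str = ""

    @property
    def n_segments(self) -> int:
        return self.k.shape[1] + 1

    @property
    def dead_fraction(self) -> float:
        total = self.n_target + self.n_dead
        return self.n_dead / total if total else 0.0

    def records(self) -> list[GrowthRecord]:
        """Materialize GrowthRecords (requires ``sites``)."""
        if self.sites is None:
            raise ValueError("ensemble was sampled without site storage")
        out = []
        logk = np.log(self.k.astype(np.float64))
        for r in range(self.k.shape[0]):
            out.append(
                GrowthRecord(
                    sites=[tuple(int(v) for v in s) for s in self.sites[r]],
                    k=[int(v) for v in self.k[r]],
                    log_weight=float(logk[r].sum()),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Environment builders
# ---------------------------------------------------------------------------

def free_environment(lattice: LatticeConfig | None = None) -> Environment:
    """A chain in empty space, started at the box centre."""
    cfg = lattice or LatticeConfig()
    return Environment(lattice=cfg, label="free")


def anchored_environment(
    parent: HeightField,
    anchor: AnchorSpec,
    lattice: LatticeConfig | None = None,
) -> Environment:
    """Graft at a fixed anchor site of ``parent``.

    The surface is cropped to the box edge around the anchor and its
    altitudes are shifted so that the anchor sits at the centre of the box
    (laterally and vertically), mirroring a chain started at the box centre.
    """
    cfg = lattice or LatticeConfig()
    window, local = reduce_surface(parent, anchor, cfg.box_edge)
    ax, ay, az = local.site
    mid = cfg.box_edge // 2
    shift = mid - az
    heights = window.z.astype(np.int64) + shift
    start = (ax, ay, mid)
    return Environment(
        lattice=cfg,
        heights=np.clip(heights, -(2**30), 2**30).astype(np.int32),
        start=start,
        label=f"anchored:{anchor.mode}",
    )


def random_anchor_environment(
    parent: HeightField,
    lattice: LatticeConfig | None = None,
) -> Environment:
    """Graft every chain at a fresh uniformly random central-region site.

    The central ``box_edge`` window of the parent is used, altitudes shifted
    so the mean surface plane sits at mid-box height.  This reproduces the
    random-altitude grafting ensemble in which trial conformations that dead
    end are discarded, so open anchor sites are visited more often.
    """
    from .surfaces import anchor_region

    cfg = lattice or LatticeConfig()
    L, e = parent.L, cfg.box_edge
    if e > L:
        raise ValueError(f"box edge {e} exceeds parent edge {L}")
    x0 = (L - e) // 2
    window = parent.z[x0 : x0 + e, x0 : x0 + e].astype(np.int64)
    shift = e // 2 - int(round(float(window.mean())))
    heights = window + shift
    (rx0, rx1), (ry0, ry1) = anchor_region(L)
    clip = lambda v: int(np.clip(v - x0, 0, e - 1))
    region = (clip(rx0), clip(rx1), clip(ry0), clip(ry1))
    return Environment(
        lattice=cfg,
        heights=np.clip(heights, -(2**30), 2**30).astype(np.int32),
        start=None,
        anchor_region=region,
        label="anchored:random",
    )


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def _site_accessible(env: Environment, site: tuple[int, int, int]) -> bool:
    x, y, z = site
    e = env.lattice.box_edge
    if not (0 <= x < e and 0 <= y < e and 0 <= z < e):
        return False
    if env.heights is not None and z < int(env.heights[x, y]):
        return False
    return True


def free_sites(
    env: Environment,
    occupied: set[tuple[int, int, int]],
    site: tuple[int, int, int],
) -> list[tuple[int, int, int]]:
    """Neighbour targets of ``site`` that are inside the box, unoccupied,
    and outside the solid, in canonical move order."""
    out = []
    x, y, z = site
    for dx, dy, dz in env.moves.vectors:
        tgt = (x + dx, y + dy, z + dz)
        if tgt in occupied:
            continue
        if _site_accessible(env, tgt):
            out.append(tgt)
    return out


def grow_chain(
    env: Environment, n_segments: int, rng: np.random.Generator
) -> GrowthRecord | DeadEnd:
    """Grow a single Rosenbluth chain of ``n_segments`` (pure Python).

    Starts at ``env.start`` (or a random anchor drawn from
    ``env.anchor_region``); picks uniformly among free sites at each step.
    Returns a :class:`DeadEnd` if the chain runs out of free sites.
    """
    if n_segments < 2:
        raise ValueError(f"need at least 2 segments, got {n_segments}")
    if n_segments > MAX_SEGMENTS:
        warnings.warn(
            f"chain length {n_segments} exceeds the validated range "
            f"(<= {MAX_SEGMENTS})",
            stacklevel=2,
        )
    if env.anchor_region is not None:
        rx0, rx1, ry0, ry1 = env.anchor_region
        e = env.lattice.box_edge
        for _ in range(1000):
            x = int(rng.integers(rx0, rx1 + 1))
            y = int(rng.integers(ry0, ry1 + 1))
            z = int(env.heights[x, y]) + 1
            if 0 <= z < e:
                break
        else:
            raise RuntimeError("could not draw a valid random anchor")
        start = (x, y, z)
    else:
        start = env.start
        if not _site_accessible(env, start):
            raise ValueError(f"start site {start} is blocked")
    sites = [start]
    occupied = {start}
    k: list[int] = []
    log_weight = 0.0
    for i in range(n_segments - 1):
        options = free_sites(env, occupied, sites[-1])
        if not options:
            return DeadEnd(step=i + 1)
        k.append(len(options))
        log_weight += np.log(len(options))
        nxt = options[int(rng.integers(len(options)))]
        sites.append(nxt)
        occupied.add(nxt)
    return GrowthRecord(sites=sites, k=k, log_weight=log_weight)


def sample_ensemble(
    env: Environment,
    n_segments: int,
    n_samples: int,
    seed: int,
    store_sites: bool = False,
    max_dead_fraction: float = 0.5,
) -> EnsembleStats:
    """Grow ``n_samples`` successful chains with the compiled kernel.

    Dead-ended chains are discarded and counted; the run aborts with a
    diagnostic if the dead-end rate exceeds ``max_dead_fraction``.
    Deterministic for a given seed.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if n_segments < 2:
        raise ValueError(f"need at least 2 segments, got {n_segments}")
    if n_segments > MAX_SEGMENTS:
        warnings.warn(
            f"chain length {n_segments} exceeds the validated range "
            f"(<= {MAX_SEGMENTS})",
            stacklevel=2,
        )
    e = env.lattice.box_edge
    if env.heights is not None:
        heights = env.heights
        use_surface = True
    else:
        heights = np.zeros((1, 1), dtype=np.int32)
        use_surface = False
    if env.anchor_region is not None:
        per_chain = True
        rx0, rx1, ry0, ry1 = env.anchor_region
        sx = sy = sz = 0
    else:
        per_chain = False
        rx0 = rx1 = ry0 = ry1 = 0
        sx, sy, sz = env.start
        if not _site_accessible(env, env.start):
            raise ValueError(f"start site {env.start} is blocked")
    moves = env.moves.as_array(np.int64)
    k, sites, anchors, n_dead, ok = _kernels.grow_ensemble(
        heights,
        use_surface,
        np.int64(e),
        np.int64(sx),
        np.int64(sy),
        np.int64(sz),
        per_chain,
        np.int64(rx0),
        np.int64(rx1),
        np.int64(ry0),
        np.int64(ry1),
        moves,
        np.int64(n_segments),
        np.int64(n_samples),
        np.uint64(seed),
        np.float64(max_dead_fraction),
        store_sites,
    )
    if not ok:
        raise RuntimeError(
            f"dead-end rate exceeded {max_dead_fraction:.0%} in environment "
            f"{env.label!r} (n_dead={int(n_dead)}); the environment is "
            "pathological for chain growth"
        )
    return EnsembleStats(
        n_target=n_samples,
        n_dead=int(n_dead),
        k=k,
        anchors=anchors,
        sites=sites if store_sites else None,
        seed=seed,
        label=env.label,
    )


def enumerate_exact(env: Environment, n_segments: int) -> list[int]:
    """Exhaustively count SAW conformations Ω(i) for i = 2..n_segments.

    Depth-first enumeration from the start site, respecting the surface and
    the box.  Guarded to short chains (the path count grows as ~24**N).
    """
    if n_segments > 5:
        raise ValueError(
            f"exact enumeration is limited to 5 segments, got {n_segments}"
        )
    if env.anchor_region is not None:
        raise ValueError("exact enumeration needs a fixed start site")
    if not _site_accessible(env, env.start):
        raise ValueError(f"start site {env.start} is blocked")
    counts = [0] * (n_segments + 1)
    occupied = {env.start}
    moves = env.moves.vectors

    def rec(site: tuple[int, int, int], depth: int) -> None:
        x, y, z = site
        for dx, dy, dz in moves:
            tgt = (x + dx, y + dy, z + dz)
            if tgt in occupied or not _site_accessible(env, tgt):
                continue
            counts[depth + 1] += 1
            if depth + 1 < n_segments:
                occupied.add(tgt)
                rec(tgt, depth + 1)
                occupied.remove(tgt)

    rec(env.start, 1)
    return counts[2 : n_segments + 1]
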