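"""Rough-surface heightfield generators, anchor selection, and surface I/O.

Three families of random surfaces are supported, all represented as square
grids of integer altitudes (in units of the lattice constant ``a``):

* **uGm** (uncorrelated Gaussian motion): every cell altitude is an
  independent integer-truncated normal variate — a "brush" of uncorrelated
  spikes.
* **Bm / fBm** ((fractional) Brownian motion): correlated relief built by
  random midpoint displacement with successive random additions, controlled
  by the Hurst exponent ``H`` (``H = 1/2`` is the Brownian case; larger ``H``
  is smoother).

A chain is grafted at an *anchor* site chosen from the central region of the
parent grid by one of four rules (minimum / maximum / nearest-to-mean /
random altitude), after which the surface is cropped to the simulation-box
edge around the anchor.  All lattice sites with ``z < z_S(x, y)`` lie inside
the solid and are inaccessible to the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

AnchorMode = Literal["min", "max", "mean", "random"]

#: Central-anchor region expressed as fractions of the parent edge length.
#: On a 1024-site parent these give the inclusive index window [301, 723].
ANCHOR_REGION_FRACTIONS = (301 / 1024, 723 / 1024)

#: Default decay exponent of the successive-random-addition amplitudes,
#: relative to the midpoint-displacement schedule (see generate_rmd).
ADDITION_DECAY = 2.2


@dataclass
class HeightField:
    """A square grid of integer surface altitudes.

    Attributes
    ----------
    z :
        ``(L, L)`` integer array of altitudes in units of ``a``.  Sites with
        vertical coordinate below ``z[x, y]`` are inside the solid.
    L :
        Edge length in sites.
    meta :
        Generation parameters (surface type, z0, sigma, H, seed, ...);
        round-trips through the text file format.
    """

    z: np.ndarray
    L: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError(f"altitude grid must be square, got {self.z.shape}")
        if not np.issubdtype(self.z.dtype, np.integer):
            raise ValueError("altitudes must be integers")
        if self.L != self.z.shape[0]:
            raise ValueError("L does not match grid shape")


@dataclass
class AnchorSpec:
    """A chosen grafting site.

    ``site`` is ``(x, y, z_S + 1)``: the chain's first segment sits one
    lattice unit above the selected surface element.  ``region`` is the
    inclusive ``((x0, x1), (y0, y1))`` index window the site was drawn from.
    """

    mode: AnchorMode
    region: tuple[tuple[int, int], tuple[int, int]]
    site: tuple[int, int, int]


def _integerize(values: np.ndarray, how: str) -> np.ndarray:
    """Convert float altitudes to integers ('trunc' toward zero or 'floor')."""
    if how == "trunc":
        return np.trunc(values).astype(np.int32)
    if how == "floor":
        return np.floor(values).astype(np.int32)
    raise ValueError(f"unknown integerization mode {how!r}")


def generate_ugm(
    L: int,
    z0: int = 0,
    sigma: float = 1.0,
    seed: int = 0,
    integerize: str = "trunc",
    literal_single_uniform: bool = False,
) -> HeightField:
    """Generate an uncorrelated Gaussian (uGm) surface.

    Each cell altitude is the integer part of an independent normal variate
    with mean ``z0`` and standard deviation ``sigma``.

    Parameters
    ----------
    L :
        Edge length in sites (>= 2; L = 1 is allowed only for fixtures).
    z0 :
        Mean altitude.
    sigma :
        Altitude standard deviation before integerization (>= 0).
    seed :
        RNG seed; identical seeds give identical grids.
    integerize :
        ``'trunc'`` (integer part toward zero, the default) or ``'floor'``.
        The two differ only for negative altitudes around zero.
    literal_single_uniform :
        If True, use the single-uniform Box–Muller variant
        ``z0 + sigma*sqrt(-2 ln X) cos(2 pi X)`` with the *same* uniform
        draw ``X`` in both factors.  This reproduces a historical recipe
        exactly but is not an exact normal generator; the default draws
        proper normal variates.
    """
    if L < 1:
        raise ValueError(f"L must be positive, got {L}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        grid = np.full((L, L), z0, dtype=np.int32)
    elif literal_single_uniform:
        x = rng.random((L, L))
        x = np.clip(x, np.finfo(float).tiny, None)
        values = z0 + sigma * np.sqrt(-2.0 * np.log(x)) * np.cos(2.0 * np.pi * x)
        grid = _integerize(values, integerize)
    else:
        values = rng.normal(loc=z0, scale=sigma, size=(L, L))
        grid = _integerize(values, integerize)
    meta = {
        "type": "ugm",
        "L": L,
        "z0": z0,
        "sigma": sigma,
        "H": "",
        "seed": seed,
        "integerize": integerize,
    }
    return HeightField(z=grid, L=L, meta=meta)


def generate_rmd(
    L: int,
    z0: int = 0,
    H: float = 0.5,
    sigma: float = 1.0,
    seed: int = 0,
    addition_prob: float = 0.5,
    addition_decay: float = ADDITION_DECAY,
    rescale_to: float | None = None,
    integerize: str = "trunc",
) -> HeightField:
    """Generate a Bm (``H = 1/2``) or fBm (``H != 1/2``) surface by random
    midpoint displacement with successive random additions.

    The initially flat grid is refined recursively: at refinement level
    ``l`` (mesh size halved per level) the midpoint displacements have
    standard deviation ``sigma * 2**(-l*H)``.  After the recursion every
    site receives one successive random addition per level, with the
    faster-decaying amplitude ``sqrt(addition_prob) * sigma *
    2**(-l*addition_decay*H)`` (the same injected power as additions firing
    with probability ``addition_prob``, without the coarse-level coin-flip
    variance); these additions set the lattice-scale roughness of the final
    integer grid, which the smooth midpoint relief alone cannot supply.
    Finally the altitudes are shifted by ``z0`` and converted to integers.

    Parameters
    ----------
    L :
        Edge length; must be a power of two (the recursion generates on a
        ``(L+1) x (L+1)`` grid and drops the last row and column).
    H :
        Hurst exponent (> 0).  Smaller values give rougher relief; for the
        self-affine float field ``H`` relates to the fractal dimension as
        ``D_F = 3 - H``.  Values above 1 are accepted and simply produce
        very smooth fields.
    sigma :
        Displacement amplitude at the coarsest scale (> 0).  Note that this
        parametrizes the generator schedule; the empirical altitude standard
        deviation of the finished grid is measured by
        :func:`graftropy.roughness.altitude_std` and generally differs from
        ``sigma``.  Pass ``rescale_to`` to force a target SD instead.
    addition_prob :
        Power fraction of the successive random additions (equivalent to a
        per-level firing probability); 0 disables them.
    rescale_to :
        If given, affinely rescale the float field to this altitude SD
        before integerization.
    """
    if L < 2 or (L & (L - 1)) != 0:
        raise ValueError(f"L must be a power of two >= 2, got {L}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not 0.0 <= addition_prob <= 1.0:
        raise ValueError(f"addition_prob must be in [0, 1], got {addition_prob}")
    rng = np.random.default_rng(seed)
    n_levels = int(math.log2(L))
    size = L + 1
    grid = np.zeros((size, size), dtype=np.float64)

    # Midpoint-displacement (diamond-square) recursion on the (L+1)^2 grid.
    step = L
    for level in range(1, n_levels + 1):
        half = step // 2
        sd = sigma * 2.0 ** (-level * H)
        # Diamond step: centers of the current squares.
        cx = np.arange(half, size, step)
        centers = grid[np.ix_(cx, cx)]
        corners = (
            grid[np.ix_(cx - half, cx - half)]
            + grid[np.ix_(cx - half, cx + half)]
            + grid[np.ix_(cx + half, cx - half)]
            + grid[np.ix_(cx + half, cx + half)]
        ) / 4.0
        grid[np.ix_(cx, cx)] = corners + rng.normal(0.0, sd, centers.shape)
        # Square step: edge midpoints, averaging available axial neighbours.
        mask = np.zeros((size, size), dtype=bool)
        mask[np.ix_(cx, np.arange(0, size, step))] = True
        mask[np.ix_(np.arange(0, size, step), cx)] = True
        xs, ys = np.nonzero(mask)
        acc = np.zeros(xs.shape[0])
        cnt = np.zeros(xs.shape[0])
        for dx, dy in ((half, 0), (-half, 0), (0, half), (0, -half)):
            nx, ny = xs + dx, ys + dy
            ok = (nx >= 0) & (nx < size) & (ny >= 0) & (ny < size)
            acc[ok] += grid[nx[ok], ny[ok]]
            cnt[ok] += 1
        grid[xs, ys] = acc / cnt + rng.normal(0.0, sd, xs.shape[0])
        step = half

    # Successive random additions: per-site noise at each level's scale.
    # The amplitude carries sqrt(addition_prob) so the injected noise power
    # matches a schedule that fires with probability addition_prob per
    # level, without the large seed-to-seed roughness swings a literal
    # per-level coin would cause (the coarsest level dominates).
    if addition_prob > 0:
        amp = math.sqrt(addition_prob)
        for level in range(1, n_levels + 1):
            sd = amp * sigma * 2.0 ** (-level * addition_decay * H)
            grid += rng.normal(0.0, sd, grid.shape)

    grid = grid[:L, :L]
    # Relief below integer resolution is flattened outright; otherwise the
    # sign of vanishing noise would dither cells across the z0 boundary.
    if np.ptp(grid) < 1e-6:
        grid = np.zeros_like(grid)
    if rescale_to is not None:
        sd_now = grid.std()
        if sd_now > 0:
            grid = grid * (rescale_to / sd_now)
    values = grid + z0
    field_z = _integerize(values, integerize)
    meta = {
        "type": "bm" if H == 0.5 else "fbm",
        "L": L,
        "z0": z0,
        "sigma": sigma,
        "H": H,
        "seed": seed,
        "addition_prob": addition_prob,
        "addition_decay": addition_decay,
        "integerize": integerize,
    }
    return HeightField(z=field_z, L=L, meta=meta)


def anchor_region(L: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Inclusive central-region index window scaled to a parent of edge L."""
    lo = int(round(ANCHOR_REGION_FRACTIONS[0] * L))
    hi = int(round(ANCHOR_REGION_FRACTIONS[1] * L))
    lo = min(lo, L - 1)
    hi = min(hi, L - 1)
    if hi < lo:
        raise ValueError(f"empty anchor region for L={L}")
    return ((lo, hi), (lo, hi))


def select_anchor(
    field: HeightField, mode: AnchorMode, seed: int = 0
) -> AnchorSpec:
    """Choose a grafting site from the central region of ``field``.

    ``min``/``max`` pick a site of extremal altitude within the region (ties
    broken uniformly at random); ``mean`` picks a region site whose altitude
    is closest to the mean altitude of *all* surface sites; ``random`` picks
    a uniformly random region site.  The returned anchor ``z`` coordinate is
    the site altitude plus one — the chain starts on the first free site
    above the surface element.
    """
    (x0, x1), (y0, y1) = region = anchor_region(field.L)
    rng = np.random.default_rng(seed)
    window = field.z[x0 : x1 + 1, y0 : y1 + 1]
    if window.size == 0:
        raise ValueError("empty anchor region")
    if mode in ("min", "max"):
        target = window.min() if mode == "min" else window.max()
        xs, ys = np.nonzero(window == target)
        pick = rng.integers(len(xs))
        x, y = x0 + int(xs[pick]), y0 + int(ys[pick])
    elif mode == "mean":
        mean_alt = field.z.mean()
        dist = np.abs(window.astype(np.float64) - mean_alt)
        xs, ys = np.nonzero(dist == dist.min())
        pick = rng.integers(len(xs))
        x, y = x0 + int(xs[pick]), y0 + int(ys[pick])
    elif mode == "random":
        x = int(rng.integers(x0, x1 + 1))
        y = int(rng.integers(y0, y1 + 1))
    else:
        raise ValueError(f"unknown anchor mode {mode!r}")
    z_s = int(field.z[x, y])
    return AnchorSpec(mode=mode, region=region, site=(x, y, z_s + 1))


def reduce_surface(
    field: HeightField, anchor: AnchorSpec, box_edge: int
) -> tuple[HeightField, AnchorSpec]:
    """Crop a ``box_edge``-wide window of ``field`` centred on the anchor.

    The window is clamped so that it stays inside the parent grid; the
    returned anchor carries window coordinates (at the window centre, or the
    nearest attainable site after clamping).
    """
    if box_edge > field.L:
        raise ValueError(
            f"box_edge {box_edge} exceeds parent edge {field.L}"
        )
    ax, ay, az = anchor.site
    half = box_edge // 2
    x0 = int(np.clip(ax - half, 0, field.L - box_edge))
    y0 = int(np.clip(ay - half, 0, field.L - box_edge))
    window = np.ascontiguousarray(
        field.z[x0 : x0 + box_edge, y0 : y0 + box_edge]
    )
    meta = dict(field.meta)
    meta.update({"parent_L": field.L, "crop_x0": x0, "crop_y0": y0})
    new_field = HeightField(z=window, L=box_edge, meta=meta)
    (rx0, rx1), (ry0, ry1) = anchor.region
    clip = lambda v, lo, hi: int(np.clip(v, lo, hi))
    new_region = (
        (clip(rx0 - x0, 0, box_edge - 1), clip(rx1 - x0, 0, box_edge - 1)),
        (clip(ry0 - y0, 0, box_edge - 1), clip(ry1 - y0, 0, box_edge - 1)),
    )
    new_anchor = AnchorSpec(
        mode=anchor.mode, region=new_region, site=(ax - x0, ay - y0, az)
    )
    return new_field, new_anchor


def is_blocked(field: HeightField, site: tuple[int, int, int]) -> bool:
    """True iff ``site`` lies inside the solid (``z < z_S(x, y)``)."""
    x, y, z = site
    if not (0 <= x < field.L and 0 <= y < field.L):
        raise IndexError(f"site {site} outside the {field.L}x{field.L} field")
    return z < int(field.z[x, y])


# ---------------------------------------------------------------------------
# Plain-text grid file format
# ---------------------------------------------------------------------------

def write_heightfield(field: HeightField, path: str | Path) -> None:
    """Write a heightfield in the plain-text grid format.

    Header lines are ``#key value`` (generation metadata), followed by ``L``
    rows of ``L`` whitespace-separated integers.  Round-trips exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key, value in field.meta.items():
            fh.write(f"#{key} {value}\n")
        for row in field.z:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_heightfield(path: str | Path) -> HeightField:
    """Read a heightfield written by :func:`write_heightfield`."""
    path = Path(path)
    meta: dict = {}
    rows: list[list[int]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(" ")
                meta[key] = _parse_meta_value(value.strip())
            else:
                rows.append([int(tok) for tok in line.split()])
    grid = np.array(rows, dtype=np.int32)
    return HeightField(z=grid, L=grid.shape[0], meta=meta)


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
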