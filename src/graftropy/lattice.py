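"""Cubic lattice, (023) move set, and simulation-box geometry.

The chain model lives on a simple cubic lattice of constant ``a``.  Successive
segments are connected by bond vectors that are signed permutations of
``(0, 2a, 3a)`` with one zero component ("(023) motion").  This gives a
lattice coordination number of 24 and a bond length of ``sqrt(13)*a``, i.e. a
highly flexible chain.  The simulation box is a finite cube of
``box_edge**3`` sites; sites outside the box are treated as blocked.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

#: Coordination number of the (023) move set.
COORDINATION = 24

#: Squared bond length in units of a**2.
BOND_LENGTH_SQ = 13


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry of the cubic lattice and the finite simulation box.

    Parameters
    ----------
    a :
        Lattice constant (the length unit of the model). Must be positive.
    box_edge :
        Number of lattice sites along each box edge.  The box is the
        half-open cube ``[0, box_edge)**3`` of 0-based integer site indices.
        Must be odd (so the box has a central site) and at least 3.
    """

    a: float = 1.0
    box_edge: int = 601

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"lattice constant must be positive, got {self.a}")
        if self.box_edge < 3 or self.box_edge % 2 == 0:
            raise ValueError(
                f"box_edge must be odd and >= 3, got {self.box_edge}"
            )

    @property
    def origin(self) -> tuple[int, int, int]:
        """The central site of the box."""
        c = self.box_edge // 2
        return (c, c, c)


@dataclass(frozen=True)
class MoveSet:
    """The ordered bond vectors of the (023) chain model.

    ``vectors`` holds the 24 signed permutations of ``(0, 2, 3)`` (one zero
    component each) in canonical lexicographic order, so that seeded runs are
    bit-reproducible.  All vectors have squared norm 13 (in units of a**2)
    and the set is closed under negation.
    """

    vectors: tuple[tuple[int, int, int], ...]
    bond_length_sq: int = BOND_LENGTH_SQ

    def __len__(self) -> int:
        return len(self.vectors)

    def as_array(self, dtype=np.int64) -> np.ndarray:
        """Return the move vectors as a ``(24, 3)`` integer array."""
        return np.array(self.vectors, dtype=dtype)


def generate_move_set() -> MoveSet:
    """Build the 24-vector (023) move set.

    Returns every distinct signed permutation of ``(0, ±2, ±3)`` with one
    zero component, sorted lexicographically.
    """
    vecs = set()
    for perm in itertools.permutations((0, 2, 3)):
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    vecs.add((sx * perm[0], sy * perm[1], sz * perm[2]))
    ordered = tuple(sorted(vecs))
    assert len(ordered) == COORDINATION
    return MoveSet(vectors=ordered)


def bond_length(a: float) -> float:
    """Segment length of the (023) chain: ``sqrt(13) * a`` (≈ 3.606 a)."""
    if not a > 0:
        raise ValueError(f"lattice constant must be positive, got {a}")
    return math.sqrt(BOND_LENGTH_SQ) * a


def in_box(site: tuple[int, int, int], cfg: LatticeConfig) -> bool:
    """True iff every coordinate of ``site`` lies in ``[0, box_edge)``."""
    e = cfg.box_edge
    x, y, z = site
    return 0 <= x < e and 0 <= y < e and 0 <= z < e
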