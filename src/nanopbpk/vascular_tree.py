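"""Symmetric power-law vascular branching element.

A branching element starts at the main-artery diameter, bifurcates
symmetrically under Murray's law ``d_parent^k = d_1^k + d_2^k`` (so each
daughter has ``d_child = (d_parent^k / 2)^(1/k)``) until the daughter
diameter reaches the red-blood-cell bound, and then mirrors back out on the
venous side.  Vessel length is tied to diameter by ``L = beta * d`` and the
branch count at descending generation ``n`` is ``N = 2^n``.

With the murine defaults (d0 = 600 um, d_min = 15 um, k = 3) this yields 16
bifurcations, i.e. 32 generations per element.  Element surface area and
volume are organ-independent; an organ is tiled by ``phi = V_bl / V_element``
copies of the element (phi may be fractional, e.g. spleen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: litres per cubic micrometre
UM3_TO_L = 1e-15


@dataclass(frozen=True)
class Generation:
    n: int        # generation index, 1..2G
    d: float      # vessel diameter, um
    l: float      # vessel length, um
    N: int        # number of parallel branches


@dataclass
class VascularTree:
    generations: list[Generation]
    G: int            # number of bifurcations
    d0: float         # root diameter, um
    d_min: float      # terminal diameter bound, um
    k: float          # Murray exponent
    beta: float       # length-to-diameter ratio

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    @property
    def terminal_diameter(self) -> float:
        """Diameter at the capillary-level generation (um)."""
        return self.generations[self.G - 1].d

    def surface_area(self) -> float:
        """Total element vessel surface area (um^2), both halves."""
        return sum(math.pi * g.d * g.l * g.N for g in self.generations)

    def volume(self) -> float:
        """Total element vascular volume (um^3), both halves."""
        return sum(math.pi * (g.d / 2.0) ** 2 * g.l * g.N for g in self.generations)

    def volume_litres(self) -> float:
        return self.volume() * UM3_TO_L

    def generation_volumes_litres(self) -> np.ndarray:
        """Per-generation vascular volume (L), ordered by generation index."""
        return np.array(
            [math.pi * (g.d / 2.0) ** 2 * g.l * g.N * UM3_TO_L for g in self.generations]
        )

    def generation_areas(self) -> np.ndarray:
        """Per-generation vessel surface area (um^2)."""
        return np.array([math.pi * g.d * g.l * g.N for g in self.generations])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"n": g.n, "d_um": g.d, "l_um": g.l, "N": g.N} for g in self.generations]
        ).set_index("n")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def daughter_diameter(d_parent: float, k: float) -> float:
    """Symmetric Murray-law daughter diameter ``(d_parent^k / 2)^(1/k)``.

    Evaluated as ``d_parent * 2**(-1/k)``, the algebraically identical form
    that cannot overflow for large exponents.
    """
    if d_parent <= 0:
        raise ValueError(f"d_parent must be > 0, got {d_parent}")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    return d_parent * 2.0 ** (-1.0 / k)


def build_tree(
    d0: float = 600.0, d_min: float = 15.0, k: float = 3.0, beta: float = 3.0
) -> VascularTree:
    """Bifurcate from ``d0`` until the daughter diameter is <= ``d_min``.

    The stopping rule is inclusive: the first generation whose diameter
    drops to or below ``d_min`` terminates the descending half.  The
    ascending (venous) half mirrors the descending generations, giving
    ``2G`` generations in total.
    """
    if d0 <= d_min:
        raise ValueError(f"d0 ({d0}) must exceed d_min ({d_min})")
    if d_min <= 0:
        raise ValueError("d_min must be > 0")

    descending: list[Generation] = []
    d = d0
    n = 0
    while True:
        d = daughter_diameter(d, k)
        n += 1
        descending.append(Generation(n=n, d=d, l=beta * d, N=2**n))
        if d <= d_min:
            break
        if n > 10_000:
            raise RuntimeError("branching did not terminate; check k and d_min")

    G = n
    ascending = [
        Generation(n=2 * G + 1 - g.n, d=g.d, l=g.l, N=g.N) for g in reversed(descending)
    ]
    return VascularTree(
        generations=descending + ascending, G=G, d0=d0, d_min=d_min, k=k, beta=beta
    )


def element_geometry(tree: VascularTree) -> tuple[float, float]:
    """(surface area um^2, volume um^3) of one element.

    Computed as twice the descending-half sums; identical to summing both
    mirrored halves explicitly.
    """
    desc = tree.generations[: tree.G]
    sa = 2.0 * sum(math.pi * g.d * g.l * g.N for g in desc)
    vol = 2.0 * sum(math.pi * (g.d / 2.0) ** 2 * g.l * g.N for g in desc)
    return sa, vol


def element_count(organ_vascular_volume_L: float, element_volume_L: float) -> float:
    """phi = organ vascular volume / element volume (fractional allowed)."""
    if organ_vascular_volume_L <= 0 or element_volume_L <= 0:
        raise ValueError("volumes must be > 0")
    return organ_vascular_volume_L / element_volume_L


def attach_phi(phys, tree: VascularTree):
    """Return a copy of ``phys`` with per-organ element counts filled in."""
    v_el = tree.volume_litres()
    for organ in phys.organs.values():
        organ.phi = element_count(organ.V_bl, v_el)
    return phys
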