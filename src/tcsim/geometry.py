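"""Cell placement: cortical cells in a layered cylinder, thalamic cells in
stacked boxes.

The depth axis is y, increasing downward from the pia (y = 0 at the top of
L1).  Cortical cells are uniform over the disc cross-section (inverse-CDF
radius sampling, r = R*sqrt(u)) and uniform in depth within their layer.
Thalamic populations are stacked boxes below the column, uniform per box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import parse_me_type

CORTICAL_LAYERS = ("L1", "L23", "L4", "L5", "L6")
THALAMIC_POPULATIONS = ("RTNo", "RTNm", "RTNi", "VPL", "VPM", "POm")
THALAMIC_INHIBITORY = ("RTNo", "RTNm", "RTNi")


@dataclass(frozen=True)
class ColumnGeometry:
    """Layered cylindrical cortical column (default 2,082 um tall, 210 um radius)."""

    height: float = 2082.0
    radius: float = 210.0
    layer_thicknesses: dict = field(default_factory=lambda: {
        "L1": 165.0, "L23": 502.0, "L4": 190.0, "L5": 525.0, "L6": 700.0})

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        total = sum(self.layer_thicknesses.values())
        if abs(total - self.height) > 1e-9:
            raise ValueError(
                f"layer thicknesses sum to {total}, not the column height {self.height}")


@dataclass(frozen=True)
class ThalamicGeometry:
    """Stacked thalamic boxes, 420 x 420 um in XZ, listed top to bottom."""

    xz_side: float = 420.0
    sector_heights: dict = field(default_factory=lambda: {
        "RTNo": 78.0, "RTNm": 78.0, "RTNi": 156.0,
        "VPL": 156.0, "VPM": 156.0, "POm": 312.0})
    y_offset: float = 2282.0  # depth of the top of the thalamic stack

    def __post_init__(self):
        if any(h <= 0 for h in self.sector_heights.values()):
            raise ValueError("sector heights must be positive")

    def bounds(self) -> dict:
        """Half-open [top, bottom) depth interval per population, stacked."""
        out, y = {}, self.y_offset
        for pop in THALAMIC_POPULATIONS:
            h = self.sector_heights[pop]
            out[pop] = (y, y + h)
            y += h
        return out


@dataclass(frozen=True)
class CellInstance:
    """A placed cell."""

    id: int
    population: str
    me_type: str
    m_type: str
    layer: str
    position: tuple[float, float, float]
    excitatory: bool


def layer_bounds(geometry: ColumnGeometry) -> dict:
    """Cumulative half-open [top, bottom) depth intervals covering [0, height)."""
    for name, t in geometry.layer_thicknesses.items():
        if t <= 0:
            raise ValueError(f"non-positive thickness for {name}")
    out, y = {}, 0.0
    for layer in geometry.layer_thicknesses:
        t = geometry.layer_thicknesses[layer]
        out[layer] = (y, y + t)
        y += t
    return out


def _sample_disc(n: int, radius: float, rng: np.random.Generator):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r * np.cos(theta), r * np.sin(theta)


def place_cortical_cells(geometry: ColumnGeometry, counts: pd.DataFrame,
                         seed: int, excitatory_map=None,
                         id_offset: int = 0) -> list[CellInstance]:
    """Place cells per the count table (columns ``me_type``, ``count``).

    The layer of each population is taken from its me-type name; each cell is
    uniform over its layer's disc slice.
    """
    rng = np.random.default_rng(seed)
    bounds = layer_bounds(geometry)
    cells: list[CellInstance] = []
    next_id = id_offset
    for _, row in counts.iterrows():
        me_type, n = str(row["me_type"]), int(row["count"])
        if n < 0:
            raise ValueError(f"negative count for {me_type}")
        layer, m_type, e_type = parse_me_type(me_type)
        if layer not in bounds:
            raise ValueError(f"unknown layer {layer!r} for {me_type}")
        y0, y1 = bounds[layer]
        x, z = _sample_disc(n, geometry.radius, rng)
        y = rng.uniform(y0, y1, size=n)
        if excitatory_map is not None:
            exc = bool(excitatory_map[me_type])
        else:
            exc = e_type.startswith("cAD")
        for i in range(n):
            cells.append(CellInstance(
                id=next_id, population=me_type, me_type=me_type, m_type=m_type,
                layer=layer, position=(float(x[i]), float(y[i]), float(z[i])),
                excitatory=exc))
            next_id += 1
    return cells


def place_thalamic_cells(geometry: ThalamicGeometry, counts: pd.DataFrame,
                         seed: int, density_scaling: dict | None = None,
                         id_offset: int = 0) -> list[CellInstance]:
    """Place thalamic cells uniformly within their population's box.

    ``density_scaling`` maps population name to a factor in (0, 1]; POm is
    halved by default to discount M1-projecting cells with no S1 projection.
    """
    scaling = {"POm": 0.5}
    if density_scaling is not None:
        scaling.update(density_scaling)
    for pop, s in scaling.items():
        if not 0 < s <= 1:
            raise ValueError(f"density scaling for {pop} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    bounds = geometry.bounds()
    half = geometry.xz_side / 2.0
    cells: list[CellInstance] = []
    next_id = id_offset
    for _, row in counts.iterrows():
        pop, n = str(row["population"]), int(row["count"])
        if pop not in bounds:
            raise ValueError(f"unknown thalamic population {pop!r}")
        n = int(round(n * scaling.get(pop, 1.0)))
        y0, y1 = bounds[pop]
        x = rng.uniform(-half, half, size=n)
        z = rng.uniform(-half, half, size=n)
        y = rng.uniform(y0, y1, size=n)
        exc = pop not in THALAMIC_INHIBITORY
        for i in range(n):
            cells.append(CellInstance(
                id=next_id, population=pop, me_type=pop, m_type=pop, layer=pop,
                position=(float(x[i]), float(y[i]), float(z[i])),
                excitatory=exc))
            next_id += 1
    return cells


def positions(cells: list[CellInstance]) -> np.ndarray:
    """(n, 3) array of x, y, z positions."""
    return np.array([c.position for c in cells], dtype=float).reshape(-1, 3)


def export_placements(cells: list[CellInstance], path: str | Path) -> None:
    df = pd.DataFrame({
        "id": [c.id for c in cells],
        "population": [c.population for c in cells],
        "x": [c.position[0] for c in cells],
        "y": [c.position[1] for c in cells],
        "z": [c.position[2] for c in cells],
    })
    df.to_csv(path, sep="\t", index=False)


def default_cortical_counts() -> pd.DataFrame:
    path = Path(resources.files("tcsim").joinpath("data", "cortical_counts.tsv"))
    return pd.read_csv(path, sep="\t")


def default_thalamic_counts() -> pd.DataFrame:
    path = Path(resources.files("tcsim").joinpath("data", "thalamic_counts.tsv"))
    return pd.read_csv(path, sep="\t")
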