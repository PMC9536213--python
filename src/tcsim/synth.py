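"""Synthetic-fixture generators.

These produce every input the rest of the package consumes: stochastic
connectome instances drawn from known ground-truth distance-probability
curves (standing in for external connectome data), scaled cell-count tables,
toy multi-segment cables for the LFP engine, and Poisson spike trains for
replay.  Edge tables are plain TSV (pre id, post id, XZ distance in um,
synapse count); spike trains are two-column text (cell id, time in ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import evaluate_form, xz_distances, FORMS
from .geometry import default_cortical_counts
from .lfp import Segment, SegmentCurrentFrame


@dataclass(frozen=True)
class GroundTruthPathway:
    """A generating distance-probability curve plus mean synapse count."""

    form: str
    params: tuple
    mean_nsyn: float = 1.0

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown probability form {self.form!r}")
        if self.mean_nsyn < 1:
            raise ValueError("mean_nsyn must be >= 1")

    def probability(self, d):
        return evaluate_form(self.form, self.params, d)


@dataclass
class SyntheticInstanceSet:
    """Edge tables for n independent instances over one fixed placement."""

    n_instances: int
    seed: int
    instances: list[pd.DataFrame] = field(default_factory=list)


def _nsyn_draw(rng: np.random.Generator, mean_nsyn: float, size: int) -> np.ndarray:
    """Poisson synapse counts conditioned >= 1, mean matched.

    Draw k ~ 1 + Poisson(mu) with mu = mean_nsyn - 1, which has exactly the
    requested mean and support >= 1.
    """
    return 1 + rng.poisson(max(mean_nsyn - 1.0, 0.0), size=size)


def gen_connectome_instances(
    gt: GroundTruthPathway, pre_xyz: np.ndarray, post_xyz: np.ndarray,
    n_instances: int = 7, seed: int = 0, same_population: bool = False,
) -> SyntheticInstanceSet:
    """Draw edges Bernoulli(p(d)) per ordered pair, independently per instance.

    Placements are fixed across instances; only the edge draws differ.
    """
    if len(pre_xyz) == 0 or len(post_xyz) == 0:
        raise ValueError("placements must be non-empty")
    rng = np.random.default_rng(seed)
    dmat = xz_distances(pre_xyz, post_xyz)
    p = gt.probability(dmat)
    if same_population:
        np.fill_diagonal(p, 0.0)
    out = SyntheticInstanceSet(n_instances=n_instances, seed=seed)
    for _ in range(n_instances):
        hit = rng.uniform(size=p.shape) < p
        pre_idx, post_idx = np.nonzero(hit)
        nsyn = _nsyn_draw(rng, gt.mean_nsyn, len(pre_idx))
        out.instances.append(pd.DataFrame({
            "pre": pre_idx, "post": post_idx,
            "distance": dmat[pre_idx, post_idx], "nsyn": nsyn,
        }))
    return out


def gen_cell_counts(scale: float, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scale the default cortical count table; every population keeps >= 1 cell."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if table is None:
        table = default_cortical_counts()
    out = table.copy()
    out["count"] = np.maximum(
        1, np.rint(table["count"].to_numpy() * scale)).astype(int)
    return out


def gen_toy_cable(n_segments: int, length: float, waveform: np.ndarray,
                  origin=(0.0, 0.0, 0.0), axis=(0.0, 1.0, 0.0),
                  balanced: bool = False) -> list[SegmentCurrentFrame]:
    """A straight cable of ``n_segments`` equal segments driven by a waveform.

    Each timestep t yields a frame whose segment currents are ``waveform[t]``
    scaled per segment.  The ``balanced`` variant assigns +waveform to the
    distal half and -waveform to the proximal half (exactly zero net current
    per frame — a current dipole).
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ds = length / n_segments
    segs = [Segment(tuple(origin + axis * (i * ds)),
                    tuple(origin + axis * ((i + 1) * ds)))
            for i in range(n_segments)]
    if balanced:
        half = n_segments // 2
        sign = np.ones(n_segments)
        sign[:half] = -1.0
        if n_segments % 2 == 1:
            sign[half] = 0.0
        # exact zero-sum even for odd counts
    else:
        sign = np.ones(n_segments)
    frames = [SegmentCurrentFrame(segs, sign * float(w)) for w in waveform]
    return frames


def gen_poisson_spikes(n_cells: int, rate_hz: float, duration_ms: float,
                       seed: int, id_offset: int = 0) -> pd.DataFrame:
    """Independent homogeneous Poisson spike trains, sorted by time."""
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for i in range(n_cells):
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        t = np.sort(rng.uniform(0.0, duration_ms, size=n))
        ids.append(np.full(n, id_offset + i, dtype=int))
        times.append(t)
    df = pd.DataFrame({"cell": np.concatenate(ids) if ids else [],
                       "time": np.concatenate(times) if times else []})
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def write_edges(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spikes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["cell", "time"])
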