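"""Standardized compartmental morphology shared by all projection-specific models.

The model cell is a soma with two primary dendrites, each splitting into two
distal branches 75-150 um from the soma.  One primary dendrite carries an
additional 50-um side branch originating 50 um from the soma; that side branch
plus the primary segment between it and the soma form the axon-bearing dendrite
(ABD), and the axon initial segment (AIS) attaches to the side branch tip.  The
dendritic tree is discretized into exactly 114 electrical segments by default.

Coordinates are path distances (um) from the soma center; no 3D embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class Region(str, Enum):
    SOMA = "soma"
    PRIMARY = "primary_dendrite"
    DISTAL = "distal_dendrite"
    ABD = "ABD"
    AIS = "AIS"


@dataclass(frozen=True)
class Compartment:
    """One electrical segment (cylinder) of the model cell."""

    id: int
    parent_id: Optional[int]
    region: Region
    length: float  # um
    diameter: float  # um
    path_distance: float  # um, soma center to segment center

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("compartment length and diameter must be positive")

    @property
    def surface_area(self) -> float:
        """Lateral cylinder area pi*d*L in um^2 (soma treated as cylinder too)."""
        return math.pi * self.diameter * self.length


def surface_area(c: Compartment) -> float:
    """Lateral cylinder area of a compartment in um^2."""
    return c.surface_area


@dataclass(frozen=True)
class MorphologyConfig:
    """Geometry knobs for :func:`build_morphology`.

    Defaults follow the standard cell: split at 100 um (midpoint of the
    admissible 75-150 um interval), 50 um ABD side branch at 50 um, 114
    dendritic segments.  Soma 25x25 um and AIS 30x1.5 um are declared
    defaults (the geometry source gives no dimensions for either).
    """

    primary_branch_split_distance: float = 100.0  # um from soma
    split_distance_bounds: tuple[float, float] = (75.0, 150.0)
    abd_branch_origin: float = 50.0  # um from soma
    abd_branch_length: float = 50.0  # um
    distal_branch_length: float = 250.0  # um
    segment_count_target: int = 114
    soma_length: float = 25.0
    soma_diameter: float = 25.0
    ais_length: float = 30.0
    ais_diameter: float = 1.5
    primary_diameter: float = 2.0
    distal_tip_diameter: float = 1.0
    max_segment_length: float = 30.0  # um, spatial-resolution guard

    def validate(self) -> None:
        lo, hi = self.split_distance_bounds
        if not (lo <= self.primary_branch_split_distance <= hi):
            raise ValueError(
                f"split distance {self.primary_branch_split_distance} outside [{lo}, {hi}]"
            )
        for name in ("abd_branch_origin", "abd_branch_length", "distal_branch_length",
                     "soma_length", "soma_diameter", "ais_length", "ais_diameter",
                     "primary_diameter", "distal_tip_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.abd_branch_origin >= self.primary_branch_split_distance:
            raise ValueError("ABD side branch must originate proximal to the primary split")
        if self.segment_count_target < 7:
            raise ValueError("cannot place >=1 segment on each of the 7 dendritic branches")


@dataclass
class Morphology:
    """Tree of compartments with fixed axial resistivity (default 200 Ohm*cm)."""

    compartments: list[Compartment]
    axial_resistivity: float = 200.0  # Ohm*cm

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if ids != list(range(len(ids))):
            raise ValueError("compartment ids must be consecutive from 0")
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1 or roots[0].region is not Region.SOMA:
            raise ValueError("exactly one root compartment (the soma) is required")
        for c in self.compartments:
            if c.parent_id is not None and not (0 <= c.parent_id < c.id):
                raise ValueError("parents must precede children (topological order)")

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def parent_index(self) -> np.ndarray:
        """Parent id per compartment (-1 for the soma root)."""
        return np.array(
            [-1 if c.parent_id is None else c.parent_id for c in self.compartments],
            dtype=np.int64,
        )

    @property
    def regions(self) -> list[Region]:
        return [c.region for c in self.compartments]

    def ids_in_region(self, region: Region) -> list[int]:
        return [c.id for c in self.compartments if c.region is region]

    @property
    def soma_id(self) -> int:
        return self.ids_in_region(Region.SOMA)[0]

    @property
    def ais_id(self) -> int:
        return self.ids_in_region(Region.AIS)[0]

    @property
    def dendritic_ids(self) -> list[int]:
        """All segments that are neither soma nor AIS (the 114-segment tree)."""
        return [c.id for c in self.compartments
                if c.region not in (Region.SOMA, Region.AIS)]

    def n_dendritic_segments(self) -> int:
        return len(self.dendritic_ids)

    def path_distance(self, comp_id: int) -> float:
        if not (0 <= comp_id < len(self.compartments)):
            raise KeyError(f"unknown compartment id {comp_id}")
        return self.compartments[comp_id].path_distance

    def path_distances(self) -> np.ndarray:
        return np.array([c.path_distance for c in self.compartments])

    def surface_areas(self) -> np.ndarray:
        """Per-compartment lateral areas in um^2."""
        return np.array([c.surface_area for c in self.compartments])

    def total_membrane_area(self) -> float:
        return float(self.surface_areas().sum())

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compartments],
                "parent": [-1 if c.parent_id is None else c.parent_id
                           for c in self.compartments],
                "region": [c.region.value for c in self.compartments],
                "length_um": [c.length for c in self.compartments],
                "diameter_um": [c.diameter for c in self.compartments],
                "path_distance_um": [c.path_distance for c in self.compartments],
            }
        )

    def to_csv(self, path) -> None:
        # %.17g guarantees float64 round-trips through the text form
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, axial_resistivity: float = 200.0) -> "Morphology":
        comps = [
            Compartment(
                id=int(r.id),
                parent_id=None if int(r.parent) < 0 else int(r.parent),
                region=Region(r.region),
                length=float(r.length_um),
                diameter=float(r.diameter_um),
                path_distance=float(r.path_distance_um),
            )
            for r in df.itertuples()
        ]
        return cls(comps, axial_resistivity=axial_resistivity)

    @classmethod
    def from_csv(cls, path, axial_resistivity: float = 200.0) -> "Morphology":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, axial_resistivity=axial_resistivity)


# ---------------------------------------------------------------------------
# construction


@dataclass
class _Branch:
    name: str
    length: float
    region: Region
    parent_branch: Optional[str]  # attach to tip of this branch (None -> soma)
    diam_start: float
    diam_end: float


def _allocate_segments(branches: list[_Branch], target: int, max_seg_len: float) -> dict[str, int]:
    """Distribute `target` segments proportionally to branch length.

    Floor of the proportional share first (at least 1 per branch), then hand the
    remainder to the longest branches — deterministic and close to uniform
    spatial resolution.
    """
    total = sum(b.length for b in branches)
    raw = {b.name: target * b.length / total for b in branches}
    counts = {k: max(1, int(math.floor(v))) for k, v in raw.items()}
    if sum(counts.values()) > target:
        raise ValueError(
            f"segment target {target} cannot give every branch >=1 segment"
        )
    remainder = target - sum(counts.values())
    order = sorted(branches, key=lambda b: (-b.length, b.name))
    i = 0
    while remainder > 0:
        counts[order[i % len(order)].name] += 1
        remainder -= 1
        i += 1
    for b in branches:
        if b.length / counts[b.name] > max_seg_len:
            raise ValueError(
                f"branch {b.name}: segment length {b.length / counts[b.name]:.1f} um "
                f"exceeds maximum {max_seg_len} um"
            )
    return counts


def build_morphology(config: MorphologyConfig | None = None) -> Morphology:
    """Build the standard model cell tree from a :class:`MorphologyConfig`."""
    cfg = config or MorphologyConfig()
    cfg.validate()

    split = cfg.primary_branch_split_distance
    branches = [
        # ABD-bearing primary dendrite, split at the side-branch origin
        _Branch("p1a", cfg.abd_branch_origin, Region.ABD, None,
                cfg.primary_diameter, cfg.primary_diameter),
        _Branch("p1b", split - cfg.abd_branch_origin, Region.PRIMARY, "p1a",
                cfg.primary_diameter, cfg.primary_diameter),
        _Branch("abd", cfg.abd_branch_length, Region.ABD, "p1a",
                cfg.primary_diameter, cfg.primary_diameter),
        _Branch("p2", split, Region.PRIMARY, None,
                cfg.primary_diameter, cfg.primary_diameter),
        _Branch("d1a", cfg.distal_branch_length, Region.DISTAL, "p1b",
                cfg.primary_diameter, cfg.distal_tip_diameter),
        _Branch("d1b", cfg.distal_branch_length, Region.DISTAL, "p1b",
                cfg.primary_diameter, cfg.distal_tip_diameter),
        _Branch("d2a", cfg.distal_branch_length, Region.DISTAL, "p2",
                cfg.primary_diameter, cfg.distal_tip_diameter),
        _Branch("d2b", cfg.distal_branch_length, Region.DISTAL, "p2",
                cfg.primary_diameter, cfg.distal_tip_diameter),
    ]
    counts = _allocate_segments(branches, cfg.segment_count_target, cfg.max_segment_length)

    comps: list[Compartment] = [
        Compartment(0, None, Region.SOMA, cfg.soma_length, cfg.soma_diameter, 0.0)
    ]
    tip_id: dict[str, int] = {}
    tip_dist: dict[str, float] = {}
    next_id = 1
    for b in branches:
        n = counts[b.name]
        seg_len = b.length / n
        if b.parent_branch is None:
            parent, dist0 = 0, 0.0
        else:
            parent, dist0 = tip_id[b.parent_branch], tip_dist[b.parent_branch]
        for k in range(n):
            mid = (k + 0.5) / n
            diam = b.diam_start + (b.diam_end - b.diam_start) * mid
            comps.append(
                Compartment(next_id, parent, b.region, seg_len, diam,
                            dist0 + (k + 0.5) * seg_len)
            )
            parent = next_id
            next_id += 1
        tip_id[b.name] = parent
        tip_dist[b.name] = dist0 + b.length

    # AIS hangs off the ABD side-branch tip
    comps.append(
        Compartment(next_id, tip_id["abd"], Region.AIS, cfg.ais_length,
                    cfg.ais_diameter, tip_dist["abd"] + cfg.ais_length / 2.0)
    )
    morph = Morphology(comps)
    assert morph.n_dendritic_segments() == cfg.segment_count_target
    return morph


def path_distance(morph: Morphology, comp_id: int) -> float:
    """Path distance (um) from soma center to the center of a segment."""
    return morph.path_distance(comp_id)
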