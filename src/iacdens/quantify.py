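"""Per-artery calcification volume and density at a ladder of HU thresholds.

The measurement model is pure in-ROI thresholding on non-contrast CT: a
voxel belongs to a calcification when its attenuation is at least 130 HU
(the conventional detection floor) and it lies inside the artery's region
of interest.  Volume is voxel count times voxel volume; mean density is
the arithmetic mean HU over supra-threshold voxels.  Repeating both
measurements at higher thresholds (200, 300, 400, 600, 800, 1000 HU)
decomposes a lesion into components of increasing density, and the
maximum in-ROI HU places each artery in one of seven ordinal density
categories (130-200 ... >1000).

No connected-component filtering or minimum lesion size is applied: any
supra-threshold in-mask voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_FLOOR_HU",
    "DEFAULT_LADDER",
    "CATEGORY_LABELS",
    "ARTERY_IDS",
    "DEFAULT_BED_MAP",
    "ThresholdLadder",
    "ArteryMeasurement",
    "ParticipantAggregate",
    "detect_voxels",
    "mean_density",
    "calc_volume",
    "threshold_profile",
    "assign_density_category",
    "aggregate_participant",
    "measurements_to_frame",
    "aggregates_to_frame",
]

DETECTION_FLOOR_HU = 130.0
DEFAULT_LADDER = (130.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1000.0)

#: Ordinal density categories, level 1..7.  Bins are left-closed /
#: right-open at the interior edges; 1000 HU itself falls in "800-1000"
#: because the top category is strictly ">1000".
CATEGORY_LABELS = (
    "130-200",
    "200-300",
    "300-400",
    "400-600",
    "600-800",
    "800-1000",
    ">1000",
)
_CATEGORY_EDGES = (130.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1000.0)

#: The five intracranial arteries: paired carotids form the anterior
#: (ICAC) bed, paired vertebrals plus the basilar the posterior (VBAC) bed.
ARTERY_IDS = (
    "ICA_left",
    "ICA_right",
    "vertebral_left",
    "vertebral_right",
    "basilar",
)
DEFAULT_BED_MAP: Mapping[str, str] = {
    "ICA_left": "ICAC",
    "ICA_right": "ICAC",
    "vertebral_left": "VBAC",
    "vertebral_right": "VBAC",
    "basilar": "VBAC",
}


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly increasing HU thresholds; the first is the detection floor."""

    thresholds: tuple = DEFAULT_LADDER

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) == 0:
            raise ValueError("ladder must contain at least one threshold")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {t}")
        object.__setattr__(self, "thresholds", t)

    @property
    def floor(self) -> float:
        return self.thresholds[0]

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class ThresholdRecord:
    threshold: float
    voxel_count: int
    volume_mm3: float
    mean_hu: Optional[float]  # None when no voxel reaches the threshold


@dataclass
class ArteryMeasurement:
    """Threshold-ladder profile of one artery's calcification."""

    artery_id: str
    records: list = field(default_factory=list)  # list[ThresholdRecord]
    max_hu: Optional[float] = None
    density_category: Optional[int] = None  # ordinal level 1..7

    @property
    def present(self) -> bool:
        return self.records[0].voxel_count > 0 if self.records else False

    def record_at(self, threshold: float) -> ThresholdRecord:
        for rec in self.records:
            if rec.threshold == threshold:
                return rec
        raise KeyError(f"no record at threshold {threshold}")


@dataclass
class BedAggregate:
    bed: str
    present: bool
    n_affected_arteries: int
    total_volume_mm3: float
    average_density_hu: Optional[float]
    max_density_category: Optional[int]


@dataclass
class ParticipantAggregate:
    """Per-bed (IAC, ICAC, VBAC) summaries for one participant."""

    participant_id: str
    beds: dict = field(default_factory=dict)  # bed -> BedAggregate

    def __getitem__(self, bed: str) -> BedAggregate:
        return self.beds[bed]


def _check_shapes(grid_data: np.ndarray, mask: np.ndarray) -> None:
    if grid_data.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid shape {grid_data.shape}"
        )


def detect_voxels(grid, mask: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of in-mask voxels with HU >= threshold (inclusive).

    Returns an (n, 3) integer array of voxel indices.
    """
    data = np.asarray(grid.data if hasattr(grid, "data") else grid)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(data, mask)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.argwhere(mask & (data >= threshold))


def mean_density(grid, voxels: np.ndarray) -> Optional[float]:
    """Arithmetic mean HU over a voxel index set; None for an empty set."""
    data = np.asarray(grid.data if hasattr(grid, "data") else grid)
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        return None
    vals = data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    return float(vals.sum(dtype=np.float64) / vals.size)


def calc_volume(voxels: np.ndarray, spacing: Sequence[float]) -> float:
    """Voxel count times voxel volume, in mm^3."""
    dx, dy, dz = (float(s) for s in spacing)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"spacing must be strictly positive, got {(dx, dy, dz)}")
    n = len(voxels) if np.asarray(voxels).size else 0
    return n * dx * dy * dz


def assign_density_category(max_hu: Optional[float]) -> Optional[int]:
    """Ordinal level 1..7 of the bin containing ``max_hu``; None passes through.

    Bins: [130,200), [200,300), [300,400), [400,600), [600,800),
    [800,1000], (1000, inf).
    """
    if max_hu is None:
        return None
    max_hu = float(max_hu)
    if max_hu < DETECTION_FLOOR_HU:
        raise ValueError(
            f"max_hu {max_hu} is below the {DETECTION_FLOOR_HU} HU detection "
            "floor; pass None for arteries without calcification"
        )
    if max_hu > 1000.0:
        return 7
    # searchsorted(side='right') gives the left-closed convention at the
    # interior edges; the min() keeps 1000.0 itself in level 6 ("800-1000")
    # since the top bin is strictly ">1000".
    return int(min(np.searchsorted(_CATEGORY_EDGES, max_hu, side="right"), 6))


def category_label(level: Optional[int]) -> Optional[str]:
    return None if level is None else CATEGORY_LABELS[level - 1]


def threshold_profile(
    grid,
    mask: np.ndarray,
    ladder: ThresholdLadder | Sequence[float] = DEFAULT_LADDER,
    spacing: Optional[Sequence[float]] = None,
    artery_id: str = "",
) -> ArteryMeasurement:
    """Volume/density records at every ladder threshold for one artery ROI."""
    if not isinstance(ladder, ThresholdLadder):
        ladder = ThresholdLadder(tuple(ladder))
    if spacing is None:
        spacing = grid.spacing
    data = np.asarray(grid.data if hasattr(grid, "data") else grid)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(data, mask)

    dx, dy, dz = (float(s) for s in spacing)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"spacing must be strictly positive, got {(dx, dy, dz)}")
    voxel_volume = dx * dy * dz

    in_mask = data[mask]
    records = []
    for t in ladder:
        vals = in_mask[in_mask >= t]
        count = int(vals.size)
        mean = float(vals.sum(dtype=np.float64) / count) if count else None
        records.append(ThresholdRecord(t, count, count * voxel_volume, mean))

    supra = in_mask[in_mask >= ladder.floor]
    max_hu = float(supra.max()) if supra.size else None
    return ArteryMeasurement(
        artery_id=artery_id,
        records=records,
        max_hu=max_hu,
        density_category=assign_density_category(max_hu),
    )


def _bed_aggregate(bed: str, members: list) -> BedAggregate:
    affected = [m for m in members if m.present]
    n_aff = len(affected)
    volume = float(sum(m.records[0].volume_mm3 for m in affected))
    if n_aff:
        # Per-artery averaging: each affected artery contributes its own
        # mean density with equal weight, regardless of lesion size.
        density = float(np.mean([m.records[0].mean_hu for m in affected]))
        category = max(m.density_category for m in affected)
    else:
        density = None
        category = None
    return BedAggregate(bed, n_aff > 0, n_aff, volume, density, category)


def aggregate_participant(
    measurements: Sequence[ArteryMeasurement],
    bed_map: Mapping[str, str] = DEFAULT_BED_MAP,
    participant_id: str = "",
) -> ParticipantAggregate:
    """Aggregate per-artery measurements into ICAC, VBAC and overall IAC.

    Bed average density is the unweighted mean of per-artery mean densities
    over affected arteries (not voxel-pooled); bed volume is the sum of
    per-artery volumes at the detection floor; the bed density category is
    the maximum per-artery category.
    """
    seen = set()
    for m in measurements:
        if m.artery_id not in bed_map:
            raise ValueError(f"unknown artery_id {m.artery_id!r}")
        if m.artery_id in seen:
            raise ValueError(f"duplicate measurement for artery {m.artery_id!r}")
        seen.add(m.artery_id)

    beds = {}
    for bed in ("ICAC", "VBAC"):
        members = [m for m in measurements if bed_map[m.artery_id] == bed]
        beds[bed] = _bed_aggregate(bed, members)
    beds["IAC"] = _bed_aggregate("IAC", list(measurements))
    return ParticipantAggregate(participant_id=participant_id, beds=beds)


def measurements_to_frame(
    measurements: Sequence[ArteryMeasurement], participant_id: str = ""
) -> pd.DataFrame:
    """Long-format per-artery table (one row per artery x threshold)."""
    rows = []
    for m in measurements:
        for rec in m.records:
            rows.append(
                {
                    "participant_id": participant_id,
                    "artery_id": m.artery_id,
                    "threshold": rec.threshold,
                    "voxel_count": rec.voxel_count,
                    "volume_mm3": rec.volume_mm3,
                    "mean_hu": rec.mean_hu,
                    "max_hu": m.max_hu,
                    "category": category_label(m.density_category),
                }
            )
    return pd.DataFrame(rows)


def aggregates_to_frame(aggregates: Sequence[ParticipantAggregate]) -> pd.DataFrame:
    rows = []
    for agg in aggregates:
        row = {"participant_id": agg.participant_id}
        for bed, b in agg.beds.items():
            row[f"{bed}_present"] = b.present
            row[f"{bed}_n_affected"] = b.n_affected_arteries
            row[f"{bed}_volume_mm3"] = b.total_volume_mm3
            row[f"{bed}_density_hu"] = b.average_density_hu
            row[f"{bed}_category"] = category_label(b.max_density_category)
        rows.append(row)
    return pd.DataFrame(rows)
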