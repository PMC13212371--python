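"""Shared phantom construction and the truth-table agreement check."""

import numpy as np

from iacdens.phantom import CalcInsert, PhantomTruth, generate_phantom, truth_table
from iacdens.quantify import ARTERY_IDS, threshold_profile

GRID_SHAPE = (48, 48, 14)
SPACING = (0.6, 0.6, 3.0)


def make_random_phantom(seed, n_inserts=3, grid_shape=GRID_SHAPE, spacing=SPACING):
    """One random phantom with at most one insert per artery, fully inside."""
    rng = np.random.default_rng(seed)
    extent = [(s - 1) * d for s, d in zip(grid_shape, spacing)]
    arteries = list(ARTERY_IDS)
    rng.shuffle(arteries)
    inserts = []
    placed = []  # (center, radius); keep masks of different arteries disjoint
    for artery in arteries[:n_inserts]:
        radius = float(rng.uniform(1.5, 3.5))
        for _ in range(200):
            center = tuple(
                float(rng.uniform(radius + 1, e - radius - 1)) for e in extent
            )
            clearance = radius + 2.0 * 1.2 + max(spacing)  # dilation margin + voxel
            if all(
                np.linalg.norm(np.subtract(center, c0)) > r0 + clearance
                for c0, r0 in placed
            ):
                break
        else:
            continue  # could not place this artery's insert; skip it
        placed.append((center, radius))
        if rng.random() < 0.5:
            profile = ("uniform", float(rng.integers(150, 1200)))
        else:
            rim = float(rng.integers(140, 400))
            profile = ("graded", rim + float(rng.integers(0, 900)), rim)
        shape = "sphere" if rng.random() < 0.7 else "shell"
        inserts.append(CalcInsert(artery, center, shape, (radius,) * 3, profile))
    spec = PhantomTruth(inserts=inserts, seed=seed)
    grid, masks = generate_phantom(spec, grid_shape, spacing)
    return spec, grid, masks


def quantify_vs_truth(seed):
    """Assert exact agreement between the quantify engine and the
    independent truth-table enumeration on one seeded phantom."""
    spec, grid, masks = make_random_phantom(seed)
    tt = truth_table(spec, grid, masks)
    for artery, mask in masks.items():
        m = threshold_profile(grid, mask, spacing=grid.spacing, artery_id=artery)
        rows = tt[tt["artery_id"] == artery]
        count = int(rows["realized_voxel_count"].sum())
        rec = m.records[0]
        assert rec.voxel_count == count, (seed, artery)
        assert rec.volume_mm3 == rows["realized_volume_mm3"].sum(), (seed, artery)
        if count:
            hu_sum = rows["realized_hu_sum"].sum()
            assert rec.mean_hu == hu_sum / count, (seed, artery)
            assert m.max_hu == rows["realized_max_hu"].max(), (seed, artery)
            assert m.density_category == int(rows["realized_category"].max()), (
                seed,
                artery,
            )
        else:
            assert rec.mean_hu is None and m.max_hu is None
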