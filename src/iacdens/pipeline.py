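"""End-to-end orchestration: phantom -> quantify -> subtype/fits.

A run is driven by a plain YAML config (``RunConfig``); every stage
records its seed, inputs and outputs, and the manifest stores a SHA-256
hash of each output file so that reruns with the same config can be
verified hash-equal.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import phantom as phantom_mod
from . import quantify as quantify_mod
from . import stats as stats_mod
from . import subtype as subtype_mod

__all__ = ["RunConfig", "run_pipeline", "export_distributions", "default_config"]

STAGES = ("phantom", "quantify", "simulate", "subtype", "fit", "report")


def default_config() -> dict:
    """Bundled demo configuration exercising every stage."""
    return {
        "version": "0.1.0",
        "seed": 0,
        "stages": list(STAGES),
        "phantom": {
            "n_participants": 3,
            "grid_shape": [48, 48, 14],
            "spacing": [0.6, 0.6, 3.0],
            "inserts_per_participant": 3,
        },
        "quantify": {"ladder": list(quantify_mod.DEFAULT_LADDER)},
        "simulate": {"n": 2040, "target_spearman": cohort_mod.DEFAULT_TARGET_SPEARMAN},
        "subtype": {"n_arteries": 3383, "test": "wilcoxon", "adjust": None},
        "fit": {"restrict_sensitivity": True},
    }


@dataclass
class RunConfig:
    out_dir: Path
    config: dict = field(default_factory=default_config)

    @classmethod
    def from_yaml(cls, path, out_dir) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        merged = default_config()
        for key, val in cfg.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        return cls(out_dir=Path(out_dir), config=merged)

    def validate(self) -> None:
        unknown = set(self.config.get("stages", [])) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for key in ("image", "masks", "arteries", "cohort"):
            path = self.config.get("inputs", {}).get(key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input {key!r} does not exist: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _random_phantom_spec(rng: np.random.Generator, cfg: dict) -> phantom_mod.PhantomTruth:
    shape = cfg["grid_shape"]
    spacing = cfg["spacing"]
    extent = [(s - 1) * d for s, d in zip(shape, spacing)]
    arteries = list(quantify_mod.ARTERY_IDS)
    rng.shuffle(arteries)
    inserts = []
    for artery in arteries[: cfg["inserts_per_participant"]]:
        radius = float(rng.uniform(1.5, 3.5))
        center = tuple(
            float(rng.uniform(radius + 1.0, e - radius - 1.0)) for e in extent
        )
        if rng.random() < 0.5:
            profile = ("uniform", float(rng.integers(150, 1200)))
        else:
            rim = float(rng.integers(140, 400))
            core = rim + float(rng.integers(0, 900))
            profile = ("graded", core, rim)
        inserts.append(
            phantom_mod.CalcInsert(
                artery_id=artery,
                center_mm=center,
                shape="sphere",
                radii_mm=(radius, radius, radius),
                hu_profile=profile,
            )
        )
    return phantom_mod.PhantomTruth(inserts=inserts, seed=int(rng.integers(2**31)))


def _validate_measurements(measurements) -> None:
    """Stage contract: threshold-ladder invariants must hold before any fit."""
    for m in measurements:
        counts = [r.voxel_count for r in m.records]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"voxel counts increase along the ladder for {m.artery_id}")
        for r in m.records:
            if r.mean_hu is not None and r.mean_hu < r.threshold:
                raise AssertionError(f"mean HU below threshold for {m.artery_id}")


def export_distributions(
    table: pd.DataFrame, category_col: str, stratum_col: Optional[str] = None
) -> pd.DataFrame:
    """Percentage composition of density categories within each stratum.

    Rows with a missing category are excluded; percentages sum to 100
    within each stratum; empty strata are emitted with n = 0.
    """
    df = table.dropna(subset=[category_col])
    strata = (
        {str(s): df[df[stratum_col] == s] for s in table[stratum_col].unique()}
        if stratum_col
        else {"all": df}
    )
    rows = []
    for name, sub in strata.items():
        n = len(sub)
        counts = sub[category_col].value_counts()
        for level in range(1, 8):
            label = quantify_mod.CATEGORY_LABELS[level - 1]
            c = int(counts.get(level, 0)) + int(counts.get(label, 0))
            rows.append(
                {
                    "stratum": name,
                    "category": label,
                    "n": c,
                    "percent": 100.0 * c / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(run: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``): per
    stage the seed, wall time and SHA-256 of every output file.  A stage
    failure aborts the run; outputs of completed stages are retained and
    the manifest marks the failed stage.
    """
    run.validate()
    cfg = run.config
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {s: int(ss.generate_state(1)[0] % 2**31) for s, ss in
                   zip(STAGES, master.spawn(len(STAGES)))}
    manifest: dict = {"version": cfg["version"], "seed": cfg["seed"], "stages": {}}
    state: dict = {}

    def record(stage: str, outputs: List[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seeds[stage],
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    try:
        for stage in [s for s in STAGES if s in cfg["stages"]]:
            t0 = time.time()
            outputs: List[Path] = []
            if stage == "phantom":
                pc = cfg["phantom"]
                rng = np.random.default_rng(stage_seeds[stage])
                state["phantoms"] = []
                pdir = out / "phantoms"
                pdir.mkdir(exist_ok=True)
                for i in range(pc["n_participants"]):
                    spec = _random_phantom_spec(rng, pc)
                    grid, masks = phantom_mod.generate_phantom(
                        spec, tuple(pc["grid_shape"]), tuple(pc["spacing"])
                    )
                    truth = phantom_mod.truth_table(spec, grid, masks)
                    gpath = pdir / f"participant{i}_image.nii"
                    phantom_mod.write_nifti(grid, gpath)
                    outputs.append(gpath)
                    for artery, mask in masks.items():
                        mpath = pdir / f"participant{i}_mask_{artery}.nii"
                        phantom_mod.write_mask_nifti(mask, grid, mpath)
                        outputs.append(mpath)
                    tpath = pdir / f"participant{i}_truth.csv"
                    truth.to_csv(tpath, index=False)
                    outputs.append(tpath)
                    state["phantoms"].append((f"participant{i}", grid, masks, truth))
            elif stage == "quantify":
                if "phantoms" not in state:
                    raise RuntimeError("quantify stage requires the phantom stage")
                ladder = quantify_mod.ThresholdLadder(tuple(cfg["quantify"]["ladder"]))
                art_frames, aggs = [], []
                for pid, grid, masks, _ in state["phantoms"]:
                    ms = [
                        quantify_mod.threshold_profile(grid, mask, ladder, artery_id=a)
                        for a, mask in masks.items()
                    ]
                    _validate_measurements(ms)
                    art_frames.append(quantify_mod.measurements_to_frame(ms, pid))
                    aggs.append(quantify_mod.aggregate_participant(ms, participant_id=pid))
                apath = out / "artery_measurements.csv"
                pd.concat(art_frames, ignore_index=True).to_csv(apath, index=False)
                ppath = out / "participant_aggregates.csv"
                quantify_mod.aggregates_to_frame(aggs).to_csv(ppath, index=False)
                state["aggregates"] = quantify_mod.aggregates_to_frame(aggs)
                outputs += [apath, ppath]
            elif stage == "simulate":
                sc = cfg["simulate"]
                table = cohort_mod.simulate_cohort(
                    n=sc["n"],
                    seed=stage_seeds[stage],
                    target_spearman=sc["target_spearman"],
                )
                cpath = out / "cohort.csv"
                table.to_csv(cpath, index=False)
                mpath = out / "cohort_manifest.yaml"
                with open(mpath, "w") as fh:
                    yaml.safe_dump(
                        {
                            "n": sc["n"],
                            "seed": stage_seeds[stage],
                            "target_spearman": sc["target_spearman"],
                            "log_odds": cohort_mod.DEFAULT_LOG_ODDS,
                            "cutpoints": list(cohort_mod.DEFAULT_CUTPOINTS),
                        },
                        fh,
                    )
                state["cohort"] = table
                outputs += [cpath, mpath]
            elif stage == "subtype":
                stc = cfg["subtype"]
                arteries = cohort_mod.simulate_subtype_arteries(
                    stc["n_arteries"], seed=stage_seeds[stage]
                )
                summary = subtype_mod.density_by_subtype(arteries)
                tests = subtype_mod.pairwise_density_tests(
                    arteries, test=stc["test"], adjust=stc["adjust"]
                )
                spath = out / "subtype_summary.csv"
                summary.to_csv(spath, index=False)
                tpath = out / "subtype_pairwise_tests.csv"
                tests.to_csv(tpath, index=False)
                state["arteries"] = arteries
                outputs += [spath, tpath]
            elif stage == "fit":
                if "cohort" not in state:
                    raise RuntimeError("fit stage requires the simulate stage")
                table = state["cohort"]
                X = table[list(cohort_mod.COVARIATE_ORDER)]
                ofit = stats_mod.fit_proportional_odds(
                    X, table["density_category"].to_numpy()
                )
                opath = out / "ordinal_fit.csv"
                ofit.summary_frame().to_csv(opath, index=False)
                outputs.append(opath)
                lfit = stats_mod.fit_linear_standardized(
                    X, table["ln_density"].to_numpy()
                )
                lpath = out / "linear_fit_density.csv"
                lfit.summary_frame().to_csv(lpath, index=False)
                outputs.append(lpath)
                corr = stats_mod.spearman_with_ci(
                    table["ln_volume_plus1"], table["ln_density"],
                    seed=stage_seeds[stage],
                )
                jpath = out / "correlation.json"
                with open(jpath, "w") as fh:
                    json.dump(
                        {
                            "spearman_rho": corr.spearman_rho,
                            "ci_low": corr.ci_low,
                            "ci_high": corr.ci_high,
                            "n": corr.n,
                        },
                        fh,
                        indent=1,
                    )
                outputs.append(jpath)
                if cfg["fit"]["restrict_sensitivity"]:
                    restricted, n_removed = stats_mod.restrict_sensitivity(table)
                    rfit = stats_mod.fit_proportional_odds(
                        restricted[[c for c in cohort_mod.COVARIATE_ORDER
                                    if c not in stats_mod.SENSITIVITY_EXCLUSION_COLUMNS]],
                        restricted["density_category"].to_numpy(),
                    )
                    rpath = out / "ordinal_fit_sensitivity.csv"
                    frame = rfit.summary_frame()
                    frame.attrs["n_removed"] = n_removed
                    frame.to_csv(rpath, index=False)
                    outputs.append(rpath)
            elif stage == "report":
                if "cohort" in state:
                    dist = export_distributions(state["cohort"], "density_category")
                    dpath = out / "category_distribution_cohort.csv"
                    dist.to_csv(dpath, index=False)
                    outputs.append(dpath)
                if "aggregates" in state:
                    agg = state["aggregates"]
                    frames = []
                    for bed in ("ICAC", "VBAC", "IAC"):
                        col = f"{bed}_category"
                        sub = agg[["participant_id", col]].copy()
                        sub["bed"] = bed
                        labels = sub[col].map(
                            lambda s: quantify_mod.CATEGORY_LABELS.index(s) + 1
                            if isinstance(s, str) else np.nan
                        )
                        sub["category_level"] = labels
                        frames.append(sub[["bed", "category_level"]])
                    beds = pd.concat(frames, ignore_index=True)
                    dist = export_distributions(beds, "category_level", "bed")
                    bpath = out / "category_distribution_beds.csv"
                    dist.to_csv(bpath, index=False)
                    outputs.append(bpath)
            record(stage, outputs, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
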