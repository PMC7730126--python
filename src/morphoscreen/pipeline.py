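"""End-to-end orchestration: design → simulate → segment → features →
classify → analyses, with a provenance manifest.

Every stage writes its artifacts under the run directory; the manifest
records the configuration, per-stage row counts and a SHA-256 checksum of
every declared output, so two runs with the same config and seed are
verifiably identical.  With ``resume=True`` a stage whose outputs already
exist is skipped and its artifacts reloaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import features as feat
from . import rankmap as rmap
from . import svd as svdmod
from .design import FactorLevels, assign_wells, enumerate_conditions, layout_frame, \
    read_design_table, write_design_table
from .effects import PHENOTYPES, ColonyCountParams, PhenotypeEffectModel
from .glm import FACTORS, PhenotypeGLM
from .render import WellImageParams, generate_plate
from .segmentation import SegmentationParams, match_to_truth, segment_well

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, serializable to/from JSON."""

    seed: int = 0
    replicates: int = 3
    #: desk-scale subsampling of the 128-condition design: keep every
    #: ``condition_stride``-th condition, at most ``max_conditions`` of them
    condition_stride: int = 1
    max_conditions: int | None = None
    # scaled-down image defaults keep a full run tractable on one CPU;
    # analysis stages are unaffected by image size
    image: WellImageParams = field(
        default_factory=lambda: WellImageParams(
            size_px=640, counts=ColonyCountParams(mean=40.0, dispersion=13.0)
        )
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    protocol: clf.TrainingProtocol = field(default_factory=clf.TrainingProtocol)
    svd_threshold: float = 0.73
    svd_max_components: int = 10
    top_fraction: float = 0.05

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(o)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1,
                          sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    model: PhenotypeEffectModel | None = None,
    resume: bool = False,
) -> dict:
    """Execute the full pipeline into ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or PhenotypeEffectModel()
    manifest: dict = {"config": json.loads(config.to_json()), "stages": {}}
    declared: list[Path] = []

    def stage(name):
        t0 = time.time()
        log.info("stage %s: start", name)
        return t0

    def done(name, t0, counts):
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3), **counts
        }
        log.info("stage %s: done (%s)", name, counts)

    # -- design ----------------------------------------------------------
    t0 = stage("design")
    design_csv = out / "design.csv"
    levels = FactorLevels(replicates=config.replicates)
    if resume and design_csv.exists():
        layout = read_design_table(design_csv)
    else:
        conditions = enumerate_conditions(levels)[:: config.condition_stride]
        if config.max_conditions is not None:
            conditions = conditions[: config.max_conditions]
        layout = assign_wells(conditions, config.replicates, seed=config.seed)
        write_design_table(layout, design_csv, levels)
    declared.append(design_csv)
    done("design", t0, {"n_wells": len(layout)})

    # -- simulate --------------------------------------------------------
    t0 = stage("simulate")
    plate_dir = out / "plate"
    truth_csv = plate_dir / "truth.csv"
    if resume and truth_csv.exists():
        import tifffile

        truth = pd.read_csv(truth_csv, float_precision="round_trip")
        images = {}
        for well_id in layout.well_ids():
            from .render import WellImage

            images[well_id] = WellImage(
                tifffile.imread(plate_dir / f"{well_id}.tif"), well_id,
                config.image.pixel_size_um,
            )
    else:
        images, truth = generate_plate(
            layout, model, seed=config.seed, params=config.image,
            out_dir=plate_dir,
        )
    declared += sorted(plate_dir.glob("*.tif")) + [truth_csv]
    done("simulate", t0, {"n_colonies_truth": len(truth)})

    # -- segment ---------------------------------------------------------
    t0 = stage("segment")
    results = [segment_well(images[w], config.segmentation)
               for w in layout.well_ids()]
    seg_csv = out / "segmentation.csv"
    seg_df = pd.concat([r.frame() for r in results], ignore_index=True)
    seg_df.to_csv(seg_csv, index=False)
    declared.append(seg_csv)
    done("segment", t0, {"n_colonies": int(seg_df.shape[0])})

    # -- features --------------------------------------------------------
    t0 = stage("features")
    features_csv = out / "features.csv"
    if resume and features_csv.exists():
        table = pd.read_csv(features_csv, float_precision="round_trip")
    else:
        table = feat.feature_table(results, images)
        table.to_csv(features_csv, index=False)
    manifest_json = out / "feature_manifest.json"
    feat.write_manifest(manifest_json)
    declared += [features_csv, manifest_json]
    done("features", t0, {"n_rows": len(table), "n_features": feat.N_FEATURES})

    # -- classify --------------------------------------------------------
    t0 = stage("classify")
    matched = pd.concat(
        [match_to_truth(r, truth) for r in results], ignore_index=True
    ).dropna(subset=["matched_colony_id"])
    labels = table.merge(
        matched[["well_id", "matched_colony_id", "phenotype"]],
        left_on=["well_id", "colony_id"],
        right_on=["well_id", "matched_colony_id"],
        how="left",
    )["phenotype"]
    labelled = labels.notna()
    split = clf.build_training_set(
        table.loc[labelled], labels.loc[labelled], config.protocol,
        seed=config.seed,
    )
    forest, itlog = clf.train_iterative(split, config.protocol, seed=config.seed)
    summary = clf.classify_plate(forest, table)
    preds_csv = out / "predictions.csv"
    summary.predictions.to_csv(preds_csv, index=False)
    profiles = clf.well_profiles(summary.predictions, layout)
    design_df = layout_frame(layout, levels)
    profiles = profiles.merge(
        design_df[["well_id", *FACTORS, "replicate"]], on="well_id"
    )
    profiles_csv = out / "profiles.csv"
    profiles.to_csv(profiles_csv, index=False)
    declared += [preds_csv, profiles_csv]
    done("classify", t0, {
        "n_classified": summary.total_colonies,
        "iterations": len(itlog.accuracies),
        "converged": itlog.converged,
    })

    # -- analyze ---------------------------------------------------------
    t0 = stage("analyze")
    scaled, dropped = svdmod.scale_features(table, list(feat.FEATURE_NAMES))
    svd_res = svdmod.svd_decompose(scaled)
    comps = svdmod.select_components(
        svd_res, config.svd_threshold, config.svd_max_components
    )
    assoc = svdmod.pc_phenotype_correlation(
        svd_res, table["well_id"], profiles, comps
    )
    clustering = svdmod.phenotype_cooccurrence_clustering(profiles)
    svd_report = {
        "variance_explained": svd_res.variance_explained[:max(comps) + 1].tolist(),
        "selected_components": comps,
        "dropped_measurements": dropped,
        "associations": assoc.to_dict(orient="records"),
        "contributions": [
            svdmod.measurement_contributions(svd_res, k) for k in comps
        ],
        "first_merge": list(clustering["first_merge"]),
    }
    svd_json = out / "svd_report.json"
    svd_json.write_text(json.dumps(svd_report, indent=1))

    glm_rows, wald_rows = [], []
    for ph in PHENOTYPES:
        res = PhenotypeGLM(profiles, ph).fit()
        for f in FACTORS:
            wald = res.factor_wald(f)
            wald_rows.append({"phenotype": ph, **wald})
            lsm = res.ls_means(f)
            lsm.insert(0, "phenotype", ph)
            glm_rows.append(lsm)
    glm_csv = out / "glm_ls_means.csv"
    pd.concat(glm_rows, ignore_index=True).to_csv(glm_csv, index=False)
    wald_csv = out / "glm_wald.csv"
    pd.DataFrame(wald_rows).to_csv(wald_csv, index=False)

    maps = {
        ph: rmap.top_fraction_map(
            rmap.rank_wells(profiles.dropna(subset=[f"f_{ph}"]), ph),
            design_df, ph, config.top_fraction,
        )
        for ph in PHENOTYPES
    }
    maps_csv = out / "ranked_maps.csv"
    rmap.composition_report(maps).to_csv(maps_csv, index=False)
    declared += [svd_json, glm_csv, wald_csv, maps_csv]
    done("analyze", t0, {"n_components": len(comps)})

    manifest["outputs"] = {
        str(p.relative_to(out)): _sha256(p) for p in declared
    }
    manifest["config_hash"] = hashlib.sha256(
        config.to_json().encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
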