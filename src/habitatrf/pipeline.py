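"""End-to-end workflow orchestration.

Stages: synthesize-or-load → harmonize → summarize → cluster →
pseudo-absences → feature extraction → OOB tuning → repeated CV →
seed-averaged importance (with zero-importance pruning) → final fit →
HSI map → class/area accounting → thematic accuracy. Every stage writes
its outputs under the configured directory so any stage can be rerun in
isolation, and a manifest records the config hash, per-stage seeds and
output paths. One master seed deterministically derives every stage
seed (by hashing the stage name), so a rerun with the same config
reproduces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from . import pseudo_absence as pa
from . import raster_ops, sdm_model, suitability, synthetic
from .config import PipelineConfig
from .points import OccurrenceSet
from .raster import EnvironmentalStack, RasterGrid, read_ascii_grid, write_ascii_grid

log = logging.getLogger("habitatrf")

__all__ = ["Pipeline", "run", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by stage-name hashing."""
    return zlib.crc32(f"{master}:{stage}".encode()) & 0x7FFFFFFF


class Pipeline:
    """Stage runner bound to one config and one output directory.

    Stage methods return their in-memory product and persist it; later
    stages reload persisted products from disk when invoked in a fresh
    process, so the CLI subcommands compose.
    """

    def __init__(self, config: PipelineConfig):
        self.config = config.validate()
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.out / "manifest.json"
        self._manifest = self._load_manifest()

    # -- manifest ----------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self._manifest_path.exists():
            return json.loads(self._manifest_path.read_text())
        digest = hashlib.sha256(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        return {"config_hash": digest, "seed": self.config.seed, "stages": {}}

    def _record(self, stage: str, **info) -> None:
        entry = {"seed": stage_seed(self.config.seed, stage), **info}
        self._manifest["stages"][stage] = entry
        self._manifest_path.write_text(json.dumps(self._manifest, indent=2, sort_keys=True))
        log.info("stage %s: %s", stage, info)

    # -- stage 1: landscape -------------------------------------------------
    def synth(self) -> tuple[EnvironmentalStack, OccurrenceSet]:
        """Synthetic mode: landscape + truth + presences. File mode: load."""
        cfg = self.config
        if cfg.mode == "files":
            stack = EnvironmentalStack(
                {name: read_ascii_grid(path, name) for name, path in cfg.files.layers.items()}
            )
            presences = OccurrenceSet.read_csv(cfg.files.presences)
            self._record("synth", mode="files", n_layers=len(stack), n_presence=len(presences))
            return stack, presences
        lc = cfg.landscape
        stack = synthetic.generate_environment(lc)
        native_dir = self.out / "landscape"
        native_dir.mkdir(exist_ok=True)
        for name, grid in stack.items():
            write_ascii_grid(grid, native_dir / f"{name}.asc")
        # ground truth lives on the harmonized grid
        harmonized = raster_ops.harmonize(stack)
        truth = synthetic.true_suitability(harmonized, lc)
        write_ascii_grid(truth, self.out / "true_suitability.asc")
        presences = synthetic.sample_presences(truth, lc.n_presence, stage_seed(cfg.seed, "presences"))
        presences.to_csv(self.out / "presences.csv")
        self._record("synth", mode="synthetic", n_layers=len(stack), n_presence=len(presences))
        return stack, presences

    # -- stage 2: harmonize ---------------------------------------------------
    def harmonize(self, stack: EnvironmentalStack | None = None) -> EnvironmentalStack:
        if stack is None:
            stack, _ = self.synth()
        harmonized = raster_ops.harmonize(stack)
        hdir = self.out / "harmonized"
        hdir.mkdir(exist_ok=True)
        for name, grid in harmonized.items():
            write_ascii_grid(grid, hdir / f"{name}.asc")
        (hdir / "layer_order.txt").write_text("\n".join(harmonized.names) + "\n")
        summary = raster_ops.layer_summary(harmonized)
        summary.to_csv(self.out / "layer_summary.csv")
        self._record("harmonize", n_layers=len(harmonized), grid=list(harmonized.geometry.shape))
        return harmonized

    def _load_harmonized(self) -> EnvironmentalStack:
        hdir = self.out / "harmonized"
        order_file = hdir / "layer_order.txt"
        if not order_file.exists():
            return self.harmonize()
        names = order_file.read_text().split()
        return EnvironmentalStack({n: read_ascii_grid(hdir / f"{n}.asc", n) for n in names})

    def _load_presences(self) -> OccurrenceSet:
        path = self.out / "presences.csv"
        if path.exists():
            return OccurrenceSet.read_csv(path)
        if self.config.mode == "files":
            return OccurrenceSet.read_csv(self.config.files.presences)
        _, presences = self.synth()
        return presences

    # -- stage 3: pseudo-absences --------------------------------------------
    def pseudo_absences(self) -> OccurrenceSet:
        cfg = self.config
        stack = self._load_harmonized()
        presences = self._load_presences()
        geom = stack.geometry
        row, col = geom.cell_index(presences.lon, presences.lat)
        presence_cells = set(zip(row.tolist(), col.tolist()))
        if cfg.pseudo_absence.policy == "cluster_exclusion":
            cmap = pa.cluster_environment(
                stack, cfg.pseudo_absence.k, stage_seed(cfg.seed, "cluster")
            )
            write_ascii_grid(cmap.labels, self.out / "clusters.asc")
            occupied = pa.presence_clusters(cmap, presences)
            absences = pa.sample_pseudo_absences(
                cmap, occupied, cfg.pseudo_absence.n,
                stage_seed(cfg.seed, "pseudo_absence"), presence_cells,
            )
            extra = {"k": cmap.k, "presence_clusters": sorted(occupied), "inertia": cmap.inertia}
        else:
            mask = pa.dissimilar_cells_by_distance(
                stack, presences, cfg.pseudo_absence.distance_quantile
            )
            labels = RasterGrid(
                np.where(mask, 1.0, -1.0), geom, nodata=-1.0, name="dissimilar"
            )
            cmap = pa.ClusterMap(labels, k=2, centroids=np.zeros((2, len(stack))), inertia=0.0)
            absences = pa.sample_pseudo_absences(
                cmap, set(), cfg.pseudo_absence.n,
                stage_seed(cfg.seed, "pseudo_absence"), presence_cells,
            )
            extra = {"policy": "distance_threshold"}
        occurrences = presences.concat(absences)
        occurrences.to_csv(self.out / "occurrences.csv")
        self._record("pseudo_absence", n_presence=len(presences), n_absence=len(absences), **extra)
        return occurrences

    def _load_occurrences(self) -> OccurrenceSet:
        path = self.out / "occurrences.csv"
        return OccurrenceSet.read_csv(path) if path.exists() else self.pseudo_absences()

    # -- stage 4: features ----------------------------------------------------
    def features(self) -> sdm_model.FeatureTable:
        table = sdm_model.extract_features(self._load_harmonized(), self._load_occurrences())
        table.to_csv(self.out / "features.csv")
        self._record("features", n_rows=len(table), n_dropped_nodata=table.n_dropped)
        return table

    def _load_features(self) -> sdm_model.FeatureTable:
        path = self.out / "features.csv"
        return sdm_model.FeatureTable.read_csv(path) if path.exists() else self.features()

    # -- stage 5: tuning ------------------------------------------------------
    def tune(self) -> sdm_model.TuningResult:
        cfg = self.config
        result = sdm_model.tune_oob(
            self._load_features(), cfg.model.ntree_grid, cfg.model.mtry_grid,
            stage_seed(cfg.seed, "tune"),
        )
        result.oob_error.to_csv(self.out / "tuning.csv")
        self._record("tune", best_ntree=result.best[0], best_mtry=result.best[1],
                     best_oob_error=float(result.oob_error.loc[result.best[0], result.best[1]]))
        return result

    def _chosen_params(self) -> tuple[int, int]:
        cfg = self.config
        if cfg.model.tune:
            entry = self._manifest["stages"].get("tune")
            if entry is None:
                result = self.tune()
                return result.best
            return entry["best_ntree"], entry["best_mtry"]
        return cfg.model.ntree, cfg.model.mtry

    # -- stage 6: cross-validation ----------------------------------------------
    def cv(self) -> sdm_model.CVReport:
        cfg = self.config
        ntree, mtry = self._chosen_params()
        report = sdm_model.repeated_cv(
            self._load_features(), ntree=ntree, mtry=mtry,
            k=cfg.model.folds, repeats=cfg.model.repeats,
            seed=stage_seed(cfg.seed, "cv"),
        )
        report.records.to_csv(self.out / "cv_records.csv", index=False)
        self._record("cv", ntree=ntree, mtry=mtry,
                     mean_train_acc_pct=report.mean_train_acc_pct,
                     mean_val_acc_pct=report.mean_val_acc_pct)
        return report

    # -- stage 7: importance ---------------------------------------------------
    def importance(self) -> sdm_model.ImportanceTable:
        cfg = self.config
        ntree, mtry = self._chosen_params()
        table = sdm_model.feature_importance(
            self._load_features(), seeds=cfg.model.seeds, ntree=ntree, mtry=mtry
        )
        table.to_csv(self.out / "importance.csv")
        self._record("importance", pruned=sorted(table.pruned), n_seeds=len(table.seed_list))
        return table

    def _load_pruned(self) -> list[str]:
        path = self.out / "importance.csv"
        if not path.exists():
            return self.importance().pruned
        df = pd.read_csv(path, index_col="layer")
        return list(df.index[df["pruned"]])

    # -- stage 8: final fit + map -----------------------------------------------
    def fit_map(self) -> tuple[RasterGrid, RasterGrid]:
        cfg = self.config
        ntree, mtry = self._chosen_params()
        pruned = self._load_pruned()
        table = self._load_features().drop_layers(pruned)
        mtry_eff = min(mtry, len(table.layer_names))
        model = sdm_model.fit_final(table, ntree=ntree, mtry=mtry_eff,
                                    seed=stage_seed(cfg.seed, "final_fit"))
        stack = self._load_harmonized().subset(table.layer_names)
        hsi = sdm_model.predict_hsi(model, stack)
        cls = sdm_model.predict_class(model, stack)
        write_ascii_grid(hsi, self.out / "hsi.asc")
        write_ascii_grid(cls, self.out / "predicted_class.asc")
        self._record("fit_map", ntree=ntree, mtry=mtry_eff, n_predictors=len(table.layer_names),
                     pruned=sorted(pruned))
        return hsi, cls

    # -- stage 9: areas ----------------------------------------------------------
    def areas(self) -> dict:
        cfg = self.config
        hsi_path = self.out / "hsi.asc"
        if not hsi_path.exists():
            self.fit_map()
        hsi = read_ascii_grid(self.out / "hsi.asc", "hsi")
        cls = read_ascii_grid(self.out / "predicted_class.asc", "predicted_class")
        s = cfg.suitability
        table = suitability.classify_hsi(
            hsi, bin_width=s.bin_width, area_mode=s.area_mode,
            suitable_range=(s.suitable_lo, s.suitable_hi),
        )
        table.to_csv(self.out / "class_areas.csv")
        pres_km2, abs_km2, pres_pct, abs_pct = suitability.binary_area(cls, s.area_mode)
        summary = {
            "total_km2": table.total_km2,
            "suitable_km2": table.suitable_km2,
            "suitable_range": [s.suitable_lo, s.suitable_hi],
            "presence_km2": pres_km2,
            "absence_km2": abs_km2,
            "presence_pct": pres_pct,
            "absence_pct": abs_pct,
        }
        (self.out / "area_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        self._record("areas", **{k: v for k, v in summary.items() if not isinstance(v, list)})
        return summary

    # -- stage 10: accuracy --------------------------------------------------------
    def accuracy(self) -> acc.AccuracyReport | None:
        """Thematic accuracy of the binary map against the reference.

        Synthetic mode scores against the known truth (true suitability
        >= 0.5); file mode needs an explicit reference map and is
        skipped (with a log line) without one.
        """
        cfg = self.config
        cls_path = self.out / "predicted_class.asc"
        if not cls_path.exists():
            self.fit_map()
        cls = read_ascii_grid(cls_path, "predicted_class")
        if cfg.mode == "synthetic":
            truth = read_ascii_grid(self.out / "true_suitability.asc")
            ref_vals = np.where(truth.valid_mask, (truth.values >= 0.5).astype(float), truth.nodata)
            ref = truth.with_values(ref_vals, name="reference")
        elif cfg.files.reference:
            ref = read_ascii_grid(cfg.files.reference, "reference")
        else:
            log.info("no reference map; skipping accuracy stage")
            return None
        report = acc.assess(cls, ref)
        report.to_frame().to_csv(self.out / "accuracy.csv", index=False)
        self._record("accuracy", overall_pct=report.overall_pct, kappa=report.kappa,
                     agreement=report.agreement)
        return report

    # -- whole workflow ---------------------------------------------------------
    def run_all(self) -> dict:
        """Run every stage in order; returns the manifest."""
        stack, _ = self.synth()
        self.harmonize(stack)
        self.pseudo_absences()
        self.features()
        if self.config.model.tune:
            self.tune()
        self.cv()
        self.importance()
        self.fit_map()
        self.areas()
        self.accuracy()
        return self._manifest


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline for a config; returns the run manifest."""
    return Pipeline(config).run_all()
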