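"""End-to-end pipeline orchestration with provenance and stage caching.

Stages: ``synth`` (or externally supplied volumes) -> ``segment`` ->
``glcm`` / ``train-vaegan`` -> ``encode`` -> ``cluster`` -> ``profile`` ->
``compare``. Each stage writes its outputs plus a JSON provenance record
(config hash, input-file hashes, seed, package version); a stage whose
provenance matches the current config and inputs is skipped unless forced.
VAE-GAN training is the only slow stage, so caching makes iterative
profiling runs cheap.

The configuration is a nested mapping (YAML on disk); the global ``seed``
feeds every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .glcm import GLCMConfig, glcm_table
from .profiling import (
    RegionStats,
    cluster_representations,
    compare_conditions,
    cooccurrence_heatmap,
    neighborhood_counts,
    cd8_proximity_report,
    region_stats,
    summarize_proximity,
)
from .segmentation import (
    SegmentationConfig,
    ThresholdMethod,
    build_cell_table,
    extract_patches,
    threshold_channel,
)
from .synthetic_data import SynthSpec, TextureClassSpec, generate_region
from .volume_io import (
    DEFAULT_VOXEL_SIZE_UM,
    CellTable,
    ChannelName,
    Condition,
    read_cell_table,
    read_labels,
    read_table,
    read_volume,
    write_labels,
    write_table,
    write_volume,
)

logger = logging.getLogger(__name__)

STAGES = ("synth", "segment", "glcm", "train-vaegan", "encode", "cluster", "profile", "compare")


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


def _hash_str(s: str) -> str:
    return hashlib.sha256(s.encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Pipeline:
    def __init__(self, config: dict, outdir: str | Path | None = None):
        self.cfg = config
        self.outdir = Path(outdir or config.get("outdir", "damagemap_out"))
        self.seed = int(config.get("seed", 0))
        self.voxel_size = tuple(config.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM))
        self.prov_dir = self.outdir / "provenance"

    # -- provenance/caching -------------------------------------------------

    def _region_ids(self) -> list[str]:
        return [r["region_id"] for r in self.cfg.get("regions", [])]

    def _provenance(self, stage: str, inputs: list[Path]) -> dict:
        return {
            "stage": stage,
            "config_hash": _hash_str(_canonical(self.cfg.get(stage.replace("-", "_"), {}))
                                     + f"|seed={self.seed}"),
            "input_hashes": {
                str(p.relative_to(self.outdir) if p.is_relative_to(self.outdir) else p):
                _hash_file(p)
                for p in inputs if p.exists()
            },
            "seed": self.seed,
            "version": __version__,
        }

    def _cached(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        prov_path = self.prov_dir / f"{stage}.json"
        if not prov_path.exists() or not all(p.exists() for p in outputs):
            return False
        with open(prov_path) as fh:
            old = json.load(fh)
        new = self._provenance(stage, inputs)
        return old == new

    def _record(self, stage: str, inputs: list[Path]) -> None:
        self.prov_dir.mkdir(parents=True, exist_ok=True)
        with open(self.prov_dir / f"{stage}.json", "w") as fh:
            json.dump(self._provenance(stage, inputs), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {path}; run the '{producer}' stage first"
            )
        return path

    # -- stages -------------------------------------------------------------

    def stage_synth(self, force: bool = False) -> None:
        regions = self.cfg.get("regions", [])
        outputs = [self.outdir / "regions" / r["region_id"] / "labels.tif" for r in regions]
        if not force and self._cached("synth", [], outputs):
            logger.info("synth: cached, skipping")
            return
        synth_cfg = dict(self.cfg.get("synth", {}))
        classes = tuple(
            TextureClassSpec(**tc) for tc in synth_cfg.pop("texture_classes", [])
        ) or None
        for idx, r in enumerate(regions):
            rdir = self.outdir / "regions" / r["region_id"]
            rdir.mkdir(parents=True, exist_ok=True)
            kwargs = dict(synth_cfg)
            kwargs.update({k: v for k, v in r.items() if k not in ("region_id", "condition")})
            if classes:
                kwargs["texture_classes"] = classes
            kwargs.setdefault("rng_seed", self.seed * 10_000 + idx)
            kwargs["shape"] = tuple(kwargs.get("shape", (130, 302, 302)))
            kwargs["voxel_size_um"] = self.voxel_size
            spec = SynthSpec(**kwargs)
            channels, labels, truth = generate_region(spec)
            for name, vol in channels.items():
                write_volume(vol, rdir / f"{name.value}.tif")
            write_labels(labels, rdir / "labels.tif")
            write_table(truth.cells, rdir / "truth.csv",
                        metadata={"region_id": r["region_id"], "condition": r.get("condition", "UNKNOWN")})
        self._record("synth", [])

    def stage_segment(self, force: bool = False) -> None:
        seg_cfg = self.cfg.get("segment", {})
        regions = self.cfg.get("regions", [])
        inputs = [self.outdir / "regions" / r["region_id"] / "labels.tif" for r in regions]
        outputs = [self.outdir / "cells" / f"{r['region_id']}.csv" for r in regions]
        outputs += [self.outdir / "patches" / f"{r['region_id']}.npz" for r in regions]
        if not force and self._cached("segment", inputs, outputs):
            logger.info("segment: cached, skipping")
            return
        cfg = SegmentationConfig(
            min_overlap_frac=seg_cfg.get("min_overlap", 0.5),
            cd8_min_overlap_frac=seg_cfg.get("cd8_min_overlap", 0.2),
            cd8_dilation_vox=seg_cfg.get("cd8_dilation", 2),
            patch_size=seg_cfg.get("patch_size", 64),
            mask_background=seg_cfg.get("mask_background", True),
        )
        for r in regions:
            rdir = self.outdir / "regions" / r["region_id"]
            self._require(rdir / "labels.tif", "synth")
            labels = read_labels(rdir / "labels.tif", self.voxel_size)
            gh_vol = read_volume(rdir / "GH2AX.tif", ChannelName.GH2AX, self.voxel_size)
            cd8_vol = read_volume(rdir / "CD8.tif", ChannelName.CD8, self.voxel_size)
            gh_mask = self._threshold(gh_vol, seg_cfg.get("gh2ax_threshold", "otsu"))
            cd8_mask = self._threshold(cd8_vol, seg_cfg.get("cd8_threshold", "otsu"))
            table = build_cell_table(labels, gh_mask, cd8_mask, cfg,
                                     condition=Condition(r.get("condition", "UNKNOWN")),
                                     region_id=r["region_id"])
            write_table(table, self.outdir / "cells" / f"{r['region_id']}.csv")
            patches = extract_patches(gh_vol, table, labels, size=cfg.patch_size,
                                      mask_background=cfg.mask_background)
            pdir = self.outdir / "patches"
            pdir.mkdir(parents=True, exist_ok=True)
            np.savez(pdir / f"{r['region_id']}.npz",
                     **{str(cid): patch for cid, patch in patches.items()})
        self._record("segment", inputs)

    @staticmethod
    def _threshold(volume, setting):
        if isinstance(setting, (int, float)):
            return threshold_channel(volume, ThresholdMethod.FIXED, float(setting))
        return threshold_channel(volume, ThresholdMethod.OTSU)

    def _load_patches(self, region_id: str) -> dict[int, np.ndarray]:
        path = self._require(self.outdir / "patches" / f"{region_id}.npz", "segment")
        with np.load(path) as data:
            return {int(k): data[k] for k in data.files}

    def stage_glcm(self, force: bool = False) -> None:
        regions = self._region_ids()
        inputs = [self.outdir / "patches" / f"{r}.npz" for r in regions]
        outputs = [self.outdir / "features" / f"glcm_{r}.csv" for r in regions]
        if not force and self._cached("glcm", inputs, outputs):
            logger.info("glcm: cached, skipping")
            return
        cfg = GLCMConfig(**self.cfg.get("glcm", {}))
        for rid in regions:
            patches = self._load_patches(rid)
            if patches:
                table = glcm_table(patches, cfg)
            else:
                table = pd.DataFrame(columns=["cell_id", "energy", "contrast",
                                              "prominence", "correlation"])
            write_table(table, self.outdir / "features" / f"glcm_{rid}.csv",
                        metadata={"region_id": rid})
        self._record("glcm", inputs)

    def _all_patches(self) -> np.ndarray:
        banks = [self._load_patches(rid) for rid in self._region_ids()]
        arrs = [p for bank in banks for p in bank.values()]
        if not arrs:
            raise ValueError("no patches found; run segment first")
        return np.stack(arrs)

    def stage_train_vaegan(self, force: bool = False) -> None:
        from .vaegan import TrainConfig, VAEGAN, VAEGANSpec, save_model, train

        regions = self._region_ids()
        inputs = [self.outdir / "patches" / f"{r}.npz" for r in regions]
        outputs = [self.outdir / "model" / "vaegan.npz"]
        if not force and self._cached("train-vaegan", inputs, outputs):
            logger.info("train-vaegan: cached, skipping")
            return
        vcfg = dict(self.cfg.get("train_vaegan", {}))
        spec = VAEGANSpec(latent_dim=vcfg.pop("latent_dim", 16))
        cfg = TrainConfig(seed=self.seed, **vcfg)
        model = VAEGAN(spec, seed=self.seed)
        t0 = time.monotonic()
        history = train(model, self._all_patches(), cfg)
        logger.info("train-vaegan: %d epochs in %.1f s", cfg.epochs, time.monotonic() - t0)
        save_model(model, self.outdir / "model" / "vaegan.npz")
        write_table(history, self.outdir / "model" / "loss_history.csv")
        self._record("train-vaegan", inputs)

    def stage_encode(self, force: bool = False) -> None:
        from .vaegan import encode_table, load_model

        regions = self._region_ids()
        inputs = [self.outdir / "model" / "vaegan.npz"]
        inputs += [self.outdir / "patches" / f"{r}.npz" for r in regions]
        outputs = [self.outdir / "features" / f"latent_{r}.csv" for r in regions]
        if not force and self._cached("encode", inputs, outputs):
            logger.info("encode: cached, skipping")
            return
        model = load_model(self._require(self.outdir / "model" / "vaegan.npz", "train-vaegan"))
        for rid in regions:
            patches = self._load_patches(rid)
            if patches:
                table = encode_table(model, patches)
            else:
                table = pd.DataFrame(columns=["cell_id"])
            write_table(table, self.outdir / "features" / f"latent_{rid}.csv",
                        metadata={"region_id": rid})
        self._record("encode", inputs)

    def stage_cluster(self, force: bool = False) -> None:
        ccfg = self.cfg.get("cluster", {})
        rep = ccfg.get("representation", "GLCM").upper()
        prefix = "glcm" if rep == "GLCM" else "latent"
        regions = self._region_ids()
        inputs = [self.outdir / "features" / f"{prefix}_{r}.csv" for r in regions]
        outputs = [self.outdir / "classes" / "pseudo_classes.csv"]
        if not force and self._cached("cluster", inputs, outputs):
            logger.info("cluster: cached, skipping")
            return
        frames = []
        for rid in regions:
            df, _ = read_table(
                self._require(self.outdir / "features" / f"{prefix}_{rid}.csv",
                              "glcm" if prefix == "glcm" else "encode")
            )
            df.insert(0, "region_id", rid)
            frames.append(df)
        pooled = pd.concat(frames, ignore_index=True)
        if len(pooled) == 0:
            raise ValueError("no feature rows to cluster")
        feats = pooled.drop(columns=["region_id"]).copy()
        feats["cell_id"] = np.arange(len(feats))  # pooled surrogate key
        k = int(ccfg.get("k", 5))
        pct = cluster_representations(feats, k=k, seed=self.seed, representation=rep,
                                      standardize=ccfg.get("standardize", True))
        out = pooled[["region_id", "cell_id"]].copy()
        out["class_label"] = pct.df["class_label"].to_numpy()
        out["pca_x"] = pct.df["pca_x"].to_numpy()
        out["pca_y"] = pct.df["pca_y"].to_numpy()
        write_table(out, self.outdir / "classes" / "pseudo_classes.csv",
                    metadata={"k": k, "representation": rep, "inertia": pct.inertia,
                              "seed": self.seed})
        self._record("cluster", inputs)

    def _load_region_classes(self, rid: str, k: int, rep: str):
        from .profiling import PseudoClassTable

        df, meta = read_table(
            self._require(self.outdir / "classes" / "pseudo_classes.csv", "cluster")
        )
        sub = df[df["region_id"] == rid][["cell_id", "class_label", "pca_x", "pca_y"]]
        return PseudoClassTable(sub.reset_index(drop=True), k=k, representation=rep,
                                cluster_centers=np.zeros((k, 0)), inertia=float("nan"))

    def stage_profile(self, force: bool = False) -> None:
        pcfg = self.cfg.get("profile", {})
        radii = [float(r) for r in pcfg.get("radii_px", (32, 64, 128))]
        regions = self.cfg.get("regions", [])
        inputs = [self.outdir / "classes" / "pseudo_classes.csv"]
        inputs += [self.outdir / "cells" / f"{r['region_id']}.csv" for r in regions]
        outputs = [self.outdir / "profiles" / "proximity_summary.csv"]
        if not force and self._cached("profile", inputs, outputs):
            logger.info("profile: cached, skipping")
            return
        _, cmeta = read_table(
            self._require(self.outdir / "classes" / "pseudo_classes.csv", "cluster")
        )
        k = int(cmeta.get("k", 5))
        rep = cmeta.get("representation", "GLCM")
        pdir = self.outdir / "profiles"
        pdir.mkdir(parents=True, exist_ok=True)
        all_prox = []
        per_cond_profiles: dict[str, dict[float, list[pd.DataFrame]]] = {}
        for r in regions:
            rid = r["region_id"]
            cells = read_cell_table(self._require(self.outdir / "cells" / f"{rid}.csv", "segment"))
            classes = self._load_region_classes(rid, k, rep)
            for radius in radii:
                prof = neighborhood_counts(cells, classes, radius, self.voxel_size)
                write_table(prof, pdir / f"neighborhood_{rid}_r{int(radius)}.csv",
                            metadata={"region_id": rid, "radius_px": radius})
                if len(prof):
                    H, absent = cooccurrence_heatmap(prof, k, cells.condition)
                    hdf = pd.DataFrame(H, columns=[f"class_{j}" for j in range(k)])
                    write_table(hdf, pdir / f"heatmap_{rid}_r{int(radius)}.csv",
                                metadata={"region_id": rid, "radius_px": radius,
                                          "absent_classes": absent})
                per_cond_profiles.setdefault(cells.condition.value, {}).setdefault(
                    radius, []).append(prof)
            rep_df = cd8_proximity_report(cells, radii, self.voxel_size)
            rep_df.insert(0, "region_id", rid)
            rep_df.insert(1, "condition", cells.condition.value)
            all_prox.append(rep_df)
        # pooled per-condition heatmaps
        for cond, by_radius in per_cond_profiles.items():
            for radius, profs in by_radius.items():
                pooled = pd.concat(profs, ignore_index=True)
                if len(pooled) == 0:
                    continue
                H, absent = cooccurrence_heatmap(pooled, k)
                hdf = pd.DataFrame(H, columns=[f"class_{j}" for j in range(k)])
                write_table(hdf, pdir / f"heatmap_{cond}_r{int(radius)}.csv",
                            metadata={"condition": cond, "radius_px": radius,
                                      "absent_classes": absent})
        prox = pd.concat(all_prox, ignore_index=True) if all_prox else pd.DataFrame()
        write_table(prox, pdir / "proximity_cells.csv")
        summary = (
            prox.groupby(["condition", "radius_px", "radius_um"])["gh2ax_count"]
            .agg(n_cd8="count", total="sum", mean="mean")
            .reset_index()
            if len(prox)
            else pd.DataFrame(columns=["condition", "radius_px", "radius_um",
                                       "n_cd8", "total", "mean"])
        )
        write_table(summary, pdir / "proximity_summary.csv")
        self._record("profile", inputs)

    def stage_compare(self, force: bool = False) -> None:
        ccfg = self.cfg.get("compare", {})
        pcfg = self.cfg.get("profile", {})
        radii = [float(r) for r in pcfg.get("radii_px", (32, 64, 128))]
        regions = self.cfg.get("regions", [])
        inputs = [self.outdir / "cells" / f"{r['region_id']}.csv" for r in regions]
        inputs += [self.outdir / "classes" / "pseudo_classes.csv"]
        outputs = [self.outdir / "compare" / "comparison.csv"]
        if not force and self._cached("compare", inputs, outputs):
            logger.info("compare: cached, skipping")
            return
        _, cmeta = read_table(
            self._require(self.outdir / "classes" / "pseudo_classes.csv", "cluster")
        )
        k = int(cmeta.get("k", 5))
        rep = cmeta.get("representation", "GLCM")
        stats = []
        for r in regions:
            rid = r["region_id"]
            cells = read_cell_table(self._require(self.outdir / "cells" / f"{rid}.csv", "segment"))
            classes = self._load_region_classes(rid, k, rep)
            stats.append(region_stats(cells, classes, radii, self.voxel_size))
        comp = compare_conditions(stats, n_permutations=int(ccfg.get("n_permutations", 999)),
                                  seed=self.seed)
        write_table(comp, self.outdir / "compare" / "comparison.csv",
                    metadata={"n_permutations": int(ccfg.get("n_permutations", 999)),
                              "seed": self.seed})
        self._record("compare", inputs)

    # -- driver -------------------------------------------------------------

    def run(self, stages=None, force: bool = False) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        dispatch = {
            "synth": self.stage_synth,
            "segment": self.stage_segment,
            "glcm": self.stage_glcm,
            "train-vaegan": self.stage_train_vaegan,
            "encode": self.stage_encode,
            "cluster": self.stage_cluster,
            "profile": self.stage_profile,
            "compare": self.stage_compare,
        }
        timings = {}
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.monotonic()
            logger.info("stage %s: start", stage)
            dispatch[stage](force=force)
            timings[stage] = time.monotonic() - t0
            logger.info("stage %s: done in %.1f s", stage, timings[stage])
        return {"status": 0, "timings": timings, "outdir": str(self.outdir)}


def run_pipeline(config: dict, stages=None, force: bool = False,
                 outdir: str | Path | None = None) -> dict:
    """Run the configured stages; see :class:`Pipeline`."""
    return Pipeline(config, outdir=outdir).run(stages=stages, force=force)
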