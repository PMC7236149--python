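"""End-to-end experiment orchestration.

``build_dataset`` takes activity classes (CSV files or synthetic specs)
through the full chain — similarity filtering, smooth/rugged reference
variants, 2D projection, GP surface interpolation, multi-view rendering and
encoding — and yields an image dataset with a provenance manifest.
``run_experiment`` repeats the class-disjoint train/test protocol over
independent trials and aggregates the evaluation reports.

All randomness derives from a single master seed: per-stage seeds are
blake2-hashed from (master seed, stage name, index), giving independent,
reproducible streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.measure import block_reduce as _block_reduce

from . import classification as clf_mod
from .compound_data import (
    ActivityClass,
    pairwise_distance_matrix,
    read_compound_table,
    rugged_reference,
    similarity_filter,
    smooth_reference,
)
from .evaluation import EvaluationReport, aggregate_trials, evaluate
from .imaging import (
    STANDARD_COLLECTIONS,
    CollectionSpec,
    RenderedImage,
    build_collection,
    normalize_and_flatten,
)
from .landscape import ColorMap, gpr_fit, gpr_surface
from .projection import canonical_orient, mds_project, neuroscale_fit, neuroscale_transform
from .synthetic_data import SyntheticClassSpec, generate_activity_class

logger = logging.getLogger("alscape")

__all__ = ["ExperimentConfig", "Dataset", "derive_seed", "build_dataset", "run_experiment"]


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed: blake2b(master|stage|index) mod 2^31."""
    digest = hashlib.blake2b(f"{master}|{stage}|{index}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment.

    Defaults describe the desk-scale profile: 12 synthetic classes, MDS
    projection, the single-elevation 0° collection, grayscale encoding and a
    reduced render size. The full-scale profile (38 classes, both
    projections, 1200×800 renders, collection "1") is reachable by overriding
    these fields.
    """

    n_classes: int = 12
    csv_paths: tuple[str, ...] | None = None  # overrides synthetic generation
    class_spec: SyntheticClassSpec = field(default_factory=SyntheticClassSpec)
    projections: tuple[str, ...] = ("MDS", "Neuroscale")
    collection: str = "7"  # name in STANDARD_COLLECTIONS, restricted to `projections`
    encoding: str = "grayscale"
    classifiers: tuple[str, ...] = ("svm", "cnn")
    n_trials: int = 10
    seed: int = 0
    out_dir: str | None = None
    render_size: tuple[int, int] = (600, 400)
    surface_resolution: int = 60
    cnn_downscale: int = 4
    similarity_threshold: float = 0.4
    neuroscale_candidates: tuple[int, ...] = (20,)
    color_mode: str = "gradient"
    cnn_config: clf_mod.CNNConfig = field(default_factory=clf_mod.CNNConfig.desk_scale)
    svm_config: clf_mod.SVMConfig = field(default_factory=clf_mod.SVMConfig.desk_scale)
    rf_config: clf_mod.RFConfig = field(default_factory=clf_mod.RFConfig)

    def collection_spec(self) -> CollectionSpec:
        spec = STANDARD_COLLECTIONS[str(self.collection)]
        projections = tuple(p for p in spec.projections if p in self.projections)
        if not projections:
            raise ValueError(
                f"collection {self.collection!r} uses none of the configured "
                f"projections {self.projections}"
            )
        return replace(spec, projections=projections, encoding=self.encoding)


@dataclass
class Dataset:
    """Images plus a manifest whose rows fully identify each image."""

    images: list[RenderedImage]
    manifest: pd.DataFrame
    class_names: tuple[str, ...]

    def image_array(self) -> np.ndarray:
        return np.stack([img.pixels for img in self.images])

    def feature_matrix(self) -> np.ndarray:
        return np.stack([normalize_and_flatten(img) for img in self.images])


def _load_classes(cfg: ExperimentConfig) -> list[ActivityClass]:
    if cfg.csv_paths:
        return [read_compound_table(p, name=os.path.splitext(os.path.basename(p))[0])
                for p in cfg.csv_paths]
    classes = []
    for i in range(cfg.n_classes):
        spec = replace(cfg.class_spec, seed=derive_seed(cfg.seed, "class", i),
                       name=f"synth{i:02d}")
        classes.append(generate_activity_class(spec))
    return classes


def _variant_sets(cls: ActivityClass, threshold: float) -> dict[str, ActivityClass]:
    filtered = similarity_filter(cls, threshold)
    if len(filtered) < 7:
        raise ValueError(f"class {cls.name!r}: too few compounds after filtering")
    return {
        "heterogeneous": filtered,
        "smooth": smooth_reference(filtered),
        "rugged": rugged_reference(filtered),
    }


def _project(variant_cls: ActivityClass, method: str, seed: int, cfg: ExperimentConfig):
    d = pairwise_distance_matrix(variant_cls)
    if method == "MDS":
        emb = mds_project(d, seed=seed)
    elif method == "Neuroscale":
        fps = [c.fingerprint for c in variant_cls.compounds]
        model = neuroscale_fit(fps, d, list(cfg.neuroscale_candidates), seed=seed)
        emb = neuroscale_transform(model, fps)
    else:
        raise ValueError(f"unknown projection {method!r}")
    return canonical_orient(emb)


def build_surfaces(cfg: ExperimentConfig) -> tuple[dict, tuple[str, ...]]:
    """(class, variant, projection) → SurfaceGrid for all configured classes."""
    cmap = ColorMap(mode=cfg.color_mode)
    spec = cfg.collection_spec()
    surfaces: dict[tuple[str, str, str], object] = {}
    names = []
    for ci, cls in enumerate(_load_classes(cfg)):
        names.append(cls.name)
        try:
            variants = _variant_sets(cls, cfg.similarity_threshold)
            for vname, vcls in variants.items():
                for proj in spec.projections:
                    emb = _project(vcls, proj, derive_seed(cfg.seed, f"proj-{proj}", ci), cfg)
                    gp = gpr_fit(emb.coords, vcls.potencies,
                                 seed=derive_seed(cfg.seed, "gpr", ci))
                    surfaces[(cls.name, vname, proj)] = gpr_surface(
                        gp, resolution=cfg.surface_resolution, cmap=cmap)
        except Exception as exc:
            raise RuntimeError(f"landscape construction failed for class {cls.name!r}: {exc}") from exc
    return surfaces, tuple(names)


def _image_filename(row: dict) -> str:
    return ("{class}_{variant}_{projection}_e{elevation:g}_a{azimuth:g}_{encoding}.png"
            .format(**{**row, "class": row["class"]}))


def build_dataset(cfg: ExperimentConfig) -> Dataset:
    """Build (or resume) the image dataset for a configuration.

    With ``out_dir`` set, images are written as PNG next to a
    ``manifest.csv``; images already on disk are loaded instead of
    re-rendered, so completed runs are no-ops.
    """
    spec = cfg.collection_spec()
    out_dir = cfg.out_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        manifest_path = os.path.join(out_dir, "manifest.csv")
        if os.path.exists(manifest_path):
            manifest = pd.read_csv(manifest_path)
            if all(os.path.exists(os.path.join(out_dir, p)) for p in manifest["path"]):
                logger.info("dataset complete in %s; skipping rendering", out_dir)
                images = [
                    RenderedImage(
                        pixels=np.asarray(iio.imread(os.path.join(out_dir, r["path"])),
                                          dtype=np.float32) / 255.0,
                        meta={k: r[k] for k in ("class", "variant", "projection",
                                                "azimuth", "elevation", "encoding")},
                    )
                    for r in manifest.to_dict("records")
                ]
                return Dataset(images=images, manifest=manifest,
                               class_names=tuple(sorted(manifest["class"].unique())))

    surfaces, names = build_surfaces(cfg)
    images, manifest = build_collection(surfaces, spec, size=cfg.render_size)
    if out_dir:
        paths = []
        for img, row in zip(images, manifest.to_dict("records")):
            fname = _image_filename(row)
            iio.imwrite(os.path.join(out_dir, fname),
                        np.round(img.pixels * 255).astype(np.uint8))
            paths.append(fname)
        manifest = manifest.assign(path=paths)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return Dataset(images=images, manifest=manifest, class_names=names)


def _cnn_inputs(dataset: Dataset, downscale: int) -> np.ndarray:
    """CNN input tensor: block-minimum downscaling, then intensity inversion.

    Landscape features (peaks, cliff walls) are thin dark strokes on a white
    background; minimum-pooling preserves them where mean/bilinear
    downscaling would wash them out, and inversion puts the background at
    zero activation.
    """
    x = dataset.image_array()
    if downscale > 1:
        block = (downscale, downscale) if x.ndim == 3 else (downscale, downscale, 1)
        x = np.stack([_block_reduce(img, block, np.min) for img in x])
    return 1.0 - x


def run_experiment(cfg: ExperimentConfig, dataset: Dataset | None = None) -> dict:
    """Run ``n_trials`` class-disjoint train/test trials and aggregate.

    Returns ``{"per_trial": {classifier: [EvaluationReport...]},
    "aggregate": {classifier: summary}, "failed_trials": {...}}``; a
    classifier failure marks that trial failed and the aggregate reports the
    completed-trial count.
    """
    if dataset is None:
        dataset = build_dataset(cfg)
    manifest = dataset.manifest
    labels = tuple(l for l in ("heterogeneous", "rugged", "smooth")
                   if l in set(manifest["variant"]))
    y_all = manifest["variant"].to_numpy()
    class_col = manifest["class"].to_numpy()

    needs_features = any(k in cfg.classifiers for k in ("svm", "rf"))
    features = dataset.feature_matrix() if needs_features else None
    x_images = _cnn_inputs(dataset, cfg.cnn_downscale) if "cnn" in cfg.classifiers else None

    per_trial: dict[str, list[EvaluationReport]] = {k: [] for k in cfg.classifiers}
    failed: dict[str, list[int]] = {k: [] for k in cfg.classifiers}
    splits = []
    for t in range(cfg.n_trials):
        split = clf_mod.split_classes(list(dataset.class_names),
                                      seed=derive_seed(cfg.seed, "split", t))
        splits.append(split)
        train_mask = np.isin(class_col, split.train_classes)
        test_mask = ~train_mask
        for kind in cfg.classifiers:
            train_seed = derive_seed(cfg.seed, f"train-{kind}", t)
            try:
                if kind == "cnn":
                    model = clf_mod.train_cnn(x_images[train_mask], y_all[train_mask],
                                              config=cfg.cnn_config, seed=train_seed,
                                              labels=labels)
                    probs, hard = clf_mod.predict(model, x_images[test_mask])
                elif kind == "svm":
                    model = clf_mod.train_svm(features[train_mask], y_all[train_mask],
                                              config=cfg.svm_config, seed=train_seed,
                                              labels=labels)
                    probs, hard = clf_mod.predict(model, features[test_mask])
                elif kind == "rf":
                    model = clf_mod.train_rf(features[train_mask], y_all[train_mask],
                                             config=cfg.rf_config, seed=train_seed,
                                             labels=labels)
                    probs, hard = clf_mod.predict(model, features[test_mask])
                else:
                    raise ValueError(f"unknown classifier {kind!r}")
            except Exception:
                logger.exception("trial %d failed for classifier %s", t, kind)
                failed[kind].append(t)
                continue
            per_trial[kind].append(evaluate(hard, y_all[test_mask], probs, labels))

    aggregate = {}
    for kind, reports in per_trial.items():
        if len(reports) >= 2:
            aggregate[kind] = aggregate_trials(reports)
        aggregate.setdefault(kind, {})["completed_trials"] = len(reports)

    result = {"per_trial": per_trial, "aggregate": aggregate, "failed_trials": failed,
              "splits": splits}
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        for kind, reports in per_trial.items():
            for i, rep in enumerate(reports):
                rep.to_json(os.path.join(cfg.out_dir, f"trial_{kind}_{i:02d}.json"))
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump({"aggregate": aggregate,
                       "failed_trials": failed}, fh, indent=2)
    return result
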