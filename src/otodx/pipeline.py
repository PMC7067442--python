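"""Pipeline configuration and end-to-end orchestration.

Ties the stages together: dataset loading, texton-dictionary / quantizer
fitting on a designated dictionary subset (40 images per class by default),
feature-matrix extraction by the configured method (``filterbank``, ``dct``
or ``ccv``), repeated stratified-split training/evaluation, and
single-image prediction.  Every artifact written to disk embeds the
configuration hash so that mismatched artifacts cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import ccv as ccv_mod
from . import dct as dct_mod
from . import filterbank as fb_mod
from .classify import ModelSpec, RepeatedEvaluation, TrainedModel, repeated_evaluation, train_model
from .preprocessing import DEFAULT_CROP_SIZE, DEFAULT_RADIUS_RANGE, preprocess_frame
from .synthetic import CLASSES, LabeledImage

FEATURE_METHODS = ("filterbank", "dct", "ccv")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    dataset_root: str = "dataset"
    class_order: tuple[str, ...] = CLASSES
    crop_size: tuple[int, int] = DEFAULT_CROP_SIZE
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE
    blur_threshold: float | None = None
    method: str = "filterbank"
    method_params: dict = field(default_factory=dict)
    model: str = "svm"
    model_params: dict = field(default_factory=dict)
    fractions: tuple[float, float] = (0.8, 0.2)
    n_reps: int = 100
    seed: int = 0
    k_per_class: int = 10
    dictionary_images_per_class: int = 40
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.method not in FEATURE_METHODS:
            raise PipelineError(f"unknown feature method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("class_order", "crop_size", "radius_range", "fractions"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class FeatureExtractor:
    """Fitted feature method: dictionary/quantizer artifacts plus dispatch."""

    method: str
    dictionary: fb_mod.TextonDictionary | None = None
    bank: fb_mod.FilterBank | None = None
    selection: dct_mod.ChannelSelection | None = None
    quantizer: dct_mod.LaplaceQuantizer | None = None
    ccv_params: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        if self.method == "ccv":
            mode = self.ccv_params.get("mode", "paper_27")
            n = self.ccv_params.get("n_colors", 27)
            return n if mode == "paper_27" else 2 * n
        return self.dictionary.n_textons

    def __call__(self, image: np.ndarray) -> np.ndarray:
        if self.method == "filterbank":
            return fb_mod.filterbank_features(image, self.dictionary, bank=self.bank)
        if self.method == "dct":
            return dct_mod.dct_texton_features(image, self.dictionary, self.selection, self.quantizer)
        return ccv_mod.ccv_features(image, **self.ccv_params)


def _dictionary_subset(images: list[LabeledImage], class_order, n_per_class: int) -> dict[str, list[np.ndarray]]:
    subset: dict[str, list[np.ndarray]] = {c: [] for c in class_order}
    for img in images:
        if img.label in subset and len(subset[img.label]) < n_per_class:
            subset[img.label].append(img.pixels)
    for cls, lst in subset.items():
        if len(lst) < n_per_class:
            raise PipelineError(f"class {cls!r}: only {len(lst)} images for a {n_per_class}-image dictionary subset")
    return subset


def fit_feature_extractor(images: list[LabeledImage], config: PipelineConfig) -> FeatureExtractor:
    """Fit dictionary/quantizer artifacts for the configured method.

    Texton dictionaries are learned from the first
    ``dictionary_images_per_class`` images of each class (the reference
    configuration pools 40 images per class, 160 in total).
    """
    mp = dict(config.method_params)
    if config.method == "ccv":
        return FeatureExtractor(method="ccv", ccv_params=mp)

    subset = _dictionary_subset(images, config.class_order, config.dictionary_images_per_class)
    if config.method == "filterbank":
        bank = fb_mod.build_mr8_bank()
        dictionary = fb_mod.build_texton_dictionary(
            subset, k=config.k_per_class, seed=config.seed, bank=bank, **mp
        )
        return FeatureExtractor(method="filterbank", dictionary=dictionary, bank=bank)

    sel = dct_mod.ChannelSelection(tuple(mp.pop("channels", dct_mod.DEFAULT_CHANNELS)))
    flat = [im for lst in subset.values() for im in lst]
    sel, quantizer = dct_mod.fit_dct_quantizer(
        flat,
        sel=sel,
        levels_ac=mp.pop("levels_ac", dct_mod.DEFAULT_LEVELS_AC),
        levels_dc=mp.pop("levels_dc", dct_mod.DEFAULT_LEVELS_DC),
    )
    dictionary = dct_mod.build_dct_texton_dictionary(subset, sel, quantizer, k=config.k_per_class, seed=config.seed, **mp)
    return FeatureExtractor(method="dct", dictionary=dictionary, selection=sel, quantizer=quantizer)


def extract_features(images: list[LabeledImage], extractor: FeatureExtractor) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, d) and label vector for a list of labeled images."""
    X = np.vstack([extractor(img.pixels) for img in images])
    y = np.array([img.label for img in images])
    return X, y


def run_training(images: list[LabeledImage], config: PipelineConfig) -> tuple[FeatureExtractor, RepeatedEvaluation, np.ndarray, np.ndarray]:
    """Fit the feature method, extract features, run the repeated protocol."""
    extractor = fit_feature_extractor(images, config)
    X, y = extract_features(images, extractor)
    spec = ModelSpec(kind=config.model, hyperparameters=dict(config.model_params), seed=config.seed)
    result = repeated_evaluation(
        X, y, spec, n_reps=config.n_reps, seed=config.seed,
        fractions=config.fractions, class_order=list(config.class_order),
    )
    return extractor, result, X, y


def metrics_table(result: RepeatedEvaluation) -> pd.DataFrame:
    """Per-repetition metrics plus mean/std summary rows."""
    rows = [{"repetition": i, **m.as_dict()} for i, m in enumerate(result.per_rep)]
    rows.append({"repetition": "mean", **result.mean})
    rows.append({"repetition": "std", **result.std})
    return pd.DataFrame(rows)


def save_model_archive(
    path: str | Path,
    config: PipelineConfig,
    extractor: FeatureExtractor,
    model: TrainedModel,
) -> None:
    joblib.dump(
        {
            "format": "otodx-model-v1",
            "config": asdict(config),
            "config_hash": config.hash(),
            "class_order": list(config.class_order),
            "method": extractor.method,
            "dictionary": extractor.dictionary,
            "bank": None,  # rebuilt on load; kernel cache is not portable
            "selection": extractor.selection,
            "quantizer": extractor.quantizer,
            "ccv_params": extractor.ccv_params,
            "model": model,
        },
        path,
    )


def load_model_archive(path: str | Path) -> dict:
    archive = joblib.load(path)
    if archive.get("format") != "otodx-model-v1":
        raise PipelineError(f"{path} is not an otodx model archive")
    if archive["method"] == "filterbank":
        archive["bank"] = fb_mod.build_mr8_bank()
    return archive


def archive_extractor(archive: dict) -> FeatureExtractor:
    return FeatureExtractor(
        method=archive["method"],
        dictionary=archive["dictionary"],
        bank=archive["bank"],
        selection=archive["selection"],
        quantizer=archive["quantizer"],
        ccv_params=archive["ccv_params"],
    )


def predict_image(
    archive: dict,
    pixels: np.ndarray,
    preprocess: bool = True,
    blur_threshold: float | None = None,
) -> dict:
    """Classify one image (raw frame or pre-cropped ROI).

    With ``preprocess`` the blur gate, aperture detection and crop run
    first; otherwise the input is treated as an ROI.  Returns the label and
    per-class scores.
    """
    cfg = archive["config"]
    if preprocess:
        roi = preprocess_frame(
            pixels,
            blur_threshold=blur_threshold if blur_threshold is not None else cfg.get("blur_threshold"),
            radius_range=tuple(cfg.get("radius_range", DEFAULT_RADIUS_RANGE)),
            crop_size=tuple(cfg.get("crop_size", DEFAULT_CROP_SIZE)),
        ).pixels
    else:
        roi = np.asarray(pixels)
    extractor = archive_extractor(archive)
    feats = extractor(roi)[None, :]
    model: TrainedModel = archive["model"]
    label = str(model.predict(feats)[0])
    scores = model.score_matrix(feats)[0]
    by_class = {str(c): float(s) for c, s in zip(model.classes_, scores)}
    return {"label": label, "scores": by_class, "roi": roi}
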