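"""Feature extraction driver: the 107-feature vector and study-level loops.

The default configuration emits exactly 107 features per (image, mask)
pair — 14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
5 NGTDM — under the canonical names ``original_<class>_<Feature>``.

Shape features depend only on the mask and spacing; first-order features
on the raw in-mask intensities (Entropy/Uniformity on the discretized
levels); texture features on the discretized gray-level grid.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from ..errors import FishradError
from ..image import ImageVolume, NamedMask, load_image, load_mask
from ..preprocess import (
    DiscretizedVolume,
    PreprocessSpec,
    apply_preprocessing,
    discretize,
    normalize_zscore,
)
from ..study import FeatureTable, StudyManifest
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .matrices import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .shape import SHAPE_FEATURES, shape_features

logger = logging.getLogger("fishrad.extract")

#: Canonical feature-class order.
FEATURE_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

_CLASS_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}


def feature_names() -> list[str]:
    """The 107 canonical feature names in canonical order."""
    return [
        f"original_{cls}_{feat}"
        for cls in FEATURE_CLASSES
        for feat in _CLASS_FEATURES[cls]
    ]


def extract_all(
    image: ImageVolume, mask: NamedMask, spec: PreprocessSpec | None = None
) -> dict[str, float]:
    """Compute the full 107-feature vector for one image/mask pair.

    Geometric preprocessing (resampling/resizing) is applied jointly for
    all masks of a specimen by the caller; this function applies the
    intensity steps of ``spec`` (normalization, discretization) and
    computes every feature class.  All values are finite.
    """
    spec = spec or PreprocessSpec()
    if mask.pixels.shape != image.shape:
        raise FishradError(
            f"mask {mask.name!r} is not aligned with the image"
        )
    work = image
    if spec.normalize == "zscore":
        work = normalize_zscore(work, mask)
    disc: DiscretizedVolume = discretize(
        work, mask, spec.bin_count, mode=spec.discretization, bin_width=spec.bin_width
    )

    values = work.pixels[mask.pixels]
    levels = disc.levels

    out: dict[str, float] = {}
    for feat, val in shape_features(mask.pixels, work.spacing).items():
        out[f"original_shape_{feat}"] = val
    fo = firstorder_features(values, disc.in_mask_levels(), work.voxel_volume)
    for feat in FIRSTORDER_FEATURES:
        out[f"original_firstorder_{feat}"] = fo[feat]
    for feat, val in glcm_features(levels).items():
        out[f"original_glcm_{feat}"] = val
    for feat, val in glrlm_features(levels).items():
        out[f"original_glrlm_{feat}"] = val
    for feat, val in glszm_features(levels).items():
        out[f"original_glszm_{feat}"] = val
    for feat, val in gldm_features(levels).items():
        out[f"original_gldm_{feat}"] = val
    for feat, val in ngtdm_features(levels).items():
        out[f"original_ngtdm_{feat}"] = val

    ordered = {name: float(out[name]) for name in feature_names()}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise FishradError(f"non-finite feature values: {bad}")
    return ordered


def extract_study(
    manifest: StudyManifest, spec: PreprocessSpec | None = None
) -> FeatureTable:
    """Extract features for every (specimen, region) of a study, serially.

    The geometric preprocessing step is applied once per specimen,
    jointly to the image and all of its masks, then each region is
    extracted in registry order.  Per-mask wall time is logged.  A
    specimen whose image or masks fail to load/extract is logged and
    skipped rather than aborting the run.
    """
    import pandas as pd

    spec = spec or PreprocessSpec(**manifest.settings) if manifest.settings else spec
    if spec is None:
        spec = PreprocessSpec()
    manifest.validate()
    rows = []
    n_skipped = 0
    for rec in manifest.specimens:
        try:
            image = load_image(manifest.resolve(rec.image_path))
        except FishradError as exc:
            logger.warning("skipping specimen %s: %s", rec.specimen_id, exc)
            n_skipped += len(rec.mask_paths)
            continue
        masks = []
        work_image = image
        for name, p in rec.mask_paths.items():
            # one unloadable or degenerate mask must not kill its siblings
            try:
                m = load_mask(manifest.resolve(p), name, image)
                work_image, processed = apply_preprocessing(image, [m], spec)
                masks.append(processed[0])
            except FishradError as exc:
                logger.warning("skipping %s/%s: %s", rec.specimen_id, name, exc)
                n_skipped += 1
        image = work_image
        for m in masks:
            t0 = time.perf_counter()
            try:
                feats = extract_all(image, m, spec)
            except FishradError as exc:
                logger.warning(
                    "skipping %s/%s: %s", rec.specimen_id, m.name, exc
                )
                n_skipped += 1
                continue
            dt = time.perf_counter() - t0
            logger.debug(
                "extracted %s/%s (%d px) in %.3f s",
                rec.specimen_id, m.name, m.n_pixels, dt,
            )
            rows.append(
                {"specimen": rec.specimen_id, "region": m.name, "label": rec.label,
                 **feats}
            )
    if n_skipped:
        logger.warning("extraction finished with %d skipped mask(s)", n_skipped)
    df = pd.DataFrame(rows, columns=["specimen", "region", "label"] + feature_names())
    return FeatureTable(df, spec.settings_fingerprint())
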