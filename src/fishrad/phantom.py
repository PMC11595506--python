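"""Synthetic zebrafish-larva phantom cohorts.

Each phantom is a grayscale image of a curved, tapered larva rendered
from geometric primitives — an arc-shaped midline with a tapering body
width, a head disc with an eye, a pericardial (heart) sac and a yolk
sac — plus additive Gaussian texture noise.  Six named region masks are
produced per specimen: ``all_fish`` (the whole silhouette), ``eye``,
``heart``, ``yolk``, ``head`` and ``length`` (a one-pixel-wide midline
band, the mask realization of the body-length measurement).

The generator encodes the classic larval malformation phenotypes as
parameters: spinal curvature (arc angle), pericardial edema (heart-sac
diameter) and microcephaly (reduced head diameter).  A two-class cohort
shifts those three parameters between classes by configurable effect
sizes expressed in within-class standard deviation units; effect 0
produces an exchangeable null cohort.

Realism is deliberately minimal — the phantoms exercise the pipeline's
statistical and structural behaviour, not photographic appearance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import PhantomError
from .image import MaskRegistry
from .study import SpecimenRecord, StudyManifest

__all__ = [
    "REGION_NAMES",
    "PhantomSpec",
    "CohortSpec",
    "render_phantom",
    "generate_specimen",
    "generate_cohort",
    "stability_cohort",
]

#: The six analyzed regions, whole animal first.
REGION_NAMES = ("all_fish", "eye", "heart", "yolk", "head", "length")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of a single phantom larva.

    Lengths are in pixels, the curvature is the total turning angle of
    the body midline in degrees (0 = straight larva), intensities are on
    the 8-bit scale.
    """

    width: int = 512
    height: int = 384
    body_length: float = 300.0
    body_halfwidth: float = 22.0
    tail_halfwidth: float = 4.0
    curvature_deg: float = 8.0
    head_diameter: float = 56.0
    eye_diameter: float = 14.0
    heart_diameter: float = 22.0
    yolk_diameter: float = 34.0
    background_level: float = 40.0
    body_level: float = 120.0
    head_level: float = 140.0
    eye_level: float = 200.0
    heart_level: float = 90.0
    yolk_level: float = 170.0
    noise_sd: float = 8.0
    #: per-image illumination model (exposure gain and offset), emulating
    #: the frame-to-frame exposure variability of optical photography
    intensity_gain: float = 1.0
    intensity_offset: float = 0.0
    seed: int = 0

    def scaled(self, factor: float) -> "PhantomSpec":
        """Uniformly scale the larva geometry (image size unchanged)."""
        return dataclasses.replace(
            self,
            body_length=self.body_length * factor,
            body_halfwidth=self.body_halfwidth * factor,
            tail_halfwidth=self.tail_halfwidth * factor,
            head_diameter=self.head_diameter * factor,
            eye_diameter=self.eye_diameter * factor,
            heart_diameter=self.heart_diameter * factor,
            yolk_diameter=self.yolk_diameter * factor,
        )


#: Small-larva preset for the resolution analysis: every region mask
#: stays below 2% of the default image area.
STABILITY_SCALE = 0.33

#: Paper-scale image dimensions for on-demand high-resolution runs.
PAPER_SCALE_SIZE = (2560, 1920)


@dataclass(frozen=True)
class CohortSpec:
    """A two-class phantom cohort with planted malformation effects.

    Between-class effects are in units of the within-class SD of the
    corresponding parameter: the high-malformation class draws larger
    curvature and heart diameter and a smaller head diameter.
    """

    n_high: int = 82
    n_low: int = 61
    base: PhantomSpec = PhantomSpec()
    curvature_effect: float = 1.0
    head_effect: float = 1.0
    heart_effect: float = 1.0
    curvature_sd: float = 4.0
    head_sd: float = 4.0
    heart_sd: float = 2.5
    length_sd: float = 15.0
    eye_sd: float = 1.0
    yolk_sd: float = 2.0
    gain_sd: float = 0.12
    offset_sd: float = 6.0
    seed: int = 0


def _midline(spec: PhantomSpec) -> np.ndarray:
    """Midline polyline (n, 2) in (row, col), centred in the image."""
    n = max(2, int(round(spec.body_length)) + 1)
    s = np.linspace(0.0, spec.body_length, n)
    theta = np.deg2rad(spec.curvature_deg)
    if abs(theta) < 1e-12:
        phi = np.zeros_like(s)
    else:
        phi = -theta / 2.0 + theta * s / spec.body_length
    ds = np.diff(s, prepend=0.0)
    x = np.cumsum(np.cos(phi) * ds)  # col
    y = np.cumsum(np.sin(phi) * ds)  # row
    pts = np.column_stack([y, x])
    # centre the midline bounding box in the image
    centre = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    target = np.array([(spec.height - 1) / 2.0, (spec.width - 1) / 2.0])
    return pts + (target - centre)


def _disc(shape: tuple[int, int], centre: np.ndarray, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one phantom: (uint8 image, {region name: bool mask}).

    Deterministic for a given spec (the seed drives the texture noise).
    Raises :class:`PhantomError` if any anatomical part leaves the image
    bounds or the eye cannot fit inside the head.
    """
    from scipy.spatial import cKDTree

    shape = (spec.height, spec.width)
    mid = _midline(spec)
    n = len(mid)
    s = np.linspace(0.0, spec.body_length, n)

    # taper: halfwidth shrinks linearly head -> tail
    halfw = spec.body_halfwidth + (spec.tail_halfwidth - spec.body_halfwidth) * s / spec.body_length

    # body = pixels within the tapered tube around the midline
    tree = cKDTree(mid)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    dist, idx = tree.query(pix, workers=-1)
    body = (dist <= halfw[idx]).reshape(shape)

    # local frame at selected midline stations
    tangents = np.gradient(mid, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])  # 90 deg CCW

    def station(frac_or_px: float) -> int:
        return int(np.clip(round(frac_or_px), 0, n - 1))

    r_head = spec.head_diameter / 2.0
    r_eye = spec.eye_diameter / 2.0
    r_heart = spec.heart_diameter / 2.0
    r_yolk = spec.yolk_diameter / 2.0

    head_centre = mid[station(r_head * 0.8)]
    eye_offset = r_head * 0.35
    if eye_offset + r_eye > r_head:
        raise PhantomError("eye does not fit inside the head")
    eye_centre = head_centre + normals[station(r_head * 0.8)] * eye_offset
    heart_centre = mid[station(r_head * 1.8)] - normals[station(r_head * 1.8)] * (r_head * 0.55)
    yolk_centre = mid[station(spec.body_length * 0.3)] - normals[
        station(spec.body_length * 0.3)
    ] * (spec.body_halfwidth * 0.35)

    head = _disc(shape, head_centre, r_head)
    eye = _disc(shape, eye_centre, r_eye)
    heart = _disc(shape, heart_centre, r_heart)
    yolk = _disc(shape, yolk_centre, r_yolk)

    all_fish = body | head | heart | yolk

    # bounds check: the silhouette must not touch the image border
    border = np.zeros(shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (all_fish & border).any():
        raise PhantomError("phantom anatomy reaches the image border")

    # length region: one-pixel-wide midline band inside the silhouette
    length = np.zeros(shape, dtype=bool)
    ri = np.clip(np.round(mid[:, 0]).astype(int), 0, shape[0] - 1)
    ci = np.clip(np.round(mid[:, 1]).astype(int), 0, shape[1] - 1)
    length[ri, ci] = True
    length &= all_fish
    if not length.any():
        raise PhantomError("length band left the silhouette")

    masks = {
        "all_fish": all_fish,
        "eye": eye,
        "heart": heart,
        "yolk": yolk,
        "head": head,
        "length": length,
    }
    for name, m in masks.items():
        if not m.any():
            raise PhantomError(f"region {name!r} is empty")

    img = np.full(shape, spec.background_level, dtype=np.float64)
    img[body] = spec.body_level
    img[head] = spec.head_level
    img[yolk] = spec.yolk_level
    img[heart] = spec.heart_level
    img[eye] = spec.eye_level
    img = img * spec.intensity_gain + spec.intensity_offset
    rng = np.random.default_rng(spec.seed)
    img += rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, masks


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr).save(path, format="PNG")


def generate_specimen(
    spec: PhantomSpec, out_dir, specimen_id: str, label: str = "low"
) -> SpecimenRecord:
    """Render and write one specimen (image + six masks + metadata).

    Files are PNG; the returned record's metadata holds the full spec so
    the specimen can be regenerated bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img, masks = render_phantom(spec)
    image_path = out_dir / f"{specimen_id}.png"
    _save_png(img, image_path)
    mask_paths = {}
    for name in REGION_NAMES:
        p = out_dir / f"{specimen_id}_{name}.png"
        _save_png((masks[name].astype(np.uint8)) * 255, p)
        mask_paths[name] = str(p.relative_to(out_dir.parent)) if out_dir.parent else str(p)
    return SpecimenRecord(
        specimen_id=specimen_id,
        image_path=str(image_path.relative_to(out_dir.parent)),
        label=label,
        mask_paths=mask_paths,
        metadata={"phantom_spec": dataclasses.asdict(spec)},
    )


def _draw_specimen_spec(
    base: PhantomSpec, cohort: CohortSpec, rng: np.random.Generator, high: bool
) -> PhantomSpec:
    sgn = 1.0 if high else 0.0
    curvature = rng.normal(
        base.curvature_deg + sgn * cohort.curvature_effect * cohort.curvature_sd,
        cohort.curvature_sd,
    )
    head_d = rng.normal(
        base.head_diameter - sgn * cohort.head_effect * cohort.head_sd,
        cohort.head_sd,
    )
    heart_d = rng.normal(
        base.heart_diameter + sgn * cohort.heart_effect * cohort.heart_sd,
        cohort.heart_sd,
    )
    body_l = rng.normal(base.body_length, cohort.length_sd)
    eye_d = rng.normal(base.eye_diameter, cohort.eye_sd)
    yolk_d = rng.normal(base.yolk_diameter, cohort.yolk_sd)
    gain = rng.normal(1.0, cohort.gain_sd)
    offset = rng.normal(0.0, cohort.offset_sd)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    head_d = float(np.clip(head_d, base.eye_diameter * 2.0, None))
    return dataclasses.replace(
        base,
        curvature_deg=float(curvature),
        head_diameter=head_d,
        heart_diameter=float(np.clip(heart_d, 4.0, None)),
        body_length=float(np.clip(body_l, base.head_diameter * 2.0, None)),
        eye_diameter=float(np.clip(eye_d, 4.0, head_d * 0.6)),
        yolk_diameter=float(np.clip(yolk_d, 6.0, None)),
        intensity_gain=float(np.clip(gain, 0.5, 1.5)),
        intensity_offset=float(offset),
        seed=seed,
    )


def generate_cohort(cohort: CohortSpec, out_dir, study_id: str = "phantom-cohort",
                    settings: dict | None = None) -> StudyManifest:
    """Generate a two-class cohort study ready for feature extraction."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(cohort.seed)
    registry = MaskRegistry(list(REGION_NAMES))
    records = []
    for i in range(cohort.n_high):
        spec = _draw_specimen_spec(cohort.base, cohort, rng, high=True)
        records.append(
            generate_specimen(spec, out_dir / "specimens", f"high_{i:03d}", "high")
        )
    for i in range(cohort.n_low):
        spec = _draw_specimen_spec(cohort.base, cohort, rng, high=False)
        records.append(
            generate_specimen(spec, out_dir / "specimens", f"low_{i:03d}", "low")
        )
    manifest = StudyManifest(
        study_id=study_id,
        registry=registry,
        settings=dict(settings or {}),
        specimens=records,
        root=out_dir,
    )
    manifest.validate()
    manifest.save(out_dir / "manifest.json")
    return manifest


def stability_cohort(
    n: int = 6, out_dir=None, seed: int = 0, base: PhantomSpec | None = None
) -> StudyManifest:
    """A small cohort of small-bodied phantoms for the resolution analysis.

    The larva geometry is scaled down so every region mask covers less
    than 2% of the image area; a second call with a different seed
    provides a replicate cohort.
    """
    if n < 1:
        raise ValueError("need at least one specimen")
    out_dir = Path(out_dir) if out_dir is not None else Path("stability_study")
    base = base or PhantomSpec().scaled(STABILITY_SCALE)
    rng = np.random.default_rng(seed)
    registry = MaskRegistry(list(REGION_NAMES))
    records = []
    for i in range(n):
        spec = dataclasses.replace(
            base,
            curvature_deg=float(rng.normal(base.curvature_deg, 4.0)),
            body_length=float(rng.normal(base.body_length, 5.0)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        records.append(
            generate_specimen(spec, out_dir / "specimens", f"fish_{i:02d}", "low")
        )
    manifest = StudyManifest(
        study_id=f"stability-{seed}",
        registry=registry,
        settings={},
        specimens=records,
        root=out_dir,
    )
    manifest.validate()
    manifest.save(out_dir / "manifest.json")
    return manifest


def regenerate_specimen(record: SpecimenRecord, out_dir) -> SpecimenRecord:
    """Re-render a specimen from its stored metadata (byte-identical)."""
    spec = PhantomSpec(**record.metadata["phantom_spec"])
    return generate_specimen(spec, out_dir, record.specimen_id, record.label)
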