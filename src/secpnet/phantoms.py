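"""Synthetic multi-organ phantom slices.

The generator emulates the structural challenges of organ-at-risk CT
segmentation without any anatomical realism: a wide organ-size spectrum
(areas scaled from published average organ volumes via the areal analogue
``volume ** (2/3)``), left/right organ pairs, organs that are absent from
individual slices (Bernoulli presence), per-slice position and size jitter,
a background intensity ramp and Gaussian noise.  Every slice is a
deterministic function of the dataset seed, the patient index and the slice
index, so datasets regenerate byte-identically.

Organs are drawn as axis-aligned ellipses in descending size order with
first-drawn-wins occupancy; the default layouts keep canonical positions
disjoint so no organ is engulfed by a larger one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "default_head_neck_spec",
    "small_five_class_spec",
    "phantom_spec_from_dict",
    "generate_slice",
    "generate_arrays",
    "generate_dataset",
]


@dataclass(frozen=True)
class OrganSpec:
    """One organ class of a phantom population.

    ``center`` is the canonical ellipse centre in (row, col) canvas
    fractions; ``semi_axes`` the (row, col) semi-axes in pixels.
    ``laterality`` is "none", "left" or "right" (informational tag for
    single-side organs) or "pair", which draws two ellipses mirrored about
    the vertical midline under the same class label.
    """

    index: int
    name: str
    center: tuple
    semi_axes: tuple
    intensity: float
    presence: float = 1.0
    laterality: str = "none"
    center_jitter: float = 0.0  # std of the Gaussian centre offset, pixels
    radius_jitter: float = 0.0  # semi-axes scaled by U(1-j, 1+j)

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("organ class indices start at 1 (0 is background)")
        if min(self.semi_axes) <= 0:
            raise ValueError(f"{self.name}: semi-axes must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"{self.name}: intensity must lie in [0, 1]")
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError(f"{self.name}: presence probability must lie in [0, 1]")
        if self.laterality not in ("none", "left", "right", "pair"):
            raise ValueError(f"{self.name}: unknown laterality {self.laterality!r}")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic slice population."""

    organs: tuple
    canvas: int = 256
    background: float = 0.15
    ramp: float = 0.10  # peak of the linear top-to-bottom intensity ramp
    noise_sigma: float = 0.03
    n_patients: int = 10
    slices_per_patient: int = 4
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "organs", tuple(self.organs))
        if self.canvas < 8:
            raise ValueError("canvas must be at least 8 pixels")
        if self.noise_sigma < 0 or self.ramp < 0:
            raise ValueError("noise sigma and ramp must be nonnegative")
        if self.n_patients < 1 or self.slices_per_patient < 1:
            raise ValueError("n_patients and slices_per_patient must be >= 1")
        indices = [o.index for o in self.organs]
        if len(set(indices)) != len(indices):
            raise ValueError("organ class indices must be unique")
        for organ in self.organs:
            self._check_fit(organ)

    def _check_fit(self, organ: OrganSpec):
        ry = organ.semi_axes[0] * (1 + organ.radius_jitter)
        rx = organ.semi_axes[1] * (1 + organ.radius_jitter)
        slack = 3.0 * organ.center_jitter  # 3-sigma bound on the centre offset
        for cy, cx in self._centers(organ, jitter=None):
            if (
                cy - ry - slack < 0
                or cy + ry + slack > self.canvas
                or cx - rx - slack < 0
                or cx + rx + slack > self.canvas
            ):
                raise ValueError(
                    f"organ {organ.name!r} cannot fit the {self.canvas}px canvas "
                    f"at semi-axes {organ.semi_axes} with its jitter"
                )

    def _centers(self, organ: OrganSpec, jitter):
        cy = organ.center[0] * self.canvas
        cx = organ.center[1] * self.canvas
        centers = [(cy, cx)]
        if organ.laterality == "pair":
            centers.append((cy, self.canvas - cx))
        if jitter is not None:
            centers = [
                (c[0] + jitter[2 * i], c[1] + jitter[2 * i + 1])
                for i, c in enumerate(centers)
            ]
        return centers

    @property
    def label_names(self) -> dict:
        names = {0: "background"}
        names.update({o.index: o.name for o in self.organs})
        return names

    @property
    def num_classes(self) -> int:
        return max(o.index for o in self.organs) + 1

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# reference populations
# ---------------------------------------------------------------------------

# published average volumes (cm^3) of the 13 head-and-neck organs-at-risk;
# phantom areas follow volume**(2/3), i.e. equivalent radius ~ volume**(1/3)
_HEAD_NECK_ORGANS = [
    # name, volume, (row_frac, col_frac), intensity, presence, laterality
    ("left eye", 8.4, (0.15, 0.35), 0.90, 0.60, "left"),
    ("right eye", 8.8, (0.15, 0.65), 0.90, 0.60, "right"),
    ("left temporal lobe", 134.3, (0.35, 0.20), 0.45, 0.80, "left"),
    ("right temporal lobe", 125.8, (0.35, 0.80), 0.45, 0.80, "right"),
    ("left mandible", 35.9, (0.62, 0.30), 0.85, 0.80, "left"),
    ("right mandible", 37.2, (0.62, 0.70), 0.85, 0.80, "right"),
    ("brain stem", 30.8, (0.35, 0.50), 0.50, 0.70, "none"),
    ("parotid left", 21.8, (0.52, 0.12), 0.60, 0.70, "left"),
    ("parotid right", 22.4, (0.52, 0.88), 0.60, 0.70, "right"),
    ("spinal cord", 23.1, (0.80, 0.50), 0.55, 0.95, "none"),
    ("submandibular left", 9.3, (0.78, 0.28), 0.65, 0.50, "left"),
    ("submandibular right", 8.9, (0.78, 0.72), 0.65, 0.50, "right"),
    ("thyroid gland", 12.8, (0.92, 0.50), 0.75, 0.40, "none"),
]


def default_head_neck_spec(
    n_patients: int = 10, slices_per_patient: int = 4, seed: int = 0
) -> PhantomSpec:
    """13-organ, 256px phantom population mirroring the head-and-neck
    organ-at-risk size spectrum (eyes ~8 cm^3 up to temporal lobe ~134 cm^3)."""
    radius_scale = 5.0  # px per cm; largest organ then spans ~26 px radius
    organs = []
    for idx, (name, volume, center, intensity, presence, side) in enumerate(
        _HEAD_NECK_ORGANS, start=1
    ):
        r = radius_scale * volume ** (1.0 / 3.0)
        organs.append(
            OrganSpec(
                index=idx,
                name=name,
                center=center,
                semi_axes=(0.8 * r, 1.1 * r),
                intensity=intensity,
                presence=presence,
                laterality=side,
                center_jitter=1.5,
                radius_jitter=0.15,
            )
        )
    return PhantomSpec(
        organs=tuple(organs),
        canvas=256,
        n_patients=n_patients,
        slices_per_patient=slices_per_patient,
        seed=seed,
    )


def small_five_class_spec(
    n_patients: int = 8, slices_per_patient: int = 4, seed: int = 0
) -> PhantomSpec:
    """64px, 4-foreground-organ population (5 classes with background) for
    CPU-scale training: one large organ, a left/right pair and one small
    organ, with absence and jitter as in the full population."""
    organs = (
        OrganSpec(1, "large organ", (0.35, 0.50), (12.0, 15.0), 0.78, 1.00,
                  "none", center_jitter=1.5, radius_jitter=0.15),
        OrganSpec(2, "paired organ left", (0.72, 0.22), (6.0, 7.0), 0.55, 0.85,
                  "left", center_jitter=1.0, radius_jitter=0.15),
        OrganSpec(3, "paired organ right", (0.72, 0.78), (6.0, 7.0), 0.55, 0.85,
                  "right", center_jitter=1.0, radius_jitter=0.15),
        OrganSpec(4, "small organ", (0.82, 0.50), (4.0, 5.0), 0.30, 0.75,
                  "none", center_jitter=1.0, radius_jitter=0.20),
    )
    return PhantomSpec(
        organs=organs,
        canvas=64,
        background=0.12,
        ramp=0.08,
        noise_sigma=0.02,
        n_patients=n_patients,
        slices_per_patient=slices_per_patient,
        seed=seed,
    )


_PRESET_BUILDERS = {
    "head-neck": default_head_neck_spec,
    "small": small_five_class_spec,
}


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a population from a parsed YAML/JSON mapping.

    Either ``preset: head-neck|small`` (with optional ``n_patients``,
    ``slices_per_patient``, ``seed`` overrides) or a full custom spec with
    an ``organs`` list whose entries mirror :class:`OrganSpec` fields.
    """
    d = dict(d)
    preset = d.pop("preset", None)
    if preset is not None:
        if d.keys() - {"n_patients", "slices_per_patient", "seed"}:
            raise ValueError(
                "a preset spec only accepts n_patients/slices_per_patient/seed "
                f"overrides, got {sorted(d)}"
            )
        try:
            builder = _PRESET_BUILDERS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(_PRESET_BUILDERS)}"
            ) from None
        return builder(**d)
    organs = tuple(
        OrganSpec(
            **{
                **o,
                "center": tuple(o["center"]),
                "semi_axes": tuple(o["semi_axes"]),
            }
        )
        for o in d.pop("organs")
    )
    return PhantomSpec(organs=organs, **d)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_slice(spec: PhantomSpec, rng: np.random.Generator):
    """One (image, mask) pair; image float64 in [0, 1], mask int labels.

    Organs are visited in descending area order; each present organ paints
    its ellipse(s) only onto still-unlabelled pixels.
    """
    n = spec.canvas
    mask = np.zeros((n, n), dtype=np.int64)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    order = sorted(spec.organs, key=lambda o: -o.area)
    for organ in order:
        present = rng.random() < organ.presence
        if not present:
            continue
        n_ellipses = 2 if organ.laterality == "pair" else 1
        jitter = (
            rng.normal(0.0, organ.center_jitter, 2 * n_ellipses)
            if organ.center_jitter > 0
            else np.zeros(2 * n_ellipses)
        )
        centers = spec._centers(organ, jitter)
        for cy, cx in centers:
            if organ.radius_jitter > 0:
                scale = rng.uniform(
                    1 - organ.radius_jitter, 1 + organ.radius_jitter, 2
                )
            else:
                scale = np.ones(2)
            ry, rx = organ.semi_axes[0] * scale[0], organ.semi_axes[1] * scale[1]
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            mask[inside & (mask == 0)] = organ.index
    image = np.full((n, n), spec.background)
    if spec.ramp > 0:
        image += spec.ramp * (yy / max(n - 1, 1))
    for organ in spec.organs:
        image[mask == organ.index] = organ.intensity
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, (n, n))
    return np.clip(image, 0.0, 1.0), mask


def _slice_rng(spec: PhantomSpec, patient: int, slice_index: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(patient, slice_index))
    )


def generate_arrays(spec: PhantomSpec):
    """In-memory dataset: images (N, 1, H, W), masks (N, H, W) and the
    patient id of every slice."""
    images, masks, patients = [], [], []
    for p in range(spec.n_patients):
        for s in range(spec.slices_per_patient):
            img, msk = generate_slice(spec, _slice_rng(spec, p, s))
            images.append(img[None])
            masks.append(msk)
            patients.append(p)
    return np.stack(images), np.stack(masks), np.asarray(patients)


def generate_dataset(spec: PhantomSpec, out_dir) -> Path:
    """Write the population to disk: ``images/`` (16-bit PNG), ``masks/``
    (8-bit PNG label maps), ``manifest.csv`` and ``labels.json``. Returns the
    manifest path.  Fully reproducible from the spec seed."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = ["patient_id,slice,image,mask"]
    for p in range(spec.n_patients):
        for s in range(spec.slices_per_patient):
            img, msk = generate_slice(spec, _slice_rng(spec, p, s))
            img_rel = f"images/p{p:03d}_s{s:03d}.png"
            msk_rel = f"masks/p{p:03d}_s{s:03d}.png"
            iio.imwrite(out_dir / img_rel, np.round(img * 65535).astype(np.uint16))
            iio.imwrite(out_dir / msk_rel, msk.astype(np.uint8))
            rows.append(f"p{p:03d},{s},{img_rel},{msk_rel}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    (out_dir / "labels.json").write_text(
        json.dumps({str(k): v for k, v in spec.label_names.items()}, indent=2)
    )
    return manifest
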