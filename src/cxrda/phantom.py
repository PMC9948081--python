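"""Synthetic radiograph phantoms with a geometrically defined cardiomegaly label.

Each phantom is a square grayscale image containing a bright thorax ellipse,
two dark lung fields and a bright cardiac silhouette straddling the midline.
The cardiothoracic ratio (CTR) — rendered heart width over internal thoracic
width — is set exactly by construction, so the class label ("cardiomegaly"
when CTR is at or above a configurable threshold, 0.55 by default) has pixel
ground truth.  A parameterized ``DomainShift`` emulates inter-hospital
appearance differences: global intensity/contrast change, additive noise,
blur and bright border artifacts.  Geometry is never altered by a shift, so
the generator's structure masks remain valid for shifted images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .manifest import LABELS, SPLITS, DatasetManifest, write_manifest
from .splits import largest_remainder_allocation

DEFAULT_CTR_THRESHOLD = 0.55  # clinical labeling rule; 0.50 is the other common convention

# Base rendering intensities. Lung fields are the single dark mode of the
# histogram; the surround (soft tissue / collimated border) is rendered
# bright-ish so intensity thresholding isolates the lungs, as it does on a
# windowed clinical radiograph.
_BACKGROUND = 0.65
_THORAX = 0.75


class PhantomValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and appearance parameters of one phantom.

    ctr
        Cardiothoracic ratio: rendered heart width / internal thoracic width.
    thorax_width_frac
        Thorax width as a fraction of the image width.
    lung_darkness / heart_brightness
        Intensity offsets (in [0, 1]) subtracted from / added to the thorax
        intensity for the lung fields and the cardiac silhouette.
    jitter
        Standard deviation (pixels) of seeded positional noise applied to the
        structure centers.
    """

    image_side: int = 128
    thorax_width_frac: float = 0.72
    ctr: float = 0.45
    lung_darkness: float = 0.55
    heart_brightness: float = 0.20
    jitter: float = 1.0

    def validate(self) -> None:
        if not self.image_side >= 32:
            raise PhantomValidationError(f"image_side must be >= 32, got {self.image_side}")
        if not 0.0 < self.ctr < 1.0:
            raise PhantomValidationError(f"ctr must be in (0, 1), got {self.ctr}")
        if not 0.0 < self.thorax_width_frac <= 1.0:
            raise PhantomValidationError(
                f"thorax_width_frac must be in (0, 1], got {self.thorax_width_frac}"
            )
        for name in ("lung_darkness", "heart_brightness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomValidationError(f"{name} must be in [0, 1], got {v}")
        if self.jitter < 0:
            raise PhantomValidationError(f"jitter must be >= 0, got {self.jitter}")


@dataclass(frozen=True)
class DomainShift:
    """Appearance-only shift applied to rendered phantoms.

    Applied in order: centered contrast gain, intensity bias, Gaussian blur,
    additive Gaussian noise, border artifacts, clipping to [0, 1].  The
    identity shift leaves images bit-identical.
    """

    intensity_bias: float = 0.0
    contrast_gain: float = 1.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    border_artifact: bool = False
    border_intensity: float = 1.0

    def validate(self) -> None:
        if not -0.3 <= self.intensity_bias <= 0.3:
            raise PhantomValidationError(f"intensity_bias outside [-0.3, 0.3]: {self.intensity_bias}")
        if not 0.5 <= self.contrast_gain <= 2.0:
            raise PhantomValidationError(f"contrast_gain outside [0.5, 2]: {self.contrast_gain}")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise PhantomValidationError("noise_sd and blur_sigma must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.intensity_bias == 0.0 and self.contrast_gain == 1.0
                and self.noise_sd == 0.0 and self.blur_sigma == 0.0
                and not self.border_artifact)

    @classmethod
    def identity(cls) -> "DomainShift":
        return cls()

    @classmethod
    def strong(cls) -> "DomainShift":
        """A pronounced appearance shift: darkened, contrast compressed to
        60%, noisy, blurred, with bright border artifacts — a different
        detector response that preserves anatomy but moves every intensity."""
        return cls(intensity_bias=-0.15, contrast_gain=0.6, noise_sd=0.06,
                   blur_sigma=1.5, border_artifact=True, border_intensity=1.0)


@dataclass
class Phantom:
    """A rendered phantom: image in [0, 1], label, and structure masks."""

    image: np.ndarray
    label: str
    ctr: float
    masks: dict[str, np.ndarray]
    spec: PhantomSpec


def _ellipse_mask(side: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the ellipse."""
    yy, xx = np.mgrid[0:side, 0:side]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def label_from_ctr(ctr: float, ctr_threshold: float = DEFAULT_CTR_THRESHOLD) -> str:
    return "cardiomegaly" if ctr >= ctr_threshold else "normal"


def render_phantom(spec: PhantomSpec, seed: int,
                   ctr_threshold: float = DEFAULT_CTR_THRESHOLD) -> Phantom:
    """Render one phantom deterministically from (spec, seed).

    The heart ellipse's semi-width is ``ctr``  times the thorax semi-width, so
    the rendered width ratio equals ``ctr`` up to pixel quantization.
    """
    spec.validate()
    s = spec.image_side
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    jit = lambda: rng.normal(0.0, spec.jitter) if spec.jitter > 0 else 0.0

    cx, cy = s / 2 + jit(), s * 0.52 + jit()
    a_t = spec.thorax_width_frac * s / 2
    b_t = 0.42 * s
    thorax = _ellipse_mask(s, cx, cy, a_t, b_t)

    lungs = np.zeros((s, s), dtype=bool)
    for sign in (-1.0, 1.0):
        lungs |= _ellipse_mask(s, cx + sign * 0.52 * a_t + jit(), cy - 0.08 * b_t + jit(),
                               0.34 * a_t, 0.72 * b_t)
    lungs &= thorax

    a_h = spec.ctr * a_t
    heart = _ellipse_mask(s, cx + 0.06 * a_t + jit(), cy + 0.38 * b_t + jit(),
                          a_h, 0.34 * b_t)
    heart &= thorax

    img = np.full((s, s), _BACKGROUND, dtype=np.float32)
    img[thorax] = _THORAX
    img[lungs] = _THORAX - spec.lung_darkness
    img[heart] = min(1.0, _THORAX + spec.heart_brightness)
    np.clip(img, 0.0, 1.0, out=img)

    return Phantom(image=img, label=label_from_ctr(spec.ctr, ctr_threshold),
                   ctr=spec.ctr, spec=spec,
                   masks={"thorax": thorax, "lungs": lungs & ~heart, "heart": heart})


def measure_widths(masks: dict[str, np.ndarray]) -> tuple[int, int]:
    """(heart width, thoracic width) in pixels, by per-row scans of the masks."""
    widths = []
    for key in ("heart", "thorax"):
        m = masks[key]
        cols = np.where(m.any(axis=0))[0]
        widths.append(int(cols.max() - cols.min() + 1) if cols.size else 0)
    return widths[0], widths[1]


def measured_ctr(masks: dict[str, np.ndarray]) -> float:
    hw, tw = measure_widths(masks)
    if tw == 0:
        raise PhantomValidationError("empty thorax mask")
    return hw / tw


def apply_domain_shift(image: np.ndarray, shift: DomainShift, seed: int) -> np.ndarray:
    """Apply an appearance shift; deterministic given seed, output in [0, 1]."""
    shift.validate()
    if image.min() < 0 or image.max() > 1:
        raise PhantomValidationError("image intensities must lie in [0, 1]")
    if shift.is_identity:
        return image.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51F7A3D]))
    out = image.astype(np.float32, copy=True)
    if shift.contrast_gain != 1.0:
        out = (out - 0.5) * shift.contrast_gain + 0.5
    if shift.intensity_bias != 0.0:
        out = out + shift.intensity_bias
    if shift.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=shift.blur_sigma, mode="reflect")
    if shift.noise_sd > 0:
        out = out + rng.normal(0.0, shift.noise_sd, size=out.shape).astype(np.float32)
    if shift.border_artifact:
        s = out.shape[0]
        t = max(1, int(round(0.02 * s)))
        v = float(shift.border_intensity)
        out[:t, :] = v
        out[-t:, :] = v
        out[:, :t] = v
        out[:, -t:] = v
        # text-like marks: a few bright blocks in the outer 8% band
        band = max(t + 1, int(round(0.08 * s)))
        for _ in range(3):
            h = int(rng.integers(2, max(3, band // 2)))
            w = int(rng.integers(4, max(5, band)))
            y = int(rng.integers(t, band - 1))
            x = int(rng.integers(t, s - w - t))
            out[y : y + h, x : x + w] = v
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 16-bit PNG."""
    arr = np.clip(np.round(image * 65535.0), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image back to float32 in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return arr.astype(np.float32)


DEFAULT_CTR_RANGES = {"normal": (0.38, 0.53), "cardiomegaly": (0.57, 0.78)}


def make_dataset(out_dir: str | Path,
                 n_per_class: dict[str, int],
                 shift: DomainShift,
                 domain: str,
                 seed: int,
                 ctr_ranges: dict[str, tuple[float, float]] | None = None,
                 split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 image_side: int = 128,
                 ctr_threshold: float = DEFAULT_CTR_THRESHOLD,
                 jitter: float = 1.0) -> DatasetManifest:
    """Generate a stratified phantom dataset on disk.

    CTRs are drawn per class from ``ctr_ranges`` (which must not cross the
    labeling threshold), images rendered, shifted and written as 16-bit PNGs;
    a ``manifest.csv`` plus a JSON sidecar of the generation parameters is
    written alongside.  Byte-identical for identical arguments.
    """
    ctr_ranges = dict(DEFAULT_CTR_RANGES if ctr_ranges is None else ctr_ranges)
    for label, n in n_per_class.items():
        if label not in LABELS:
            raise PhantomValidationError(f"unknown label {label!r}")
        if n <= 0:
            raise PhantomValidationError(f"n_per_class[{label!r}] must be > 0")
        lo, hi = ctr_ranges[label]
        if not 0 < lo <= hi < 1:
            raise PhantomValidationError(f"bad ctr range for {label!r}: {(lo, hi)}")
        implied = {label_from_ctr(lo, ctr_threshold), label_from_ctr(hi, ctr_threshold)}
        if implied != {label}:
            raise PhantomValidationError(
                f"ctr range {(lo, hi)} for class {label!r} crosses the "
                f"threshold {ctr_threshold}"
            )
    allocations = {
        label: largest_remainder_allocation(n, split_fractions)
        for label, n in n_per_class.items()
    }
    for label, alloc in allocations.items():
        if any(a == 0 for a in alloc):
            raise PhantomValidationError(
                f"class {label!r} receives an empty split under fractions "
                f"{split_fractions} (counts {alloc})"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    records = []
    for label in sorted(n_per_class):
        n = n_per_class[label]
        lo, hi = ctr_ranges[label]
        child = np.random.SeedSequence([seed, LABELS.index(label)])
        rng = np.random.default_rng(child)
        image_seeds = rng.integers(0, 2**31 - 1, size=n)
        ctrs = rng.uniform(lo, hi, size=n)
        split_of = [s for s, count in zip(SPLITS, allocations[label]) for _ in range(count)]
        for i in range(n):
            spec = PhantomSpec(image_side=image_side, ctr=float(ctrs[i]), jitter=jitter)
            ph = render_phantom(spec, int(image_seeds[i]), ctr_threshold)
            img = apply_domain_shift(ph.image, shift, int(image_seeds[i]) + 1)
            rel = f"{label}_{i:04d}.png"
            write_image(img, out_dir / rel)
            records.append({"path": str(out_dir / rel), "label": ph.label,
                            "domain": domain, "split": split_of[i]})

    import pandas as pd

    manifest = DatasetManifest(pd.DataFrame.from_records(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    sidecar = {
        "n_per_class": n_per_class, "ctr_ranges": {k: list(v) for k, v in ctr_ranges.items()},
        "shift": asdict(shift), "domain": domain, "seed": seed,
        "split_fractions": list(split_fractions), "image_side": image_side,
        "ctr_threshold": ctr_threshold, "jitter": jitter,
    }
    (out_dir / "generation.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
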