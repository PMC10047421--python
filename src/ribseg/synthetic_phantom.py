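"""Seeded 2D rib-cage phantoms with thin crack lesions.

Each phantom imitates a windowed axial chest-CT slice: a noisy
soft-tissue background, two dark lung fields, and a ring of bright
elliptical rib cross-sections.  A random minority of ribs carries a thin
dark crack polyline crossing the bright shell; the ground-truth mask
marks exactly those crack pixels.  Lesion pixels are well under 1% of the
image, reproducing the class imbalance of real fracture data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .io_preprocess import SliceSample


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 256
    n_ribs: tuple = (10, 14)          # inclusive range, or a fixed int
    rib_intensity: tuple = (0.92, 1.0)
    background_intensity: tuple = (0.4, 0.6)
    lung_intensity: float = 0.12
    fracture_probability: float = 0.3
    crack_width: int = 2
    crack_intensity: float = 0.35
    noise_sigma: float = 0.02
    rib_length_frac: float = 0.055    # rib semi-axis along the ring / size
    rib_thickness_frac: float = 0.032  # rib semi-axis across the ring / size
    n_distractors: int = 2            # cracked bright blobs off the rib ring
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.crack_width < 1:
            raise ValueError("crack_width must be >= 1")
        if not 0.0 <= self.fracture_probability <= 1.0:
            raise ValueError("fracture_probability must lie in [0,1]")
        for lo, hi in (self.rib_intensity, self.background_intensity):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("intensity ranges must lie in [0,1]")
        if not 0.0 <= self.crack_intensity <= 1.0:
            raise ValueError("crack_intensity must lie in [0,1]")
        if self.rib_length_frac * self.image_size >= self.image_size / 4:
            raise ValueError("ribs too large for the image")
        if self.rib_length_frac * self.image_size < 1:
            raise ValueError("ribs degenerate: under one pixel long")

    def n_ribs_range(self) -> tuple:
        if isinstance(self.n_ribs, int):
            return (self.n_ribs, self.n_ribs)
        lo, hi = self.n_ribs
        return int(lo), int(hi)


def _thicken(mask: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return mask
    return ndimage.binary_dilation(mask, structure=np.ones((width, width)))


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> SliceSample:
    """Render one phantom slice; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    cy = cx = s / 2.0

    image = np.full((s, s), rng.uniform(*spec.background_intensity),
                    dtype=np.float64)

    # lung fields: two dark ellipses inside the rib ring
    for side in (-1, 1):
        rr, cc = draw_ellipse(cy + 0.03 * s, cx + side * 0.17 * s,
                              0.22 * s, 0.13 * s, shape=(s, s))
        image[rr, cc] = spec.lung_intensity

    lo, hi = spec.n_ribs_range()
    n_ribs = int(rng.integers(lo, hi + 1))
    ring_rx, ring_ry = 0.38 * s, 0.32 * s
    a_px = spec.rib_length_frac * s
    b_px = spec.rib_thickness_frac * s

    mask = np.zeros((s, s), dtype=np.uint8)
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(n_ribs):
        angle = phase + 2 * np.pi * k / max(n_ribs, 1) \
            + rng.normal(0, 0.015)
        ry_c = cy + ring_ry * np.sin(angle)
        rx_c = cx + ring_rx * np.cos(angle)
        # tangent of the ring at this angle orients the rib's long axis
        tangent = np.arctan2(ring_ry * np.cos(angle), -ring_rx * np.sin(angle))
        shell = rng.uniform(*spec.rib_intensity)
        rr, cc = draw_ellipse(ry_c, rx_c, b_px, a_px, shape=(s, s),
                              rotation=-tangent)
        image[rr, cc] = shell
        rib_region = np.zeros((s, s), dtype=bool)
        rib_region[rr, cc] = True

        if rng.uniform() < spec.fracture_probability:
            crack = _draw_crack(rng, (s, s), (ry_c, rx_c), tangent,
                                a_px, spec.crack_width)
            crack &= rib_region
            if crack.any():
                image[crack] = spec.crack_intensity
                mask |= crack.astype(np.uint8)

    # distractors: vertebra/sternum-like bright blobs off the rib ring whose
    # dark clefts look locally like cracks but are NOT lesions — telling them
    # apart requires positional context, not just local contrast
    slots = [(cy + 0.18 * s, cx), (cy - 0.18 * s, cx)]
    for d in range(min(spec.n_distractors, len(slots))):
        dy, dx = slots[d]
        dy += rng.normal(0, 0.01 * s)
        dx += rng.normal(0, 0.02 * s)
        rot = rng.normal(0, 0.2)
        rr, cc = draw_ellipse(dy, dx, b_px, a_px, shape=(s, s),
                              rotation=rot)
        region = np.zeros((s, s), dtype=bool)
        region[rr, cc] = True
        region &= ~mask.astype(bool)  # never repaint lesion pixels
        image[region] = rng.uniform(*spec.rib_intensity)
        cleft = _draw_crack(rng, (s, s), (dy, dx), -rot, a_px,
                            spec.crack_width)
        image[cleft & region] = spec.crack_intensity

    image += rng.normal(0.0, spec.noise_sigma, (s, s))
    np.clip(image, 0.0, 1.0, out=image)
    return SliceSample(image=image.astype(np.float32), mask=mask,
                       volume_id=f"phantom{spec.seed}", slice_index=0)


def _draw_crack(rng, shape, center, tangent, half_len, width) -> np.ndarray:
    """Thin jittered polyline through `center`, roughly across the rib's
    long axis, long enough to cross the whole shell."""
    cyc, cxc = center
    theta = tangent + np.pi / 2 + rng.normal(0, 0.25)
    dy, dx = np.sin(theta), np.cos(theta)
    reach = half_len + 3
    n_seg = 4
    ts = np.linspace(-reach, reach, n_seg + 1)
    jitter = rng.normal(0, 0.8, n_seg + 1)
    jitter[0] = jitter[-1] = 0.0
    pts = [(cyc + t * dy - j * dx, cxc + t * dx + j * dy)
           for t, j in zip(ts, jitter)]
    line_mask = np.zeros(shape, dtype=bool)
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(int(round(y0)), int(round(x0)),
                           int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        line_mask[rr[keep], cc[keep]] = True
    return _thicken(line_mask, width)


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-derived per-sample seed, regenerable in isolation."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0])


def generate_dataset(n: int, spec: PhantomSpec = PhantomSpec(),
                     seed: int | None = None):
    """n phantoms with per-sample derived seeds plus a manifest table.

    Returns (samples, manifest) where the manifest is a DataFrame with
    volume_id, slice_index and n_lesion_pixels columns.
    """
    import pandas as pd

    if n < 0:
        raise ValueError("n must be >= 0")
    master = spec.seed if seed is None else seed
    samples = []
    for i in range(n):
        sub = dataclasses.replace(spec, seed=derive_seed(master, i))
        sample = generate_phantom(sub)
        sample.volume_id = f"phantom{master}_{i:04d}"
        samples.append(sample)
    manifest = pd.DataFrame(
        [{"volume_id": s.volume_id, "slice_index": s.slice_index,
          "n_lesion_pixels": s.n_lesion_pixels} for s in samples],
        columns=["volume_id", "slice_index", "n_lesion_pixels"],
    )
    return samples, manifest
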