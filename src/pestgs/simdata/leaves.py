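"""Render synthetic leaf photographs with a controllable damage fraction.

The recipe is deliberately simple — a green ellipse with vein texture on a
contrasting soil-coloured background, with background-coloured blobs punched
through the blade as feeding holes. Only the area contract matters to the
downstream networks: the realised damaged-area fraction is held within
+/-0.02 of the request, and the stored labels are derived from the realised
fraction by the same rules used to label real photographs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from pestgs.core import LeafImage

_BG_COLOR = np.array([0.52, 0.42, 0.30])  # dry-soil background
_LEAF_COLOR = np.array([0.18, 0.52, 0.16])
_VEIN_COLOR = np.array([0.55, 0.75, 0.40])

#: Realised-vs-requested damage fraction tolerance.
DAMAGE_TOL = 0.02


def label_from_fraction(f: float) -> tuple[int, int]:
    """Binary and severity labels for a damaged-area fraction ``f``.

    Binary: 1 iff more than 25% of the blade is damaged. Severity: 1 for up
    to 20% damage, stepping by one class per additional 20%, so 5 covers
    anything above 80%. The two rules intentionally use different thresholds
    (25% vs 20% steps), so f in (0.20, 0.25] is severity 2 yet binary 0.
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"damage fraction must lie in [0, 1], got {f}")
    binary = 1 if f > 0.25 else 0
    if f <= 0.20:
        severity = 1
    elif f > 0.80:
        severity = 5
    else:
        # bins (0.2,0.4] -> 2, (0.4,0.6] -> 3, (0.6,0.8] -> 4
        severity = int(np.ceil((f - 0.2) / 0.2 - 1e-12)) + 1
    return binary, severity


def _smooth_noise(rng: np.random.Generator, size: int, cells: int, amp: float) -> np.ndarray:
    """Low-frequency value noise: coarse Gaussian grid upsampled to size x size."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells))
    fine = ndimage.zoom(coarse, size / cells, order=1, mode="nearest", grid_mode=True)
    return amp * fine[:size, :size]


def _blob_mask(
    yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float, wob: tuple[float, float, float]
) -> np.ndarray:
    """Irregular disc: radius modulated around the perimeter for a bitten look."""
    amp, k, phase = wob
    theta = np.arctan2(yy - cy, xx - cx)
    r_theta = r * (1.0 + amp * np.cos(k * theta + phase))
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_theta**2


def generate_leaf_image(damage_fraction: float, size: int = 64, seed: int = 0) -> LeafImage:
    """Render one leaf with the requested damaged-area fraction.

    Parameters
    ----------
    damage_fraction
        Target removed-area / blade-area ratio, in [0, 0.95]. The realised
        fraction lands within ``DAMAGE_TOL`` of this.
    size
        Square image side in pixels (>= 32).
    seed
        Same seed, same arguments => bit-identical image.
    """
    if not 0.0 <= damage_fraction <= 0.95:
        raise ValueError("damage_fraction must lie in [0, 0.95]")
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), size, 9151]))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = size * rng.uniform(0.40, 0.46)  # semi-major
    b = size * rng.uniform(0.26, 0.33)  # semi-minor
    phi = rng.uniform(0, np.pi)
    u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    leaf_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    leaf_area = int(leaf_mask.sum())

    # Background with mild mottling.
    img = np.empty((size, size, 3))
    bg_tex = _smooth_noise(rng, size, 8, 0.05)
    img[:] = np.clip(_BG_COLOR[None, None, :] + bg_tex[:, :, None], 0, 1)

    # Blade: green with value-noise mottling plus a midrib and lateral veins.
    blade_tex = _smooth_noise(rng, size, 12, 0.06)
    mid = np.abs(v) < max(1.0, 0.012 * size)
    lateral = np.zeros_like(leaf_mask)
    n_veins = int(rng.integers(4, 7))
    for k in range(1, n_veins + 1):
        off = (k / (n_veins + 1) - 0.5) * 2 * b * 0.9
        slope = rng.uniform(0.35, 0.7) * np.sign(off if off != 0 else 1.0)
        lateral |= np.abs((v - off) - slope * u) < max(1.0, 0.008 * size)
    vein = (mid | lateral) & leaf_mask
    leaf_rgb = np.clip(_LEAF_COLOR[None, None, :] + blade_tex[:, :, None], 0, 1)
    img[leaf_mask] = leaf_rgb[leaf_mask]
    img[vein] = 0.65 * img[vein] + 0.35 * _VEIN_COLOR[None, :]

    # Punch feeding holes until the realised fraction is inside tolerance.
    holes = np.zeros_like(leaf_mask)
    target = damage_fraction
    if target > 0 and leaf_area > 0:
        inner = 0.5 * DAMAGE_TOL
        max_r = 0.16 * size
        for _ in range(400):
            frac = holes.sum() / leaf_area
            deficit = target - frac
            if abs(deficit) <= inner:
                break
            # Radius sized to the remaining deficit, shrunk on overshoot.
            r = min(max_r, max(1.2, np.sqrt(deficit * leaf_area / np.pi)))
            iy, ix = np.nonzero(leaf_mask & ~holes)
            pick = rng.integers(len(iy))
            hy, hx = float(iy[pick]), float(ix[pick])
            wob = (rng.uniform(0.0, 0.35), float(rng.integers(3, 7)), rng.uniform(0, 2 * np.pi))
            for _shrink in range(12):
                cand = _blob_mask(yy, xx, hy, hx, r, wob) & leaf_mask
                new = (holes | cand).sum() / leaf_area
                if new <= target + inner or r <= 1.0:
                    holes |= cand
                    break
                r *= 0.7
    # Holes expose the background (slightly darkened, as if shadowed).
    shade = rng.uniform(0.75, 0.95)
    img[holes] = np.clip(_BG_COLOR[None, :] * shade, 0, 1)

    realized = float(holes.sum() / leaf_area) if leaf_area else 0.0
    binary, severity = label_from_fraction(realized)
    return LeafImage(
        pixels=np.clip(img, 0.0, 1.0),
        leaf_mask=leaf_mask & ~holes,
        damage_fraction=realized,
        binary_label=binary,
        severity_class=severity,
        seed=int(seed),
    )
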