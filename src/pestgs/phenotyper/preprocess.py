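"""Image preparation: resize/normalise, seeded augmentation, leaf detection.

Augmentation bounds follow the training recipe for the damage networks:
rotations up to 45 degrees, width/height shifts up to 15%, horizontal flips,
and zooms within a 50% range. The leaf detector is a deterministic
colour/connected-component rule — the cropping contract (a tight padded box
around the largest green-dominant blob) is all downstream code relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


class LeafNotFoundError(RuntimeError):
    """No green-dominant connected component in the image."""


def preprocess_image(raw, input_size: int = 224) -> np.ndarray:
    """Resize to ``input_size`` square and normalise pixel values to [0, 1].

    Accepts a PIL image, an H x W x 3 uint8 array, or a float array already
    in [0, 1]. Conforming input (right size, float in [0, 1]) passes through
    unchanged, so the operation is idempotent.
    """
    from PIL import Image

    if hasattr(raw, "convert"):  # PIL image
        arr = np.asarray(raw.convert("RGB"))
    else:
        arr = np.asarray(raw)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    if arr.size == 0:
        raise ValueError("image has no pixels")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
        if float(arr.min()) < 0.0 or float(arr.max()) > 1.0:
            raise ValueError("float input must already lie in [0, 1]")
    h, w = arr.shape[:2]
    if (h, w) != (input_size, input_size):
        im = Image.fromarray(np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8))
        im = im.resize((input_size, input_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return np.clip(arr, 0.0, 1.0)


def sample_augmentation_params(
    seed: int,
    rotation_deg: float = 45.0,
    shift_frac: float = 0.15,
    flip: bool = True,
    zoom_range: float = 0.5,
) -> dict:
    """Draw one augmentation parameter set (the bounds are inclusive limits)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4411]))
    return {
        "angle": float(rng.uniform(-rotation_deg, rotation_deg)),
        "shift_x": float(rng.uniform(-shift_frac, shift_frac)),
        "shift_y": float(rng.uniform(-shift_frac, shift_frac)),
        "flip": bool(flip and rng.random() < 0.5),
        "zoom": float(rng.uniform(1.0 - zoom_range, 1.0 + zoom_range)),
    }


def augment(
    img: np.ndarray,
    seed: int,
    rotation_deg: float = 45.0,
    shift_frac: float = 0.15,
    flip: bool = True,
    zoom_range: float = 0.5,
) -> np.ndarray:
    """Random rotation / shift / horizontal flip / zoom of one [0,1] tensor.

    Same seed, same bounds => identical output. Disabled components
    (``rotation_deg=0`` etc.) apply exactly the identity, so e.g. a
    flip-only policy on a mirror-symmetric image returns the input.
    """
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 tensor")
    p = sample_augmentation_params(seed, rotation_deg, shift_frac, flip, zoom_range)
    out = img
    if p["flip"]:
        out = out[:, ::-1, :]
    if p["angle"] != 0.0 or p["zoom"] != 1.0 or p["shift_x"] != 0.0 or p["shift_y"] != 0.0:
        h, w = out.shape[:2]
        theta = np.deg2rad(p["angle"])
        # affine_transform maps output coords to input: rotate+scale about the
        # centre, then translate by the sampled shifts.
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        mat = rot / p["zoom"]
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        shift = np.array([p["shift_y"] * h, p["shift_x"] * w])
        offset = centre - mat @ (centre - shift)
        out = np.stack(
            [
                ndimage.affine_transform(
                    out[:, :, c], mat, offset=offset, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=2,
        )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def detect_leaf_bbox(image: np.ndarray, pad: float = 0.05) -> tuple[int, int, int, int]:
    """Tight padded box (row0, col0, row1, col1; half-open) around the leaf.

    The leaf is taken to be the largest 8-connected component of
    green-dominant pixels (G strictly the largest channel). Raises
    :class:`LeafNotFoundError` when no such component exists.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    r, g, b = image[:, :, 0], image[:, :, 1], image[:, :, 2]
    green = (g > r) & (g > b)
    labels, n = ndimage.label(green, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise LeafNotFoundError("no green-dominant component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    rows = np.nonzero(comp.any(axis=1))[0]
    cols = np.nonzero(comp.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pr = int(round(pad * (r1 - r0)))
    pc = int(round(pad * (c1 - c0)))
    h, w = image.shape[:2]
    return (max(0, r0 - pr), max(0, c0 - pc), min(h, r1 + pr), min(w, c1 + pc))
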