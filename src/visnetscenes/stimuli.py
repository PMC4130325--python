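"""Procedural stimulus generation: objects, training canvases, cluttered scenes.

Four object classes (two person-like, two vehicle-like) are rendered from
parametric 3-D part lists by orthographic projection after rotation about the
vertical axis, so the 2-D silhouette changes smoothly and substantially with
view angle.  Rendering is deterministic given (object_id, view, seed).

Conventions (used everywhere in the package): images are 2-D uint8 grayscale
rasters, 0-based row-major (row, col) coordinates; translation offsets are
given as (dx, dy) = (column, row) displacements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BACKGROUND = 127
N_OBJECTS = 4


@dataclass(frozen=True)
class ObjectSpec:
    """Parametric description of one of the four object classes."""

    object_id: int
    albedo_texture_seed: int = 0

    def __post_init__(self):
        if self.object_id not in range(N_OBJECTS):
            raise ValueError(f"unknown object_id {self.object_id}; expected 0..3")


@dataclass(frozen=True)
class Pose:
    view_deg: float
    offset: tuple = (0, 0)  # (dx, dy) pixels relative to canvas centre


@dataclass
class Scene:
    image: np.ndarray
    # list of (object_id, Pose, (row, col) true centre in scene coordinates)
    placements: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# part lists: (shape exponent p, centre xyz, semi-axes xyz, albedo, phase)
# coordinates in object units; +y is up, view rotates about the y axis.
# p=2 gives an ellipsoid footprint, larger p a boxier superellipse.
# ---------------------------------------------------------------------------

_PART_TABLES = {
    # person A: slim biped — tall torso, head, offset legs and arms
    0: [
        (2, (0.0, 0.25, 0.0), (0.28, 0.62, 0.18), 205, 0.0),
        (2, (0.0, 1.05, 0.05), (0.22, 0.24, 0.22), 230, 0.5),
        (2, (-0.16, -0.75, 0.10), (0.11, 0.55, 0.11), 175, 1.0),
        (2, (0.16, -0.75, -0.10), (0.11, 0.55, 0.11), 165, 1.5),
        (2, (-0.42, 0.30, -0.12), (0.09, 0.45, 0.09), 190, 2.0),
        (2, (0.42, 0.18, 0.15), (0.09, 0.45, 0.09), 185, 2.5),
    ],
    # person B: squat broad figure — wide torso, big head, arms out
    1: [
        (2, (0.0, 0.05, 0.0), (0.55, 0.50, 0.30), 70, 0.3),
        (2, (0.0, 0.85, 0.0), (0.30, 0.30, 0.30), 55, 0.9),
        (2, (-0.70, 0.15, 0.20), (0.16, 0.38, 0.14), 95, 1.3),
        (2, (0.70, 0.15, -0.20), (0.16, 0.38, 0.14), 90, 1.9),
        (2, (-0.22, -0.80, -0.05), (0.14, 0.42, 0.14), 60, 2.4),
        (2, (0.22, -0.80, 0.05), (0.14, 0.42, 0.14), 65, 2.9),
    ],
    # vehicle A: jeep-like — long boxy body, cabin, four dark wheels
    2: [
        (6, (0.0, -0.05, 0.0), (1.00, 0.30, 0.62), 215, 0.2),
        (6, (-0.35, 0.40, 0.0), (0.40, 0.25, 0.55), 195, 0.8),
        (2, (-0.65, -0.50, 0.45), (0.22, 0.22, 0.08), 40, 0.0),
        (2, (0.65, -0.50, 0.45), (0.22, 0.22, 0.08), 40, 0.0),
        (2, (-0.65, -0.50, -0.45), (0.22, 0.22, 0.08), 45, 0.0),
        (2, (0.65, -0.50, -0.45), (0.22, 0.22, 0.08), 45, 0.0),
    ],
    # vehicle B: tank-like — low long hull, turret, barrel, track skirts
    3: [
        (6, (0.0, -0.35, 0.0), (1.05, 0.25, 0.55), 90, 0.4),
        (2, (0.05, 0.10, 0.0), (0.45, 0.28, 0.40), 110, 1.1),
        (6, (0.80, 0.15, 0.0), (0.50, 0.06, 0.06), 130, 0.0),
        (6, (0.0, -0.62, 0.50), (1.00, 0.14, 0.10), 35, 0.0),
        (6, (0.0, -0.62, -0.50), (1.00, 0.14, 0.10), 35, 0.0),
    ],
}


# canonical heading of each object relative to the camera at view 0, so the
# boxy forms are never seen exactly axis-on at a trained view
_POSE_OFFSET_DEG = {0: 10.0, 1: -12.0, 2: 20.0, 3: -17.0}


def _texture(size: int, seed: int, object_id: int) -> np.ndarray:
    """Zero-mean, unit-variance albedo texture, distinctive per object class.

    Each class gets its own surface statistics (smooth mottle, fine grain,
    coarse or fine oriented weave), mimicking the distinct materials of real
    object classes; this is what makes the classes separable in early
    oriented-energy channels, not just in silhouette.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    if object_id == 0:        # smooth mottle
        tex = ndimage.gaussian_filter(
            ndimage.zoom(rng.standard_normal((size // 16, size // 16)), 16,
                         order=1), 6.0)
    elif object_id == 1:      # horizontal weave
        tex = np.sin(2 * np.pi * rows / 16.0)
        tex = tex + 0.3 * ndimage.gaussian_filter(
            rng.standard_normal((size, size)), 2.0)
    elif object_id == 2:      # coarse diagonal weave
        tex = np.sin(2 * np.pi * (rows + cols) / (16.0 * np.sqrt(2.0)))
        tex = tex + 0.3 * ndimage.gaussian_filter(
            rng.standard_normal((size, size)), 2.0)
    else:                     # fine counter-diagonal weave
        tex = np.sin(2 * np.pi * (rows - cols) / (8.0 * np.sqrt(2.0)))
        tex = tex + 0.3 * ndimage.gaussian_filter(
            rng.standard_normal((size, size)), 2.0)
    tex = tex - tex.mean()
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def render_object_with_mask(spec: ObjectSpec, view_deg: float,
                            size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Render one object; return (uint8 image, boolean foreground mask)."""
    theta = np.deg2rad(view_deg % 360.0 + _POSE_OFFSET_DEG[spec.object_id])
    c, s = np.cos(theta), np.sin(theta)
    scale = size * 0.28  # px per object unit; object fills most of the tile
    half = size / 2.0

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    img = np.full((size, size), float(BACKGROUND))
    mask = np.zeros((size, size), dtype=bool)
    tex = _texture(size, spec.albedo_texture_seed + 7919 * spec.object_id,
                   spec.object_id)

    parts = _PART_TABLES[spec.object_id]
    # painter's algorithm: far parts (small depth) first
    def depth(part):
        _, (cx, cy, cz), _, _, _ = part
        return -cx * s + cz * c
    for p, (cx, cy, cz), (sx, sy, sz), albedo, phase in sorted(parts, key=depth):
        x_scr = cx * c + cz * s
        d = -cx * s + cz * c
        col0 = half + x_scr * scale
        row0 = half - cy * scale
        a_col = scale * np.sqrt((sx * c) ** 2 + (sz * s) ** 2)
        a_row = scale * sy
        u = (cols - col0) / max(a_col, 1e-9)
        v = (rows - row0) / max(a_row, 1e-9)
        inside = np.abs(u) ** p + np.abs(v) ** p <= 1.0
        shade = albedo * (0.80 + 0.20 * np.cos(theta + phase)) + 12.0 * np.tanh(d)
        img[inside] = shade
        mask |= inside

    img = img + mask * 28.0 * tex
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def render_object(spec: ObjectSpec, view_deg: float, size: int = 256) -> np.ndarray:
    """256x256 grayscale render of the object at the given view angle.

    Intensity spans 0-255 with the background at approximately 127.
    """
    img, _ = render_object_with_mask(spec, view_deg, size)
    return img


def place_on_canvas(obj: np.ndarray, offset: tuple, canvas_size: int = 512) -> np.ndarray:
    """Paste an object tile onto a mid-gray canvas, centre displaced by (dx, dy).

    The larger canvas prevents wrap-around/border effects in the V1 filtering
    stage.  Raises if the tile would clip the canvas edge.
    """
    dx, dy = int(offset[0]), int(offset[1])
    h, w = obj.shape
    r0 = canvas_size // 2 + dy - h // 2
    c0 = canvas_size // 2 + dx - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > canvas_size or c0 + w > canvas_size:
        raise ValueError(
            f"offset ({dx}, {dy}) clips the {h}x{w} object on a "
            f"{canvas_size}x{canvas_size} canvas")
    canvas = np.full((canvas_size, canvas_size), BACKGROUND, dtype=np.uint8)
    canvas[r0:r0 + h, c0:c0 + w] = obj
    return canvas


def make_translation_grid(n_per_side: int, spacing_px: int) -> list[tuple]:
    """Centred square grid of (dx, dy) training offsets."""
    if n_per_side % 2 != 1:
        raise ValueError("n_per_side must be odd so the grid is centred on (0,0)")
    half = n_per_side // 2
    coords = [spacing_px * k for k in range(-half, half + 1)]
    return [(dx, dy) for dy in coords for dx in coords]


def _clutter_background(size: int, seed: int, contrast: float,
                        n_distractors: int) -> np.ndarray:
    """Multi-scale filtered noise plus scattered high-contrast blobs.

    Amplitudes are set so that a scene's bottom-up saliency map carries a
    couple of non-object peaks alongside the object peaks, without the
    clutter itself flooding the map with spurious candidate fixations.
    """
    rng = np.random.default_rng(seed)
    acc = np.zeros((size, size))
    for block in (16, 32):
        coarse = rng.standard_normal((size // block, size // block))
        acc += ndimage.zoom(coarse, block, order=1)
    acc = ndimage.gaussian_filter(acc, 2.0)
    acc *= contrast / max(acc.std(), 1e-12)

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(n_distractors):
        r = rng.uniform(0.1 * size, 0.9 * size)
        c = rng.uniform(0.1 * size, 0.9 * size)
        rad = rng.uniform(0.03 * size, 0.06 * size)
        amp = rng.choice([-45.0, 45.0])
        acc += amp * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * rad ** 2))
    return np.clip(np.round(BACKGROUND + acc), 0, 255).astype(np.uint8)


def compose_scene(background_seed: int, placements: list,
                  scene_size: int = 1024, object_size: int = 256,
                  n_distractors: int = 2, clutter_contrast: float = 6.0) -> Scene:
    """Paste objects (foreground pixels only) onto textured clutter.

    ``placements`` is a list of (object_id, view_deg, (row, col) centre).
    Object bounding boxes must stay inside the scene and must not overlap.
    """
    img = _clutter_background(scene_size, background_seed, clutter_contrast,
                              n_distractors)
    half = object_size // 2
    boxes = []
    out_placements = []
    for object_id, view_deg, (row, col) in placements:
        r0, c0 = int(row) - half, int(col) - half
        if r0 < 0 or c0 < 0 or r0 + object_size > scene_size or c0 + object_size > scene_size:
            raise ValueError(f"object {object_id} at ({row},{col}) leaves the scene")
        for (pr, pc) in boxes:
            if abs(pr - r0) < object_size and abs(pc - c0) < object_size:
                raise ValueError("overlapping object bounding boxes")
        boxes.append((r0, c0))
        spec = ObjectSpec(object_id=object_id)
        tile, m = render_object_with_mask(spec, view_deg, object_size)
        region = img[r0:r0 + object_size, c0:c0 + object_size]
        region[m] = tile[m]
        out_placements.append((object_id, Pose(view_deg=view_deg),
                               (int(row), int(col))))
    return Scene(image=img, placements=out_placements)


def scene_ground_truth(scene: Scene) -> list[dict]:
    return [{"object_id": oid, "view_deg": pose.view_deg, "center": list(center)}
            for oid, pose, center in scene.placements]


def save_scene(scene: Scene, png_path, json_path, scene_id: str = "scene") -> None:
    from PIL import Image as PILImage
    PILImage.fromarray(scene.image, mode="L").save(png_path)
    with open(json_path, "w") as fh:
        json.dump({"scene_id": scene_id, "placements": scene_ground_truth(scene)},
                  fh, indent=2)
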