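"""Graph-based visual saliency: the dorsal-stream surrogate.

Feature maps (intensity contrast and Gabor orientation energy, no color) are
computed at several dyadic scales.  For each map a fully connected graph over
map nodes is built whose edge weight combines feature dissimilarity
|log(f_i/f_j)| with spatial proximity exp(-d^2 / 2 sigma^2); normalizing
outgoing weights gives a Markov chain whose equilibrium distribution is the
activation map.  A second Markov pass with weights proportional to the target
node's activation concentrates mass at peaks.  The channel/scale maps are
averaged into a master saliency map from which fixations are extracted as
saliency-weighted centroids of thresholded peak regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from skimage.transform import resize

from . import gabor

logger = logging.getLogger(__name__)

_EPS_FRAC = 1e-6       # positivity offset before logs, fraction of map max
_TELEPORT = 1e-6       # uniform ergodicity weight added to every edge
_POWER_TOL = 1e-8
_POWER_MAXITER = 10000


@dataclass
class FeatureMap:
    channel: str           # "intensity" or "orientation(<deg>)"
    scale: int             # map side length
    values: np.ndarray


@dataclass
class Fixation:
    center: tuple          # (row, col) weighted centroid
    peak_mass: float
    rank: int


# a small bank reused for the orientation channels
_SAL_BANK = None


def _sal_bank():
    global _SAL_BANK
    if _SAL_BANK is None:
        _SAL_BANK = gabor.build_bank(orientations=(0.0, 45.0, 90.0, 135.0),
                                     frequencies=(0.125,), sigma_per_cycle=0.4)
    return _SAL_BANK


def feature_pyramid(scene: np.ndarray, scales=(32, 16, 8)) -> list:
    """Intensity-contrast and orientation-energy maps at dyadic scales.

    Each pyramid level filters the scene at a working resolution four times
    the graph scale and then pools the rectified *energy* down to the graph
    scale, so high-frequency structure (texture, edges) survives
    downsampling instead of averaging away.
    """
    scene = np.asarray(scene, dtype=np.float64)
    if scene.ndim != 2:
        raise ValueError("scene must be grayscale")
    if min(scene.shape) < max(scales):
        raise ValueError("scene smaller than the coarsest pyramid scale")
    x = scene / 255.0 if scene.max() > 1.5 else scene
    bank = _sal_bank()
    maps = []
    for s in scales:
        work = resize(x, (4 * s, 4 * s), anti_aliasing=True)
        contrast = np.abs(work - ndimage.gaussian_filter(work, 2.0))
        maps.append(FeatureMap("intensity", s,
                               block_reduce(contrast, (4, 4), np.mean)))
        for i, th in enumerate(bank.orientations):
            energy = np.abs(gabor._convolve_reflect(work, bank.kernels[i][0]))
            maps.append(FeatureMap(f"orientation({th:g})", s,
                                   block_reduce(energy, (4, 4), np.mean)))
    return maps


_DECAY_CACHE: dict = {}


def _decay_matrix(shape: tuple, sigma: float) -> np.ndarray:
    key = (shape, round(sigma, 9))
    if key not in _DECAY_CACHE:
        h, w = shape
        rows, cols = np.mgrid[0:h, 0:w]
        r = rows.reshape(-1).astype(np.float64)
        c = cols.reshape(-1).astype(np.float64)
        d2 = (r[:, None] - r[None, :]) ** 2 + (c[:, None] - c[None, :]) ** 2
        _DECAY_CACHE[key] = np.exp(-d2 / (2.0 * sigma ** 2))
    return _DECAY_CACHE[key]


def _equilibrium(weights: np.ndarray) -> np.ndarray:
    """Stationary distribution of the outgoing-normalized Markov chain."""
    w = weights + _TELEPORT
    p = w / w.sum(axis=1, keepdims=True)
    v = np.full(p.shape[0], 1.0 / p.shape[0])
    for _ in range(_POWER_MAXITER):
        nv = v @ p
        nv /= nv.sum()
        if np.abs(nv - v).sum() < _POWER_TOL:
            return nv
        v = nv
    raise RuntimeError("Markov equilibrium power iteration did not converge")


def gbvs_activate(fm_values: np.ndarray, sigma_frac: float = 0.15) -> np.ndarray:
    """Activation map: equilibrium of the dissimilarity-weighted chain."""
    vals = np.asarray(fm_values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("feature map contains non-finite values")
    shape = vals.shape
    mx = vals.max()
    logf = np.log(vals.reshape(-1) + max(mx, 1.0) * _EPS_FRAC)
    dissim = np.abs(logf[:, None] - logf[None, :])
    sigma = sigma_frac * shape[1]
    weights = dissim * _decay_matrix(shape, sigma)
    return _equilibrium(weights).reshape(shape)


def gbvs_normalize(am: np.ndarray, sigma_frac: float = 0.15) -> np.ndarray:
    """Mass-concentration pass: edge weight to j proportional to am_j."""
    am = np.asarray(am, dtype=np.float64)
    shape = am.shape
    sigma = sigma_frac * shape[1]
    weights = am.reshape(-1)[None, :] * _decay_matrix(shape, sigma)
    return _equilibrium(weights).reshape(shape)


def master_map(normalized_maps: list, scene_shape: tuple) -> np.ndarray:
    """Upsample all channel/scale maps to scene resolution and average."""
    if len(normalized_maps) < 1:
        raise ValueError("need at least one map")
    acc = np.zeros(scene_shape)
    for m in normalized_maps:
        vals = m.values if isinstance(m, FeatureMap) else np.asarray(m)
        up = np.clip(resize(vals.astype(np.float64), scene_shape, order=1), 0, None)
        acc += up / up.sum()
    return acc / acc.sum()


def compute_saliency(scene: np.ndarray, scales=(32, 16, 8),
                     sigma_frac: float = 0.15) -> np.ndarray:
    """Full pipeline: pyramid -> activate -> normalize -> master map."""
    maps = feature_pyramid(scene, scales)
    normed = []
    for fm in maps:
        am = gbvs_activate(fm.values, sigma_frac)
        normed.append(FeatureMap(fm.channel, fm.scale,
                                 gbvs_normalize(am, sigma_frac)))
    return master_map(normed, scene.shape)


def extract_fixations(sm: np.ndarray, k: int = 6,
                      threshold_frac: float = 0.1) -> list:
    """Top-k saliency peaks as weighted centroids of thresholded regions.

    The map is thresholded at ``threshold_frac`` of its maximum and the
    suprathreshold support is segmented into one region per local maximum
    (watershed on the inverted map), so neighbouring peaks that share a
    plateau are still resolved as separate fixation targets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sm = np.asarray(sm, dtype=np.float64)
    mask = sm >= threshold_frac * sm.max()
    min_dist = max(4, min(sm.shape) // 16)
    peaks = peak_local_max(sm, min_distance=min_dist, labels=mask)
    if peaks.shape[0] == 0:
        return []
    markers = np.zeros(sm.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = watershed(-sm, markers, mask=mask)
    # background-subtracted saliency is the centroid/mass weight; each
    # region is confined to a window around its peak so that broad shallow
    # basins do not accrue mass from distant plateau
    excess = np.clip(sm - threshold_frac * sm.max(), 0.0, None)
    win = int(round(1.5 * min_dist))
    regions = []
    for i, pk in enumerate(peaks):
        r0, r1 = max(0, pk[0] - win), min(sm.shape[0], pk[0] + win + 1)
        c0, c1 = max(0, pk[1] - win), min(sm.shape[1], pk[1] + win + 1)
        sub = excess[r0:r1, c0:c1] * (labels[r0:r1, c0:c1] == i + 1)
        mass = sub.sum()
        if mass <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        regions.append((mass, ((rr * sub).sum() / mass,
                               (cc * sub).sum() / mass)))
    regions.sort(key=lambda t: (-t[0], t[1][0], t[1][1]))
    if len(regions) < k:
        logger.warning("only %d salient regions found (k=%d requested)",
                       len(regions), k)
    return [Fixation(center=cen, peak_mass=float(mass), rank=r + 1)
            for r, (mass, cen) in enumerate(regions[:k])]


def extract_patch(scene: np.ndarray, fx: Fixation,
                  patch_size: int = 384) -> np.ndarray:
    """Fixation-centred crop; regions outside the scene padded with mid-gray."""
    if patch_size % 2 != 0:
        raise ValueError("patch_size must be even")
    half = patch_size // 2
    r = int(round(fx.center[0]))
    c = int(round(fx.center[1]))
    patch = np.full((patch_size, patch_size), 127, dtype=np.uint8)
    r0, r1 = r - half, r + half
    c0, c1 = c - half, c + half
    sr0, sr1 = max(r0, 0), min(r1, scene.shape[0])
    sc0, sc1 = max(c0, 0), min(c1, scene.shape[1])
    if sr1 > sr0 and sc1 > sc0:
        patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = scene[sr0:sr1, sc0:sc1]
    return patch


def offset_statistics(fixations: list, truths: list,
                      match_radius: float = 64.0) -> dict:
    """Match each ground-truth object to its nearest fixation.

    ``truths`` is a list of dicts with keys ``object_id`` and ``center``.
    Returns per-object offsets (Euclidean px), fixation assignment, and
    misses (no fixation within ``match_radius``).
    """
    matches, misses, offsets = [], [], []
    centers = np.array([f.center for f in fixations]) if fixations else np.empty((0, 2))
    for t in truths:
        tc = np.asarray(t["center"], dtype=np.float64)
        if centers.shape[0] == 0:
            misses.append(t["object_id"])
            continue
        d = np.linalg.norm(centers - tc, axis=1)
        j = int(np.argmin(d))
        if d[j] <= match_radius:
            matches.append({"object_id": t["object_id"], "fixation": j,
                            "offset_px": float(d[j])})
            offsets.append(float(d[j]))
        else:
            misses.append(t["object_id"])
    hist, edges = np.histogram(offsets, bins=np.arange(0, 129, 16))
    return {"matches": matches, "misses": misses, "offsets_px": offsets,
            "histogram": hist.tolist(), "histogram_edges": edges.tolist()}
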