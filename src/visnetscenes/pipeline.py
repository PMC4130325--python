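"""End-to-end drivers: training set, network training, readout, evaluations.

The training protocol: each object is rendered at the trained views (45 deg
apart) and pasted at every location of a centred square grid on a mid-gray
canvas; each canvas is Gabor-filtered once and cached.  During an epoch the
transforms of one object are presented in a random permuted sequence with
the trace reset between objects.  Performance is read out by a pattern
associator over the most object-selective layer-4 cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gabor, info, network, saliency, stimuli
from .config import RunConfig

logger = logging.getLogger(__name__)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class TrainSet:
    """Per-object lists of flattened V1 responses plus their poses."""

    per_object: list                 # [object][transform] -> 1-D array
    poses: list                      # [object][transform] -> (view_deg, (dx, dy))
    config_digest: str = ""

    @property
    def n_transforms(self) -> int:
        return len(self.per_object[0])


def build_trainset(cfg: RunConfig, cache_dir=None) -> TrainSet:
    """Render, place, and Gabor-filter every (object, view, location).

    With a ``cache_dir``, tensors are stored under the config hash and
    re-runs are byte-identical loads; a hash collision with a different
    config raises.
    """
    digest = config_hash(cfg)
    if cache_dir is not None:
        from pathlib import Path
        cache = Path(cache_dir) / f"trainset_{digest}.npz"
        if cache.exists():
            with np.load(cache, allow_pickle=False) as d:
                if d["digest_check"].tobytes().decode() != json.dumps(
                        cfg.to_dict(), sort_keys=True, default=str):
                    raise ValueError("trainset cache collision with different config")
                return _trainset_from_arrays(d, digest)
    bank = gabor.build_bank(cfg.gabor.orientations, cfg.gabor.frequencies,
                            cfg.gabor.sigma_per_cycle)
    grid = stimuli.make_translation_grid(cfg.stimulus.grid_n,
                                         cfg.stimulus.grid_spacing)
    per_object, poses = [], []
    for oid in range(stimuli.N_OBJECTS):
        spec = stimuli.ObjectSpec(object_id=oid)
        vecs, ps = [], []
        for view in cfg.stimulus.views:
            tile = stimuli.render_object(spec, view, cfg.stimulus.object_size)
            for off in grid:
                canvas = stimuli.place_on_canvas(tile, off, cfg.stimulus.canvas_size)
                v1 = gabor.filter_image(canvas, bank, cfg.gabor.lattice_size)
                vecs.append(v1.flat.copy())
                ps.append((view, off))
        per_object.append(vecs)
        poses.append(ps)
    ts = TrainSet(per_object=per_object, poses=poses, config_digest=digest)
    if cache_dir is not None:
        arrays = {"digest_check": np.frombuffer(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode(),
            dtype=np.uint8)}
        for o, vecs in enumerate(per_object):
            arrays[f"obj_{o}"] = np.stack(vecs)
            arrays[f"poses_{o}"] = np.array(
                [(v, dx, dy) for v, (dx, dy) in poses[o]], dtype=np.float64)
        np.savez(cache, **arrays)
    return ts


def _trainset_from_arrays(d, digest) -> TrainSet:
    per_object, poses = [], []
    o = 0
    while f"obj_{o}" in d:
        per_object.append(list(d[f"obj_{o}"]))
        poses.append([(float(v), (int(dx), int(dy)))
                      for v, dx, dy in d[f"poses_{o}"]])
        o += 1
    return TrainSet(per_object=per_object, poses=poses, config_digest=digest)


@dataclass
class PipelineResult:
    net: network.Network
    readout: info.PatternAssociator
    selected_cells: np.ndarray
    cell_info: list                   # (bits, best_object) per layer-4 cell
    tensor: info.ResponseTensor
    history: dict = field(default_factory=dict)
    config: RunConfig = None


def response_tensor(net: network.Network, trainset: TrainSet) -> info.ResponseTensor:
    """Layer-4 rates for every (object, transform), learning off."""
    S = len(trainset.per_object)
    T = trainset.n_transforms
    n4 = net.layers[3].n
    rates = np.empty((n4, S, T))
    for s in range(S):
        for t, vec in enumerate(trainset.per_object[s]):
            rates[:, s, t] = network.present(net, vec, learn=False)[3]
    return info.ResponseTensor(rates=rates)


def fit_readout(net: network.Network, trainset: TrainSet,
                cfg: RunConfig) -> tuple:
    rt = response_tensor(net, trainset)
    cell_info = info.all_cell_information(rt, cfg.readout.n_bins)
    selected = info.select_cells(cell_info, cfg.readout.per_object,
                                 n_objects=rt.n_objects)
    X = rt.rates[selected]                        # (C, S, T)
    samples = X.transpose(1, 2, 0).reshape(-1, selected.size)
    labels = np.repeat(np.arange(rt.n_objects), rt.n_transforms)
    pa = info.train_readout(samples, labels)
    return pa, selected, cell_info, rt


def train_pipeline(cfg: RunConfig, trainset: TrainSet = None,
                   train: bool = True) -> PipelineResult:
    """Initialize, (optionally) train, and fit the readout."""
    if trainset is None:
        trainset = build_trainset(cfg)
    net = network.init_network(cfg.layers, cfg.gabor.lattice_size,
                               cfg.gabor.n_channels, eta=cfg.eta,
                               seed=cfg.seed)
    history = {}
    if train:
        history = network.train_all(net, trainset.per_object, cfg.epochs)
    pa, selected, cell_info, rt = fit_readout(net, trainset, cfg)
    return PipelineResult(net=net, readout=pa, selected_cells=selected,
                          cell_info=cell_info, tensor=rt, history=history,
                          config=cfg)


def _classify_canvas(result: PipelineResult, canvas: np.ndarray,
                     bank: gabor.GaborBank) -> int:
    cfg = result.config
    v1 = gabor.filter_image(canvas, bank, cfg.gabor.lattice_size)
    y4 = network.present(result.net, v1, learn=False)[3]
    return info.classify(result.readout, y4[result.selected_cells])


# ---------------------------------------------------------------------------
# evaluation suites
# ---------------------------------------------------------------------------

def evaluate_translation_sweep(result: PipelineResult,
                               offsets=(0, 8, 16, 24, 32, 40, 48)) -> pd.DataFrame:
    """Percent correct vs horizontal offset from the grid centre.

    Trained offsets are multiples of the grid spacing inside the trained
    range; other offsets probe interpolation and extrapolation.
    """
    cfg = result.config
    bank = gabor.build_bank(cfg.gabor.orientations, cfg.gabor.frequencies,
                            cfg.gabor.sigma_per_cycle)
    spacing = cfg.stimulus.grid_spacing
    max_trained = spacing * (cfg.stimulus.grid_n // 2)
    rows = []
    for off in offsets:
        preds, truths = [], []
        for oid in range(stimuli.N_OBJECTS):
            spec = stimuli.ObjectSpec(object_id=oid)
            for view in cfg.stimulus.views:
                tile = stimuli.render_object(spec, view, cfg.stimulus.object_size)
                canvas = stimuli.place_on_canvas(tile, (off, 0),
                                                 cfg.stimulus.canvas_size)
                preds.append(_classify_canvas(result, canvas, bank))
                truths.append(oid)
        rows.append({"offset_px": off,
                     "trained": off % spacing == 0 and off <= max_trained,
                     "percent_correct": info.percent_correct(preds, truths),
                     "n": len(preds)})
    return pd.DataFrame(rows)


def evaluate_view_sweep(result: PipelineResult,
                        n_intermediate: int = 6) -> pd.DataFrame:
    """Percent correct at trained views and intermediates on plain backgrounds.

    The trained views span 270..45 deg in 45-deg steps; ``n_intermediate``
    equally spaced views are probed inside each interval.
    """
    cfg = result.config
    bank = gabor.build_bank(cfg.gabor.orientations, cfg.gabor.frequencies,
                            cfg.gabor.sigma_per_cycle)
    trained = sorted(v % 360 for v in cfg.stimulus.views)
    # walk the contiguous arc through the trained views (270 -> 45 across 0)
    arc_start = 270.0
    views = []
    for i in range(len(trained)):
        base = (arc_start + 45.0 * i) % 360.0
        views.append((base, True))
        if i < len(trained) - 1:
            for j in range(1, n_intermediate + 1):
                views.append(((base + 45.0 * j / (n_intermediate + 1)) % 360.0,
                              False))
    rows = []
    for view, is_trained in views:
        preds, truths = [], []
        for oid in range(stimuli.N_OBJECTS):
            spec = stimuli.ObjectSpec(object_id=oid)
            tile = stimuli.render_object(spec, view, cfg.stimulus.object_size)
            canvas = stimuli.place_on_canvas(tile, (0, 0), cfg.stimulus.canvas_size)
            preds.append(_classify_canvas(result, canvas, bank))
            truths.append(oid)
        rows.append({"view_deg": view, "trained": is_trained,
                     "percent_correct": info.percent_correct(preds, truths),
                     "n": len(preds)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def make_scene_set(cfg: RunConfig, n_scenes: int, seed: int) -> list:
    """Cluttered test scenes, each containing every object in one trained view."""
    rng = np.random.default_rng(seed)
    size = cfg.stimulus.scene_size
    q = size // 4
    anchors = [(q, q), (q, 3 * q), (3 * q, q), (3 * q, 3 * q)]
    scenes = []
    for i in range(n_scenes):
        order = rng.permutation(stimuli.N_OBJECTS)
        placements = []
        for oid, (ar, ac) in zip(order, anchors):
            view = cfg.stimulus.views[rng.integers(len(cfg.stimulus.views))]
            jr = int(rng.integers(-48, 49))
            jc = int(rng.integers(-48, 49))
            placements.append((int(oid), float(view), (ar + jr, ac + jc)))
        scenes.append(stimuli.compose_scene(
            int(rng.integers(2 ** 31)), placements, scene_size=size,
            object_size=cfg.stimulus.object_size,
            n_distractors=cfg.stimulus.n_distractors,
            clutter_contrast=cfg.stimulus.clutter_contrast))
    return scenes


@dataclass
class ScenePatches:
    """Saliency-derived fixation patches for a scene set (network-independent)."""

    fixations: list            # per scene: list of Fixation
    stats: list                # per scene: offset_statistics dict
    object_patches: list       # (scene_idx, object_id, v1_flat) for matched objects
    background_patches: list   # (scene_idx, fixation_rank, v1_flat)
    n_truths: int = 0


def extract_scene_patches(scenes: list, cfg: RunConfig) -> ScenePatches:
    """Saliency -> fixations -> 384-px patches -> V1 responses, per scene."""
    bank = gabor.build_bank(cfg.gabor.orientations, cfg.gabor.frequencies,
                            cfg.gabor.sigma_per_cycle)
    sal = cfg.saliency
    out = ScenePatches([], [], [], [])
    for si, scene in enumerate(scenes):
        sm = saliency.compute_saliency(scene.image, sal.scales, sal.sigma_frac)
        fxs = saliency.extract_fixations(sm, sal.k_fixations, sal.threshold_frac)
        truths = stimuli.scene_ground_truth(scene)
        stats = saliency.offset_statistics(fxs, truths, sal.match_radius)
        out.fixations.append(fxs)
        out.stats.append(stats)
        out.n_truths += len(truths)
        matched_fix = {m["fixation"] for m in stats["matches"]}
        for m in stats["matches"]:
            patch = saliency.extract_patch(scene.image, fxs[m["fixation"]],
                                           sal.patch_size)
            canvas = _embed_patch(patch, cfg.stimulus.canvas_size)
            v1 = gabor.filter_image(canvas, bank, cfg.gabor.lattice_size)
            out.object_patches.append((si, m["object_id"], v1.flat.copy()))
        for j, fx in enumerate(fxs):
            if j not in matched_fix:
                patch = saliency.extract_patch(scene.image, fx, sal.patch_size)
                canvas = _embed_patch(patch, cfg.stimulus.canvas_size)
                v1 = gabor.filter_image(canvas, bank, cfg.gabor.lattice_size)
                out.background_patches.append((si, fx.rank, v1.flat.copy()))
    return out


def _embed_patch(patch: np.ndarray, canvas_size: int) -> np.ndarray:
    """Centre the fixation patch in a mid-gray canvas at training scale."""
    canvas = np.full((canvas_size, canvas_size), stimuli.BACKGROUND, dtype=np.uint8)
    h, w = patch.shape
    r0 = (canvas_size - h) // 2
    c0 = (canvas_size - w) // 2
    canvas[r0:r0 + h, c0:c0 + w] = patch
    return canvas


def score_patches(result: PipelineResult, patches: ScenePatches) -> dict:
    """Classify fixation patches; unmatched ground-truth objects count as errors."""
    S = stimuli.N_OBJECTS
    conf = np.zeros((S, S), dtype=int)
    correct = 0
    for _, oid, vec in patches.object_patches:
        y4 = network.present(result.net, vec, learn=False)[3]
        pred = info.classify(result.readout, y4[result.selected_cells])
        conf[oid, pred] += 1
        correct += int(pred == oid)
    background_preds = []
    for si, rank, vec in patches.background_patches:
        y4 = network.present(result.net, vec, learn=False)[3]
        background_preds.append(
            {"scene": si, "rank": rank,
             "predicted": info.classify(result.readout, y4[result.selected_cells])})
    n = patches.n_truths
    misses = n - len(patches.object_patches)
    offsets = [o for st in patches.stats for o in st["offsets_px"]]
    return {
        "n_objects": n,
        "n_matched": len(patches.object_patches),
        "n_missed": misses,
        "n_correct": correct,
        "percent_correct": 100.0 * correct / n if n else float("nan"),
        "confusion": conf.tolist(),
        "background_fixations": background_preds,
        "offsets_px": offsets,
        "median_offset_px": float(np.median(offsets)) if offsets else float("nan"),
    }


def run_scene_pipeline(result: PipelineResult, scenes: list) -> dict:
    """Full dorsal+ventral loop over a scene set; embeds config provenance."""
    patches = extract_scene_patches(scenes, result.config)
    report = score_patches(result, patches)
    report["config_digest"] = config_hash(result.config)
    report["seed"] = result.config.seed
    return report
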