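"""Four-layer hierarchical competitive network with trace-rule learning.

Each layer is a square grid of neurons with sparse, topologically sampled
feedforward afferents from the layer below (layer 1 from the V1 lattice).
A forward pass per layer is: weighted-sum activation -> short-range lateral
inhibition (centre-surround filter) -> percentile-thresholded sigmoid that
fixes the active fraction.  Learning is a Hebb rule whose postsynaptic term
is an exponentially decaying trace of recent firing,

    ybar(t) = (1 - eta) * y(t) + eta * ybar(t-1),
    dw_ij   = alpha * ybar_i * x_j,

followed by L2 renormalization of each neuron's weight vector.  The trace,
reset between objects and carried across the permuted transform sequence of
one object, is what binds different transforms (views, translations) of the
same object onto the same neurons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .config import LayerConfig
from .gabor import V1Response

logger = logging.getLogger(__name__)

_COVERAGE_MIN = 0.95


@dataclass
class Layer:
    cfg: LayerConfig
    src_idx: np.ndarray          # (n_neurons, fan_in) int32 indices into the source
    weights: np.ndarray          # (n_neurons, fan_in) float64, rows unit-L2
    trace: np.ndarray            # (n_neurons,) running average of firing
    y: np.ndarray = None         # last activations

    @property
    def n(self) -> int:
        return self.cfg.grid_size ** 2


@dataclass
class Network:
    layers: list
    retina_size: int
    n_channels: int
    eta: float
    seed: int
    perm_rng: np.random.Generator = None
    presentations: int = 0


def _sample_sources(rng, n_grid: int, src_grid: int, src_channels: int,
                    fan_in: int, sigma: float) -> np.ndarray:
    """Gaussian topological sampling of afferents (with replacement)."""
    centers = (np.arange(n_grid) + 0.5) / n_grid * src_grid - 0.5
    rr, cc = np.meshgrid(centers, centers, indexing="ij")
    n = n_grid * n_grid
    r = rr.reshape(-1, 1) + rng.normal(0.0, sigma, (n, fan_in))
    c = cc.reshape(-1, 1) + rng.normal(0.0, sigma, (n, fan_in))
    r = np.clip(np.rint(r), 0, src_grid - 1).astype(np.int64)
    c = np.clip(np.rint(c), 0, src_grid - 1).astype(np.int64)
    spatial = r * src_grid + c
    if src_channels > 1:
        ch = rng.integers(0, src_channels, (n, fan_in))
        return (spatial * src_channels + ch).astype(np.int32)
    return spatial.astype(np.int32)


def receptive_coverage(net: Network) -> float:
    """Fraction of retina cells reachable from a central layer-4 neuron.

    Brute-force union of afferent chains down the hierarchy; the spatial
    (channel-collapsed) retina cells are counted.
    """
    g4 = net.layers[3].cfg.grid_size
    reach = np.array([(g4 // 2) * g4 + g4 // 2])
    for k in (3, 2, 1):
        reach = np.unique(net.layers[k].src_idx[reach].reshape(-1))
    v1 = np.unique(net.layers[0].src_idx[reach].reshape(-1))
    cells = np.unique(v1 // net.n_channels)
    return cells.size / net.retina_size ** 2


def init_network(configs, retina_size: int, n_channels: int,
                 eta: float = 0.8, seed: int = 0,
                 check_coverage: bool = True) -> Network:
    """Build connectivity and positive random unit-norm weights from a seed.

    Connectivity, weight initialization, and training permutations each draw
    from named child streams of the seed, so they are independently
    reproducible.
    """
    if len(configs) != 4:
        raise ValueError("expected exactly 4 layer configurations")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(9)
    layers = []
    for k, cfg in enumerate(configs):
        conn_rng = np.random.default_rng(children[k])
        w_rng = np.random.default_rng(children[4 + k])
        if k == 0:
            src_grid, src_ch = retina_size, n_channels
        else:
            src_grid, src_ch = configs[k - 1].grid_size, 1
        src = _sample_sources(conn_rng, cfg.grid_size, src_grid, src_ch,
                              cfg.fan_in, cfg.conn_sigma)
        w = w_rng.uniform(0.0, 1.0, src.shape)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        layers.append(Layer(cfg=cfg, src_idx=src, weights=w,
                            trace=np.zeros(cfg.grid_size ** 2)))
    net = Network(layers=layers, retina_size=retina_size, n_channels=n_channels,
                  eta=eta, seed=seed,
                  perm_rng=np.random.default_rng(children[8]))
    if check_coverage:
        cov = receptive_coverage(net)
        if cov < _COVERAGE_MIN:
            raise ValueError(
                f"layer-4 receptive-field coverage {cov:.3f} < {_COVERAGE_MIN}; "
                "increase conn_sigma")
    return net


# ---------------------------------------------------------------------------
# forward-pass primitives
# ---------------------------------------------------------------------------

def propagate(x: np.ndarray, layer: Layer) -> np.ndarray:
    """Inner-product activation over each neuron's sparse afferents."""
    return np.einsum("ij,ij->i", layer.weights, x[layer.src_idx])


_FILTER_CACHE: dict = {}


def _inhibition_filter(sigma: float, contrast: float) -> np.ndarray:
    """Centre-excitatory, surround-inhibitory contrast filter.

    Centre weight 1; the Gaussian surround carries total mass ``contrast``,
    so contrast = 1 zeroes a uniform field and contrast > 1 suppresses it.
    """
    key = (round(sigma, 9), round(contrast, 9))
    if key not in _FILTER_CACHE:
        half = max(1, int(np.ceil(3.0 * sigma)))
        y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
        surround = np.exp(-(x ** 2 + y ** 2) / (sigma ** 2))
        surround[half, half] = 0.0
        filt = -contrast * surround / surround.sum()
        filt[half, half] = 1.0
        _FILTER_CACHE[key] = filt
    return _FILTER_CACHE[key]


def lateral_inhibit(h: np.ndarray, inhib_sigma: float,
                    inhib_contrast: float) -> np.ndarray:
    """Local contrast enhancement by centre-surround filtering.

    Suppressed neurons may go negative here; the sigmoid stage maps them to
    (near-)zero firing.  Rectifying at this point instead would pile a point
    mass at zero that coincides with the percentile threshold and collapse
    the activation function to its degenerate midpoint for most of a layer.
    """
    grid = int(round(np.sqrt(h.size)))
    filt = _inhibition_filter(inhib_sigma, inhib_contrast)
    out = ndimage.convolve(h.reshape(grid, grid), filt, mode="reflect")
    return out.reshape(-1)


def apply_sigmoid_sparseness(h: np.ndarray, sparseness_percentile: float,
                             slope: float) -> np.ndarray:
    """Percentile-thresholded sigmoid fixing the active fraction.

    The threshold sits at the given quantile of the activation distribution
    across the layer, so approximately (1 - percentile) of neurons end up
    above half-activation.  An all-equal input is degenerate and maps to a
    uniform 0.5 (logged).
    """
    if h.max() == h.min():
        logger.info("degenerate all-equal activations; sigmoid output uniform 0.5")
        return np.full_like(h, 0.5)
    theta = np.quantile(h, sparseness_percentile)
    return expit(2.0 * slope * (h - theta))


def update_trace(y: np.ndarray, trace: np.ndarray, eta: float) -> np.ndarray:
    """ybar(t) = (1 - eta) y(t) + eta ybar(t-1)."""
    return (1.0 - eta) * y + eta * trace


def learn_step(layer: Layer, x: np.ndarray, alpha: float = None) -> None:
    """Trace-Hebbian update on existing synapses + per-neuron renormalization."""
    if alpha is None:
        alpha = layer.cfg.learning_rate
    if alpha == 0.0:
        return
    layer.weights += alpha * layer.trace[:, None] * x[layer.src_idx]
    norms = np.linalg.norm(layer.weights, axis=1, keepdims=True)
    np.divide(layer.weights, norms, out=layer.weights, where=norms > 0)


# ---------------------------------------------------------------------------
# full passes and training schedule
# ---------------------------------------------------------------------------

def _as_input(v1) -> np.ndarray:
    x = v1.flat if isinstance(v1, V1Response) else np.asarray(v1, dtype=np.float64).reshape(-1)
    nrm = np.linalg.norm(x)
    return x / nrm if nrm > 0 else x


def present(net: Network, v1, learn: bool = False,
            alpha_scale: float = 1.0) -> list:
    """One forward pass; optionally update traces and weights layer by layer.

    ``alpha_scale`` multiplies every layer's learning rate for this
    presentation (used by the optional within-sequence rate decay).
    """
    x = _as_input(v1)
    ys = []
    for layer in net.layers:
        if x.max() == x.min():
            # constant input carries no stimulus information; the whole layer
            # sits at the degenerate sigmoid midpoint
            y = np.full(layer.n, 0.5)
            logger.info("constant layer input; activations uniform 0.5")
        else:
            h = propagate(x, layer)
            hp = lateral_inhibit(h, layer.cfg.inhib_sigma,
                                 layer.cfg.inhib_contrast)
            y = apply_sigmoid_sparseness(hp, layer.cfg.sparseness_percentile,
                                         layer.cfg.sigmoid_slope)
        layer.y = y
        if learn:
            layer.trace = update_trace(y, layer.trace, net.eta)
            learn_step(layer, x, alpha=alpha_scale * layer.cfg.learning_rate)
        ys.append(y)
        x = y
    if learn:
        net.presentations += 1
    return ys


def reset_traces(net: Network) -> None:
    for layer in net.layers:
        layer.trace = np.zeros(layer.n)


def train_object_sequence(net: Network, transforms: list,
                          alpha_decay: float = 1.0) -> None:
    """Present all transforms of one object in a random permuted sequence.

    The trace is reset beforehand so invariance binding never crosses an
    object boundary.  ``alpha_decay`` optionally shrinks the learning rate
    geometrically across the presentations of the sequence (default: no
    decay).
    """
    if len(transforms) < 1:
        raise ValueError("need at least one transform")
    reset_traces(net)
    order = net.perm_rng.permutation(len(transforms))
    scale = 1.0
    for idx in order:
        present(net, transforms[idx], learn=True, alpha_scale=scale)
        scale *= alpha_decay


def train_all(net: Network, dataset: list, epochs: int,
              alpha_decay: float = 1.0) -> dict:
    """Run the full schedule: per epoch, each object's permuted sequence.

    ``dataset`` is a list (per object) of transform lists.  Returns a history
    dict with per-layer mean |dw| per epoch; aborts on sustained divergence.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    history = {"mean_abs_dw": []}
    growing = 0
    prev_total = None
    for _ in range(epochs):
        before = [layer.weights.copy() for layer in net.layers]
        for transforms in dataset:
            train_object_sequence(net, transforms, alpha_decay=alpha_decay)
        dws = [float(np.mean(np.abs(layer.weights - b)))
               for layer, b in zip(net.layers, before)]
        history["mean_abs_dw"].append(dws)
        total = sum(dws)
        if prev_total is not None and total > prev_total * (1 + 1e-12):
            growing += 1
            if growing >= 5:
                raise RuntimeError(
                    f"weight change grew for 5 consecutive epochs "
                    f"(last per-layer mean |dw| = {dws}); training diverging")
        else:
            growing = 0
        prev_total = total
        logger.info("epoch mean |dw| per layer: %s", dws)
    return history


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_network(net: Network, path) -> None:
    """Bit-exact checkpoint (configs, connectivity, weights, RNG state)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "retina_size": net.retina_size,
        "n_channels": net.n_channels,
        "eta": net.eta,
        "seed": net.seed,
        "presentations": net.presentations,
        "perm_state": net.perm_rng.bit_generator.state,
        "configs": [vars(layer.cfg) for layer in net.layers],
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for k, layer in enumerate(net.layers):
        arrays[f"src_{k}"] = layer.src_idx
        arrays[f"w_{k}"] = layer.weights
        arrays[f"trace_{k}"] = layer.trace
    np.savez(path, **arrays)


def load_network(path) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        layers = []
        for k, cfg_d in enumerate(meta["configs"]):
            layers.append(Layer(cfg=LayerConfig(**cfg_d),
                                src_idx=data[f"src_{k}"],
                                weights=data[f"w_{k}"],
                                trace=data[f"trace_{k}"]))
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["perm_state"]
    return Network(layers=layers, retina_size=meta["retina_size"],
                   n_channels=meta["n_channels"], eta=meta["eta"],
                   seed=meta["seed"], perm_rng=rng,
                   presentations=meta["presentations"])
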