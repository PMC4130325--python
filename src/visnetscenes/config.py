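"""Run configuration: typed parameter blocks for every stage of the model.

Two stock profiles are provided.  ``full`` matches the published scale of the
model family (128x128 neurons per layer, 5x5 training grid, 50 epochs);
``test`` is the scaled-down profile (32x32 layers, 5x5 grid, 15 epochs) that
smaller versions of this architecture are known to support, sized so a whole
train/evaluate cycle runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

TRAINED_VIEWS = (270.0, 315.0, 0.0, 45.0)


@dataclass
class GaborConfig:
    """V1 front-end: bank geometry and the retinal lattice."""

    orientations: tuple = (0.0, 45.0, 90.0, 135.0)   # degrees
    frequencies: tuple = (0.0625, 0.125, 0.25)        # cycles/pixel
    sigma_per_cycle: float = 0.4                      # envelope sigma = this / f
    lattice_size: int = 32                            # retina grid per side

    @property
    def n_channels(self) -> int:
        return len(self.orientations) * len(self.frequencies) * 2


@dataclass
class LayerConfig:
    """One competitive layer of the hierarchy."""

    grid_size: int
    fan_in: int
    conn_sigma: float            # std of Gaussian afferent sampling, source-grid units
    inhib_sigma: float           # lateral-inhibition surround radius, grid units
    inhib_contrast: float        # surround mass relative to the centre (>1 = net inhibitory)
    sparseness_percentile: float  # fraction of neurons pushed below half-activation
    sigmoid_slope: float
    learning_rate: float

    def __post_init__(self):
        if self.fan_in < 1:
            raise ValueError("fan_in must be >= 1")
        if not 0.0 < self.sparseness_percentile < 1.0:
            raise ValueError("sparseness_percentile must lie in (0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


# Per-layer learning rates chosen for weight convergence within 15-50 epochs.
LEARNING_RATES = (0.05, 0.03, 0.005, 0.005)
# Sparseness percentile / sigmoid slope pairs, canonical for this model family.
SIGMOID_PARAMS = ((0.992, 190.0), (0.98, 40.0), (0.88, 75.0), (0.91, 26.0))
INHIB_SIGMAS_32 = (1.4, 2.8, 4.5, 6.0)  # at a 32-cell grid; scaled linearly


def default_layers(grid_size: int, retina_size: int) -> list[LayerConfig]:
    scale = grid_size / 32.0
    layers = []
    for k in range(4):
        pct, slope = SIGMOID_PARAMS[k]
        layers.append(
            LayerConfig(
                grid_size=grid_size,
                fan_in=272 if k == 0 else 100,
                conn_sigma=0.25 * (retina_size if k == 0 else grid_size),
                inhib_sigma=INHIB_SIGMAS_32[k] * scale,
                inhib_contrast=1.5,
                sparseness_percentile=pct,
                sigmoid_slope=slope,
                learning_rate=LEARNING_RATES[k],
            )
        )
    return layers


@dataclass
class StimulusConfig:
    views: tuple = TRAINED_VIEWS
    grid_n: int = 5              # locations per side of the training grid
    grid_spacing: int = 16       # pixels between adjacent trained locations
    object_size: int = 256
    canvas_size: int = 512
    scene_size: int = 1024
    n_distractors: int = 2       # high-contrast background blobs per scene
    clutter_contrast: float = 6.0   # RMS gray-level contrast of the clutter field


@dataclass
class SaliencyConfig:
    scales: tuple = (32, 16)     # pyramid graph resolutions (per side)
    sigma_frac: float = 0.15     # Gaussian locality, fraction of map width
    k_fixations: int = 6
    threshold_frac: float = 0.1
    patch_size: int = 384
    match_radius: float = 64.0   # px, fixation-to-object association


@dataclass
class ReadoutConfig:
    per_object: int = 25         # most selective cells kept per object
    n_bins: int = 10             # firing-rate bins for the information measure
    cv_folds: int = 5


@dataclass
class RunConfig:
    profile: str = "test"
    seed: int = 0
    epochs: int = 15
    eta: float = 0.8             # trace decay
    n_scenes: int = 12
    gabor: GaborConfig = field(default_factory=GaborConfig)
    layers: list = field(default_factory=lambda: default_layers(32, 32))
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gabor" in d:
            d["gabor"] = GaborConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["gabor"].items()})
        if "layers" in d:
            d["layers"] = [LayerConfig(**lc) for lc in d["layers"]]
        if "stimulus" in d:
            d["stimulus"] = StimulusConfig(**{k: tuple(v) if isinstance(v, list) else v
                                              for k, v in d["stimulus"].items()})
        if "saliency" in d:
            d["saliency"] = SaliencyConfig(**{k: tuple(v) if isinstance(v, list) else v
                                              for k, v in d["saliency"].items()})
        if "readout" in d:
            d["readout"] = ReadoutConfig(**d["readout"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def test_profile(seed: int = 0) -> RunConfig:
    """Scaled-down profile: 32x32 layers, 5x5 location grid, 15 epochs.

    Layer 1 keeps roughly the same *number* of active cells as the full
    scale rather than the same active fraction: at 1024 neurons the
    full-scale percentile would leave only ~8 cells above half-activation,
    which starves the upper layers of signal.
    """
    cfg = RunConfig(profile="test", seed=seed)
    cfg.gabor = GaborConfig(lattice_size=32)
    cfg.layers = default_layers(32, cfg.gabor.lattice_size)
    cfg.layers[0].sparseness_percentile = 0.95
    cfg.layers[0].sigmoid_slope = 40.0
    cfg.stimulus = StimulusConfig(grid_n=5)
    cfg.epochs = 15
    return cfg


def full_profile(seed: int = 0) -> RunConfig:
    """Published scale: 128x128 layers (65,536 neurons), 5x5 grid, 50 epochs."""
    cfg = RunConfig(profile="full", seed=seed)
    cfg.gabor = GaborConfig(lattice_size=128,
                            frequencies=(0.0625, 0.125, 0.25, 0.5))
    cfg.layers = default_layers(128, cfg.gabor.lattice_size)
    cfg.stimulus = StimulusConfig(grid_n=5)
    cfg.saliency = SaliencyConfig(scales=(64, 32))
    cfg.epochs = 50
    return cfg
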