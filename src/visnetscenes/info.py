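"""Information measures and the pattern-associator readout.

The stimulus-specific (single-cell) information of a neuron is
``max_s I(s)`` with ``I(s) = sum_r P(r|s) log2 [P(r|s) / P(r)]`` over
equi-spaced firing-rate bins and uniform object priors; its ceiling is
log2(S) bits for S objects.  The multiple-cell measure is the mutual
information of the cross-validated confusion matrix of a nearest-class-mean
(normalized dot product) decoder.  Identity is decoded by a one-shot
Hebbian pattern associator with one output neuron per object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ResponseTensor:
    """Firing rates indexed (cell, object, transform)."""

    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=np.float64)
        if r.ndim != 3:
            raise ValueError("rates must be (cell, object, transform)")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("rates must be finite and nonnegative")
        self.rates = r

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_objects(self) -> int:
        return self.rates.shape[1]

    @property
    def n_transforms(self) -> int:
        return self.rates.shape[2]


def single_cell_information(rt: ResponseTensor, cell: int,
                            n_bins: int = 10) -> tuple[float, int]:
    """Stimulus-specific information (bits) and the most effective object."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if rt.n_transforms < 2:
        raise ValueError("need >= 2 transforms per object")
    rates = rt.rates[cell]                     # (S, T)
    S, T = rates.shape
    lo, hi = rates.min(), rates.max()
    if hi == lo:
        return 0.0, 0
    bins = np.clip(((rates - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    p_r_given_s = np.zeros((S, n_bins))
    for s in range(S):
        p_r_given_s[s] = np.bincount(bins[s], minlength=n_bins) / T
    p_r = p_r_given_s.mean(axis=0)             # uniform priors
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_r_given_s > 0, p_r_given_s / p_r, 1.0)
        info_s = np.sum(p_r_given_s * np.log2(ratio), axis=1)
    best = int(np.argmax(info_s))
    return float(info_s[best]), best


def all_cell_information(rt: ResponseTensor, n_bins: int = 10) -> list[tuple]:
    return [single_cell_information(rt, c, n_bins) for c in range(rt.n_cells)]


def _confusion_mutual_information(conf: np.ndarray) -> float:
    """MI in bits of a joint (true, decoded) count/probability matrix."""
    p = conf / conf.sum()
    ps = p.sum(axis=1, keepdims=True)
    pd = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (ps * pd)), 0.0)
    return float(terms.sum())


def multiple_cell_information(rt: ResponseTensor, cell_subset,
                              cv_folds: int = 5) -> float:
    """Cross-validated decoding information of a cell population (bits)."""
    cells = np.asarray(list(cell_subset), dtype=int)
    if cells.size < 1:
        raise ValueError("cell_subset must be non-empty")
    T = rt.n_transforms
    if not 2 <= cv_folds <= T:
        raise ValueError("need T >= cv_folds >= 2")
    S = rt.n_objects
    X = rt.rates[cells]                         # (C, S, T)
    folds = np.array_split(np.arange(T), cv_folds)
    conf = np.zeros((S, S))
    for held in folds:
        if held.size == 0:
            raise ValueError("fold with a missing class")
        train_mask = np.ones(T, dtype=bool)
        train_mask[held] = False
        means = X[:, :, train_mask].mean(axis=2)        # (C, S)
        mn = np.linalg.norm(means, axis=0, keepdims=True)
        means_n = np.divide(means, mn, where=mn > 0, out=np.zeros_like(means))
        for s in range(S):
            for t in held:
                v = X[:, s, t]
                nv = np.linalg.norm(v)
                vh = v / nv if nv > 0 else v
                decoded = int(np.argmax(vh @ means_n))
                conf[s, decoded] += 1
    return _confusion_mutual_information(conf)


def select_cells(info_results: list, per_object: int,
                 n_objects: int = 4) -> np.ndarray:
    """Most selective cells per object by stimulus-specific information.

    For each object, the ``per_object`` highest-information cells whose best
    object is that object; ties broken by cell index.  Returns the union.
    """
    chosen = []
    for s in range(n_objects):
        pool = [(bits, c) for c, (bits, best) in enumerate(info_results)
                if best == s]
        pool.sort(key=lambda bc: (-bc[0], bc[1]))
        if len(pool) < per_object:
            logger.warning("only %d cells prefer object %d (wanted %d)",
                           len(pool), s, per_object)
        chosen.extend(c for _, c in pool[:per_object])
    return np.array(sorted(set(chosen)), dtype=int)


@dataclass
class PatternAssociator:
    """One-shot Hebbian mapping from selected cells to S output neurons."""

    weights: np.ndarray        # (S, n_cells)

    @property
    def n_objects(self) -> int:
        return self.weights.shape[0]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def train_readout(rates: np.ndarray, labels) -> PatternAssociator:
    """Hebbian batch: accumulate unit-normalized input vectors per object.

    ``rates`` is (n_samples, n_cells); ``labels`` the object id per sample.
    """
    labels = np.asarray(labels, dtype=int)
    S = labels.max() + 1
    W = np.zeros((S, rates.shape[1]))
    if not np.any(rates):
        logger.warning("all-zero readout inputs; associator is undecidable")
    for x, lab in zip(rates, labels):
        W[lab] += _unit(np.asarray(x, dtype=np.float64))
    # synaptic scaling: each output neuron's weight vector is normalized so
    # the output competition compares pattern match, not accumulated mass
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    W = np.divide(W, norms, where=norms > 0, out=W)
    return PatternAssociator(weights=W)


def classify(pa: PatternAssociator, response: np.ndarray) -> int:
    """Argmax over output activations; ties go to the lowest object id."""
    act = pa.weights @ _unit(np.asarray(response, dtype=np.float64))
    top = act.max()
    if np.sum(act == top) > 1:
        logger.warning("classification tie; returning lowest object id")
    return int(np.argmax(act))


def percent_correct(predictions, truth) -> float:
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    return 100.0 * float(np.mean(predictions == truth))
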