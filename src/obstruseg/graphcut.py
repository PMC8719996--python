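"""Graph-cut segmentation: map an image plus per-pixel foreground
probabilities onto a source/sink flow network and split it with the
max-flow/min-cut theorem.

Terminal capacities are negative log-likelihoods of the clamped
probabilities (the sink link of a pixel carries -ln p_fg, the source link
-ln(1 - p_fg)); neighbor links on the 4-connected lattice carry
lambda_ * exp(-(I_p - I_q)^2 / (2 sigma_^2)), symmetric.  The cut is found
exactly: capacities are scaled to integers and handed to
scipy.sparse.csgraph.maximum_flow, and the partition is residual-graph
reachability from the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .images import GrayImage, LabelMask
from .util import ValidationError

__all__ = ["FlowNetwork", "CutResult", "build_flow_network", "max_flow", "graphcut_refine"]

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-6
_SCALE = 2**20  # fixed-point factor for exact integer max-flow


@dataclass(frozen=True)
class FlowNetwork:
    """Capacitated digraph; node n_nodes-2 is the source, n_nodes-1 the sink
    (pixels, if any, occupy nodes 0..H*W-1 in row-major order)."""

    n_nodes: int
    source: int
    sink: int
    capacity: csr_matrix  # float capacities
    shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.capacity.shape != (self.n_nodes, self.n_nodes):
            raise ValidationError("capacity matrix shape mismatch")
        if self.capacity.nnz and self.capacity.data.min() < 0:
            raise ValidationError("negative capacity")


@dataclass(frozen=True)
class CutResult:
    max_flow_value: float
    source_side: np.ndarray  # bool per node (terminals included)
    shape: tuple[int, int] | None = None

    @property
    def pixel_source_side(self) -> np.ndarray:
        if self.shape is None:
            raise ValidationError("network carries no image shape")
        h, w = self.shape
        return self.source_side[: h * w].reshape(h, w)


def network_from_edges(n_nodes: int, source: int, sink: int, edges) -> FlowNetwork:
    """Build a FlowNetwork from (u, v, capacity) triples (testing/CLI aid)."""
    rows, cols, caps = [], [], []
    for u, v, c in edges:
        rows.append(u)
        cols.append(v)
        caps.append(float(c))
    cap = csr_matrix((caps, (rows, cols)), shape=(n_nodes, n_nodes))
    return FlowNetwork(n_nodes=n_nodes, source=source, sink=sink, capacity=cap)


def build_flow_network(
    image: GrayImage, fg_prob: np.ndarray, lambda_: float = 1.0, sigma_: float = 0.1
) -> FlowNetwork:
    """Image + foreground-probability map -> s/t flow network."""
    p = np.asarray(fg_prob, dtype=np.float64)
    if p.shape != image.shape:
        raise ValidationError(f"fg_prob shape {p.shape} != image shape {image.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    if lambda_ < 0:
        raise ValidationError("lambda_ must be >= 0")
    if sigma_ <= 0:
        raise ValidationError("sigma_ must be > 0")

    h, w = image.shape
    n_px = h * w
    source, sink = n_px, n_px + 1
    idx = np.arange(n_px).reshape(h, w)
    pc = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)

    rows, cols, caps = [], [], []
    # terminal links: source->pixel carries -ln(1-p), pixel->sink carries -ln(p)
    rows.append(np.full(n_px, source))
    cols.append(idx.ravel())
    caps.append(-np.log(1.0 - pc).ravel())
    rows.append(idx.ravel())
    cols.append(np.full(n_px, sink))
    caps.append(-np.log(pc).ravel())

    I = image.pixels
    if lambda_ > 0:
        # 4-neighborhood, symmetric
        for (a, b) in (
            (idx[:-1, :], idx[1:, :]),
            (idx[:, :-1], idx[:, 1:]),
        ):
            ia = I.ravel()[a.ravel()]
            ib = I.ravel()[b.ravel()]
            cap = lambda_ * np.exp(-((ia - ib) ** 2) / (2.0 * sigma_**2))
            rows.extend([a.ravel(), b.ravel()])
            cols.extend([b.ravel(), a.ravel()])
            caps.extend([cap, cap])

    cap = csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_px + 2, n_px + 2),
    )
    return FlowNetwork(n_nodes=n_px + 2, source=source, sink=sink, capacity=cap, shape=(h, w))


def max_flow(net: FlowNetwork) -> CutResult:
    """Exact maximum flow and the corresponding minimum-cut partition.

    Capacities are converted to fixed-point integers (factor 2**20), so
    integer-valued inputs are handled exactly; the flow value is returned on
    the original scale.
    """
    cap_int = net.capacity.copy()
    cap_int.data = np.round(cap_int.data * _SCALE)
    cap_int = cap_int.astype(np.int64)
    res = maximum_flow(cap_int, net.source, net.sink)
    # res.flow carries negative reverse entries, so this is the full residual
    residual = (cap_int - res.flow).tocsr()
    residual.eliminate_zeros()
    order = breadth_first_order(
        residual, net.source, directed=True, return_predecessors=False
    )
    side = np.zeros(net.n_nodes, dtype=bool)
    side[order] = True
    if side[net.sink]:
        raise RuntimeError("sink reachable in residual graph after max flow")
    return CutResult(
        max_flow_value=float(res.flow_value) / _SCALE,
        source_side=side,
        shape=net.shape,
    )


def cut_capacity(net: FlowNetwork, source_side: np.ndarray) -> float:
    """Total capacity crossing from the source side to the sink side."""
    coo = net.capacity.tocoo()
    mask = source_side[coo.row] & ~source_side[coo.col]
    return float(coo.data[mask].sum())


def graphcut_refine(
    image: GrayImage,
    class_probs: np.ndarray,
    lambda_: float = 1.0,
    sigma_: float = 0.1,
) -> LabelMask:
    """Refine a per-pixel K-class probability map with min-cut smoothing.

    K = 2 runs a single cut on the class-1 probability.  K > 2 runs
    one-vs-rest cuts in class order 0..K-1; a pixel takes the first class
    whose cut puts it on the source (foreground) side, with an argmax
    fallback for pixels never claimed.
    """
    probs = np.asarray(class_probs, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[:2] != image.shape:
        raise ValidationError("class_probs must be (H, W, K) matching the image")
    K = probs.shape[2]
    if K < 2:
        raise ValidationError("need at least 2 classes")
    sums = probs.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        logger.warning("class probabilities do not sum to 1; renormalizing")
        probs = probs / np.clip(sums[:, :, None], 1e-12, None)

    if K == 2:
        net = build_flow_network(image, probs[:, :, 1], lambda_, sigma_)
        fg = max_flow(net).pixel_source_side
        return LabelMask(fg.astype(np.int64))

    h, w = image.shape
    labels = np.full((h, w), -1, dtype=np.int64)
    for c in range(K):
        net = build_flow_network(image, probs[:, :, c], lambda_, sigma_)
        fg = max_flow(net).pixel_source_side
        claim = fg & (labels < 0)
        labels[claim] = c
    fallback = labels < 0
    if np.any(fallback):
        labels[fallback] = np.argmax(probs, axis=2)[fallback]
    return LabelMask(labels)
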