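"""Distance-threshold hypergraph construction and residual hypergraph
convolution over multi-scale grid features.

A hypergraph G = (V, E) generalises a graph by letting a hyperedge connect
any number of vertices; it is encoded by a binary incidence matrix
H (|V| x |E|) with H[v, e] = 1 iff vertex v belongs to hyperedge e. Here
every position of a common feature grid is a vertex, its feature vector is
the channel-wise concatenation of five pyramid stages resampled to that
grid, and one hyperedge is anchored at each vertex v:

    e_v = { u : ||x_u - x_v||_2 < lambda }

(strict inequality, so the anchor always belongs to its own hyperedge and
|E| = |V|, duplicates retained). Convolution is two-stage message passing
with a residual term — vertex features are averaged into hyperedge
features through a shared learnable matrix Theta, then averaged back:

    HyperConv(X, H) = X + Dv^-1 H De^-1 H^T X Theta

where Dv, De are the diagonal vertex/hyperedge degree matrices. Zero
degrees are treated by the pseudo-inverse convention (a degree-0 vertex
receives no aggregated term and passes through the residual unchanged).

Two equivalent implementations are provided: an explicit per-hyperedge
"spatial" form and the normalised-matrix form above; tests hold them to
agreement. :class:`HypergraphNeck` wraps the same computation as a
differentiable layer, rebuilding the hypergraph from the current features
on every forward pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor, concat, resize_bilinear
from .layers import ConvBNAct, Module, DTYPE

__all__ = [
    "PyramidFeatures", "HybridFeature", "VertexSet", "IncidenceMatrix",
    "HyperConvParams", "build_vertex_set", "construct_hyperedges",
    "hyperconv_spatial", "hyperconv_matrix", "HypergraphNeck",
]

DEFAULT_LAMBDA = 8.0  # operating point of the distance threshold


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PyramidFeatures:
    """Ordered multi-scale feature maps F1..F5 from backbone stages P3..P7.

    Each map has shape (C_i, H_i, W_i); spatial sizes must be monotonically
    non-increasing from the shallowest to the deepest stage.
    """
    maps: list
    stage_labels: tuple = ("P3", "P4", "P5", "P6", "P7")

    def __post_init__(self):
        if len(self.maps) != 5:
            raise ValueError(
                f"a feature pyramid has exactly 5 maps, got {len(self.maps)}")
        self.maps = [np.asarray(m) for m in self.maps]
        prev = None
        for m in self.maps:
            if m.ndim != 3 or min(m.shape) < 1:
                raise ValueError(f"each map must be (C,H,W) with dims >= 1, "
                                 f"got {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError("feature maps must be finite")
            hw = m.shape[1:]
            if prev is not None and (hw[0] > prev[0] or hw[1] > prev[1]):
                raise ValueError("spatial sizes must be non-increasing "
                                 "across the pyramid")
            prev = hw

    @property
    def channels(self):
        return [m.shape[0] for m in self.maps]


@dataclass
class HybridFeature:
    """Concatenated multi-scale features on a common grid.

    X_m has shape (N, C_m) with N = H_c * W_c rows in row-major grid order
    and C_m the sum of the five stage channel counts.
    """
    X_m: np.ndarray
    grid_shape: tuple
    C_m: int


@dataclass
class VertexSet:
    """N vertex feature vectors as the rows of an (N, D) matrix."""
    X: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValueError("vertex features must be a non-empty (N, D) matrix")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("vertex features must be finite")

    @property
    def N(self):
        return self.X.shape[0]


@dataclass
class IncidenceMatrix:
    """Binary |V| x |E| incidence matrix with cached degree vectors."""
    H: np.ndarray
    Dv: np.ndarray = field(init=False)
    De: np.ndarray = field(init=False)

    def __post_init__(self):
        self.H = np.asarray(self.H)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D")
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("H must be binary")
        self.Dv = self.H.sum(axis=1)
        self.De = self.H.sum(axis=0)


@dataclass
class HyperConvParams:
    """Shared transform Theta (D_in x D_out) and distance threshold lambda.

    The residual form requires D_in == D_out; lambda must be positive
    (the strict inequality makes lambda = 0 produce empty hyperedges)."""
    Theta: np.ndarray
    lambda_thresh: float = DEFAULT_LAMBDA

    def __post_init__(self):
        self.Theta = np.asarray(self.Theta)
        if self.Theta.ndim != 2:
            raise ValueError("Theta must be 2-D")
        if self.Theta.shape[0] != self.Theta.shape[1]:
            raise ValueError("residual hyperconvolution needs a square Theta "
                             f"(got {self.Theta.shape})")
        if not self.lambda_thresh > 0:
            raise ValueError("lambda_thresh must be > 0")


# --------------------------------------------------------------------------
# operations (pure numpy)
# --------------------------------------------------------------------------

def _resample_map(m: np.ndarray, out_hw) -> np.ndarray:
    """Bilinear-resample a (C,H,W) map to out_hw (half-pixel convention)."""
    from .autodiff import _interp_matrix
    H, W = m.shape[1:]
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return m
    Ah = _interp_matrix(H, Ho)
    Aw = _interp_matrix(W, Wo)
    return Ah @ m @ Aw.T


def build_vertex_set(pyramid: PyramidFeatures, common_grid) -> HybridFeature:
    """Resample all five maps to a common grid and concatenate channels.

    Returns the hybrid feature X_m of shape (H_c*W_c, sum C_i); each grid
    position is one hypergraph vertex, rows in row-major order.
    """
    Hc, Wc = int(common_grid[0]), int(common_grid[1])
    if Hc < 1 or Wc < 1:
        raise ValueError("common grid dims must be >= 1")
    res = [_resample_map(m, (Hc, Wc)) for m in pyramid.maps]
    stacked = np.concatenate(res, axis=0)          # (C_m, Hc, Wc)
    C_m = stacked.shape[0]
    X_m = stacked.reshape(C_m, Hc * Wc).T          # row-major grid order
    return HybridFeature(X_m=X_m, grid_shape=(Hc, Wc), C_m=C_m)


def construct_hyperedges(vertices: VertexSet,
                         lambda_thresh: float) -> IncidenceMatrix:
    """One hyperedge per anchor vertex: e_v = {u : ||x_u - x_v||_2 < lambda}.

    Column v of the returned incidence matrix encodes e_v. Strict
    inequality keeps the anchor in its own hyperedge for any lambda > 0;
    duplicate hyperedges are retained so |E| = |V|.
    """
    if not lambda_thresh > 0:
        raise ValueError("lambda_thresh must be > 0")
    X = vertices.X.astype(np.float64, copy=False)
    D = cdist(X, X, metric="euclidean")
    H = (D < lambda_thresh).astype(np.int64)
    return IncidenceMatrix(H=H)


def hyperconv_spatial(vertices: VertexSet, inc: IncidenceMatrix,
                      params: HyperConvParams) -> VertexSet:
    """Explicit two-stage aggregation with residual.

    Stage 1: X_e = mean over v in e of X_v Theta (empty hyperedges
    contribute nothing). Stage 2: X'_v = X_v + mean over hyperedges e
    containing v of X_e (degree-0 vertices keep the pure residual).
    """
    X = vertices.X
    H = inc.H
    N, D = X.shape
    if params.Theta.shape[0] != D:
        raise ValueError("Theta rows must match vertex feature dimension")
    if H.shape[0] != N:
        raise ValueError("incidence matrix rows must match vertex count")
    XT = X @ params.Theta
    E = H.shape[1]
    Xe = np.zeros((E, XT.shape[1]), dtype=XT.dtype)
    for e in range(E):
        members = np.flatnonzero(H[:, e])
        if members.size:
            Xe[e] = XT[members].mean(axis=0)
    out = X.astype(Xe.dtype).copy()
    for v in range(N):
        edges = np.flatnonzero(H[v])
        if edges.size:
            out[v] += Xe[edges].mean(axis=0)
    return VertexSet(X=out)


def _norm_adjacency(inc: IncidenceMatrix) -> np.ndarray:
    """Dv^-1 H De^-1 H^T with pseudo-inverted (zero-masked) degrees."""
    H = inc.H.astype(np.float64)
    dv = np.where(inc.Dv > 0, 1.0 / np.maximum(inc.Dv, 1), 0.0)
    de = np.where(inc.De > 0, 1.0 / np.maximum(inc.De, 1), 0.0)
    return (dv[:, None] * H) @ (de[:, None] * H.T)


def hyperconv_matrix(vertices: VertexSet, inc: IncidenceMatrix,
                     params: HyperConvParams) -> VertexSet:
    """Matrix form: X + Dv^-1 H De^-1 H^T X Theta."""
    X = vertices.X
    if inc.H.shape[0] != X.shape[0]:
        raise ValueError("incidence matrix rows must match vertex count")
    if params.Theta.shape[0] != X.shape[1]:
        raise ValueError("Theta rows must match vertex feature dimension")
    A = _norm_adjacency(inc)
    return VertexSet(X=X + A @ X @ params.Theta)


# --------------------------------------------------------------------------
# differentiable neck layer
# --------------------------------------------------------------------------

class HypergraphConvLayer(Module):
    """One residual hypergraph convolution with a learnable shared Theta.

    The incidence structure is recomputed from the current (detached)
    features at every call; gradients flow through the aggregation, not
    through the discrete hyperedge construction."""

    def __init__(self, rng, dim, lambda_thresh=DEFAULT_LAMBDA):
        super().__init__()
        self.lambda_thresh = float(lambda_thresh)
        # zero-init: the layer starts as the identity (pure residual) and
        # learns how much aggregated context to inject — stabilises early
        # training the same way the zero-init deformable offsets do
        self.Theta = Tensor(np.zeros((dim, dim), dtype=DTYPE),
                            requires_grad=True)
        del rng

    def forward(self, X: Tensor) -> Tensor:
        inc = construct_hyperedges(VertexSet(X.data), self.lambda_thresh)
        A = Tensor(_norm_adjacency(inc).astype(DTYPE))
        return X + (A @ X) @ self.Theta


class HypergraphNeck(Module):
    """Hypergraph neck over a 5-stage feature pyramid.

    Resamples the five stage maps to a common grid, runs residual
    hypergraph convolutions on the flattened vertices (per image — the
    hypergraph is image-specific), reshapes the result back to the grid and
    redistributes it to the three head scales through bilinear resizing and
    a per-scale 1x1 projection.
    """

    def __init__(self, rng, stage_channels, head_channels,
                 lambda_thresh=DEFAULT_LAMBDA, n_layers=1,
                 common_grid="middle"):
        super().__init__()
        self.common_grid = common_grid
        c_m = int(sum(stage_channels))
        self.c_m = c_m
        self.layers = [HypergraphConvLayer(rng, c_m, lambda_thresh)
                       for _ in range(n_layers)]
        self.heads = [ConvBNAct(rng, c_m, ch, k=1) for ch in head_channels]

    def _grid(self, maps):
        if self.common_grid == "middle":
            return maps[len(maps) // 2].shape[-2:]
        return tuple(self.common_grid)

    def forward(self, maps):
        """maps: list of 5 NCHW tensors -> list of per-scale neck outputs
        matching the first three (head) scales."""
        if len(maps) != 5:
            raise ValueError("hypergraph neck expects a 5-map pyramid")
        Hc, Wc = self._grid(maps)
        hybrid = concat([resize_bilinear(m, (Hc, Wc)) for m in maps], axis=1)
        B = hybrid.shape[0]
        outs = []
        for b in range(B):
            X = hybrid[b].reshape(self.c_m, Hc * Wc).T   # (N, C_m)
            for layer in self.layers:
                X = layer(X)
            outs.append(X.T.reshape(1, self.c_m, Hc, Wc))
        grid = concat(outs, axis=0) if B > 1 else outs[0]
        results = []
        for head, m in zip(self.heads, maps[:len(self.heads)]):
            results.append(head(resize_bilinear(grid, m.shape[-2:])))
        return results
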