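"""Graph representation learners for pathway hypergraphs.

Four models map an attributed hypergraph (X, H) to node embeddings Z:

* ``hgnn`` — spectral hypergraph convolution,
  Z(l+1) = sigma( Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2} Z(l) Theta(l) )
* ``hgnn_plus`` — two-stage spatial hypergraph convolution,
  Z(l+1) = sigma( Dv^{-1} H W De^{-1} H^T Z(l) Theta(l) )
* ``gcn`` — ordinary graph convolution on the clique expansion A = H H^T,
  Z(l+1) = sigma( D^{-1/2} A D^{-1/2} Z(l) W(l) )
* ``mf`` — biased matrix factorisation of the incidence matrix,
  Hhat = mu + b_z 1^T + 1 b_r^T + Z R^T

Layers are bias-free; the elementwise nonlinearity (default: rectifier) is
applied after every layer except the last, whose output is linear.  Zero
degrees use a pseudo-inverse convention (1/0 -> 0) so isolated nodes produce
zero embedding rows instead of NaNs.  The diagonal hyperedge-weight matrix W
of the hypergraph models is stored as log-weights ``rho`` (W = diag(exp rho),
initialised at identity) so that trained weights stay positive.

Everything here is plain numpy; gradients for training are the hand-derived
adjoints of these same matrix products (see ``backward_layers``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PathwayNetwork

MODEL_KINDS = ("hgnn", "hgnn_plus", "gcn", "mf")
LAYER_MODEL_KINDS = ("hgnn", "hgnn_plus", "gcn")


def _pinv(x: np.ndarray) -> np.ndarray:
    """Elementwise 1/x with the 1/0 -> 0 pseudo-inverse convention."""
    out = np.zeros_like(x, dtype=np.float64)
    nz = x != 0
    out[nz] = 1.0 / x[nz]
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {"relu": relu, "identity": lambda x: x}


@dataclass
class LayerParams:
    """Parameters of the three layer models.

    ``theta_per_layer`` are the feature extractors (first layer |F|xD, then
    DxD); ``rho`` are log hyperedge weights (length |E|, all zero =>
    W = I); ``gcn`` ignores ``rho``.  ``activation`` names the hidden-layer
    nonlinearity.
    """

    kind: str
    theta_per_layer: list[np.ndarray]
    rho: np.ndarray
    n_layers: int
    activation: str = "relu"

    @property
    def edge_weights(self) -> np.ndarray:
        return np.exp(self.rho)

    def copy(self) -> "LayerParams":
        return LayerParams(
            kind=self.kind,
            theta_per_layer=[t.copy() for t in self.theta_per_layer],
            rho=self.rho.copy(),
            n_layers=self.n_layers,
            activation=self.activation,
        )


@dataclass
class MFParams:
    """Biased matrix-factorisation parameters.

    ``mu`` is the global average rating (set from the training incidence
    density before optimisation, not trained); ``b_z``/``b_r`` are node and
    hyperedge biases; ``Z``/``R`` the latent factors.  The all-ones matrices
    of the model statement are implied by broadcasting and never stored.
    """

    mu: float
    b_z: np.ndarray
    b_r: np.ndarray
    Z: np.ndarray
    R: np.ndarray

    def copy(self) -> "MFParams":
        return MFParams(self.mu, self.b_z.copy(), self.b_r.copy(),
                        self.Z.copy(), self.R.copy())


def init_params(
    kind: str,
    n_entities: int,
    n_reactions: int,
    n_attributes: int,
    embedding_dim: int,
    n_layers: int = 2,
    seed: int = 0,
    activation: str = "relu",
):
    """Seeded parameter initialisation.

    Layer weights use a symmetric scaled-uniform (Glorot) draw; hyperedge
    log-weights start at 0 (W = I); MF factors are small-random with zero
    biases and ``mu = 0`` until set from data.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind: {kind!r}")
    for name, val in (("n_entities", n_entities), ("n_reactions", n_reactions),
                      ("embedding_dim", embedding_dim), ("n_layers", n_layers)):
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    rng = np.random.default_rng(seed)
    if kind == "mf":
        return MFParams(
            mu=0.0,
            b_z=np.zeros(n_entities),
            b_r=np.zeros(n_reactions),
            Z=rng.normal(0.0, 0.05, size=(n_entities, embedding_dim)),
            R=rng.normal(0.0, 0.05, size=(n_reactions, embedding_dim)),
        )
    # an attribute-free network gets a zero-width first layer (Z stays 0)
    widths = [n_attributes] + [embedding_dim] * n_layers
    thetas = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        thetas.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
    return LayerParams(
        kind=kind,
        theta_per_layer=thetas,
        rho=np.zeros(n_reactions),
        n_layers=n_layers,
        activation=activation,
    )


# ---------------------------------------------------------------------------
# propagation operators
# ---------------------------------------------------------------------------

@dataclass
class Propagation:
    """A node-to-node propagation matrix P plus the factors needed for the
    hyperedge-weight gradient (P = left @ diag(w) @ right for the hypergraph
    models; ``left``/``right`` are None for GCN, whose P has no edge
    weights)."""

    P: np.ndarray
    left: np.ndarray | None = None
    right: np.ndarray | None = None


def propagation(network: PathwayNetwork, kind: str,
                edge_weights: np.ndarray | None = None) -> Propagation:
    """Build the model's propagation matrix from the network's incidence."""
    H = np.asarray(network.H.todense(), dtype=np.float64)
    if kind == "gcn":
        A = H @ H.T
        d = A.sum(axis=1)
        dinv = np.sqrt(_pinv(d))
        P = dinv[:, None] * A * dinv[None, :]
        return Propagation(P=P)
    d_v = H.sum(axis=1)
    d_e = H.sum(axis=0)
    if kind == "hgnn":
        dv_half = np.sqrt(_pinv(d_v))
        left = dv_half[:, None] * H
        right = _pinv(d_e)[:, None] * H.T * dv_half[None, :]
    elif kind == "hgnn_plus":
        left = _pinv(d_v)[:, None] * H
        right = _pinv(d_e)[:, None] * H.T
    else:
        raise ValueError(f"unknown layer model kind: {kind!r}")
    w = np.ones(network.n_reactions) if edge_weights is None else edge_weights
    P = (left * w[None, :]) @ right
    return Propagation(P=P, left=left, right=right)


@dataclass
class LayerCache:
    """Intermediates of a layered forward pass, for backpropagation."""

    inputs: list[np.ndarray] = field(default_factory=list)   # Z(l) per layer
    pre_act: list[np.ndarray] = field(default_factory=list)  # P Z(l) Theta(l)


def forward_layers(P: np.ndarray, X: np.ndarray, params: LayerParams,
                   cache: LayerCache | None = None) -> np.ndarray:
    """Run the layer stack: hidden layers activated, final layer linear."""
    act = _ACTIVATIONS[params.activation]
    Z = np.asarray(X, dtype=np.float64)
    n_layers = len(params.theta_per_layer)
    for l, theta in enumerate(params.theta_per_layer):
        if cache is not None:
            cache.inputs.append(Z)
        pre = P @ Z @ theta
        if cache is not None:
            cache.pre_act.append(pre)
        Z = pre if l == n_layers - 1 else act(pre)
    return Z


def backward_layers(P: np.ndarray, params: LayerParams, cache: LayerCache,
                    dZ: np.ndarray, need_dP: bool = False):
    """Adjoint of :func:`forward_layers`.

    Given dLoss/dZ_final, returns per-layer Theta gradients and, if
    ``need_dP``, the gradient with respect to the propagation matrix (used
    for the hyperedge-weight gradient).  Only the rectifier and identity
    activations are supported, matching the forward pass.
    """
    n_layers = len(params.theta_per_layer)
    d_thetas: list[np.ndarray | None] = [None] * n_layers
    dP = np.zeros_like(P) if need_dP else None
    for l in range(n_layers - 1, -1, -1):
        pre = cache.pre_act[l]
        if l == n_layers - 1 or params.activation == "identity":
            d_pre = dZ
        else:  # relu
            d_pre = dZ * (pre > 0)
        Z_in = cache.inputs[l]
        PZ = P @ Z_in
        d_thetas[l] = PZ.T @ d_pre
        if need_dP:
            dP += d_pre @ (Z_in @ params.theta_per_layer[l]).T
        dZ = P.T @ d_pre @ params.theta_per_layer[l].T
    return d_thetas, dP


def edge_weight_grad(prop: Propagation, dP: np.ndarray,
                     rho: np.ndarray) -> np.ndarray:
    """Gradient of the loss w.r.t. the log hyperedge weights rho.

    P = left @ diag(exp rho) @ right, so dL/dw_e = (left^T dP right^T)_{ee}
    and the chain rule through w = exp(rho) multiplies by w.
    """
    diag = np.einsum("ve,vu,eu->e", prop.left, dP, prop.right, optimize=True)
    return diag * np.exp(rho)


# ---------------------------------------------------------------------------
# public forward passes
# ---------------------------------------------------------------------------

def _layer_forward(network: PathwayNetwork, params: LayerParams,
                   kind: str) -> np.ndarray:
    if params.kind != kind:
        raise ValueError(f"params are for {params.kind!r}, not {kind!r}")
    X = np.asarray(network.X.todense(), dtype=np.float64)
    if X.shape[1] != params.theta_per_layer[0].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match first-layer Theta "
            f"{params.theta_per_layer[0].shape}"
        )
    prop = propagation(network, kind,
                       None if kind == "gcn" else params.edge_weights)
    return forward_layers(prop.P, X, params)


def hgnn_forward(network: PathwayNetwork, params: LayerParams) -> np.ndarray:
    """Spectral hypergraph convolution; returns the final-layer Z (|V|xD)."""
    return _layer_forward(network, params, "hgnn")


def hgnn_plus_forward(network: PathwayNetwork, params: LayerParams) -> np.ndarray:
    """Two-stage spatial hypergraph convolution; returns the final Z."""
    return _layer_forward(network, params, "hgnn_plus")


def gcn_forward(network: PathwayNetwork, params: LayerParams) -> np.ndarray:
    """Graph convolution on the clique expansion; returns the final Z."""
    return _layer_forward(network, params, "gcn")


def forward(network: PathwayNetwork, params) -> np.ndarray:
    """Dispatch on parameter kind; for MF returns the node factor Z."""
    if isinstance(params, MFParams):
        return params.Z
    return _layer_forward(network, params, params.kind)


def mf_predict(params: MFParams) -> np.ndarray:
    """Raw predicted incidence matrix Hhat (|V|x|E|), before any squashing."""
    return (params.mu
            + params.b_z[:, None]
            + params.b_r[None, :]
            + params.Z @ params.R.T)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam on a dict of named numpy arrays.

    ``step`` applies a full update; ``lazy_step`` updates only the given row
    indices of a parameter (with the shared global step counter for the bias
    correction), which keeps entry-minibatch MF training cheap.
    """

    def __init__(self, shapes: dict[str, tuple], lr: float = 5e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def begin_step(self):
        self.t += 1

    def _corrected(self, m, v):
        mhat = m / (1.0 - self.beta1 ** self.t)
        vhat = v / (1.0 - self.beta2 ** self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def update(self, name: str, param: np.ndarray, grad: np.ndarray):
        m, v = self.m[name], self.v[name]
        m *= self.beta1
        m += (1.0 - self.beta1) * grad
        v *= self.beta2
        v += (1.0 - self.beta2) * grad * grad
        param -= self._corrected(m, v)

    def lazy_update(self, name: str, param: np.ndarray, rows: np.ndarray,
                    grad_rows: np.ndarray):
        m, v = self.m[name], self.v[name]
        m[rows] = self.beta1 * m[rows] + (1.0 - self.beta1) * grad_rows
        v[rows] = self.beta2 * v[rows] + (1.0 - self.beta2) * grad_rows ** 2
        param[rows] -= self._corrected(m[rows], v[rows])
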