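"""Scikit-learn style estimators for the two pathway prediction tasks.

``LinkPredictor`` learns to rank candidate entities for a reaction (input or
output role); ``AttributePredictor`` learns to rank candidate attributes for
an entity.  Both follow the sklearn estimator protocol: hyperparameters in
``__init__`` (``get_params``/``set_params`` work, so the classes compose with
sklearn model selection), learning in ``fit``, fitted state in
trailing-underscore attributes.  ``fit`` takes a
:class:`~pathpred.network.PathwayNetwork` instead of a feature matrix — the
hypergraph is the sample.

Training minimises mean elementwise binary cross-entropy between the
sigmoid scores and the task's incidence/assignment matrix with Adam,
backpropagating through the hand-derived adjoints in
:mod:`pathpred.models`.  Given a seed, runs are deterministic up to
floating-point reduction order.

The module-level ``train_*`` / ``predict_*`` functions are thin wrappers
kept for script use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import models as M
from .network import PathwayNetwork
from .pipelines import (RankingResult, TrainConfig, cross_entropy_loss,
                        rank_candidates, readout, readout_matrix, score_links)


class NotFittedError(RuntimeError):
    pass


def _dense(mat) -> np.ndarray:
    return np.asarray(mat.todense(), dtype=np.float64)


class _PathwayEstimator(BaseEstimator):
    """Shared hyperparameters and fitting plumbing."""

    def __init__(self, model="hgnn", embedding_dim=128, learning_rate=5e-3,
                 epochs=200, n_layers=2, batch_size=128,
                 train_edge_weights=True, activation="relu", random_state=0):
        self.model = model
        self.embedding_dim = embedding_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.n_layers = n_layers
        self.batch_size = batch_size
        self.train_edge_weights = train_edge_weights
        self.activation = activation
        self.random_state = random_state

    # -- common helpers ----------------------------------------------------
    def _check_network(self, network: PathwayNetwork) -> PathwayNetwork:
        if not isinstance(network, PathwayNetwork):
            raise TypeError("expected a PathwayNetwork")
        if self.model not in M.MODEL_KINDS:
            raise ValueError(f"unknown model kind: {self.model!r}")
        counts = np.asarray(network.H.sum(axis=0)).ravel()
        if (counts == 0).any():
            empty = int(np.argmax(counts == 0))
            raise ValueError(
                f"reaction {network.reactions[empty].id!r} has no members")
        return network

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise NotFittedError(
                f"{type(self).__name__} is not fitted; call fit() first")

    def embed(self, network: PathwayNetwork | None = None) -> np.ndarray:
        """Node embeddings Z for ``network`` under the frozen fitted
        parameters (the training network by default).  For MF the node
        factor is a free parameter, so Z does not depend on the network."""
        self._check_fitted()
        net = self.network_ if network is None else network
        if isinstance(self.params_, M.MFParams):
            return self.params_.Z
        return M.forward(net, self.params_)

    def _init_layer_state(self, network: PathwayNetwork):
        params = M.init_params(
            self.model, network.n_entities, network.n_reactions,
            network.n_attributes, self.embedding_dim,
            n_layers=self.n_layers, seed=self.random_state,
            activation=self.activation)
        shapes = {f"theta{l}": t.shape
                  for l, t in enumerate(params.theta_per_layer)}
        if self.model != "gcn" and self.train_edge_weights:
            shapes["rho"] = params.rho.shape
        return params, shapes

    def _layer_epoch_grads(self, network, params, dZ_fn):
        """One forward/backward pass through the layer stack.

        ``dZ_fn(Z)`` must return (loss, dLoss/dZ, extra-grads dict); returns
        (loss, grads dict, extras)."""
        train_w = self.model != "gcn" and self.train_edge_weights
        prop = M.propagation(
            network, self.model,
            None if self.model == "gcn" else params.edge_weights)
        cache = M.LayerCache()
        X = _dense(network.X)
        Z = M.forward_layers(prop.P, X, params, cache)
        loss, dZ, extra = dZ_fn(Z)
        d_thetas, dP = M.backward_layers(prop.P, params, cache, dZ,
                                         need_dP=train_w)
        grads = {f"theta{l}": g for l, g in enumerate(d_thetas)}
        if train_w:
            grads["rho"] = M.edge_weight_grad(prop, dP, params.rho)
        return loss, grads, extra

    @staticmethod
    def _apply(opt: M.Adam, params, grads: dict):
        opt.begin_step()
        for l, theta in enumerate(params.theta_per_layer):
            opt.update(f"theta{l}", theta, grads[f"theta{l}"])
        if "rho" in grads:
            opt.update("rho", params.rho, grads["rho"])


class LinkPredictor(_PathwayEstimator):
    """Rank candidate entities for a reaction's input or output side.

    Parameters
    ----------
    model : {"hgnn", "hgnn_plus", "gcn", "mf"}
        Representation learner producing node embeddings (or, for MF, a
        factorisation of the incidence matrix).
    direction : {"input", "output"}
        Which role matrix (H_s or H_t) supplies the training labels.
    embedding_dim, learning_rate, epochs, n_layers, batch_size,
    train_edge_weights, activation, random_state
        See :class:`~pathpred.pipelines.TrainConfig`; ``batch_size`` is the
        MF entry-minibatch size and is ignored by the layer models.

    Attributes
    ----------
    params_ : LayerParams | MFParams
        Fitted parameters.
    embeddings_ : ndarray of shape (n_entities, embedding_dim)
        Node embeddings on the training network.
    loss_history_ : list of float
        Training BCE per epoch (initial loss first).
    network_ : PathwayNetwork
        The training network (used as the default at prediction time).
    """

    def __init__(self, model="hgnn", direction="input", embedding_dim=128,
                 learning_rate=5e-3, epochs=200, n_layers=2, batch_size=128,
                 train_edge_weights=True, activation="relu", random_state=0):
        super().__init__(model=model, embedding_dim=embedding_dim,
                         learning_rate=learning_rate, epochs=epochs,
                         n_layers=n_layers, batch_size=batch_size,
                         train_edge_weights=train_edge_weights,
                         activation=activation, random_state=random_state)
        self.direction = direction

    # -- fitting -----------------------------------------------------------
    def fit(self, network: PathwayNetwork, y=None) -> "LinkPredictor":
        network = self._check_network(network)
        if self.direction not in ("input", "output"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        Hd = _dense(network.H_s if self.direction == "input" else network.H_t)
        if self.model == "mf":
            self._fit_mf(network, Hd)
        else:
            self._fit_layers(network, Hd)
        self.network_ = network
        self.embeddings_ = self.embed(network)
        return self

    def _fit_layers(self, network: PathwayNetwork, Hd: np.ndarray):
        params, shapes = self._init_layer_state(network)
        opt = M.Adam(shapes, lr=self.learning_rate)
        # readout over the training members of the direction's matrix;
        # a reaction with no members on this side gets a zero readout row
        Mread = readout_matrix(Hd)
        Y = Hd.T  # |E| x |V| labels
        losses = []

        def dZ_fn(Z):
            R = Mread @ Z
            S = R @ Z.T
            Q = M.sigmoid(S)
            loss = cross_entropy_loss(Q, Y)
            dS = (Q - Y) / S.size
            dZ = dS.T @ R + Mread.T @ (dS @ Z)
            return loss, dZ, None

        for _ in range(self.epochs):
            loss, grads, _ = self._layer_epoch_grads(network, params, dZ_fn)
            losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss became non-finite ({loss}) at epoch "
                    f"{len(losses)}; lower the learning rate")
            self._apply(opt, params, grads)
        # final loss after the last update (also the initial loss if epochs=0)
        prop = M.propagation(network, self.model,
                             None if self.model == "gcn" else params.edge_weights)
        Z = M.forward_layers(prop.P, _dense(network.X), params)
        losses.append(cross_entropy_loss(M.sigmoid((Mread @ Z) @ Z.T), Y))
        self.params_ = params
        self.loss_history_ = losses

    def _fit_mf(self, network: PathwayNetwork, Hd: np.ndarray):
        params = M.init_params("mf", network.n_entities, network.n_reactions,
                               network.n_attributes, self.embedding_dim,
                               seed=self.random_state)
        # global average rating: mean of the training incidence entries
        params.mu = float(Hd.mean())
        n_v, n_e = Hd.shape
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 1]))
        opt = M.Adam({"Z": params.Z.shape, "R": params.R.shape,
                      "b_z": params.b_z.shape, "b_r": params.b_r.shape},
                     lr=self.learning_rate)
        losses = [cross_entropy_loss(M.sigmoid(M.mf_predict(params)), Hd)]
        n_cells = n_v * n_e
        bs = self.batch_size
        for _ in range(self.epochs):
            order = rng.permutation(n_cells)
            for start in range(0, n_cells, bs):
                cells = order[start:start + bs]
                i, j = cells // n_e, cells % n_e
                pred = (params.mu + params.b_z[i] + params.b_r[j]
                        + np.einsum("bd,bd->b", params.Z[i], params.R[j]))
                g = (M.sigmoid(pred) - Hd[i, j]) / cells.size
                opt.begin_step()
                ui, inv_i = np.unique(i, return_inverse=True)
                uj, inv_j = np.unique(j, return_inverse=True)
                # scatter-add via indicator matmuls (much faster than add.at)
                b = cells.size
                Ii = np.zeros((b, ui.size))
                Ii[np.arange(b), inv_i] = g
                Ij = np.zeros((b, uj.size))
                Ij[np.arange(b), inv_j] = g
                gZ = Ii.T @ params.R[j]
                gR = Ij.T @ params.Z[i]
                gbz = np.bincount(inv_i, weights=g)
                gbr = np.bincount(inv_j, weights=g)
                opt.lazy_update("Z", params.Z, ui, gZ)
                opt.lazy_update("R", params.R, uj, gR)
                opt.lazy_update("b_z", params.b_z, ui, gbz)
                opt.lazy_update("b_r", params.b_r, uj, gbr)
            loss = cross_entropy_loss(M.sigmoid(M.mf_predict(params)), Hd)
            if not np.isfinite(loss):
                raise FloatingPointError("MF training loss became non-finite")
            losses.append(loss)
        self.params_ = params
        self.loss_history_ = losses

    # -- prediction --------------------------------------------------------
    def decision_function(self, reaction_id: str,
                          network: PathwayNetwork | None = None) -> np.ndarray:
        """Connection probabilities phi (length |V|) for one reaction.

        For the layer models: readout over the reaction's members in the
        queried direction (falling back to all known members when that side
        is empty), then sigmoid inner products against all node embeddings.
        For MF: the reaction's column of sigmoid(Hhat)."""
        self._check_fitted()
        net = self.network_ if network is None else network
        e = net.reaction_index(reaction_id)
        if isinstance(self.params_, M.MFParams):
            return M.sigmoid(M.mf_predict(self.params_)[:, e])
        Z = self.embed(net)
        members = net.reaction_members(e, self.direction)
        if not members:
            members = net.reaction_members(e)
        return score_links(readout(Z, members), Z)

    def predict(self, reaction_id: str, k: int = 10,
                network: PathwayNetwork | None = None) -> RankingResult:
        """Top-k candidate entities not already linked in this direction."""
        self._check_fitted()
        net = self.network_ if network is None else network
        e = net.reaction_index(reaction_id)
        phi = self.decision_function(reaction_id, net)
        role = self.direction
        known = [net.entities[v].id for v in net.reaction_members(e, role)]
        ids = [rec.id for rec in net.entities]
        return rank_candidates(reaction_id, ids, phi, excluded=known, k=k)

    def coalition_score(self, network: PathwayNetwork, reaction_id: str,
                        candidate_id: str) -> float:
        """Readout-route score used by the Shapley explainer.

        Always goes through the readout + inner-product route (also for MF,
        whose free node factor ignores X but still supports membership
        masking through the readout)."""
        self._check_fitted()
        e = network.reaction_index(reaction_id)
        v = network.entity_index(candidate_id)
        Z = self.embed(network)
        members = network.reaction_members(e, self.direction)
        if not members:
            members = network.reaction_members(e)
        r = readout(Z, members)
        return float(M.sigmoid(np.array([r @ Z[v]]))[0])


class AttributePredictor(_PathwayEstimator):
    """Rank candidate attributes for an entity.

    A linear classifier m_v = sigmoid(W z_v + b) over the |F| attributes is
    trained jointly with the representation model on the binary assignment
    matrix X.  ``exclude_pairs`` passed to :meth:`fit` are held-out
    (entity, attribute) cells removed from both the loss and the input
    features, preventing label leakage.  With ``model="mf"`` the node
    embeddings are free parameters (no message passing).

    Attributes
    ----------
    params_ : LayerParams | MFParams-like
    classifier_weight_ : ndarray (|F|, D)
    classifier_bias_ : ndarray (|F|,)
    embeddings_, loss_history_, network_ : as for :class:`LinkPredictor`.
    """

    def fit(self, network: PathwayNetwork, y=None,
            exclude_pairs=()) -> "AttributePredictor":
        network = self._check_network(network)
        if network.n_attributes < 1:
            raise ValueError("attribute prediction needs >= 1 attribute")
        X_lab = _dense(network.X)
        mask = np.ones_like(X_lab)
        for (v, f) in exclude_pairs:
            X_lab[v, f] = 0.0  # keep held-out cells out of the input features
            mask[v, f] = 0.0   # ... and out of the loss
        rng_clf = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 2]))
        n_f, d = network.n_attributes, self.embedding_dim
        bound = np.sqrt(6.0 / (n_f + d))
        Wc = rng_clf.uniform(-bound, bound, size=(n_f, d))
        bc = np.zeros(n_f)
        total = mask.sum()

        def head(Z):
            logits = Z @ Wc.T + bc
            Q = M.sigmoid(logits)
            loss = cross_entropy_loss(Q, X_lab, mask=mask)
            dlog = (Q - X_lab) * mask / total
            return loss, Q, dlog

        if self.model == "mf":
            self._fit_free(network, X_lab, Wc, bc, head)
        else:
            self._fit_layers_attr(network, X_lab, mask, Wc, bc, head)
        self.network_ = network
        self.classifier_weight_ = Wc
        self.classifier_bias_ = bc
        self.embeddings_ = self.embed(network)
        return self

    def _fit_layers_attr(self, network, X_lab, mask, Wc, bc, head):
        # the masked cells are also removed from the model's input features
        masked_net = network
        if not np.array_equal(X_lab, _dense(network.X)):
            masked_net = _replace_X(network, X_lab)
        params, shapes = self._init_layer_state(masked_net)
        shapes["Wc"] = Wc.shape
        shapes["bc"] = bc.shape
        opt = M.Adam(shapes, lr=self.learning_rate)
        losses = []

        def dZ_fn(Z):
            loss, Q, dlog = head(Z)
            dWc = dlog.T @ Z
            dbc = dlog.sum(axis=0)
            dZ = dlog @ Wc
            return loss, dZ, {"Wc": dWc, "bc": dbc}

        for _ in range(self.epochs):
            loss, grads, extra = self._layer_epoch_grads(masked_net, params, dZ_fn)
            losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError("training loss became non-finite")
            self._apply(opt, params, grads)
            opt.update("Wc", Wc, extra["Wc"])
            opt.update("bc", bc, extra["bc"])
        Z = M.forward(masked_net, params)
        losses.append(head(Z)[0])
        self.params_ = params
        self.loss_history_ = losses
        self._masked_network_ = masked_net

    def _fit_free(self, network, X_lab, Wc, bc, head):
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 0]))
        Z = rng.normal(0.0, 0.05, size=(network.n_entities, self.embedding_dim))
        opt = M.Adam({"Z": Z.shape, "Wc": Wc.shape, "bc": bc.shape},
                     lr=self.learning_rate)
        losses = []
        for _ in range(self.epochs):
            loss, Q, dlog = head(Z)
            losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError("training loss became non-finite")
            opt.begin_step()
            opt.update("Z", Z, dlog @ Wc)
            opt.update("Wc", Wc, dlog.T @ Z)
            opt.update("bc", bc, dlog.sum(axis=0))
        losses.append(head(Z)[0])
        self.params_ = M.MFParams(mu=0.0, b_z=np.zeros(network.n_entities),
                                  b_r=np.zeros(network.n_reactions),
                                  Z=Z, R=np.zeros((network.n_reactions,
                                                   self.embedding_dim)))
        self.loss_history_ = losses
        self._masked_network_ = network

    def embed(self, network: PathwayNetwork | None = None) -> np.ndarray:
        self._check_fitted()
        if network is None:
            network = getattr(self, "_masked_network_", self.network_)
        return super().embed(network)

    def decision_function(self, entity_id: str,
                          network: PathwayNetwork | None = None) -> np.ndarray:
        """Attribute probabilities m_v (length |F|) for one entity."""
        self._check_fitted()
        net = (getattr(self, "_masked_network_", self.network_)
               if network is None else network)
        v = net.entity_index(entity_id)
        Z = self.embed(net)
        return M.sigmoid(self.classifier_weight_ @ Z[v] + self.classifier_bias_)

    def predict(self, entity_id: str, k: int = 10,
                network: PathwayNetwork | None = None) -> RankingResult:
        """Top-k attributes not already assigned to the entity."""
        self._check_fitted()
        net = (getattr(self, "_masked_network_", self.network_)
               if network is None else network)
        v = net.entity_index(entity_id)
        m_v = self.decision_function(entity_id, net)
        known = [net.attributes[f].id for f in net.entity_attributes(v)]
        ids = [rec.id for rec in net.attributes]
        return rank_candidates(entity_id, ids, m_v, excluded=known, k=k)


def _replace_X(network: PathwayNetwork, X_new: np.ndarray) -> PathwayNetwork:
    """Network copy whose assignments/X match the dense matrix ``X_new``."""
    import scipy.sparse as sp
    pairs = frozenset(zip(*np.nonzero(X_new)))
    pairs = frozenset((int(v), int(f)) for v, f in pairs)
    return PathwayNetwork(
        entities=network.entities, reactions=network.reactions,
        attributes=network.attributes, memberships=network.memberships,
        assignments=pairs,
        H=network.H, H_s=network.H_s, H_t=network.H_t,
        X=sp.csr_matrix(X_new),
    )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _estimator_kwargs(config: TrainConfig) -> dict:
    return dict(model=config.model, embedding_dim=config.embedding_dim,
                learning_rate=config.learning_rate, epochs=config.epochs,
                n_layers=config.n_layers, batch_size=config.batch_size,
                train_edge_weights=config.train_edge_weights,
                activation=config.activation, random_state=config.seed)


def train_link_model(network: PathwayNetwork, direction: str,
                     config: TrainConfig) -> LinkPredictor:
    """Fit a :class:`LinkPredictor` described by ``config`` on ``network``."""
    est = LinkPredictor(direction=direction, **_estimator_kwargs(config))
    return est.fit(network)


def predict_link_candidates(model: LinkPredictor, network: PathwayNetwork,
                            reaction_id: str, k: int = 10) -> RankingResult:
    return model.predict(reaction_id, k=k, network=network)


def train_attribute_model(network: PathwayNetwork, config: TrainConfig,
                          exclude_pairs=()) -> AttributePredictor:
    """Fit an :class:`AttributePredictor` described by ``config``."""
    est = AttributePredictor(**_estimator_kwargs(config))
    return est.fit(network, exclude_pairs=exclude_pairs)


def predict_attribute_candidates(model: AttributePredictor,
                                 network: PathwayNetwork, entity_id: str,
                                 k: int = 10) -> RankingResult:
    return model.predict(entity_id, k=k, network=network)
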