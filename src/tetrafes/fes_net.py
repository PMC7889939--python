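"""Force-matching neural network for the six-dimensional free energy surface.

The free energy A(d) over the six inter-nucleosome distances is represented
by a small multilayer perceptron applied to reversal-invariant features
s(d), so A(d) = A(d~) holds exactly for any weights.  Training minimises

    mean over centres  | grad_d A(d_o) + F(d_o) |^2

i.e. the network's negative input gradient is matched to the estimated mean
forces.  The input gradient is obtained by back-propagation through the
network and the feature map; the gradient of the force-matching loss with
respect to the weights therefore involves second derivatives of the network
and is computed here by an analytically derived second-order backward pass
(verified against finite differences in the test suite).  Activations are
smooth (tanh by default) so the learned surface has continuous gradients —
a requirement of the string method that consumes them.

Free energies are defined up to an additive constant (the loss only sees
gradients); the gauge is fixed by shifting the minimum over training
centres to zero.  Predictions carry a trusted-domain flag: the surface is
only meaningful near the centres where forces were estimated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cvlib import symmetric_features, symmetric_features_jacobian
from .errors import DivergenceError, InputError
from .meanforce import MeanForceRecord

_ACTIVATIONS = {
    # name -> (phi(z), phi'(z) given a=phi(z) and z, phi''(z) given a and z)
    "tanh": (
        np.tanh,
        lambda a, z: 1.0 - a * a,
        lambda a, z: -2.0 * a * (1.0 - a * a),
    ),
    "softplus": (
        lambda z: np.logaddexp(0.0, z),
        lambda a, z: 1.0 / (1.0 + np.exp(-z)),
        lambda a, z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
}

_FEATURE_MAPS = ("symmetric", "identity")


@dataclass
class Prediction:
    energy: float | np.ndarray
    mean_force: np.ndarray
    trusted: bool | np.ndarray


@dataclass
class TrainingReport:
    """Per-epoch losses and held-out force correlation."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopping_epoch: int = 0
    pearson_pooled: float = float("nan")
    pearson_per_component: np.ndarray | None = None
    hyperparams: dict = field(default_factory=dict)


class FESModel:
    """A(d) as an MLP over (normalised) reversal-symmetric features."""

    def __init__(self, weights, biases, activation: str = "tanh",
                 feature_map: str = "symmetric", norm_mu=None, norm_sd=None,
                 centers=None, cutoff: float = np.inf, offset: float = 0.0,
                 meta: dict | None = None):
        if activation not in _ACTIVATIONS:
            raise InputError(f"unknown activation {activation!r}")
        if feature_map not in _FEATURE_MAPS:
            raise InputError(f"unknown feature map {feature_map!r}")
        self.weights = [np.asarray(W, dtype=float) for W in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.activation = activation
        self.feature_map = feature_map
        n_in = self.weights[0].shape[1]
        self.norm_mu = np.zeros(n_in) if norm_mu is None else np.asarray(norm_mu, dtype=float)
        self.norm_sd = np.ones(n_in) if norm_sd is None else np.asarray(norm_sd, dtype=float)
        self.centers = None if centers is None else np.atleast_2d(np.asarray(centers, dtype=float))
        self.cutoff = float(cutoff)
        self.offset = float(offset)
        self.meta = meta or {}
        self._tree = None

    # -- feature plumbing ---------------------------------------------------

    @property
    def dimension(self) -> int:
        return 6 if self.feature_map == "symmetric" else self.weights[0].shape[1]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights) - 1

    def _features(self, d: np.ndarray) -> np.ndarray:
        if self.feature_map == "symmetric":
            s = symmetric_features(d)
        else:
            s = np.asarray(d, dtype=float)
        return (s - self.norm_mu) / self.norm_sd

    def _feature_jacobian(self, d: np.ndarray) -> np.ndarray:
        """d(normalised features)/dd, shape (B, n_in, n_dim)."""
        d = np.atleast_2d(np.asarray(d, dtype=float))
        if self.feature_map == "symmetric":
            J = symmetric_features_jacobian(d)
        else:
            J = np.broadcast_to(np.eye(d.shape[1]), (len(d), d.shape[1], d.shape[1])).copy()
        return J / self.norm_sd[None, :, None]

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray):
        phi, dphi, _ = _ACTIVATIONS[self.activation]
        acts = [X]
        zs = []
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ W.T + b
            a = phi(z)
            zs.append(z)
            acts.append(a)
        y = a @ self.weights[-1].T + self.biases[-1]
        return y[:, 0], zs, acts

    def _input_gradient(self, zs, acts):
        """dA/d(features) via reverse pass; returns G plus per-layer U, V."""
        _, dphi, _ = _ACTIVATIONS[self.activation]
        L = len(zs)
        B = len(acts[0])
        Vs = [None] * (L + 1)
        Us = [None] * L
        V = np.broadcast_to(self.weights[-1][0], (B, self.weights[-1].shape[1])).copy()
        Vs[L] = V
        for l in range(L - 1, -1, -1):
            U = dphi(acts[l + 1], zs[l]) * Vs[l + 1]
            Us[l] = U
            Vs[l] = U @ self.weights[l]
        return Vs[0], Us, Vs

    # -- public surface -----------------------------------------------------

    def predict_energy(self, d) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        single = d.ndim == 1
        X = self._features(np.atleast_2d(d))
        y, _, _ = self._forward(X)
        y = y - self.offset
        return float(y[0]) if single else y

    def predict_force(self, d) -> np.ndarray:
        """Mean force -dA/dd at d (back-propagated through the feature map)."""
        d = np.asarray(d, dtype=float)
        single = d.ndim == 1
        db = np.atleast_2d(d)
        X = self._features(db)
        _, zs, acts = self._forward(X)
        G, _, _ = self._input_gradient(zs, acts)
        Jhat = self._feature_jacobian(db)
        dAdd = np.einsum("bij,bi->bj", Jhat, G)
        return -dAdd[0] if single else -dAdd

    def trusted(self, d) -> bool | np.ndarray:
        """Whether d lies within the cutoff of a training centre."""
        d = np.asarray(d, dtype=float)
        single = d.ndim == 1
        db = np.atleast_2d(d)
        if self.centers is None:
            out = np.ones(len(db), dtype=bool)
        else:
            if self._tree is None:
                from scipy.spatial import cKDTree

                self._tree = cKDTree(self.centers)
            dist, _ = self._tree.query(db)
            out = dist <= self.cutoff
        return bool(out[0]) if single else out

    def predict(self, d) -> Prediction:
        return Prediction(self.predict_energy(d), self.predict_force(d), self.trusted(d))

    # aliases so learned surfaces can be consumed wherever an analytic
    # surface is accepted (profiles, string method)
    def energy(self, x):
        return self.predict_energy(x)

    def gradient(self, x):
        return -self.predict_force(x)

    @property
    def bounds(self):
        if self.centers is None:
            return np.array([[-np.inf, np.inf]] * self.dimension)
        lo = self.centers.min(axis=0) - self.cutoff
        hi = self.centers.max(axis=0) + self.cutoff
        return np.stack([lo, hi], axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        blob = {
            "activation": self.activation,
            "feature_map": self.feature_map,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "norm_mu": self.norm_mu.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "centers": None if self.centers is None else self.centers.tolist(),
            "cutoff": self.cutoff if np.isfinite(self.cutoff) else None,
            "offset": self.offset,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "FESModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            weights=blob["weights"],
            biases=blob["biases"],
            activation=blob["activation"],
            feature_map=blob["feature_map"],
            norm_mu=blob["norm_mu"],
            norm_sd=blob["norm_sd"],
            centers=blob["centers"],
            cutoff=np.inf if blob["cutoff"] is None else blob["cutoff"],
            offset=blob["offset"],
            meta=blob.get("meta", {}),
        )


def build_model(hidden=(64, 64), activation: str = "tanh",
                feature_map: str = "symmetric", n_in: int = 6,
                seed: int = 0) -> FESModel:
    """Fresh model with deterministically seeded Glorot-style weights."""
    hidden = tuple(int(h) for h in hidden)
    if len(hidden) < 1:
        raise InputError("at least one hidden layer is required")
    if any(h <= 0 for h in hidden):
        raise InputError(f"zero-width layer in {hidden}")
    rng = np.random.default_rng(seed)
    sizes = (n_in,) + hidden + (1,)
    weights, biases = [], []
    for nin, nout in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (nin + nout))
        weights.append(rng.standard_normal((nout, nin)) * scale)
        biases.append(np.zeros(nout))
    return FESModel(weights, biases, activation, feature_map,
                    meta={"seed": seed, "hidden": list(hidden)})


# ---------------------------------------------------------------------------
# Force-matching loss and its analytic parameter gradient
# ---------------------------------------------------------------------------

def _loss_and_grads(model: FESModel, X: np.ndarray, Jhat: np.ndarray, F: np.ndarray):
    """Mean squared force residual and its gradient w.r.t. all weights.

    The loss depends on the network through its input gradient G, so the
    parameter gradient is a second-order backward pass: a forward
    "tangent" sweep (C-chain) through the reverse pass plus a standard
    backward sweep collecting the dependence through the pre-activations.
    """
    phi, dphi, d2phi = _ACTIVATIONS[model.activation]
    B = len(X)
    L = model.n_hidden_layers
    _, zs, acts = model._forward(X)
    G, Us, Vs = model._input_gradient(zs, acts)

    dAdd = np.einsum("bij,bi->bj", Jhat, G)
    R = dAdd + F
    loss = float(np.mean(np.sum(R * R, axis=1)))
    Gbar = (2.0 / B) * np.einsum("bij,bj->bi", Jhat, R)

    dW = [np.zeros_like(W) for W in model.weights]
    db = [np.zeros_like(b) for b in model.biases]

    # tangent sweep: Chat_0 = Gbar, C_l = Chat_{l-1} W_l^T, Chat_l = C_l phi'(z_l)
    Chat = Gbar
    Cs = [None] * (L + 1)   # C_l for l = 1..L
    Chats = [Chat]          # Chat_0 .. Chat_L
    for l in range(1, L + 1):
        C = Chat @ model.weights[l - 1].T
        Cs[l] = C
        Chat = C * dphi(acts[l], zs[l - 1])
        Chats.append(Chat)

    # output layer: S = sum_b (W_out Chat_L)_b
    dW[L] += Chats[L].sum(axis=0, keepdims=True)

    # direct occurrences of W_l in the tangent chain
    for l in range(1, L + 1):
        dW[l - 1] += Us[l - 1].T @ Chats[l - 1]

    # dependence through the pre-activations z_l (phi'(z_l) factors)
    delta = None
    for l in range(L, 0, -1):
        sigma = Cs[l] * d2phi(acts[l], zs[l - 1]) * Vs[l]
        if delta is None:
            delta = sigma
        else:
            delta = sigma + dphi(acts[l], zs[l - 1]) * (delta @ model.weights[l])
        # note: delta here is delta_l after combining with deeper layers
        dW[l - 1] += delta.T @ acts[l - 1]
        db[l - 1] += delta.sum(axis=0)
    return loss, dW, db


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train_force_matching(model: FESModel, records: list[MeanForceRecord],
                         split_fraction: float = 0.2, hyperparams: dict | None = None,
                         seed: int = 0) -> tuple[FESModel, TrainingReport]:
    """Fit the network to mean forces; returns (trained model, report).

    hyperparams keys (defaults): lr 3e-3, max_epochs 2000, weight_decay 1e-5,
    patience 50, min_epochs 100, lr_decay 0.1 (the factor the learning rate
    decays to, exponentially, over max_epochs).  Full-batch Adam with
    decoupled weight decay on the matrices; early stopping on the validation
    force loss with the stated patience, restoring the best weights.  The report's pooled Pearson
    correlation between predicted mean forces and the reference forces is
    computed on the held-out split only.
    """
    hp = {"lr": 3e-3, "max_epochs": 2000, "weight_decay": 1e-5,
          "patience": 50, "min_epochs": 100, "lr_decay": 0.1}
    hp.update(hyperparams or {})
    if not 0.0 < split_fraction < 1.0:
        raise InputError(f"split_fraction must be in (0,1), got {split_fraction}")
    if len(records) < 50:
        raise InputError(f"need at least 50 mean-force records, got {len(records)}")

    D = np.stack([r.center for r in records])
    F = np.stack([r.force for r in records])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(D))
    n_val = max(1, int(round(split_fraction * len(D))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    # normalisation fitted on training features only
    if model.feature_map == "symmetric":
        S_train = symmetric_features(D[train_idx])
    else:
        S_train = D[train_idx]
    model.norm_mu = S_train.mean(axis=0)
    model.norm_sd = np.maximum(S_train.std(axis=0), 1e-8)

    X_tr = model._features(D[train_idx])
    X_va = model._features(D[val_idx])
    J_tr = model._feature_jacobian(D[train_idx])
    J_va = model._feature_jacobian(D[val_idx])
    F_tr, F_va = F[train_idx], F[val_idx]

    # Adam state
    mW = [np.zeros_like(W) for W in model.weights]
    vW = [np.zeros_like(W) for W in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr, wd = hp["lr"], hp["weight_decay"]

    report = TrainingReport(hyperparams=dict(hp))
    best_val = np.inf
    best_weights = None
    best_epoch = 0
    for epoch in range(1, hp["max_epochs"] + 1):
        loss, dW, db = _loss_and_grads(model, X_tr, J_tr, F_tr)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at lr={hp['lr']}")
        t = epoch
        lr = hp["lr"] * hp["lr_decay"] ** (epoch / hp["max_epochs"])
        for i in range(len(model.weights)):
            for g, m, v, p, decay in ((dW[i], mW[i], vW[i], model.weights[i], wd),
                                      (db[i], mb[i], vb[i], model.biases[i], 0.0)):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * (mhat / (np.sqrt(vhat) + eps) + decay * p)
        val_loss, _, _ = _loss_and_grads(model, X_va, J_va, F_va)
        report.train_loss.append(loss)
        report.val_loss.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_weights = ([W.copy() for W in model.weights],
                            [b.copy() for b in model.biases])
        if epoch - best_epoch >= hp["patience"] and epoch >= hp["min_epochs"]:
            break
    if best_weights is not None:
        model.weights, model.biases = best_weights
    report.stopping_epoch = best_epoch

    # trusted domain from the training centres
    model.centers = D[train_idx].copy()
    model._tree = None
    from scipy.spatial import cKDTree

    tree = cKDTree(model.centers)
    nn = tree.query(model.centers, k=2)[0][:, 1]
    model.cutoff = 2.0 * float(np.percentile(nn, 95))

    # gauge: minimum over training centres -> 0
    model.offset = 0.0
    model.offset = float(np.min(model.predict_energy(model.centers)))

    pred_F = model.predict_force(D[val_idx])
    report.pearson_pooled = _pearson(pred_F, F_va)
    report.pearson_per_component = np.array(
        [_pearson(pred_F[:, j], F_va[:, j]) for j in range(F_va.shape[1])]
    )
    model.meta.update(
        {"trained": True, "seed": seed, "epochs_run": len(report.train_loss),
         "stopping_epoch": best_epoch, "final_train_loss": report.train_loss[-1],
         "final_val_loss": best_val, "pearson_pooled": report.pearson_pooled}
    )
    return model, report
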