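"""The neural pairwise-interaction scoring function.

Two stacked feed-forward stages score a Cα-trace conformation:

* the pair stage maps each pair encoding x_ij to a 3-vector
  X_ij = tanh(tanh(x W1 + b1) W2 + b2)        (hidden width 5),
* per-residue feature vectors Y_i = K Σ_{j∈C_i} X_ij are summed over the
  chain and the global stage maps the 3-vector to a scalar
  O = tanh(Σ_i Y_i V1 + c1) V2 + c2           (hidden width 3, linear out).

Because both sums commute, O depends on the multiset of pair encodings only.
K normalizes by the neighbour-count cap (K = 1/10) so Y_i is a bounded mean.
Training minimizes the squared error (O − q)² against the contact-map
quality label q by plain mini-batch gradient descent (batch 2), with the
exact gradient obtained by back-propagation through both stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .encoding import MAX_NEIGHBORS

PAIR_HIDDEN = 5
PAIR_OUT = 3
GLOBAL_HIDDEN = 3
DEFAULT_K = 1.0 / MAX_NEIGHBORS

_WEIGHT_NAMES = ("W1", "b1", "W2", "b2", "V1", "c1", "V2", "c2")


@dataclass
class NNPIFModel:
    """Weights of the pair stage (input→5→3, tanh/tanh) and the global stage
    (3→3→1, tanh/linear), plus the normalization constant K."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    V1: np.ndarray
    c1: np.ndarray
    V2: np.ndarray
    c2: np.ndarray
    K: float = DEFAULT_K
    seed: int | None = None

    def __post_init__(self):
        din = self.W1.shape[0]
        expected = {
            "W1": (din, PAIR_HIDDEN), "b1": (PAIR_HIDDEN,),
            "W2": (PAIR_HIDDEN, PAIR_OUT), "b2": (PAIR_OUT,),
            "V1": (PAIR_OUT, GLOBAL_HIDDEN), "c1": (GLOBAL_HIDDEN,),
            "V2": (GLOBAL_HIDDEN, 1), "c2": (1,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite weights")
            setattr(self, name, arr)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    def weights(self) -> dict:
        return {name: getattr(self, name) for name in _WEIGHT_NAMES}

    def copy(self) -> "NNPIFModel":
        return NNPIFModel(
            **{n: getattr(self, n).copy() for n in _WEIGHT_NAMES},
            K=self.K, seed=self.seed,
        )

    # -- serialization: JSON keeps the deliverable text-only and float repr
    # round-trips are bit-exact
    def save(self, path) -> None:
        payload = {n: getattr(self, n).tolist() for n in _WEIGHT_NAMES}
        payload["K"] = self.K
        payload["seed"] = self.seed
        payload["input_dim"] = self.input_dim
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NNPIFModel":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {n: np.array(payload[n], float) for n in _WEIGHT_NAMES}
        return cls(**kwargs, K=payload["K"], seed=payload.get("seed"))


def init_model(input_dim: int, seed: int, K: float = DEFAULT_K) -> NNPIFModel:
    """Random model with weights uniform in [−0.1, 0.1], reproducible.

    The global-stage input weights V1 are drawn from [−0.01, 0.01]: the
    summed feature vector S = K·ΣΣ X_ij grows with chain length (‖S‖ is
    O(L) in the worst case), and a smaller scale keeps the global tanh units
    in their sensitive range at initialization so gradients can flow.
    """
    if input_dim <= 0:
        raise ValueError("input_dim must be positive")
    rng = np.random.default_rng(seed)

    def u(*shape, scale=0.1):
        return rng.uniform(-scale, scale, size=shape)

    return NNPIFModel(
        W1=u(input_dim, PAIR_HIDDEN), b1=u(PAIR_HIDDEN),
        W2=u(PAIR_HIDDEN, PAIR_OUT), b2=u(PAIR_OUT),
        V1=u(PAIR_OUT, GLOBAL_HIDDEN, scale=0.01), c1=u(GLOBAL_HIDDEN),
        V2=u(GLOBAL_HIDDEN, 1), c2=u(1),
        K=K, seed=seed,
    )


@dataclass
class ForwardCache:
    X: np.ndarray       # (P, din) pair encodings
    H1: np.ndarray      # (P, 5) pair hidden activations
    Xout: np.ndarray    # (P, 3) pair outputs
    S: np.ndarray       # (3,) global sum K·ΣΣ X_ij
    hG: np.ndarray      # (3,) global hidden activations
    O: float
    input_dim: int


def forward(model: NNPIFModel, encodings) -> tuple[float, ForwardCache]:
    """Score one conformation; returns (O, cache for backward).

    ``encodings`` is a ConformationEncoding or a raw (P, din) array of pair
    vectors.  An empty pair set scores the global stage on the zero vector.
    """
    X = encodings if isinstance(encodings, np.ndarray) else encodings.X
    X = np.asarray(X, float).reshape(-1, model.input_dim) if X.size else np.zeros((0, model.input_dim))
    if X.size and X.shape[1] != model.input_dim:
        raise ValueError(
            f"encoding dim {X.shape[1]} does not match model input_dim {model.input_dim}"
        )
    if len(X):
        H1 = np.tanh(X @ model.W1 + model.b1)
        Xout = np.tanh(H1 @ model.W2 + model.b2)
        S = model.K * Xout.sum(axis=0)
    else:
        H1 = np.zeros((0, PAIR_HIDDEN))
        Xout = np.zeros((0, PAIR_OUT))
        S = np.zeros(PAIR_OUT)
    hG = np.tanh(S @ model.V1 + model.c1)
    O = float((hG @ model.V2 + model.c2)[0])
    return O, ForwardCache(X, H1, Xout, S, hG, O, model.input_dim)


def backward(model: NNPIFModel, cache: ForwardCache, target: float) -> dict:
    """Exact gradient of (O − target)² w.r.t. every weight."""
    if cache.input_dim != model.input_dim:
        raise ValueError("cache does not match model input dimension")
    dO = 2.0 * (cache.O - target)
    g = {}
    g["c2"] = np.array([dO])
    g["V2"] = cache.hG[:, None] * dO
    dhG = dO * model.V2[:, 0] * (1.0 - cache.hG**2)
    g["V1"] = np.outer(cache.S, dhG)
    g["c1"] = dhG
    dS = model.V1 @ dhG  # (3,)
    if len(cache.X):
        dXout = model.K * dS[None, :] * (1.0 - cache.Xout**2)  # (P, 3)
        g["W2"] = cache.H1.T @ dXout
        g["b2"] = dXout.sum(axis=0)
        dH1 = (dXout @ model.W2.T) * (1.0 - cache.H1**2)
        g["W1"] = cache.X.T @ dH1
        g["b1"] = dH1.sum(axis=0)
    else:
        g["W2"] = np.zeros_like(model.W2)
        g["b2"] = np.zeros_like(model.b2)
        g["W1"] = np.zeros_like(model.W1)
        g["b1"] = np.zeros_like(model.b1)
    return g


def _apply_gradient(model: NNPIFModel, grad: dict, lr: float) -> None:
    for name in _WEIGHT_NAMES:
        getattr(model, name).__isub__(lr * grad[name])


def train_epochs(
    model: NNPIFModel,
    examples,
    lr: float,
    batch: int = 2,
    epochs: int = 1,
    seed: int = 0,
) -> tuple[NNPIFModel, list]:
    """Mini-batch gradient descent over (encoding, q) examples.

    ``examples`` is a sequence of (ConformationEncoding-or-array, q) pairs.
    Each epoch visits the examples in a freshly shuffled (seeded) order and
    applies one plain gradient step per batch (default two conformations per
    batch).  Returns a trained copy and the per-epoch mean squared error
    measured during the pass.
    """
    examples = list(examples)
    if not examples:
        raise ValueError("empty training set")
    if lr < 0:
        raise ValueError("learning rate must be non-negative")
    model = model.copy()
    rng = np.random.default_rng(seed)
    history = []
    n = len(examples)
    for _ in range(epochs):
        order = rng.permutation(n)
        sq_err = 0.0
        for start in range(0, n, batch):
            grads = None
            for idx in order[start : start + batch]:
                enc, q = examples[idx]
                O, cache = forward(model, enc)
                sq_err += (O - q) ** 2
                g = backward(model, cache, q)
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] = grads[k] + g[k]
            _apply_gradient(model, grads, lr)
        history.append(sq_err / n)
    return model, history


def evaluate_error(model: NNPIFModel, examples) -> float:
    """Mean squared error of the model over (encoding, q) examples."""
    examples = list(examples)
    if not examples:
        raise ValueError("empty evaluation set")
    errs = [(forward(model, enc)[0] - q) ** 2 for enc, q in examples]
    return float(np.mean(errs))
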