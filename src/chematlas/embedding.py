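"""Parametric t-SNE: a feed-forward network trained to map fingerprints to 2D.

Classic t-SNE optimizes the low-dimensional coordinates directly, so every run
of the optimizer yields a different map and new compounds cannot be placed on
an existing one.  The parametric variant instead trains a neural network
``f: {0,1}^d -> R^2`` to minimize the same Kullback-Leibler divergence between
the high- and low-dimensional neighbor distributions.  After training the
weights are frozen, so projecting a compound is a pure feed-forward pass:
deterministic, repeatable, and consistent for new molecules -- compounds
sharing a scaffold land in the same region of the map.

High-dimensional neighborhoods are built from Jaccard distances between binary
fingerprints.  Per point, a Gaussian bandwidth is calibrated by bisection so
that the perplexity (2 to the Shannon entropy of the conditional neighbor
distribution) hits a target -- a smooth effective-neighbor count.  The
low-dimensional kernel is a Student-t with one degree of freedom, whose heavy
tail prevents the "crowding" of moderately distant points.

Training here is minibatch: neighbor distributions are computed within each
shuffled batch, which keeps the pairwise work quadratic in the batch size
rather than the library size.  The network and its gradients are implemented
directly in numpy; the gradient of the KL loss with respect to the output
coordinates is the standard t-SNE gradient

    dC/dy_i = 4 * sum_j (p_ij - q_ij) * (1 + ||y_i - y_j||^2)^-1 * (y_i - y_j)

backpropagated through the ReLU layers, with Adam updates.  All randomness
(weight initialization, shuffling) flows from a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ModelFormatError

MODEL_FORMAT_VERSION = 1
DEFAULT_HIDDEN_DIMS = (500, 500, 2000)
_EPS = 1e-12


# ---------------------------------------------------------------------------
# distances and affinities


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard distance 1 - |a&b|/|a|b| between two binary vectors.

    Defined as 0 when both vectors are empty (identical by convention).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a != 0
    b = b != 0
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    inter = np.count_nonzero(a & b)
    return 1.0 - inter / union


def jaccard_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between the rows of a binary matrix."""
    Xf = (np.asarray(X) != 0).astype(np.float64)
    inter = Xf @ Xf.T
    pop = Xf.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - inter / union
    D[union == 0] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


def conditional_affinities(
    dist_row: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_steps: int = 50,
) -> np.ndarray:
    """Gaussian conditional neighbor distribution p_{j|i} for one point.

    ``dist_row`` holds the distances from point i to every other point (self
    excluded).  The Gaussian bandwidth is found by bisection on the precision
    beta = 1/(2 sigma^2) so that 2**H(p) matches ``perplexity`` within ``tol``
    (H is the Shannon entropy in bits).  Returns a row summing to 1.
    """
    d2 = np.asarray(dist_row, dtype=np.float64) ** 2
    n = d2.size
    if not perplexity < n:
        raise ValueError(f"perplexity {perplexity} must be < row length {n}")
    if np.allclose(d2, d2[0]):
        # all neighbors equidistant: every bandwidth gives the uniform row
        if abs(n - perplexity) > tol:
            warnings.warn(
                "all distances identical; perplexity unreachable, returning uniform row",
                stacklevel=2,
            )
        return np.full(n, 1.0 / n)

    target = np.log2(perplexity)

    def row_and_entropy(beta: float) -> tuple[np.ndarray, float]:
        logits = -beta * (d2 - d2.min())  # shift for numerical stability
        p = np.exp(logits)
        p /= p.sum()
        nz = p > 0
        H = -np.sum(p[nz] * np.log2(p[nz]))
        return p, H

    beta, lo, hi = 1.0, 0.0, np.inf
    p, H = row_and_entropy(beta)
    for _ in range(max_steps):
        if abs(2.0 ** H - perplexity) <= tol:
            break
        if H > target:  # too flat -> narrow the kernel
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
        else:
            hi = beta
            beta = (beta + lo) / 2.0
        p, H = row_and_entropy(beta)
    else:
        if abs(2.0 ** H - perplexity) > tol:
            warnings.warn(
                f"perplexity calibration stopped at 2^H={2.0 ** H:.4f} "
                f"(target {perplexity}) after {max_steps} steps",
                stacklevel=2,
            )
    return p


def conditional_affinity_matrix(
    D: np.ndarray, perplexity: float, tol: float = 1e-5, max_steps: int = 50
) -> np.ndarray:
    """Row-wise conditional affinities for a full distance matrix (diagonal 0)."""
    n = D.shape[0]
    P = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        P[i, others] = conditional_affinities(D[i, others], perplexity, tol, max_steps)
    return P


def joint_affinities(P_conditional: np.ndarray) -> np.ndarray:
    """Symmetrized joint distribution p_ij = (p_{j|i} + p_{i|j}) / 2n."""
    n = P_conditional.shape[0]
    return (P_conditional + P_conditional.T) / (2.0 * n)


def low_dim_affinities(Y: np.ndarray) -> np.ndarray:
    """Student-t (df=1) joint distribution over 2D coordinates."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 points")
    sq = np.sum((Y[:, None, :] - Y[None, :, :]) ** 2, axis=-1)
    num = 1.0 / (1.0 + sq)
    np.fill_diagonal(num, 0.0)
    return num / num.sum()


def kl_loss(P: np.ndarray, Q: np.ndarray, eps: float = _EPS) -> float:
    """KL divergence sum p log(p/q) over the support of P; q floored at eps."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch between P and Q")
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], eps))))


# ---------------------------------------------------------------------------
# the projector network


@dataclass
class TrainingConfig:
    perplexity: float = 30.0
    batch_size: int = 512
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    entropy_tol: float = 1e-5
    max_bisection_steps: int = 50
    hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS

    def validate(self) -> None:
        if not self.perplexity > 0:
            raise ConfigError("perplexity must be positive")
        if not self.perplexity < self.batch_size:
            raise ConfigError(
                f"perplexity ({self.perplexity}) must be < batch_size ({self.batch_size})"
            )
        if self.batch_size < self.perplexity + 1:
            raise ConfigError("batch smaller than perplexity + 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigError("epochs must be >= 1 and learning_rate > 0")


@dataclass
class EmbeddingModel:
    """Weights of the fingerprint->2D projector plus training provenance."""

    layer_dims: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "relu"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer_dims[-1] != 2:
            raise ConfigError("output dimension must be exactly 2 (map coordinates X, Y)")

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Feed-forward pass; returns output and per-layer pre-activation inputs."""
        A = np.asarray(X, dtype=np.float64)
        if A.ndim != 2 or A.shape[1] != self.input_dim:
            raise ValueError(
                f"input has {A.shape[1] if A.ndim == 2 else '?'} features, "
                f"model expects {self.input_dim}"
            )
        cache = []
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            cache.append(A)
            Z = A @ W + b
            A = Z if k == last else np.maximum(Z, 0.0)  # linear output, ReLU hidden
        return A, cache


def _init_model(input_dim: int, hidden_dims: tuple[int, ...], rng: np.random.Generator) -> EmbeddingModel:
    dims = [input_dim, *hidden_dims, 2]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / fan_in)  # fan-in scaled uniform init
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return EmbeddingModel(layer_dims=dims, weights=weights, biases=biases)


def _tsne_output_gradient(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    sq = np.sum((Y[:, None, :] - Y[None, :, :]) ** 2, axis=-1)
    num = 1.0 / (1.0 + sq)
    np.fill_diagonal(num, 0.0)
    Q = np.maximum(num / num.sum(), _EPS)
    PQ = (P - Q) * num
    return 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)


def train(fingerprints: np.ndarray, config: TrainingConfig | None = None) -> EmbeddingModel:
    """Train the projector on a fingerprint matrix by minibatch KL minimization.

    Within each shuffled batch the joint neighbor distribution P is built from
    Jaccard distances with per-point perplexity calibration; the network output
    defines Q through the Student-t kernel; Adam descends the KL divergence.
    Fully reproducible from ``config.seed``.
    """
    config = config or TrainingConfig()
    config.validate()
    X = (np.asarray(fingerprints) != 0).astype(np.float64)
    n = X.shape[0]
    if n < 2 * config.batch_size:
        raise ConfigError(
            f"need at least 2*batch_size={2 * config.batch_size} molecules, got {n}"
        )

    rng = np.random.default_rng(config.seed)
    model = _init_model(X.shape[1], config.hidden_dims, rng)

    # Adam state
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    mW = [np.zeros_like(W) for W in model.weights]
    vW = [np.zeros_like(W) for W in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    t = 0

    loss_trace: list[float] = []
    n_batches = n // config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for k in range(n_batches):
            batch = order[k * config.batch_size : (k + 1) * config.batch_size]
            Xb = X[batch]
            D = jaccard_distance_matrix(Xb)
            P = joint_affinities(
                conditional_affinity_matrix(
                    D, config.perplexity, config.entropy_tol, config.max_bisection_steps
                )
            )
            Y, cache = model.forward(Xb)
            Q = low_dim_affinities(Y)
            loss = kl_loss(P, Q)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {k}: "
                    "lower the learning rate or check input fingerprints"
                )
            epoch_losses.append(loss)

            # backprop: t-SNE gradient at the output, then through the layers
            delta = _tsne_output_gradient(Y, P)
            t += 1
            for layer in range(len(model.weights) - 1, -1, -1):
                A = cache[layer]
                gW = A.T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * (A > 0.0)
                for g, m, v, param in (
                    (gW, mW, vW, model.weights),
                    (gb, mb, vb, model.biases),
                ):
                    m[layer] = beta1 * m[layer] + (1 - beta1) * g
                    v[layer] = beta2 * v[layer] + (1 - beta2) * g * g
                    mhat = m[layer] / (1 - beta1 ** t)
                    vhat = v[layer] / (1 - beta2 ** t)
                    param[layer] -= config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        loss_trace.append(float(np.mean(epoch_losses)))

    model.training_meta = {
        "perplexity": config.perplexity,
        "seed": config.seed,
        "epochs": config.epochs,
        "batch_size": config.batch_size,
        "learning_rate": config.learning_rate,
        "final_loss": loss_trace[-1],
        "loss_trace": loss_trace,
    }
    return model


def project(model: EmbeddingModel, fingerprints: np.ndarray) -> np.ndarray:
    """Deterministic projection: a pure feed-forward pass, rows independent."""
    X = (np.atleast_2d(np.asarray(fingerprints)) != 0).astype(np.float64)
    Y, _ = model.forward(X)
    return Y


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EmbeddingModel, path) -> None:
    """Write the model as a versioned container of named arrays + JSON metadata."""
    arrays = {"format_version": np.array([MODEL_FORMAT_VERSION])}
    arrays["layer_dims"] = np.asarray(model.layer_dims)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {"activation": model.activation, "training_meta": model.training_meta}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:  # exact filename, no implicit .npz suffix
        np.savez(fh, **arrays)


def load_model(path) -> EmbeddingModel:
    """Load a saved model; corruption or version mismatch raises ModelFormatError."""
    try:
        with np.load(path) as data:
            version = int(data["format_version"][0])
            if version != MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"unsupported model format version {version} "
                    f"(this build reads version {MODEL_FORMAT_VERSION})"
                )
            layer_dims = [int(d) for d in data["layer_dims"]]
            n_layers = len(layer_dims) - 1
            weights = [np.array(data[f"W{i}"]) for i in range(n_layers)]
            biases = [np.array(data[f"b{i}"]) for i in range(n_layers)]
            meta = json.loads(bytes(data["meta_json"]).decode())
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"corrupted or unreadable model file {path}: {exc}") from exc
    for i, (W, fan_in, fan_out) in enumerate(zip(weights, layer_dims[:-1], layer_dims[1:])):
        if W.shape != (fan_in, fan_out):
            raise ModelFormatError(f"weight array W{i} has shape {W.shape}, expected {(fan_in, fan_out)}")
    return EmbeddingModel(
        layer_dims=layer_dims,
        weights=weights,
        biases=biases,
        activation=meta.get("activation", "relu"),
        training_meta=meta.get("training_meta", {}),
    )
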