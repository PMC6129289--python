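"""Supervised self-organizing map with a sigmoid perceptron output layer.

The network has three layers: the input feature vector, a rectangular SOM
grid of prototype vectors (the hidden layer), and two sigmoid perceptrons
fully connected to the grid, one per class (coding, non-coding).

Training proceeds in two stages:

1. the grid is initialized by classical unsupervised Kohonen learning
   (best-matching-unit search under the L2 norm, neighborhood updates with
   a Gaussian kernel over the Manhattan grid distance);
2. the whole network is then trained by backpropagation of a cross-entropy
   loss with an L2 penalty on the output weights, using a momentum
   optimizer ``w <- w - mu1 * (mu2 * acc + grad)`` whose accumulator is a
   geometrically decayed sum of past gradients (a raw running sum is
   available behind a flag but oscillates without settling).

During supervised training the activation of unit ``u`` for sample ``x``
is neighborhood-smoothed,

    a_u(x) = sum_{u'} exp(-1/2 ||x - w_u'||^2) * sigma_t(u', u),
    sigma_t(u', u) = exp(-d(u', u)^2 / (alpha * (1 - t/T) * r)),

so early iterations propagate credit across the map and the smoothing
vanishes as ``t -> T``.  At prediction time the neighborhood term is
dropped and each unit activates only on its own prototype,
``a'_u(x) = exp(-1/2 ||x - w_u||^2)``; the class is the argmax of the two
sigmoid outputs, with ties resolved to non-coding.

The backpropagated gradient for the prototype vectors routes the error
through the best matching unit only (a deliberate simplification of the
full derivative of the neighborhood-smoothed activation); the gradient
direction remains a descent direction in the regimes where the BMU term
dominates, which the unsupervised initialization promotes.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .features import FEATURE_LAYOUT_VERSION

__all__ = [
    "SomGrid",
    "OutputLayer",
    "TrainConfig",
    "MinMaxScaler",
    "SomModel",
    "som_init",
    "sigma_t",
    "forward_train",
    "loss",
    "gradients",
    "train",
    "predict",
]

_DECAY_FLOOR = 1e-8  # floor on (1 - t/T) so the kernel is defined at t=T-1


@dataclass
class SomGrid:
    """Rectangular, non-toroidal SOM grid with Manhattan topology.

    ``weights`` has shape (rows * cols, m); unit ``u`` sits at grid
    coordinates ``(u // cols, u % cols)``.  The map radius ``r`` used in
    neighborhood kernels is the maximum grid distance, rows + cols - 2.
    """

    rows: int
    cols: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("weights row count must equal rows * cols")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def radius(self) -> float:
        return float(max(self.rows + self.cols - 2, 1))

    def coordinates(self) -> np.ndarray:
        """(U, 2) array of (row, col) coordinates in unit-index order."""
        r, c = np.divmod(np.arange(self.n_units), self.cols)
        return np.stack([r, c], axis=1)

    def distance_matrix(self) -> np.ndarray:
        """U x U Manhattan distances between unit coordinates."""
        xy = self.coordinates()
        return np.abs(xy[:, None, :] - xy[None, :, :]).sum(axis=2).astype(float)


@dataclass
class OutputLayer:
    """Two sigmoid perceptrons fully connected to the grid units."""

    weights: np.ndarray  # (U, 2)
    biases: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 2:
            raise ValueError("output weights must have shape (U, 2)")
        if self.biases.shape != (2,):
            raise ValueError("biases must have shape (2,)")


@dataclass
class TrainConfig:
    """Hyperparameters of the supervised SOM.

    Defaults: 10 x 10 grid, neighborhood constant ``alpha`` = 0.5, L2
    weight ``lambda_reg`` = 0.001, batches of 100, learning rate ``mu1`` =
    0.05, momentum factor ``mu2`` = 0.25, at most 10 000 iterations (one
    iteration = one batch), stopping early when two consecutive batch
    losses differ by less than 1e-6.
    """

    rows: int = 10
    cols: int = 10
    alpha: float = 0.5
    lambda_reg: float = 0.001
    batch_size: int = 100
    mu1: float = 0.05
    mu2: float = 0.25
    max_iterations: int = 10_000
    loss_tolerance: float = 1e-6
    seed: int = 0
    scale: bool = True
    som_epochs: int = 10
    som_alpha_start: float = 0.5
    som_alpha_end: float = 0.01
    neighborhood_scale: float = 1.0
    momentum_mode: str = "decayed"  # "decayed" (geometric) or "sum" (raw sum)
    momentum_decay: float = 0.25  # only used when momentum_mode == "decayed"

    def __post_init__(self) -> None:
        for name in ("alpha", "lambda_reg", "batch_size", "mu2",
                     "max_iterations", "loss_tolerance", "neighborhood_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu1 < 0:
            raise ValueError("mu1 must be non-negative")
        if self.momentum_mode not in ("sum", "decayed"):
            raise ValueError("momentum_mode must be 'sum' or 'decayed'")


@dataclass
class MinMaxScaler:
    """Range-gated min-max scaling plus a global kernel-bandwidth factor.

    The unit activation kernel exp(-1/2 ||x - w||^2) has a fixed
    bandwidth, so the feature scale *is* the kernel bandwidth.  Fitting:

    1. features whose training range exceeds 1 (the unbounded ORF-length
       statistics) are min-max mapped to [0, 1]; frequency-type features
       keep their natural scale — stretching every k-mer frequency to
       [0, 1] would amplify ~1300 near-noise dimensions and drown the
       class signal in the distance geometry;
    2. all features are then divided by a single factor chosen by the
       median heuristic: the median squared pairwise distance between
       (up to 512) training samples is brought to 2, so a
       median-distance pair has kernel value exp(-1).
    """

    data_min: np.ndarray
    data_range: np.ndarray
    bandwidth: float = 1.0

    #: target median squared pairwise distance after scaling
    TARGET_MEDIAN_SQDIST = 2.0

    @classmethod
    def fit(cls, X: np.ndarray, max_pairs_sample: int = 512) -> "MinMaxScaler":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        gate = rng > 1.0
        lo = np.where(gate, lo, 0.0)
        rng = np.where(gate, rng, 1.0)
        Xs = (X - lo) / rng
        sub = Xs[:max_pairs_sample]  # deterministic leading slice
        if sub.shape[0] >= 2:
            d2 = cdist(sub, sub, metric="sqeuclidean")
            med = float(np.median(d2[np.triu_indices(sub.shape[0], k=1)]))
        else:
            med = 0.0
        bw = np.sqrt(med / cls.TARGET_MEDIAN_SQDIST) if med > 0 else 1.0
        return cls(data_min=lo, data_range=rng, bandwidth=float(bw))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.data_min) / self.data_range / self.bandwidth


@dataclass
class SomModel:
    """A trained (or initialized) supervised SOM ready for prediction."""

    grid: SomGrid
    out: OutputLayer
    config: TrainConfig
    scaler: Optional[MinMaxScaler] = None
    feature_layout_version: str = FEATURE_LAYOUT_VERSION
    loss_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stop_reason: str = "untrained"
    n_iterations: int = 0

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Write a deterministic zip archive (same model -> same bytes)."""
        arrays = {
            "W": self.grid.weights,
            "W_out": self.out.weights,
            "b": self.out.biases,
            "loss_trace": self.loss_trace,
        }
        if self.scaler is not None:
            arrays["scaler_min"] = self.scaler.data_min
            arrays["scaler_range"] = self.scaler.data_range
            arrays["scaler_bandwidth"] = np.array([self.scaler.bandwidth])
        meta = {
            "rows": self.grid.rows,
            "cols": self.grid.cols,
            "config": asdict(self.config),
            "feature_layout_version": self.feature_layout_version,
            "stop_reason": self.stop_reason,
            "n_iterations": self.n_iterations,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in sorted(arrays):
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())
            info = zipfile.ZipInfo("meta.json", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, json.dumps(meta, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path) -> "SomModel":
        path = Path(path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["feature_layout_version"] != FEATURE_LAYOUT_VERSION:
                raise ValueError(
                    f"model {path} was trained under feature layout "
                    f"{meta['feature_layout_version']!r}; this build uses "
                    f"{FEATURE_LAYOUT_VERSION!r}"
                )

            def arr(name):
                return np.lib.format.read_array(io.BytesIO(zf.read(name + ".npy")))

            scaler = None
            names = set(zf.namelist())
            if "scaler_min.npy" in names:
                scaler = MinMaxScaler(
                    arr("scaler_min"),
                    arr("scaler_range"),
                    float(np.ravel(arr("scaler_bandwidth"))[0]),
                )
            grid = SomGrid(meta["rows"], meta["cols"], arr("W"))
            out = OutputLayer(arr("W_out"), arr("b"))
            return cls(
                grid=grid,
                out=out,
                config=TrainConfig(**meta["config"]),
                scaler=scaler,
                feature_layout_version=meta["feature_layout_version"],
                loss_trace=arr("loss_trace"),
                stop_reason=meta["stop_reason"],
                n_iterations=meta["n_iterations"],
            )


# -- unsupervised initialization ----------------------------------------


def bmu(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Best matching unit per sample: argmin_u ||w_u - x|| (L2), ties to
    the lowest unit index."""
    d2 = cdist(np.atleast_2d(X), weights, metric="sqeuclidean")
    return d2.argmin(axis=1)


def som_init(
    X: np.ndarray,
    rows: int,
    cols: int,
    epochs: int,
    seed: int,
    alpha_start: float = 0.5,
    alpha_end: float = 0.01,
) -> SomGrid:
    """Classical unsupervised Kohonen pass used to initialize the grid.

    Prototypes start as small uniform noise around the feature mean.  One
    step processes one sample (shuffled once with the seed, then cycled):
    the BMU and its neighbors move toward the sample under a Gaussian
    kernel h_t = exp(-d(BMU, u)^2 / (r * (1 - t/T))) whose reach shrinks
    to zero over the run, with a linearly decaying learning rate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    rng = np.random.default_rng(seed)
    m = X.shape[1]
    center = X.mean(axis=0)
    weights = center + rng.uniform(-0.01, 0.01, size=(rows * cols, m))
    grid = SomGrid(rows, cols, weights)
    D2 = grid.distance_matrix() ** 2
    r = grid.radius

    order = rng.permutation(X.shape[0])
    total = epochs * X.shape[0]
    t = 0
    for _ in range(epochs):
        for i in order:
            frac = 1.0 - t / total
            alpha_t = alpha_end + (alpha_start - alpha_end) * frac
            x = X[i]
            u_star = int(
                np.argmin(((grid.weights - x) ** 2).sum(axis=1))
            )
            h = np.exp(-D2[u_star] / (r * max(frac, _DECAY_FLOOR)))
            grid.weights += alpha_t * h[:, None] * (x - grid.weights)
            t += 1
    return grid


# -- supervised network --------------------------------------------------


def sigma_t(
    u_prime: int, u: int, t: int, config: TrainConfig, grid: SomGrid
) -> float:
    """Neighborhood smoothing kernel between two units at iteration t."""
    d = grid.distance_matrix()[u_prime, u]
    return float(np.exp(-(d**2) / _sigma_denominator(t, config, grid)))


def _sigma_denominator(t: int, config: TrainConfig, grid: SomGrid) -> float:
    decay = max(1.0 - t / config.max_iterations, _DECAY_FLOOR)
    return config.alpha * decay * grid.radius * config.neighborhood_scale


def _sigma_matrix(t: int, config: TrainConfig, grid: SomGrid) -> np.ndarray:
    D2 = grid.distance_matrix() ** 2
    return np.exp(-D2 / _sigma_denominator(t, config, grid))


def _kernel(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """K[i, u] = exp(-1/2 ||x_i - w_u||^2)."""
    d2 = cdist(np.atleast_2d(X), weights, metric="sqeuclidean")
    return np.exp(-0.5 * d2)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward_train(
    X_batch: np.ndarray, model: "SomModel", t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Training-time forward pass.

    Returns the neighborhood-smoothed unit activations ``A`` (N x U) and
    the sigmoid perceptron outputs ``O`` (N x 2).
    """
    K = _kernel(X_batch, model.grid.weights)
    A = K @ _sigma_matrix(t, model.config, model.grid)
    act = A @ model.out.weights + model.out.biases
    return A, sigmoid(act)


def loss(Y: np.ndarray, O: np.ndarray, model: "SomModel") -> float:
    """Cross-entropy plus L2 penalty on the output weights.

    The cross-entropy is the standard form for independent sigmoid
    outputs, summed over both perceptrons:

        C = -(1/N) sum_i sum_l [ y_il ln o_il + (1 - y_il) ln(1 - o_il) ]

    (the one-sided variant without the ``(1 - y) ln(1 - o)`` term admits
    a degenerate optimum where both outputs saturate at 1 through the
    biases and the classifier cannot discriminate at all).  Outputs are
    clipped to [1e-12, 1 - 1e-12] before the log, so the loss is finite
    and non-negative.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != O.shape:
        raise ValueError("Y and O must have the same shape")
    Oc = np.clip(O, 1e-12, 1.0 - 1e-12)
    ce = -(Y * np.log(Oc) + (1.0 - Y) * np.log(1.0 - Oc)).sum() / Y.shape[0]
    reg = model.config.lambda_reg * float((model.out.weights**2).sum())
    return float(ce + reg)


def gradients(
    X_batch: np.ndarray,
    Y_batch: np.ndarray,
    model: "SomModel",
    t: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the loss for one batch.

    Returns ``(grad_W_out, grad_b, grad_W_som)``.  With the sigmoid
    derivative folded in, the per-sample error signal is
    ``y_il - o_il``, and the output-weight and bias gradients are exact:

        dL/dw_ul = -(1/N) sum_i (y_il - o_il) a_iu + 2 lambda w_ul
        dL/db_l  = -(1/N) sum_i (y_il - o_il)

    The prototype gradient routes the error through each sample's best
    matching unit only:

        dL/dw_u = -(1/N) sum_i [sum_l (y_il - o_il)]
                  * sigma_t(BMU(x_i), u) * exp(-1/2 ||x_i - w_u||^2)
                  * (x_i - w_u)
    """
    X_batch = np.atleast_2d(np.asarray(X_batch, dtype=float))
    Y_batch = np.atleast_2d(np.asarray(Y_batch, dtype=float))
    N = X_batch.shape[0]
    W = model.grid.weights
    K = _kernel(X_batch, W)
    Sigma = _sigma_matrix(t, model.config, model.grid)
    A = K @ Sigma
    O = sigmoid(A @ model.out.weights + model.out.biases)
    Oc = np.clip(O, 1e-12, 1.0 - 1e-12)

    resid = Y_batch - Oc  # y_il - o_il
    grad_W_out = -(A.T @ resid) / N + 2.0 * model.config.lambda_reg * model.out.weights
    grad_b = -resid.sum(axis=0) / N

    bmus = K.argmax(axis=1)  # argmax of the kernel == argmin distance
    s = resid.sum(axis=1)  # per-sample error mass
    C = s[:, None] * Sigma[bmus, :] * K  # (N, U)
    grad_W_som = -(C.T @ X_batch - C.sum(axis=0)[:, None] * W) / N
    return grad_W_out, grad_b, grad_W_som


def train(
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig,
) -> SomModel:
    """Train a supervised SOM on a labeled feature matrix.

    The grid is initialized by :func:`som_init`, then the network runs
    mini-batch gradient descent with the momentum rule
    ``w <- w - mu1 * (mu2 * acc_w + grad)`` where ``acc_w`` accumulates
    past gradients (geometrically decayed by default, a raw sum behind
    ``momentum_mode="sum"``).  One iteration consumes one batch, taken as
    sequential slices of a seed-shuffled order, cycling.  Training stops
    at ``max_iterations`` or as soon as two consecutive batch losses
    differ by less than ``loss_tolerance``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if Y.shape != (X.shape[0], 2):
        raise ValueError("Y must have shape (n_samples, 2)")
    if not np.all(Y.sum(axis=1) == 1) or not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y rows must be one-hot")
    if Y[:, 0].sum() == 0 or Y[:, 1].sum() == 0:
        warnings.warn("training labels contain a single class", stacklevel=2)

    scaler = MinMaxScaler.fit(X) if config.scale else None
    Xs = scaler.transform(X) if scaler is not None else X

    grid = som_init(
        Xs,
        config.rows,
        config.cols,
        epochs=config.som_epochs,
        seed=config.seed,
        alpha_start=config.som_alpha_start,
        alpha_end=config.som_alpha_end,
    )
    rng = np.random.default_rng(config.seed + 1)
    out = OutputLayer(
        weights=rng.uniform(-0.01, 0.01, size=(grid.n_units, 2)),
        biases=np.zeros(2),
    )
    model = SomModel(grid=grid, out=out, config=config, scaler=scaler)

    n = Xs.shape[0]
    order = rng.permutation(n)
    acc = [np.zeros_like(out.weights), np.zeros(2), np.zeros_like(grid.weights)]
    trace = []
    prev_loss = None
    stop_reason = "max_iterations"
    pos = 0
    it = 0
    for it in range(config.max_iterations):
        take = order[pos : pos + config.batch_size]
        pos += config.batch_size
        if pos >= n:
            pos = 0
        if take.size == 0:
            continue
        Xb, Yb = Xs[take], Y[take]
        grads = gradients(Xb, Yb, model, it)
        params = [out.weights, out.biases, grid.weights]
        for p, g, a in zip(params, grads, acc):
            p -= config.mu1 * (config.mu2 * a + g)
            if config.momentum_mode == "sum":
                a += g
            else:
                a *= config.momentum_decay
                a += g
        _, O = forward_train(Xb, model, it)
        cur = loss(Yb, O, model)
        trace.append(cur)
        if prev_loss is not None and abs(cur - prev_loss) < config.loss_tolerance:
            stop_reason = "loss_tolerance"
            it += 1
            break
        prev_loss = cur
    else:
        it = config.max_iterations

    model.loss_trace = np.array(trace)
    model.stop_reason = stop_reason
    model.n_iterations = it
    return model


def predict(
    X: np.ndarray, model: SomModel
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Prediction-time forward pass (no neighborhood smoothing).

    Each unit activates only on its own prototype,
    ``a'_iu = exp(-1/2 ||x_i - w_u||^2)``; the class is coding when
    ``o_coding > o_noncoding``, non-coding otherwise (ties included).

    Returns
    -------
    O : (n, 2) sigmoid outputs (coding, noncoding)
    bmus : (n, 2) grid coordinates of each sample's best matching unit
    classes : list of "coding"/"noncoding" strings
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.grid.weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"({model.grid.weights.shape[1]})"
        )
    Xs = model.scaler.transform(X) if model.scaler is not None else X
    Kp = _kernel(Xs, model.grid.weights)
    O = sigmoid(Kp @ model.out.weights + model.out.biases)
    units = Kp.argmax(axis=1)
    coords = model.grid.coordinates()[units]
    classes = ["coding" if o0 > o1 else "noncoding" for o0, o1 in O]
    return O, coords, classes
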