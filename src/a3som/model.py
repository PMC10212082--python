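"""The A3SOM model: a self-organizing map feeding a dense block, trained
semi-supervised with a joint cross-entropy + distortion loss.

Architecture
------------
A sample ``x`` is propagated through:

1. the SOM layer, whose output is the vector of Euclidean distances from
   ``x`` to every prototype (one per map unit);
2. ``B`` fully-connected ReLU layers;
3. an output layer with one neuron per class and either a softmax head
   (standard, mutually-exclusive classification) or a sigmoid head
   (independent per-class probabilities, required for abstention).

Loss
----
    L = CE(Y_L, Yhat_L) + gamma * D(X, U) + eta * ||w||^2

``CE`` is the cross-entropy summed over the labeled samples only (softmax
head: -sum y ln yhat; sigmoid head: the one-vs-all binary cross-entropy).
``D`` is the SOM distortion over ALL samples, labeled and unlabeled — this
is where the unlabeled data shapes the model. ``||w||^2`` is the squared L2
norm of the dense-block weights. Gradients flow into both the dense block
and the prototypes; the BMU assignment is held fixed within a step (no
gradient through the argmin). An alternative ``analytic_batch`` mode trains
only the dense block by gradient and refreshes the prototypes after each
epoch with the classic batch-SOM update.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .som import (
    SOMGrid,
    NeighborhoodState,
    activation,
    batch_update,
    distortion,
    neighborhood_matrix,
    prototypes_from_csv,
    prototypes_to_csv,
)
from .datasets import SemiLabeledDataset

__all__ = [
    "TrainingConfig",
    "LossBreakdown",
    "ModelParams",
    "A3SOM",
    "A3SOMResults",
    "forward",
    "cross_entropy",
    "total_loss",
]

_EPS = 1e-7  # probability clip before logs


@dataclass
class TrainingConfig:
    """Knobs of the training loop.

    gamma weighs the distortion term, eta the L2 penalty; both default to
    values that keep all three loss terms active on unit-scaled data. The
    neighborhood radius decays exponentially per optimizer step from
    ``sigma_initial`` (default max(height, width)/2) to ``sigma_final``.
    """

    gamma: float = 1.0
    eta: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "sgd"  # "sgd" | "adam"
    som_update_mode: str = "gradient"  # "gradient" | "analytic_batch"
    sigma_initial: float | None = None
    sigma_final: float = 0.5

    def __post_init__(self):
        if self.gamma < 0 or self.eta < 0:
            raise ValueError("gamma and eta must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.som_update_mode not in ("gradient", "analytic_batch"):
            raise ValueError(f"unknown som_update_mode {self.som_update_mode!r}")


@dataclass
class LossBreakdown:
    """Additive decomposition of the training loss."""

    ce: float
    distortion: float
    l2: float
    gamma: float
    eta: float

    @property
    def total(self) -> float:
        return self.ce + self.gamma * self.distortion + self.eta * self.l2


@dataclass
class ModelParams:
    """All trainable parameters plus the fixed architecture description."""

    grid: SOMGrid
    prototypes: np.ndarray  # (U, m)
    weights: list  # dense-block weight matrices, incl. output layer (last)
    biases: list  # matching bias vectors
    head: str  # "softmax" | "sigmoid"

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[1]

    def dense_l2(self) -> float:
        """Squared L2 norm of the dense-block weights (biases excluded)."""
        return float(sum(np.sum(W**2) for W in self.weights))

    def copy(self) -> "ModelParams":
        return ModelParams(
            grid=self.grid,
            prototypes=self.prototypes.copy(),
            weights=[W.copy() for W in self.weights],
            biases=[b.copy() for b in self.biases],
            head=self.head,
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cached(X: np.ndarray, params: ModelParams):
    """Forward pass keeping intermediate activations for backprop."""
    A = activation(np.atleast_2d(X), params.prototypes)
    hs = [A]
    h = A
    for W, b in zip(params.weights[:-1], params.biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        hs.append(h)
    z = h @ params.weights[-1] + params.biases[-1]
    P = _softmax(z) if params.head == "softmax" else _sigmoid(z)
    return A, hs, z, P


def forward(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Class-membership probabilities for each row of X.

    Softmax rows sum to 1; sigmoid entries are independent probabilities in
    (0, 1) whose rows need not sum to 1.
    """
    return _forward_cached(X, params)[3]


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray, head: str = "softmax") -> float:
    """Cross-entropy summed (not averaged) over the given labeled rows.

    ``y_true`` holds one-hot rows; predictions are clipped to
    [eps, 1 - eps] before the logs. With a sigmoid head the one-vs-all
    binary cross-entropy is used, so wrong-class outputs are driven down as
    well — without that pressure the independent sigmoid outputs would all
    drift to 1 and confidence-based abstention would be meaningless.
    """
    y_true = np.atleast_2d(y_true)
    y_pred = np.atleast_2d(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    if y_true.shape[0] == 0:
        warnings.warn("no labeled samples: cross-entropy is 0 (distortion-only)")
        return 0.0
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    if head == "softmax":
        return float(-np.sum(y_true * np.log(p)))
    return float(-np.sum(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def total_loss(
    dataset: SemiLabeledDataset,
    params: ModelParams,
    gamma: float = 1.0,
    eta: float = 1e-4,
    sigma: float = 0.5,
) -> LossBreakdown:
    """Full-dataset loss breakdown at a given neighborhood radius.

    Cross-entropy covers labeled rows only; distortion covers every row.
    """
    P = forward(dataset.X, params)
    lab = dataset.labeled_mask
    if lab.any():
        ce = cross_entropy(dataset.one_hot()[lab], P[lab], head=params.head)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ce = 0.0
    D = distortion(dataset.X, params.prototypes, params.grid, sigma)
    return LossBreakdown(ce=ce, distortion=D, l2=params.dense_l2(),
                         gamma=gamma, eta=eta)


# ---------------------------------------------------------------------------
# Optimizers

class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Model / Results

class A3SOM:
    """Semi-supervised SOM-based classifier (model object).

    Parameters
    ----------
    data : SemiLabeledDataset or array-like
        Training data. Arrays need ``y`` (with -1 for unlabeled) and, if not
        all classes appear among the labels, ``class_count``.
    map_shape : (height, width) of the SOM grid.
    hidden_layers : widths of the ReLU layers between the SOM and the output.
    head : "softmax" for standard classification, "sigmoid" for the abstained
        task. The head is chosen before training; abstention itself is
        applied post hoc to the trained model's outputs.

    Examples
    --------
    >>> from a3som import A3SOM, generate_artificial
    >>> res = A3SOM(generate_artificial(), map_shape=(8, 8)).fit(epochs=20)
    >>> labels, probs, bmus = res.predict()
    """

    def __init__(
        self,
        data,
        y=None,
        class_count: int | None = None,
        map_shape: tuple[int, int] = (8, 8),
        hidden_layers: tuple[int, ...] = (32,),
        head: str = "softmax",
        feature_names: list[str] | None = None,
    ):
        if isinstance(data, SemiLabeledDataset):
            self.dataset = data
        else:
            X = np.asarray(data, dtype=float)
            y = np.asarray(y, dtype=int)
            if class_count is None:
                class_count = int(y.max()) + 1
            self.dataset = SemiLabeledDataset(
                X=X, y=y, class_count=class_count, feature_names=feature_names
            )
        if self.dataset.class_count < 2:
            raise ValueError("classification needs at least 2 classes")
        if head not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown head {head!r}")
        if self.dataset.n_labeled == 0:
            warnings.warn("dataset has no labeled samples; training will be "
                          "distortion-only")
        self.grid = SOMGrid(*map_shape)
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.head = head
        self._results: "A3SOMResults | None" = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        y = df[label_col].to_numpy(dtype=int)
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        names = [c for c in df.columns if c != label_col]
        return cls(X, y=y, feature_names=names, **kwargs)

    # -- initialization ----------------------------------------------------

    def _init_prototypes(self) -> np.ndarray:
        """Deterministic PCA-plane initialization: the grid spans the first
        two principal axes of the data, scaled to two standard deviations."""
        X = self.dataset.X
        mean = X.mean(axis=0)
        Xc = X - mean
        _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        n_pc = min(2, Vt.shape[0])
        sd = S[:n_pc] / np.sqrt(max(X.shape[0] - 1, 1))
        h, w = self.grid.height, self.grid.width
        r = self.grid.coords[:, 0] / max(h - 1, 1) * 2.0 - (1.0 if h > 1 else 0.0)
        c = self.grid.coords[:, 1] / max(w - 1, 1) * 2.0 - (1.0 if w > 1 else 0.0)
        axes = (r, c) if h >= w else (c, r)
        W = np.tile(mean, (self.grid.n_units, 1))
        for k in range(n_pc):
            W += np.outer(axes[k], 2.0 * sd[k] * Vt[k])
        return W

    def _init_params(self, rng: np.random.Generator) -> ModelParams:
        widths = [self.grid.n_units, *self.hidden_layers, self.dataset.class_count]
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return ModelParams(
            grid=self.grid,
            prototypes=self._init_prototypes(),
            weights=weights,
            biases=biases,
            head=self.head,
        )

    # -- training ----------------------------------------------------------

    def fit(self, config: TrainingConfig | None = None, **overrides) -> "A3SOMResults":
        """Mini-batch gradient descent on the joint loss.

        Returns an :class:`A3SOMResults` carrying the trained parameters and
        the per-epoch loss log. Deterministic for a fixed seed.
        """
        if config is None:
            config = TrainingConfig(**overrides)
        elif overrides:
            config = TrainingConfig(**{**asdict(config), **overrides})
        ds = self.dataset
        rng = np.random.default_rng(config.seed)
        params = self._init_params(rng)

        sigma_init = config.sigma_initial
        if sigma_init is None:
            sigma_init = max(self.grid.height, self.grid.width) / 2.0
        nb = NeighborhoodState(
            sigma=sigma_init, sigma_initial=sigma_init, sigma_final=config.sigma_final
        )

        N = ds.n_samples
        bs = min(config.batch_size, N)
        n_batches = int(np.ceil(N / bs))
        total_steps = config.epochs * n_batches
        Y = ds.one_hot()
        lab = ds.labeled_mask

        opt = (_Adam(config.learning_rate) if config.optimizer == "adam"
               else _SGD(config.learning_rate))
        train_som_by_gradient = config.som_update_mode == "gradient"

        history = []
        step = 0
        sigma = nb.at_step(0, total_steps)
        for epoch in range(config.epochs):
            order = rng.permutation(N)
            for start in range(0, N, bs):
                idx = order[start:start + bs]
                Xb, Yb, labb = ds.X[idx], Y[idx], lab[idx]
                n = Xb.shape[0]
                sigma = nb.at_step(step, total_steps)

                A, hs, z, P = _forward_cached(Xb, params)
                bmu_idx = np.argmin(A, axis=1)
                Hmat = neighborhood_matrix(self.grid, sigma)[bmu_idx]

                # dCE/dz = P - Y on labeled rows (holds for both softmax-CE
                # and sigmoid-BCE), zero on unlabeled rows.
                dZ = P - Yb
                dZ[~labb] = 0.0

                grads_W, grads_b = [], []
                delta = dZ
                for j in range(len(params.weights) - 1, -1, -1):
                    grads_W.append(hs[j].T @ delta + 2.0 * config.eta * params.weights[j])
                    grads_b.append(delta.sum(axis=0))
                    if j > 0:
                        delta = (delta @ params.weights[j].T) * (hs[j] > 0)
                grads_W.reverse()
                grads_b.reverse()

                tensors = params.weights + params.biases
                grads = grads_W + grads_b

                if train_som_by_gradient:
                    # CE path into prototypes through the distance activation.
                    dH0 = dZ
                    for j in range(len(params.weights) - 1, 0, -1):
                        dH0 = (dH0 @ params.weights[j].T) * (hs[j] > 0)
                    dH0 = dH0 @ params.weights[0].T  # (n, U) = dCE/dA
                    safe = np.where(A > 1e-12, A, np.inf)
                    S = dH0 / safe
                    gP = S.sum(axis=0)[:, None] * params.prototypes - S.T @ Xb
                    # distortion path (BMU and sigma fixed within the step)
                    gP += (2.0 * config.gamma / n) * (
                        Hmat.sum(axis=0)[:, None] * params.prototypes - Hmat.T @ Xb
                    )
                    tensors = tensors + [params.prototypes]
                    grads = grads + [gP]

                opt.step(tensors, grads)
                step += 1

            if not train_som_by_gradient:
                A_full = activation(ds.X, params.prototypes)
                params.prototypes = batch_update(
                    params.prototypes, ds.X, np.argmin(A_full, axis=1),
                    self.grid, sigma,
                )

            lb = total_loss(ds, params, gamma=config.gamma, eta=config.eta,
                            sigma=sigma)
            if not np.isfinite(lb.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: ce={lb.ce}, "
                    f"distortion={lb.distortion}, l2={lb.l2} "
                    f"(try a smaller learning rate)"
                )
            history.append(
                {"epoch": epoch, "ce": lb.ce, "distortion": lb.distortion,
                 "l2": lb.l2, "total": lb.total, "sigma": sigma}
            )

        results = A3SOMResults(
            model=self,
            params=params,
            config=config,
            history=pd.DataFrame(history),
        )
        self._results = results
        return results

    def predict(self, X: np.ndarray | None = None):
        if self._results is None:
            raise RuntimeError("model has not been fit; call .fit() first")
        return self._results.predict(X)


class A3SOMResults:
    """Trained A3SOM parameters, loss history, predictions and diagnostics."""

    def __init__(self, model: A3SOM | None, params: ModelParams,
                 config: TrainingConfig, history: pd.DataFrame):
        self.model = model
        self.params = params
        self.config = config
        self.history = history

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self._resolve_X(X)
        return forward(X, self.params)

    def predict(self, X: np.ndarray | None = None):
        """Labels (argmax; ties -> lowest class index), probabilities and
        BMU indices for each sample. The BMU localizes the sample on the map
        and anchors the prototype-based explanation."""
        X = self._resolve_X(X)
        P = forward(X, self.params)
        A = activation(X, self.params.prototypes)
        return np.argmax(P, axis=1), P, np.argmin(A, axis=1)

    def _resolve_X(self, X) -> np.ndarray:
        if X is None:
            if self.model is None:
                raise ValueError("no training data attached; pass X explicitly")
            return self.model.dataset.X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.params.n_features:
            raise ValueError(
                f"expected {self.params.n_features} features, got {X.shape[1]}"
            )
        return X

    # -- abstention hooks ---------------------------------------------------

    def calibrate_thresholds(self, mode: str = "both"):
        """Mean-based per-class thresholds from the training-set predictions."""
        from .abstention import calibrate_thresholds

        return calibrate_thresholds(self.predict_proba(), mode=mode)

    def abstain(self, X: np.ndarray | None = None, thresholds=None):
        from .abstention import apply_abstention

        if thresholds is None:
            thresholds = self.calibrate_thresholds()
        return apply_abstention(self.predict_proba(X), thresholds)

    # -- reporting ----------------------------------------------------------

    def final_loss(self) -> LossBreakdown:
        row = self.history.iloc[-1]
        return LossBreakdown(ce=row["ce"], distortion=row["distortion"],
                             l2=row["l2"], gamma=self.config.gamma,
                             eta=self.config.eta)

    def training_accuracy(self) -> float:
        """Accuracy on the labeled part of the training data."""
        ds = self.model.dataset
        lab = ds.labeled_mask
        if not lab.any():
            return float("nan")
        labels, _, _ = self.predict(ds.X[lab])
        return float(np.mean(labels == ds.y[lab]))

    def summary(self) -> str:
        p = self.params
        g = p.grid
        ds = self.model.dataset if self.model is not None else None
        lines = [
            "A3SOM Results",
            "=" * 58,
            f"{'Map size:':<28}{g.height} x {g.width} ({g.n_units} units)",
            f"{'Dense layers:':<28}{[W.shape[1] for W in p.weights[:-1]]}",
            f"{'Classes:':<28}{p.n_classes}",
            f"{'Output head:':<28}{p.head}",
            f"{'Optimizer:':<28}{self.config.optimizer} "
            f"(lr={self.config.learning_rate})",
            f"{'SOM update mode:':<28}{self.config.som_update_mode}",
            f"{'gamma (distortion wt):':<28}{self.config.gamma}",
            f"{'eta (L2 wt):':<28}{self.config.eta}",
            f"{'Epochs:':<28}{self.config.epochs}",
            f"{'Seed:':<28}{self.config.seed}",
        ]
        if ds is not None:
            lines += [
                f"{'Samples (labeled):':<28}{ds.n_samples} ({ds.n_labeled})",
                f"{'Features:':<28}{ds.n_features}",
            ]
        lb = self.final_loss()
        lines += [
            "-" * 58,
            f"{'Final cross-entropy:':<28}{lb.ce:.6g}",
            f"{'Final distortion:':<28}{lb.distortion:.6g}",
            f"{'Final L2:':<28}{lb.l2:.6g}",
            f"{'Final total loss:':<28}{lb.total:.6g}",
        ]
        if ds is not None and ds.n_labeled:
            lines.append(f"{'Training accuracy:':<28}{self.training_accuracy():.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: zip archive with prototype CSV, dense weights (npz)
        and a JSON metadata block."""
        feature_names = None
        if self.model is not None:
            feature_names = self.model.dataset.feature_names
        proto_buf = _io.StringIO()
        prototypes_to_csv(proto_buf, self.params.grid, self.params.prototypes,
                          feature_names)
        npz_buf = _io.BytesIO()
        arrays = {}
        for j, (W, b) in enumerate(zip(self.params.weights, self.params.biases)):
            arrays[f"W{j}"] = W
            arrays[f"b{j}"] = b
        np.savez(npz_buf, **arrays)
        meta = {
            "map_shape": [self.params.grid.height, self.params.grid.width],
            "n_dense_layers": len(self.params.weights),
            "n_classes": self.params.n_classes,
            "head": self.params.head,
            "config": asdict(self.config),
            "feature_names": feature_names,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("prototypes.csv", proto_buf.getvalue())
            zf.writestr("weights.npz", npz_buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=2))
        hist_buf = _io.StringIO()
        self.history.to_csv(hist_buf, index=False)
        with zipfile.ZipFile(path, "a") as zf:
            zf.writestr("history.csv", hist_buf.getvalue())

    @classmethod
    def load(cls, path) -> "A3SOMResults":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            grid, prototypes, _ = prototypes_from_csv(
                _io.StringIO(zf.read("prototypes.csv").decode())
            )
            npz = np.load(_io.BytesIO(zf.read("weights.npz")))
            weights = [npz[f"W{j}"] for j in range(meta["n_dense_layers"])]
            biases = [npz[f"b{j}"] for j in range(meta["n_dense_layers"])]
            history = pd.read_csv(_io.BytesIO(zf.read("history.csv")))
        params = ModelParams(grid=grid, prototypes=prototypes, weights=weights,
                             biases=biases, head=meta["head"])
        return cls(model=None, params=params,
                   config=TrainingConfig(**meta["config"]), history=history)
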