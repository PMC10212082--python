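"""Semi-labeled datasets and synthetic generators.

Two generators cover the package's study conditions without any downloads:

* :func:`generate_artificial` — a 2-D, 6-class benchmark (three Gaussian
  clusters, three uniform boxes) with a graded ambiguity structure: the three
  boxes overlap each other pairwise, one box reaches into a Gaussian's
  high-density region, one Gaussian sits close to (but separable from) a box,
  and one Gaussian is far from everything. The well-separated cluster is the
  natural "hidden class" for new-class-discovery experiments.
* :func:`generate_expression` — a PAM50-like bulk expression table: 50
  features, 4 breast-cancer subtypes (LumA, LumB, Her2, Basal) whose four
  marker features follow the expected clinical signature (Luminals high
  ESR1/PGR, Her2 high ERBB2, LumB above LumA on MKI67, Basal low on
  ESR1/PGR/ERBB2 — the "triple-negative"-like pattern).

Label-masking utilities implement the semi-supervised protocol: unlabeled
samples carry the sentinel ``-1``, and an entire class can be hidden so the
model must discover it via abstention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SemiLabeledDataset",
    "ArtificialSpec",
    "ExpressionSpec",
    "generate_artificial",
    "generate_expression",
    "mask_labels",
    "hide_class",
    "train_test_split_dataset",
]

UNLABELED = -1


@dataclass
class SemiLabeledDataset:
    """Feature matrix plus partially-observed integer labels.

    ``y`` uses the sentinel ``-1`` for unlabeled samples. ``y_full`` retains
    the ground-truth labels from before any masking/hiding, for evaluation
    only — training code must never read it.
    """

    X: np.ndarray
    y: np.ndarray
    class_count: int
    feature_names: list[str] | None = None
    class_names: list[str] | None = None
    y_full: np.ndarray | None = None
    #: original label -> training label after hide_class (identity otherwise)
    label_map: dict[int, int] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("X and y length mismatch")
        valid = (self.y == UNLABELED) | ((self.y >= 0) & (self.y < self.class_count))
        if not np.all(valid):
            raise ValueError("labels must be -1 or in [0, class_count)")
        if self.y_full is None:
            self.y_full = self.y.copy()

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != UNLABELED

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labeled_mask))

    def one_hot(self) -> np.ndarray:
        """(N, C) one-hot of the labels; unlabeled rows are all-zero."""
        Y = np.zeros((self.n_samples, self.class_count))
        lab = self.labeled_mask
        Y[np.where(lab)[0], self.y[lab]] = 1.0
        return Y

    def subset(self, idx: np.ndarray) -> "SemiLabeledDataset":
        return replace(
            self,
            X=self.X[idx],
            y=self.y[idx],
            y_full=None if self.y_full is None else self.y_full[idx],
        )


# ---------------------------------------------------------------------------
# Artificial 2-D benchmark

#: Gaussian components (mean, covariance) for classes 0, 1, 2.
_DEFAULT_GAUSSIANS = (
    (np.array([0.15, 0.82]), np.diag([0.04**2, 0.04**2])),  # class 0: near box 3
    (np.array([0.92, 0.92]), np.diag([0.03**2, 0.03**2])),  # class 1: isolated
    (np.array([0.73, 0.21]), np.diag([0.05**2, 0.05**2])),  # class 2: under box 5
)

#: Axis-aligned boxes (xmin, xmax, ymin, ymax) for classes 3, 4, 5. The 3-4
#: overlap strip is wide enough that a linear classifier cannot separate the
#: pair above ~0.93; the 4-5 strip and the box-5/Gaussian-2 intersection are
#: narrower, keeping the overall Bayes accuracy near 0.96.
_DEFAULT_BOXES = (
    (0.05, 0.33, 0.38, 0.62),  # class 3
    (0.285, 0.565, 0.36, 0.60),  # class 4, overlaps 3
    (0.545, 0.825, 0.30, 0.56),  # class 5, overlaps 4 and reaches class 2
)


@dataclass
class ArtificialSpec:
    """Parameters of the artificial 2-D benchmark.

    Defaults: 3000 points, 6 balanced classes — Gaussians 0/1/2 and uniform
    boxes 3/4/5 laid out so that 3-4 and 4-5 overlap (ambiguous strips of
    equal density), box 5 intersects Gaussian 2's high-density region,
    Gaussian 0 sits just above box 3 (close but separable), and Gaussian 1 is
    far from every other component.
    """

    n_total: int = 3000
    gaussian_components: tuple = _DEFAULT_GAUSSIANS
    uniform_components: tuple = _DEFAULT_BOXES
    seed: int = 0
    normalize: bool = True


def _minmax(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def _class_sizes(n_total: int, n_classes: int) -> np.ndarray:
    sizes = np.full(n_classes, n_total // n_classes, dtype=int)
    rem = n_total - sizes.sum()
    if rem:
        warnings.warn(
            f"n_total={n_total} not divisible by {n_classes}; "
            f"distributing remainder to the lowest class indices"
        )
        sizes[:rem] += 1
    return sizes


def generate_artificial(spec: ArtificialSpec | None = None) -> SemiLabeledDataset:
    """Draw the artificial 2-D 6-class dataset. Pure function of spec+seed."""
    spec = spec or ArtificialSpec()
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.gaussian_components) + len(spec.uniform_components)
    sizes = _class_sizes(spec.n_total, n_classes)

    parts, labels = [], []
    for c, (mean, cov) in enumerate(spec.gaussian_components):
        parts.append(rng.multivariate_normal(mean, cov, size=sizes[c]))
        labels.append(np.full(sizes[c], c))
    off = len(spec.gaussian_components)
    for j, (xmin, xmax, ymin, ymax) in enumerate(spec.uniform_components):
        c = off + j
        pts = np.column_stack(
            [
                rng.uniform(xmin, xmax, size=sizes[c]),
                rng.uniform(ymin, ymax, size=sizes[c]),
            ]
        )
        parts.append(pts)
        labels.append(np.full(sizes[c], c))

    X = np.vstack(parts)
    y = np.concatenate(labels).astype(int)
    perm = rng.permutation(X.shape[0])
    X, y = X[perm], y[perm]
    if spec.normalize:
        X = _minmax(X)
    return SemiLabeledDataset(
        X=X, y=y, class_count=n_classes,
        feature_names=["x1", "x2"],
        class_names=[str(c) for c in range(n_classes)],
    )


# ---------------------------------------------------------------------------
# PAM50-like expression stand-in

_SUBTYPES = ("LumA", "LumB", "Her2", "Basal")
_MARKERS = ("ESR1_like", "PGR_like", "ERBB2_like", "MKI67_like")

#: Marker signature means per subtype (rows: markers, cols: LumA/LumB/Her2/Basal).
#: Luminals high on ESR1/PGR; Her2 high on ERBB2; LumB > LumA on MKI67;
#: Basal low on the first three markers (triple-negative-like).
_DEFAULT_SIGNATURE = {
    "ESR1_like": (0.80, 0.80, 0.20, 0.15),
    "PGR_like": (0.75, 0.70, 0.20, 0.15),
    "ERBB2_like": (0.25, 0.25, 0.85, 0.30),
    "MKI67_like": (0.25, 0.55, 0.35, 0.50),
}


@dataclass
class ExpressionSpec:
    """Parameters of the synthetic PAM50-like expression table.

    A 50-feature table: 4 named marker roles carrying the subtype signature
    plus 46 background features with mild subtype-specific offsets. This is a
    synthetic stand-in for a curated bulk-transcriptomics cohort; values are
    min-max normalized to [0, 1] like a preprocessed expression matrix.
    """

    n_per_subtype: int = 150
    feature_count: int = 50
    signature: dict = field(default_factory=lambda: dict(_DEFAULT_SIGNATURE))
    noise_scale: float = 0.12
    seed: int = 0
    normalize: bool = True


def generate_expression(spec: ExpressionSpec | None = None) -> SemiLabeledDataset:
    """Draw the synthetic expression dataset. Pure function of spec+seed."""
    spec = spec or ExpressionSpec()
    if spec.feature_count < len(_MARKERS):
        raise ValueError("feature_count must cover the marker features")
    rng = np.random.default_rng(spec.seed)
    n_sub = len(_SUBTYPES)
    n_bg = spec.feature_count - len(_MARKERS)

    # Background features: per-(subtype, feature) means drawn once from the
    # spec seed — mild, unstructured subtype signal as real cohorts show.
    bg_means = rng.uniform(0.35, 0.65, size=(n_sub, n_bg))

    means = np.zeros((n_sub, spec.feature_count))
    for j, marker in enumerate(_MARKERS):
        means[:, j] = spec.signature[marker]
    means[:, len(_MARKERS):] = bg_means

    blocks, labels = [], []
    for s in range(n_sub):
        block = means[s] + rng.normal(
            0.0, spec.noise_scale, size=(spec.n_per_subtype, spec.feature_count)
        )
        blocks.append(block)
        labels.append(np.full(spec.n_per_subtype, s))
    X = np.clip(np.vstack(blocks), 0.0, 1.0)
    y = np.concatenate(labels).astype(int)
    perm = rng.permutation(X.shape[0])
    X, y = X[perm], y[perm]
    if spec.normalize and spec.noise_scale > 0:
        X = _minmax(X)
    names = list(_MARKERS) + [f"bg_{j:02d}" for j in range(1, n_bg + 1)]
    return SemiLabeledDataset(
        X=X, y=y, class_count=n_sub,
        feature_names=names, class_names=list(_SUBTYPES),
    )


# ---------------------------------------------------------------------------
# Label masking

def mask_labels(
    dataset: SemiLabeledDataset,
    fraction: float,
    seed: int = 0,
    stratified: bool = False,
) -> SemiLabeledDataset:
    """Replace ``round(fraction * n_labeled)`` labels with the -1 sentinel.

    Masked indices are drawn uniformly at random (per seed) from the
    currently-labeled samples; with ``stratified=True`` at least one label
    per class is kept whenever possible. X is never altered.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labeled_idx = np.where(dataset.labeled_mask)[0]
    n_mask = int(round(fraction * labeled_idx.size))
    if n_mask == 0:
        return replace(dataset, y=dataset.y.copy())

    if stratified:
        keep: list[int] = []
        for c in np.unique(dataset.y[labeled_idx]):
            members = labeled_idx[dataset.y[labeled_idx] == c]
            keep.append(rng.choice(members))
        pool = np.setdiff1d(labeled_idx, np.array(keep))
        n_mask = min(n_mask, pool.size)
        chosen = rng.choice(pool, size=n_mask, replace=False)
    else:
        chosen = rng.choice(labeled_idx, size=n_mask, replace=False)

    y = dataset.y.copy()
    y[chosen] = UNLABELED
    return replace(dataset, y=y)


def hide_class(dataset: SemiLabeledDataset, class_id: int) -> SemiLabeledDataset:
    """Hide an entire class: its labels become -1 and the remaining classes
    are re-indexed to a contiguous 0..C-2 range (the hidden class has no
    output neuron during training). Ground truth stays in ``y_full``;
    ``label_map`` records original -> training indices.
    """
    if class_id not in np.unique(dataset.y_full):
        raise ValueError(f"class {class_id} absent from dataset")
    remaining = [c for c in range(dataset.class_count) if c != class_id]
    label_map = {c: i for i, c in enumerate(remaining)}
    y = np.full_like(dataset.y, UNLABELED)
    for c, i in label_map.items():
        y[dataset.y == c] = i
    names = None
    if dataset.class_names is not None:
        names = [dataset.class_names[c] for c in remaining]
    return replace(
        dataset,
        y=y,
        class_count=dataset.class_count - 1,
        class_names=names,
        y_full=dataset.y_full.copy(),
        label_map=label_map,
    )


def train_test_split_dataset(
    dataset: SemiLabeledDataset, test_fraction: float = 0.25, seed: int = 0
) -> tuple[SemiLabeledDataset, SemiLabeledDataset]:
    """Stratified (on ground truth) train/test split of a dataset."""
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for c in np.unique(dataset.y_full):
        members = np.where(dataset.y_full == c)[0]
        n_test = max(1, int(round(test_fraction * members.size)))
        test_idx.append(rng.choice(members, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(dataset.n_samples), test)
    return dataset.subset(train), dataset.subset(test)
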