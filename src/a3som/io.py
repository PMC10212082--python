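"""CSV / config plumbing: dataset round-trips, min-max normalization with
persisted bounds, prediction export and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SemiLabeledDataset

__all__ = [
    "NormalizationBounds",
    "read_table",
    "write_dataset",
    "write_predictions",
    "write_manifest",
]

logger = logging.getLogger("a3som")


@dataclass
class NormalizationBounds:
    """Per-feature min/max recorded at train time and reused at inference."""

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        rng = self.hi - self.lo
        rng = np.where(rng == 0, 1.0, rng)
        return (np.asarray(X, dtype=float) - self.lo) / rng

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"lo": self.lo.tolist(), "hi": self.hi.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "NormalizationBounds":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["lo"], float), np.array(obj["hi"], float))


def read_table(
    path,
    label_col: str = "label",
    class_count: int | None = None,
    normalize: bool = False,
    bounds: NormalizationBounds | None = None,
) -> tuple[SemiLabeledDataset, NormalizationBounds | None]:
    """Read a CSV into a SemiLabeledDataset.

    The label column holds integers with -1 for unlabeled. Rows with missing
    values are dropped (with a logged count). With ``normalize=True`` the
    features are min-max scaled; pass ``bounds`` to reuse bounds recorded at
    train time, otherwise they are computed from this file and returned.
    """
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path}")
    n0 = len(df)
    df = df.dropna()
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values from %s", dropped, path)
    feats = [c for c in df.columns if c != label_col]
    try:
        X = df[feats].to_numpy(dtype=float)
    except ValueError as exc:
        for c in feats:
            bad = pd.to_numeric(df[c], errors="coerce").isna()
            if bad.any():
                row = int(df.index[bad][0])
                raise ValueError(
                    f"non-numeric value in column {c!r}, row {row}"
                ) from exc
        raise
    y = df[label_col].to_numpy(dtype=int)
    if normalize:
        if bounds is None:
            bounds = NormalizationBounds(lo=X.min(axis=0), hi=X.max(axis=0))
        X = bounds.transform(X)
    if class_count is None:
        class_count = int(y.max()) + 1
    ds = SemiLabeledDataset(
        X=X, y=y, class_count=class_count, feature_names=feats
    )
    return ds, bounds


def write_dataset(path, dataset: SemiLabeledDataset, label_col: str = "label") -> None:
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    df = pd.DataFrame(dataset.X, columns=names)
    df[label_col] = dataset.y
    df.to_csv(path, index=False)


def write_predictions(path, predictions, sample_ids=None) -> None:
    """Export abstained predictions: sample_id, predicted_class (-1 for
    abstain), reason, top_prob, margin."""
    if sample_ids is None:
        sample_ids = list(range(len(predictions)))
    rows = [
        {
            "sample_id": sid,
            "predicted_class": p.decision,
            "reason": p.reason,
            "top_prob": p.top_prob,
            "margin": p.top_prob - p.runner_up_prob,
        }
        for sid, p in zip(sample_ids, predictions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, seed: int | None, config: dict,
                   inputs: list | None = None) -> None:
    """Reproducibility manifest: command, seed, config, versions, input hashes."""
    import a3som

    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {
            "a3som": a3som.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _file_sha256(p) for p in (inputs or [])},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
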