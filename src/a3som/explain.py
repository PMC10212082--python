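"""Prototype-based explanation and map visualization.

Every sample is anchored to its best-matching unit (BMU): a prediction can
be explained by showing the BMU's prototype vector (a representative point
in feature space), the label make-up of the training samples that share that
unit, and the same information for the neighboring units — nearby units on
the map encode similar concepts, so a sample surrounded by single-class
units sits safely inside a class, while mixed neighborhoods signal
ambiguity. The same machinery renders whole-map views: units colored by the
majority (true, predicted or abstained) label, or per-unit bar profiles of
prototype feature values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import patches

from .som import SOMGrid, activation

__all__ = [
    "MapLabelComposition",
    "Explanation",
    "label_composition",
    "explain_prediction",
    "prototype_profiles",
    "bmu_region_connected",
    "plot_label_map",
    "plot_profile_map",
]


@dataclass
class MapLabelComposition:
    """Per-unit histogram of sample labels.

    ``table`` is indexed by unit, one column per label category; row sums
    equal the number of samples whose BMU is that unit (empty units are
    all-zero rows).
    """

    grid: SOMGrid
    table: pd.DataFrame
    source: str  # "true" | "predicted" | "abstained"

    def majority(self) -> pd.Series:
        """Majority category per unit; empty units get the empty string."""
        out = self.table.idxmax(axis=1).astype(object)
        out[self.table.sum(axis=1) == 0] = ""
        return out

    def is_mixed(self) -> pd.Series:
        counts = self.table.to_numpy()
        totals = counts.sum(axis=1)
        maxes = counts.max(axis=1)
        return pd.Series((totals > 0) & (maxes < totals), index=self.table.index)


@dataclass
class Explanation:
    """Prototype-based explanation of one prediction."""

    predicted_class: int
    bmu: int
    bmu_coords: tuple[int, int]
    bmu_distance: float
    prototype: np.ndarray
    bmu_composition: dict
    neighbor_units: list[int]
    neighbor_compositions: dict


def _labels_for_source(results, dataset, source: str, abstained=None):
    if source == "true":
        return np.asarray(dataset.y_full).astype(object)
    if source == "predicted":
        labels, _, _ = results.predict(dataset.X)
        return labels.astype(object)
    if source == "abstained":
        if abstained is None:
            raise RuntimeError(
                "labels_source='abstained' needs the abstention predictions; "
                "run apply_abstention first and pass them in"
            )
        out = np.empty(len(abstained), dtype=object)
        for i, p in enumerate(abstained):
            out[i] = f"abstain-{p.reason}" if p.abstained else p.decision
        return out
    raise ValueError(f"unknown labels_source {source!r}")


def label_composition(
    results, dataset, labels_source: str = "true", abstained=None
) -> MapLabelComposition:
    """Tally the chosen label variant per map unit.

    ``labels_source``: "true" (ground truth, incl. pre-masking labels),
    "predicted" (model argmax), or "abstained" (class, "abstain-distance" or
    "abstain-ambiguity"; requires the abstention predictions). Unlabeled
    ground truth (-1) is tallied as "unlabeled".
    """
    grid = results.params.grid
    _, _, bmus = results.predict(dataset.X)
    labels = _labels_for_source(results, dataset, labels_source, abstained)
    labels = np.array(
        ["unlabeled" if lbl == -1 else str(lbl) for lbl in labels], dtype=object
    )
    cats = sorted(set(labels))
    table = pd.DataFrame(
        0, index=pd.RangeIndex(grid.n_units, name="unit"), columns=cats
    )
    for u, lbl in zip(bmus, labels):
        table.loc[u, lbl] += 1
    return MapLabelComposition(grid=grid, table=table, source=labels_source)


def explain_prediction(results, x: np.ndarray, neighbor_radius: int = 1) -> Explanation:
    """Explain one prediction via its BMU and the BMU's grid neighborhood.

    The neighbor set contains the units within Chebyshev grid distance
    ``neighbor_radius`` of the BMU, excluding the BMU itself.
    """
    if neighbor_radius < 1:
        raise ValueError("neighbor_radius must be >= 1")
    x = np.asarray(x, dtype=float)
    labels, _, bmus = results.predict(x[None, :])
    u = int(bmus[0])
    grid = results.params.grid
    d = activation(x, results.params.prototypes)
    comp = label_composition(results, results.model.dataset, "true")
    neighbors = grid.neighbors_within(u, neighbor_radius)
    return Explanation(
        predicted_class=int(labels[0]),
        bmu=u,
        bmu_coords=grid.unit_coords(u),
        bmu_distance=float(d[u]),
        prototype=results.params.prototypes[u].copy(),
        bmu_composition=comp.table.loc[u].to_dict(),
        neighbor_units=neighbors,
        neighbor_compositions={v: comp.table.loc[v].to_dict() for v in neighbors},
    )


def prototype_profiles(results, features=None) -> pd.DataFrame:
    """Prototype weights restricted to the requested features.

    ``features`` may be names (when the model knows its feature names) or
    integer indices; default is all features. Rows are units, with grid
    row/col as leading columns.
    """
    params = results.params
    names = None
    if results.model is not None:
        names = results.model.dataset.feature_names
    if names is None:
        names = [f"f{j}" for j in range(params.n_features)]
    if features is None:
        sel = list(range(params.n_features))
    else:
        sel = []
        for f in features:
            if isinstance(f, (int, np.integer)):
                sel.append(int(f))
            elif f in names:
                sel.append(names.index(f))
            else:
                raise KeyError(f"unknown feature {f!r}")
    df = pd.DataFrame(
        params.prototypes[:, sel], columns=[names[j] for j in sel],
        index=pd.RangeIndex(params.grid.n_units, name="unit"),
    )
    df.insert(0, "grid_col", params.grid.coords[:, 1].astype(int))
    df.insert(0, "grid_row", params.grid.coords[:, 0].astype(int))
    return df


def bmu_region_connected(grid: SOMGrid, units) -> bool:
    """True iff the given units form one 8-connected region on the grid."""
    units = np.unique(np.asarray(list(units), dtype=int))
    if units.size == 0:
        return False
    mask = np.zeros((grid.height, grid.width), dtype=bool)
    mask[units // grid.width, units % grid.width] = True
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    return n_comp == 1


# ---------------------------------------------------------------------------
# Plot artifacts (written to files; no interactive display)

def _category_colors(categories):
    cmap = plt.get_cmap("tab10")
    colors = {}
    k = 0
    for cat in categories:
        if cat == "unlabeled":
            colors[cat] = (0.85, 0.85, 0.85)
        elif str(cat).startswith("abstain-distance"):
            colors[cat] = (0.15, 0.15, 0.15)
        elif str(cat).startswith("abstain-ambiguity"):
            colors[cat] = (0.55, 0.55, 0.55)
        else:
            colors[cat] = cmap(k % 10)
            k += 1
    return colors


def plot_label_map(comp: MapLabelComposition, path, title: str | None = None):
    """Render the map with units colored by majority label.

    Mixed units (majority below 100%) are hatched; empty units stay white.
    The full composition table should accompany the figure (CSV export).
    """
    grid = comp.grid
    majority = comp.majority()
    mixed = comp.is_mixed()
    colors = _category_colors([c for c in comp.table.columns])
    fig, ax = plt.subplots(figsize=(1.0 * grid.width + 2, 1.0 * grid.height + 1))
    for u in range(grid.n_units):
        r, c = grid.unit_coords(u)
        cat = majority.loc[u]
        face = colors.get(cat, "white") if cat != "" else "white"
        ax.add_patch(
            patches.Rectangle(
                (c, grid.height - 1 - r), 1, 1,
                facecolor=face, edgecolor="black",
                hatch="//" if mixed.loc[u] else None,
            )
        )
    ax.set_xlim(0, grid.width)
    ax.set_ylim(0, grid.height)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    handles = [patches.Patch(facecolor=colors[c], edgecolor="black", label=str(c))
               for c in comp.table.columns]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5),
              fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile_map(results, path, features=None, comp: MapLabelComposition | None = None):
    """Per-unit bar profiles of prototype feature values, optionally over a
    majority-label background coloring."""
    profiles = prototype_profiles(results, features)
    feat_cols = [c for c in profiles.columns if c not in ("grid_row", "grid_col")]
    grid = results.params.grid
    vals = profiles[feat_cols].to_numpy()
    vmax = max(vals.max(), 1e-12)
    bg = None
    if comp is not None:
        colors = _category_colors(list(comp.table.columns))
        majority = comp.majority()
        bg = [colors.get(majority.loc[u], "white") if majority.loc[u] != "" else "white"
              for u in range(grid.n_units)]
    fig, axes = plt.subplots(
        grid.height, grid.width,
        figsize=(1.3 * grid.width, 1.1 * grid.height), squeeze=False,
    )
    for u in range(grid.n_units):
        r, c = grid.unit_coords(u)
        ax = axes[r][c]
        if bg is not None:
            ax.set_facecolor((*matplotlib.colors.to_rgb(bg[u]), 0.35))
        ax.bar(range(len(feat_cols)), vals[u] / vmax, color="tab:blue")
        ax.set_ylim(0, 1.05)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(", ".join(map(str, feat_cols)), fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
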