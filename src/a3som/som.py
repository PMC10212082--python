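"""Self-organizing-map core: grid geometry, BMU assignment, neighborhood,
batch prototype update, activation and distortion.

The map is a fixed rectangular lattice of units. Each unit ``u`` carries a
grid coordinate ``r_u = (row, col)`` and a prototype vector ``w_u`` living in
input space. The best-matching unit (BMU) of a sample is the unit whose
prototype is closest in Euclidean distance; the neighborhood function

    H_sigma(u, v) = exp(-||r_u - r_v||^2 / (2 sigma^2))

couples nearby units so that training preserves topology. Distortion, the
SOM cost, is the neighborhood-weighted mean squared distance between samples
and all prototypes; it combines quantization and topology error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SOMGrid",
    "NeighborhoodState",
    "bmu",
    "neighborhood",
    "neighborhood_matrix",
    "batch_update",
    "activation",
    "distortion",
    "prototypes_to_csv",
    "prototypes_from_csv",
]

# Units whose Eq-3 denominator falls below this keep their previous prototype.
_EMPTY_UNIT_TOL = 1e-12


class SOMGrid:
    """Fixed rectangular lattice of map units.

    Units are indexed row-major: unit ``u`` sits at integer coordinates
    ``(u // width, u % width)``, 0-based from the top-left corner. Map-space
    distance is Euclidean on these integer coordinates.
    """

    def __init__(self, height: int, width: int):
        if height < 1 or width < 1:
            raise ValueError("grid dimensions must be positive")
        self.height = int(height)
        self.width = int(width)
        rows, cols = np.meshgrid(
            np.arange(self.height), np.arange(self.width), indexing="ij"
        )
        #: (U, 2) float array of unit coordinates r_u
        self.coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)

    @property
    def n_units(self) -> int:
        return self.height * self.width

    def unit_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.height and 0 <= col < self.width):
            raise IndexError(f"unit ({row}, {col}) outside {self.height}x{self.width} grid")
        return row * self.width + col

    def unit_coords(self, u: int) -> tuple[int, int]:
        return int(self.coords[u, 0]), int(self.coords[u, 1])

    def squared_grid_distances(self) -> np.ndarray:
        """(U, U) matrix of squared Euclidean map-space distances."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.einsum("uvk,uvk->uv", diff, diff)

    def neighbors_within(self, u: int, radius: int = 1) -> list[int]:
        """Units (excluding ``u``) within Chebyshev grid radius of ``u``."""
        r, c = self.unit_coords(u)
        cheb = np.maximum(
            np.abs(self.coords[:, 0] - r), np.abs(self.coords[:, 1] - c)
        )
        out = np.where((cheb <= radius) & (cheb > 0))[0]
        return [int(v) for v in out]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SOMGrid(height={self.height}, width={self.width})"


@dataclass
class NeighborhoodState:
    """Neighborhood radius sigma(t) and its decay schedule.

    The radius decays exponentially from ``sigma_initial`` to ``sigma_final``
    over training: sigma(t) = s_i * (s_f / s_i)**(t / T), evaluated per
    optimizer step. A large radius orders the map globally; the final small
    radius refines prototypes locally.
    """

    sigma: float
    sigma_initial: float = field(default=None)  # type: ignore[assignment]
    sigma_final: float = 0.5

    def __post_init__(self):
        if self.sigma_initial is None:
            self.sigma_initial = self.sigma
        if self.sigma <= 0 or self.sigma_initial <= 0 or self.sigma_final <= 0:
            raise ValueError("sigma values must be strictly positive")

    def at_step(self, step: int, total_steps: int) -> float:
        """sigma after ``step`` of ``total_steps`` optimizer steps."""
        if total_steps <= 1:
            return float(self.sigma_final)
        frac = min(max(step / (total_steps - 1), 0.0), 1.0)
        return float(
            self.sigma_initial * (self.sigma_final / self.sigma_initial) ** frac
        )


def _check_dims(X: np.ndarray, prototypes: np.ndarray) -> None:
    if X.shape[-1] != prototypes.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: x has {X.shape[-1]}, "
            f"prototypes have {prototypes.shape[1]}"
        )


def activation(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Euclidean distance from each sample to every prototype.

    This distance vector (NOT a similarity) is the SOM layer's output and
    feeds the dense block. Accepts a single sample (m,) or a batch (n, m);
    returns (U,) or (n, U) accordingly.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xb = X[None, :] if single else X
    _check_dims(Xb, prototypes)
    sq = (
        np.sum(Xb**2, axis=1)[:, None]
        - 2.0 * Xb @ prototypes.T
        + np.sum(prototypes**2, axis=1)[None, :]
    )
    d = np.sqrt(np.maximum(sq, 0.0))
    return d[0] if single else d


def bmu(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray | int:
    """Best-matching unit: argmin over units of the Euclidean distance.

    Exact ties resolve to the lowest unit index (``np.argmin`` order).
    """
    d = activation(X, prototypes)
    if d.ndim == 1:
        return int(np.argmin(d))
    return np.argmin(d, axis=1)


def neighborhood(grid: SOMGrid, u: int, v: int, sigma: float) -> float:
    """Gaussian neighborhood H_sigma(u, v) on grid coordinates."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    diff = grid.coords[u] - grid.coords[v]
    return float(np.exp(-float(diff @ diff) / (2.0 * sigma**2)))


def neighborhood_matrix(grid: SOMGrid, sigma: float) -> np.ndarray:
    """(U, U) symmetric matrix of H_sigma over all unit pairs."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    return np.exp(-grid.squared_grid_distances() / (2.0 * sigma**2))


def indicator_matrix(bmu_idx: np.ndarray, n_units: int) -> np.ndarray:
    """(n, U) 0/1 matrix with a single 1 per row at the BMU column."""
    bmu_idx = np.asarray(bmu_idx, dtype=int)
    ind = np.zeros((bmu_idx.shape[0], n_units))
    ind[np.arange(bmu_idx.shape[0]), bmu_idx] = 1.0
    return ind


def batch_update(
    prototypes: np.ndarray,
    X: np.ndarray,
    bmu_idx: np.ndarray,
    grid: SOMGrid,
    sigma: float,
) -> np.ndarray:
    """Analytic batch prototype update.

    With a fixed BMU assignment, each prototype moves to the neighborhood-
    weighted mean of the batch:

        w_u <- [sum_v H(u,v) sum_i Ind(x_i,v) x_i] / [sum_v H(u,v) sum_i Ind(x_i,v)]

    Units whose denominator is (numerically) zero keep their previous
    prototype, so an empty corner of the map cannot blow up.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("batch must be a non-empty 2-D array")
    _check_dims(X, prototypes)
    H = neighborhood_matrix(grid, sigma)
    counts = np.bincount(np.asarray(bmu_idx, int), minlength=grid.n_units).astype(float)
    sums = np.zeros_like(prototypes)
    np.add.at(sums, np.asarray(bmu_idx, int), X)
    num = H @ sums
    den = H @ counts
    new = prototypes.copy()
    ok = den > _EMPTY_UNIT_TOL
    new[ok] = num[ok] / den[ok, None]
    return new


def distortion(
    X: np.ndarray, prototypes: np.ndarray, grid: SOMGrid, sigma: float
) -> float:
    """SOM distortion: neighborhood-weighted mean squared projection error.

    D = (1/N) sum_i sum_u H_sigma(BMU(x_i), u) * d(x_i, w_u)^2.

    All samples enter, labeled or not; in the sigma->0 limit D reduces to the
    quantization error (mean squared BMU distance).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    d = activation(X, prototypes)
    bmu_idx = np.argmin(d, axis=1)
    H = neighborhood_matrix(grid, sigma)[bmu_idx]  # (n, U)
    return float(np.mean(np.sum(H * d**2, axis=1)))


def prototypes_to_csv(path, grid: SOMGrid, prototypes: np.ndarray,
                      feature_names: list[str] | None = None) -> None:
    """Write prototypes as CSV: first two columns grid row/col, then features."""
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(prototypes.shape[1])]
    df = pd.DataFrame(prototypes, columns=feature_names)
    df.insert(0, "grid_col", grid.coords[:, 1].astype(int))
    df.insert(0, "grid_row", grid.coords[:, 0].astype(int))
    df.to_csv(path, index=False)


def prototypes_from_csv(path) -> tuple[SOMGrid, np.ndarray, list[str]]:
    """Read a prototype CSV written by :func:`prototypes_to_csv`."""
    df = pd.read_csv(path)
    if not {"grid_row", "grid_col"} <= set(df.columns):
        raise ValueError("prototype CSV must contain grid_row and grid_col columns")
    height = int(df["grid_row"].max()) + 1
    width = int(df["grid_col"].max()) + 1
    grid = SOMGrid(height, width)
    order = (df["grid_row"] * width + df["grid_col"]).to_numpy()
    df = df.iloc[np.argsort(order)]
    feats = [c for c in df.columns if c not in ("grid_row", "grid_col")]
    return grid, df[feats].to_numpy(dtype=float), feats
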