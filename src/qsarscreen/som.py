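"""Self-organizing map activity landscape and the HP screening statistic.

A rectangular SOM is trained by competitive learning on the fingerprints of
the labeled inhibitors: each sample pulls its best-matching unit (BMU, by
Euclidean distance) and a Gaussian neighborhood of it toward itself, with
learning rate and neighborhood width decaying over epochs. After training,
every labeled molecule is assigned to its BMU and each cell receives

    HP = (# highly active molecules in the cell) / (# molecules in the cell),

undefined (NaN) for empty cells. Candidates inherit the HP of the cell they
map to; the screening rule keeps candidates whose cell HP is at least 0.8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .featurize import FeatureMatrix


def _values(X):
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


class SOMActivityLandscape(BaseEstimator):
    """SOM trained on labeled inhibitors, with per-cell HP.

    Parameters
    ----------
    width, height : int
        Grid dimensions; cells are indexed row-major (cell = row·width+col).
    n_epochs : int
        Full passes over the training data.
    learning_rate : float
        Initial learning rate; decays linearly to ~0 over training.
    sigma : float or None
        Initial Gaussian neighborhood radius (grid units); defaults to
        max(width, height) / 2, decaying linearly to 0.5.
    """

    def __init__(self, width: int = 10, height: int = 11, n_epochs: int = 20,
                 learning_rate: float = 0.5, sigma: float | None = None,
                 random_state: int = 0):
        self.width = width
        self.height = height
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.sigma = sigma
        self.random_state = random_state

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def _grid_coords(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.n_cells), self.width)
        return np.column_stack([rows, cols]).astype(float)

    def fit(self, X, y=None):
        values = _values(X)
        if values.shape[0] == 0:
            raise ValueError("empty training data")
        if self.n_cells < 2:
            raise ValueError("grid must have at least 2 cells")
        if not np.all(np.isfinite(values)):
            raise ValueError("training features must be finite")
        rng = np.random.default_rng(self.random_state)
        lo, hi = values.min(axis=0), values.max(axis=0)
        weights = rng.random((self.n_cells, values.shape[1])) * (hi - lo) + lo
        coords = self._grid_coords()
        # squared grid distances between cells, for the neighborhood kernel
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        sigma0 = self.sigma if self.sigma is not None else max(
            self.width, self.height) / 2.0
        n = values.shape[0]
        total_steps = self.n_epochs * n
        qe_history = []
        step = 0
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for i in order:
                frac = step / max(total_steps - 1, 1)
                lr = self.learning_rate * (1.0 - frac) + 1e-3
                sig = sigma0 * (1.0 - frac) + 0.5
                x = values[i]
                bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                h = lr * np.exp(-grid_d2[bmu] / (2.0 * sig * sig))
                weights += h[:, None] * (x - weights)
                step += 1
            d2 = ((values[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
            qe_history.append(float(np.sqrt(d2.min(axis=1)).mean()))
        self.weights_ = weights
        self.qe_history_ = qe_history
        if y is not None:
            self._populate_counts(values, np.asarray(y))
        return self

    def _populate_counts(self, values: np.ndarray, y: np.ndarray) -> None:
        cells = self._bmu(values)
        self.n_total_ = np.bincount(cells, minlength=self.n_cells)
        self.n_high_ = np.bincount(cells, weights=(y == 1).astype(float),
                                   minlength=self.n_cells).astype(int)
        with np.errstate(invalid="ignore"):
            self.hp_ = np.where(self.n_total_ > 0,
                                self.n_high_ / np.maximum(self.n_total_, 1),
                                np.nan)

    def _bmu(self, values: np.ndarray) -> np.ndarray:
        if values.shape[1] != self.weights_.shape[1]:
            raise ValueError("feature dimension does not match the trained map")
        d2 = (-2.0 * values @ self.weights_.T
              + (self.weights_ ** 2).sum(axis=1)[None, :])
        # argmin breaks ties by the lower row-major cell index
        return np.argmin(np.round(d2, 9), axis=1)

    def predict(self, X) -> np.ndarray:
        """Row-major cell index of each candidate's best-matching unit."""
        return self._bmu(_values(X))

    def hp_of(self, X) -> np.ndarray:
        """HP inherited from each candidate's cell (NaN if cell is empty)."""
        return self.hp_[self.predict(X)]

    def hp_grid(self) -> pd.DataFrame:
        """Per-cell HP as a (height × width) table for heat-mapping."""
        return pd.DataFrame(self.hp_.reshape(self.height, self.width))


def train_som(fm_labeled, y, width: int = 10, height: int = 11,
              seed: int = 0, **params) -> SOMActivityLandscape:
    """Train a SOM on labeled data and populate the per-cell HP counts."""
    return SOMActivityLandscape(width=width, height=height,
                                random_state=seed, **params).fit(fm_labeled, y)


def map_candidates(grid: SOMActivityLandscape, fm_candidates) -> pd.DataFrame:
    """BMU cell assignment and inherited HP per candidate."""
    cells = grid.predict(fm_candidates)
    hp = grid.hp_[cells]
    ids = (fm_candidates.ids
           if isinstance(fm_candidates, FeatureMatrix) and fm_candidates.ids
           else list(range(len(cells))))
    return pd.DataFrame({"id": ids, "cell": cells, "hp": hp})


def screen_by_hp(assignments: pd.DataFrame,
                 threshold: float = 0.8, strict: bool = False) -> pd.DataFrame:
    """Keep candidates whose cell HP meets the threshold.

    By default the rule is inclusive (HP ≥ threshold); ``strict=True``
    requires HP > threshold. A candidate mapping to an empty cell has
    undefined HP and is dropped with reason ``"unmapped"``.
    """
    hp = assignments["hp"].to_numpy()
    defined = np.isfinite(hp)
    keep = defined & ((hp > threshold) if strict else (hp >= threshold))
    out = assignments.copy()
    out["keep"] = keep
    out["reason"] = np.where(keep, "",
                             np.where(defined, "hp_below_threshold", "unmapped"))
    return out
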