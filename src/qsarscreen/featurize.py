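"""Molecular featurization and the feature filtering/scaling protocol.

Fingerprints (MACCS 166, Avalon 1024, ECFP4 1024) characterize molecules for
classification; 2D descriptor sets characterize them for regression. The
protocol layered on top: bottom-quartile variance filtering for fingerprints,
pairwise Pearson-correlation pruning, recursive feature elimination with a
random forest (RF-RFE) for descriptor ranking, and linear auto-scaling of
every feature onto the interval [0.1, 0.9] with parameters learned on the
training partition only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .molecule_io import MoleculeRecord, to_mols

FINGERPRINT_KINDS = ("maccs166", "avalon1024", "ecfp4_1024")
DESCRIPTOR_SETS = ("physchem_2d", "fragment_counts")

# Descriptor providers are pluggable: a set id maps to an ordered list of
# (name, callable) pairs. The two open 2D sets below are the defaults; a 3D
# provider can be registered by client code via register_descriptor_set.
_DESCRIPTOR_REGISTRY: dict[str, list[tuple[str, object]]] = {}


def register_descriptor_set(set_id: str, providers: list[tuple[str, object]]) -> None:
    """Register an ordered list of ``(name, mol -> float)`` descriptor providers."""
    _DESCRIPTOR_REGISTRY[set_id] = list(providers)


def _builtin_descriptor_sets() -> None:
    all_desc = Descriptors._descList
    fragments = [(n, f) for n, f in all_desc if n.startswith("fr_")]
    # Ipc grows combinatorially with molecule size and overflows; excluded.
    physchem = [(n, f) for n, f in all_desc
                if not n.startswith("fr_") and n != "Ipc"]
    register_descriptor_set("physchem_2d", physchem)
    register_descriptor_set("fragment_counts", fragments)


_builtin_descriptor_sets()


@dataclass
class FeatureMatrix:
    """An n×d numeric feature block with names, kind and provenance.

    ``kind`` is ``"fingerprint"`` (values in {0,1}) or ``"descriptor"``;
    ``provenance`` records the ordered transforms applied.
    """

    values: np.ndarray
    feature_names: list[str]
    kind: str
    provenance: list[str] = field(default_factory=list)
    ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select(self, column_indices: np.ndarray | list[int],
               note: str | None = None) -> "FeatureMatrix":
        names = [self.feature_names[i] for i in column_indices]
        prov = self.provenance + ([note] if note else [])
        return FeatureMatrix(self.values[:, column_indices], names, self.kind,
                             prov, self.ids)

    def subset_rows(self, row_indices) -> "FeatureMatrix":
        ids = [self.ids[i] for i in row_indices] if self.ids else None
        return FeatureMatrix(self.values[row_indices], list(self.feature_names),
                             self.kind, list(self.provenance), ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


class FingerprintFeaturizer(BaseEstimator, TransformerMixin):
    """Binary structural fingerprints of one of the three supported kinds.

    kind : {"maccs166", "avalon1024", "ecfp4_1024"}
        MACCS 166-bit keys, 1024-bit Avalon topological fingerprints, or
        1024-bit ECFP4 (Morgan radius 2) circular fingerprints.
    """

    def __init__(self, kind: str = "ecfp4_1024"):
        self.kind = kind

    def fit(self, X, y=None):
        if self.kind not in FINGERPRINT_KINDS:
            raise ValueError(f"unsupported fingerprint kind {self.kind!r}")
        return self

    def transform(self, X: list[MoleculeRecord]) -> FeatureMatrix:
        self.fit(X)
        mols = to_mols(X)
        if self.kind == "maccs166":
            # RDKit emits 167 bits with bit 0 always unset; keep keys 1..166.
            rows = [np.array(MACCSkeys.GenMACCSKeys(m))[1:] for m in mols]
            names = [f"maccs_{i}" for i in range(1, 167)]
        elif self.kind == "avalon1024":
            rows = [np.array(pyAvalonTools.GetAvalonFP(m, nBits=1024))
                    for m in mols]
            names = [f"avalon_{i}" for i in range(1024)]
        else:
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2,
                                                            fpSize=1024)
            rows = [np.array(gen.GetFingerprint(m)) for m in mols]
            names = [f"ecfp4_{i}" for i in range(1024)]
        values = (np.vstack(rows) if rows
                  else np.empty((0, len(names))))
        return FeatureMatrix(values.astype(float), names, "fingerprint",
                             [f"fingerprint({self.kind})"],
                             ids=[r.id for r in X])


class DescriptorFeaturizer(BaseEstimator, TransformerMixin):
    """Numeric molecular descriptors from a registered provider set.

    A descriptor that fails or returns a non-finite value is treated as
    missing and imputed by the per-feature median learned in ``fit``.
    """

    def __init__(self, set_id: str = "physchem_2d"):
        self.set_id = set_id

    def _raw(self, records: list[MoleculeRecord]) -> np.ndarray:
        providers = _DESCRIPTOR_REGISTRY[self.set_id]
        mols = to_mols(records)
        out = np.full((len(mols), len(providers)), np.nan)
        for i, mol in enumerate(mols):
            for j, (_, func) in enumerate(providers):
                try:
                    v = float(func(mol))
                except Exception:
                    continue
                if np.isfinite(v):
                    out[i, j] = v
        return out

    def fit(self, X: list[MoleculeRecord], y=None):
        if self.set_id not in _DESCRIPTOR_REGISTRY:
            raise ValueError(f"unknown descriptor set {self.set_id!r}")
        raw = self._raw(X)
        with np.errstate(all="ignore"):
            med = np.nanmedian(raw, axis=0)
        self.medians_ = np.where(np.isfinite(med), med, 0.0)
        return self

    def transform(self, X: list[MoleculeRecord]) -> FeatureMatrix:
        raw = self._raw(X)
        raw = np.where(np.isnan(raw), self.medians_, raw)
        names = [n for n, _ in _DESCRIPTOR_REGISTRY[self.set_id]]
        return FeatureMatrix(raw, names, "descriptor",
                             [f"descriptors({self.set_id})"],
                             ids=[r.id for r in X])


class VarianceQuartileFilter(BaseEstimator, TransformerMixin):
    """Drop the lowest-variance quartile of columns.

    Exactly ``floor(d * quartile)`` columns are removed, lowest variance
    first; ties broken by column index (lower index dropped first).
    """

    def __init__(self, quartile: float = 0.25):
        self.quartile = quartile

    def fit(self, X, y=None):
        if not 0 < self.quartile < 1:
            raise ValueError("quartile must lie strictly inside (0, 1)")
        values = _values(X)
        if values.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate variance")
        variances = values.var(axis=0)
        d = values.shape[1]
        n_drop = int(np.floor(d * self.quartile))
        order = np.lexsort((np.arange(d), variances))  # variance, then index
        dropped = set(order[:n_drop].tolist())
        self.kept_idx_ = np.array([i for i in range(d) if i not in dropped])
        self.variances_ = variances
        return self

    def transform(self, X):
        if isinstance(X, FeatureMatrix):
            return X.select(self.kept_idx_,
                            note=f"variance_filter(q={self.quartile})")
        return _values(X)[:, self.kept_idx_]


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Prune highly inter-correlated features.

    For every pair with |pairwise Pearson r| > ``r_cut`` the member with the
    lower |correlation to the response| is removed, greedily over pairs in
    descending |r|. A constant feature correlates 0 with everything and is
    therefore removable but never triggers removal.
    """

    def __init__(self, r_cut: float = 0.95):
        self.r_cut = r_cut

    def fit(self, X, y):
        values = _values(X)
        y = np.asarray(y, float)
        if values.shape[0] != y.shape[0]:
            raise ValueError("row count must match response length")
        d = values.shape[1]
        if d < 2:
            self.kept_idx_ = np.arange(d)
            return self
        sd = values.std(axis=0)
        nonconst = sd > 0
        z = np.zeros_like(values)
        z[:, nonconst] = ((values[:, nonconst] - values[:, nonconst].mean(0))
                          / sd[nonconst])
        corr = np.abs(z.T @ z) / values.shape[0]
        ysd = y.std()
        if ysd > 0:
            yz = (y - y.mean()) / ysd
            ycorr = np.abs(z.T @ yz) / values.shape[0]
        else:
            ycorr = np.zeros(d)
        iu, ju = np.triu_indices(d, k=1)
        offending = corr[iu, ju] > self.r_cut
        pairs = sorted(
            zip(corr[iu[offending], ju[offending]],
                iu[offending], ju[offending]),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        removed: set[int] = set()
        for _, i, j in pairs:
            if i in removed or j in removed:
                continue
            if ycorr[i] < ycorr[j]:
                removed.add(i)
            else:
                removed.add(j)  # ties: drop the higher index
        self.kept_idx_ = np.array([i for i in range(d) if i not in removed])
        return self

    def transform(self, X):
        if isinstance(X, FeatureMatrix):
            return X.select(self.kept_idx_,
                            note=f"pcc_filter(r_cut={self.r_cut})")
        return _values(X)[:, self.kept_idx_]


class RFRFERanker(BaseEstimator):
    """Recursive feature elimination with a random forest (RF-RFE).

    Features are eliminated one per step — the least important by forest
    impurity importance — until none remain; ``ranking_`` lists feature
    names from most to least important (reverse elimination order).
    """

    def __init__(self, n_estimators: int = 500, task: str = "regression",
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.task = task
        self.random_state = random_state

    def fit(self, X, y):
        values = _values(X)
        names = (list(X.feature_names) if isinstance(X, FeatureMatrix)
                 else [f"f{i}" for i in range(values.shape[1])])
        y = np.asarray(y)
        forest_cls = (RandomForestClassifier if self.task == "classification"
                      else RandomForestRegressor)
        alive = list(range(values.shape[1]))
        eliminated: list[int] = []
        while len(alive) > 1:
            forest = forest_cls(n_estimators=self.n_estimators,
                                random_state=self.random_state, n_jobs=1)
            forest.fit(values[:, alive], y)
            imp = forest.feature_importances_
            # least important; ties broken by lower original index
            worst = min(range(len(alive)), key=lambda k: (imp[k], alive[k]))
            eliminated.append(alive.pop(worst))
        order = alive + eliminated[::-1]
        self.ranking_idx_ = np.array(order)
        self.ranking_ = [names[i] for i in order]
        return self


@dataclass
class ScalerParams:
    """Per-feature min/max learned on training data for [0.1, 0.9] scaling."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    feature_range: tuple[float, float] = (0.1, 0.9)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "feature_range": list(self.feature_range),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        payload = json.loads(Path(path).read_text())
        return cls(payload["feature_names"], np.array(payload["mins"]),
                   np.array(payload["maxs"]),
                   tuple(payload["feature_range"]))


class IntervalScaler(BaseEstimator, TransformerMixin):
    """Linear auto-scaling of each feature onto [0.1, 0.9].

    The training minimum maps to 0.1, the training maximum to 0.9. A
    constant training feature maps to the midpoint 0.5. Out-of-range values
    at apply time are NOT clipped, so the map stays affine everywhere.
    """

    def __init__(self, feature_range: tuple[float, float] = (0.1, 0.9)):
        self.feature_range = feature_range

    def fit(self, X, y=None):
        values = _values(X)
        self.params_ = ScalerParams(
            feature_names=(list(X.feature_names)
                           if isinstance(X, FeatureMatrix)
                           else [f"f{i}" for i in range(values.shape[1])]),
            mins=values.min(axis=0),
            maxs=values.max(axis=0),
            feature_range=self.feature_range,
        )
        return self

    def transform(self, X):
        params = self.params_
        if isinstance(X, FeatureMatrix) and X.feature_names != params.feature_names:
            raise ValueError("feature names do not match fitted scaler")
        values = _values(X)
        lo, hi = params.feature_range
        span = params.maxs - params.mins
        mid = 0.5 * (lo + hi)
        out = np.empty_like(values, dtype=float)
        const = span == 0
        out[:, const] = mid
        nc = ~const
        out[:, nc] = lo + (values[:, nc] - params.mins[nc]) / span[nc] * (hi - lo)
        if isinstance(X, FeatureMatrix):
            return FeatureMatrix(out, list(X.feature_names), X.kind,
                                 X.provenance + [f"autoscale{params.feature_range}"],
                                 X.ids)
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers matching the operation-level API

def fingerprints(records: list[MoleculeRecord], kind: str) -> FeatureMatrix:
    return FingerprintFeaturizer(kind).fit(records).transform(records)

def descriptors(records: list[MoleculeRecord],
                set_id: str = "physchem_2d") -> FeatureMatrix:
    return DescriptorFeaturizer(set_id).fit(records).transform(records)

def variance_filter(fm: FeatureMatrix, quartile: float = 0.25) -> FeatureMatrix:
    return VarianceQuartileFilter(quartile).fit(fm).transform(fm)

def pcc_filter(fm: FeatureMatrix, y, r_cut: float = 0.95) -> FeatureMatrix:
    return CorrelationFilter(r_cut).fit(fm, y).transform(fm)

def rfrfe_rank(fm: FeatureMatrix, y, seed: int = 0,
               n_estimators: int = 500, task: str = "regression") -> list[str]:
    return RFRFERanker(n_estimators, task, seed).fit(fm, y).ranking_

def autoscale_fit(fm_train: FeatureMatrix) -> ScalerParams:
    return IntervalScaler().fit(fm_train).params_

def autoscale_apply(fm: FeatureMatrix, params: ScalerParams) -> FeatureMatrix:
    scaler = IntervalScaler(params.feature_range)
    scaler.params_ = params
    return scaler.transform(fm)
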