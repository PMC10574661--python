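"""Labeled modeling datasets and repeated stratified train/test splitting.

Activity labeling follows explicit IC50 threshold schemes: a "high" rule and
a "weak" rule, each a (comparator, threshold in μM) pair. Schemes with a gap
between the rules exclude mid-range molecules entirely. Splitting is
stratified with a round-half-up test-set size and largest-remainder
per-class allocation, repeated over consecutive seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molecule_io import MoleculeRecord

_COMPARATORS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


def pic50(ic50_um: float) -> float:
    """pIC50 = −log10(IC50 in mol/L) = 6 − log10(IC50 in μM)."""
    if not ic50_um > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)


@dataclass(frozen=True)
class LabelScheme:
    """High/weak activity labeling rules over IC50 (μM).

    Each rule is a (comparator, threshold) pair with exact comparator
    semantics; molecules matching neither rule are excluded. The two rules
    must be disjoint over positive IC50 values.
    """

    name: str
    high_rule: tuple[str, float]
    weak_rule: tuple[str, float]

    def __post_init__(self):
        hc, ht = self.high_rule
        wc, wt = self.weak_rule
        if hc not in ("<", "<=") or wc not in (">", ">="):
            raise ValueError("high rule must be an upper bound, weak a lower bound")
        if ht > wt or (ht == wt and hc == "<=" and wc == ">="):
            raise ValueError("high and weak rules overlap")

    @property
    def has_gap(self) -> bool:
        hc, ht = self.high_rule
        wc, wt = self.weak_rule
        if ht < wt:
            return True
        return hc == "<" and wc == ">"  # both strict at a shared threshold


#: Labeling schemes used for the two inhibition targets. The gapped schemes
#: exclude moderately active molecules; the single-cut schemes are total.
SCHEMES = {
    # COX-2 classification, gapped: high < 0.1 μM, weak > 10 μM
    "cox2_gap": LabelScheme("cox2_gap", ("<", 0.1), (">", 10.0)),
    # COX-2 classification, single cut at 1 μM: high ≤ 1 μM, weak > 1 μM
    "cox2_cut1": LabelScheme("cox2_cut1", ("<=", 1.0), (">", 1.0)),
    # mPGES-1 classification, gapped: high < 0.6 μM, weak > 10 μM
    "mpges1_gap": LabelScheme("mpges1_gap", ("<", 0.6), (">", 10.0)),
    # mPGES-1 classification, single cut at 10 μM: high < 10 μM, weak ≥ 10 μM
    "mpges1_cut10": LabelScheme("mpges1_cut10", ("<", 10.0), (">=", 10.0)),
}


def label(ic50_um: float, scheme: LabelScheme) -> str:
    """Label an IC50 as ``"high"``, ``"weak"`` or ``"excluded"``."""
    if not ic50_um > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_um}")
    hc, ht = scheme.high_rule
    if _COMPARATORS[hc](ic50_um, ht):
        return "high"
    wc, wt = scheme.weak_rule
    if _COMPARATORS[wc](ic50_um, wt):
        return "weak"
    return "excluded"


@dataclass
class ActivityDataset:
    """Labeled compounds for one target, for classification or regression.

    Classification: ``y`` is 1 for highly active, 0 for weakly active, via
    the attached :class:`LabelScheme` (excluded molecules dropped at build
    time). Regression: ``y`` is pIC50.
    """

    records: list[MoleculeRecord]
    target: str
    task: str
    scheme: LabelScheme | None = None
    labels: list[str] | None = field(default=None, repr=False)

    @classmethod
    def build(cls, records: list[MoleculeRecord], target: str, task: str,
              scheme: LabelScheme | None = None) -> "ActivityDataset":
        if task == "classification":
            if scheme is None:
                raise ValueError("classification requires a LabelScheme")
            kept, labels = [], []
            for rec in records:
                if rec.ic50_um is None:
                    raise ValueError(f"record {rec.id} lacks an IC50")
                lab = label(rec.ic50_um, scheme)
                if lab != "excluded":
                    kept.append(rec)
                    labels.append(lab)
            ds = cls(kept, target, task, scheme, labels)
            if len(set(labels)) < 2:
                raise ValueError("both classes must be present")
            return ds
        if task == "regression":
            kept = []
            for rec in records:
                if rec.pic50 is None:
                    if rec.ic50_um is None:
                        raise ValueError(f"record {rec.id} lacks activity")
                    rec = MoleculeRecord(rec.id, rec.smiles, rec.source,
                                         rec.ic50_um, pic50(rec.ic50_um))
                if not np.isfinite(rec.pic50):
                    raise ValueError(f"record {rec.id} has non-finite pIC50")
                kept.append(rec)
            return cls(kept, target, task, scheme)
        raise ValueError(f"unknown task {task!r}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        if self.task == "classification":
            return np.array([1 if l == "high" else 0 for l in self.labels])
        return np.array([r.pic50 for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.records):
            rows.append({
                "id": rec.id, "smiles": rec.smiles, "ic50_um": rec.ic50_um,
                "pic50": rec.pic50,
                "label": self.labels[i] if self.labels else None,
            })
        return pd.DataFrame(rows)


def _strata(ds_or_y, task: str | None = None, n_bins: int = 5) -> np.ndarray:
    """Stratification groups: class labels, or response-quantile bins."""
    if isinstance(ds_or_y, ActivityDataset):
        task = ds_or_y.task
        y = ds_or_y.y
    else:
        y = np.asarray(ds_or_y)
        if task is None:
            task = ("classification"
                    if y.dtype.kind in "biu" and len(np.unique(y)) <= 10
                    else "regression")
    if task == "classification":
        return y
    # regression: 5 response-quantile bins
    n_bins = min(n_bins, max(1, len(y) // 2))
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, y, side="right")


def stratified_split(ds_or_y, test_fraction: float,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split.

    The test-set size is round-half-up(n · test_fraction); per-stratum test
    counts follow largest-remainder allocation, so each deviates from exact
    proportionality by less than one molecule. Sampling within strata is
    seeded and reproducible.
    """
    strata = _strata(ds_or_y)
    n = len(strata)
    if isinstance(ds_or_y, ActivityDataset) and ds_or_y.task == "classification":
        _, counts = np.unique(strata, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 members")
    elif isinstance(ds_or_y, ActivityDataset) and n < 5:
        raise ValueError("regression split needs n >= 5")
    n_test = int(math.floor(n * test_fraction + 0.5))
    groups, counts = np.unique(strata, return_counts=True)
    quotas = n_test * counts / n
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = n_test - base.sum()
    # hand the leftover seats to the largest remainders; ties by group order
    order = np.lexsort((np.arange(len(groups)), -remainder))
    take = base.copy()
    take[order[:short]] += 1
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for g, t in zip(groups, take):
        members = np.flatnonzero(strata == g)
        test_idx.extend(rng.choice(members, size=t, replace=False))
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


@dataclass
class SplitSet:
    """Repeated stratified splits with their seeds."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    test_fraction: float
    seeds: list[int]

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def to_dataframe(self, ids: list[str] | None = None) -> pd.DataFrame:
        """Long-format table: one row per (repeat, molecule) with its
        partition, suitable for CSV serialization."""
        rows = []
        for rep, (train, test) in enumerate(self.splits):
            for part, idx in (("train", train), ("test", test)):
                for i in idx:
                    rows.append({"repeat": rep,
                                 "index": int(i),
                                 "id": ids[i] if ids else str(i),
                                 "partition": part})
        return pd.DataFrame(rows)


def repeated_splits(ds_or_y, n_repeats: int = 10, test_fraction: float = 0.25,
                    base_seed: int = 0) -> SplitSet:
    """``n_repeats`` stratified splits seeded base_seed .. base_seed+n−1."""
    seeds = list(range(base_seed, base_seed + n_repeats))
    splits = [stratified_split(ds_or_y, test_fraction, seed=s) for s in seeds]
    return SplitSet(splits, test_fraction, seeds)
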