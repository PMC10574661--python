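"""The multi-stage ligand-based virtual screen.

Stage order (default): (1) consensus of the selected activity classifiers —
a candidate survives only if the required fraction of classifiers calls it
highly active; (2) averaged-regression potency — predicted pIC50 values are
averaged across the selected regressors and the implied IC50 (10^(6−pIC50)
μM) must fall strictly below the potency cut; (3) the SOM HP rule — the
candidate's map cell must hold at least the threshold proportion of highly
active training molecules; (4) the known-aggregator filter. Failures
short-circuit: later stages are not evaluated for a failed molecule, and
every input molecule appears exactly once in the audit trail. Scaffold /
nearest-neighbor context for the survivors is reported, not used as an
automatic filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemspace import tanimoto, top_scaffolds
from .featurize import FeatureMatrix, fingerprints
from .molecule_io import MoleculeRecord
from .pains_filter import AggregatorSet, flag_aggregator
from .som import SOMActivityLandscape


@dataclass
class CascadeConfig:
    """Thresholds and rules governing a cascade run."""

    consensus_fraction: float = 1.0     # fraction of classifiers required
    potency_cut_um: float = 10.0        # strict "<" on implied IC50
    hp_threshold: float = 0.8           # inclusive "≥" on cell HP
    hp_strict: bool = False
    aggregator_threshold: float = 1.0   # MACCS Tanimoto for the flag

    def __post_init__(self):
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must lie in (0, 1]")
        if self.potency_cut_um <= 0:
            raise ValueError("potency cut must be positive")
        if not 0 <= self.hp_threshold <= 1:
            raise ValueError("hp_threshold must lie in [0, 1]")


@dataclass
class CascadeModel:
    """A fitted model plus the key(s) of the features it consumes.

    ``feature_key`` is the id of the entry in the features dict handed to
    the cascade; for a stacked classifier it is a mapping from fingerprint
    kind to feature id.
    """

    model: object
    feature_key: str | dict[str, str]
    model_id: str = ""

    def _features(self, features: dict, rows=None):
        def pick(key):
            fm = features[key]
            return fm.subset_rows(rows) if rows is not None else fm
        if isinstance(self.feature_key, dict):
            return {kind: pick(key) for kind, key in self.feature_key.items()}
        return pick(self.feature_key)

    def predict(self, features: dict, rows=None) -> np.ndarray:
        return np.asarray(self.model.predict(self._features(features, rows)))


@dataclass
class ScreeningResult:
    """Per-candidate cascade outcome with a per-stage audit trail."""

    id: str
    status: str                       # "passed" | "failed@<stage>"
    n_classifiers_positive: int | None = None
    n_classifiers: int | None = None
    mean_pic50: float | None = None
    implied_ic50_um: float | None = None
    cell: int | None = None
    hp: float | None = None
    aggregator_flag: bool | None = None
    audit: dict = field(default_factory=dict)


def select_models(scores: dict[str, float], top_k: int | None = None,
                  threshold: float | None = None,
                  higher_is_better: bool = True) -> list[str]:
    """Pick models by external-validation score.

    Either the best ``top_k`` models, or all models meeting ``threshold``
    (≥ if higher is better, ≤ otherwise). Ordering is by score then model
    id, fully deterministic. An empty selection is an error.
    """
    if not scores:
        raise ValueError("empty selection: no models supplied")
    sign = -1 if higher_is_better else 1
    ordered = sorted(scores, key=lambda m: (sign * scores[m], m))
    if threshold is not None:
        ordered = [m for m in ordered
                   if (scores[m] >= threshold if higher_is_better
                       else scores[m] <= threshold)]
    if top_k is not None:
        ordered = ordered[:top_k]
    if not ordered:
        raise ValueError("empty selection: no model meets the criterion")
    return ordered


def consensus_classify(classifiers: list[CascadeModel], features: dict,
                       rows=None, fraction: float = 1.0):
    """(n_positive per molecule, keep mask) under the consensus rule."""
    votes = np.column_stack([clf.predict(features, rows)
                             for clf in classifiers])
    n_pos = votes.sum(axis=1).astype(int)
    keep = n_pos / votes.shape[1] >= fraction
    return n_pos, keep


def average_potency(regressors: list[CascadeModel], features: dict,
                    rows=None, cut_um: float = 10.0):
    """(mean pIC50, implied IC50 μM, keep mask); keep is strict "<" on IC50."""
    preds = np.column_stack([reg.predict(features, rows)
                             for reg in regressors])
    mean_pic50 = preds.mean(axis=1)
    implied_ic50 = 10.0 ** (6.0 - mean_pic50)
    return mean_pic50, implied_ic50, implied_ic50 < cut_um


def run_cascade(library: list[MoleculeRecord],
                classifiers: list[CascadeModel],
                regressors: list[CascadeModel],
                som: SOMActivityLandscape,
                som_feature_key: str,
                aggregators: AggregatorSet | None,
                features: dict[str, FeatureMatrix],
                config: CascadeConfig | None = None) -> list[ScreeningResult]:
    """Screen a library through the full cascade.

    ``features`` maps featurization ids to library-wide feature matrices
    (rows aligned with ``library``). Returns one result per input molecule;
    passed molecules are ranked first, by ascending implied IC50.
    """
    config = config or CascadeConfig()
    if not classifiers or not regressors:
        raise ValueError("need at least one classifier and one regressor")
    n = len(library)
    results = {i: ScreeningResult(id=library[i].id, status="pending")
               for i in range(n)}
    if n == 0:
        return []

    alive = np.arange(n)
    # stage 1: consensus classification
    n_pos, keep = consensus_classify(classifiers, features, alive,
                                     config.consensus_fraction)
    for i, idx in enumerate(alive):
        r = results[idx]
        r.n_classifiers_positive = int(n_pos[i])
        r.n_classifiers = len(classifiers)
        r.audit["classify"] = {"n_positive": int(n_pos[i]),
                               "n_classifiers": len(classifiers)}
        if not keep[i]:
            r.status = "failed@classify"
    alive = alive[keep]

    # stage 2: averaged regression potency
    if len(alive):
        mean_p, ic50, keep = average_potency(regressors, features, alive,
                                             config.potency_cut_um)
        for i, idx in enumerate(alive):
            r = results[idx]
            r.mean_pic50 = float(mean_p[i])
            r.implied_ic50_um = float(ic50[i])
            r.audit["potency"] = {"mean_pic50": float(mean_p[i]),
                                  "implied_ic50_um": float(ic50[i])}
            if not keep[i]:
                r.status = "failed@potency"
        alive = alive[keep]

    # stage 3: SOM HP rule
    if len(alive):
        fm = features[som_feature_key].subset_rows(alive)
        cells = som.predict(fm)
        hp = som.hp_[cells]
        defined = np.isfinite(hp)
        keep = defined & ((hp > config.hp_threshold) if config.hp_strict
                          else (hp >= config.hp_threshold))
        for i, idx in enumerate(alive):
            r = results[idx]
            r.cell = int(cells[i])
            r.hp = float(hp[i]) if defined[i] else None
            r.audit["hp"] = {"cell": int(cells[i]), "hp": r.hp,
                             "reason": ("" if keep[i] else
                                        ("unmapped" if not defined[i]
                                         else "hp_below_threshold"))}
            if not keep[i]:
                r.status = "failed@hp"
        alive = alive[keep]

    # stage 4: known-aggregator filter
    if len(alive):
        for idx in alive:
            r = results[idx]
            if aggregators is None or aggregators.n == 0:
                flag, match, sim = False, None, 0.0
            else:
                flag, match, sim = flag_aggregator(
                    library[idx], aggregators, config.aggregator_threshold)
            r.aggregator_flag = flag
            r.audit["aggregator"] = {"flag": flag, "best_match": match,
                                     "similarity": sim}
            r.status = "failed@aggregator" if flag else "passed"

    out = list(results.values())
    out.sort(key=lambda r: (r.status != "passed",
                            r.implied_ic50_um if r.implied_ic50_um is not None
                            else np.inf,
                            r.id))
    return out


def results_table(results: list[ScreeningResult]) -> pd.DataFrame:
    """Results as a flat table mirroring a screening report (candidate,
    predicted IC50 μM, SOM HP, consensus count, status)."""
    return pd.DataFrame([{
        "id": r.id, "status": r.status,
        "n_classifiers_positive": r.n_classifiers_positive,
        "n_classifiers": r.n_classifiers,
        "mean_pic50": r.mean_pic50, "predicted_ic50_um": r.implied_ic50_um,
        "som_cell": r.cell, "som_hp": r.hp,
        "aggregator_flag": r.aggregator_flag,
    } for r in results])


def scaffold_report(passed: list[MoleculeRecord],
                    labeled: list[MoleculeRecord],
                    n_scaffolds: int = 20) -> dict:
    """Scaffold table plus nearest labeled neighbor per passed candidate.

    This is the manual scaffold/literature review stage rendered as a
    report: it never drops candidates.
    """
    if not passed:
        return {"scaffolds": pd.DataFrame(), "nearest": pd.DataFrame()}
    scaffolds = top_scaffolds(passed, n=n_scaffolds)
    cand_fp = fingerprints(passed, "ecfp4_1024").values
    lab_fp = fingerprints(labeled, "ecfp4_1024").values
    rows = []
    for i, rec in enumerate(passed):
        sims = [tanimoto(cand_fp[i], lab_fp[j]) for j in range(len(labeled))]
        best = int(np.argmax(sims))
        rows.append({"id": rec.id, "nearest_labeled": labeled[best].id,
                     "tanimoto": float(sims[best])})
    return {"scaffolds": scaffolds, "nearest": pd.DataFrame(rows)}
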