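"""Chemical-space and diversity profiling of a compound library.

Covers molecular-weight/LogP profiles, pairwise Tanimoto similarity
statistics, Murcko scaffold extraction, scaffold clustering (t-SNE embedding
followed by K-means) and top-N scaffold frequency tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .featurize import FeatureMatrix, fingerprints
from .molecule_io import MoleculeRecord


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two binary vectors.

    Two all-zero vectors are defined to have similarity 0.
    """
    a = np.asarray(fp_a, bool)
    b = np.asarray(fp_b, bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class DiversityReport:
    """Pairwise-similarity summary of a library."""

    n_molecules: int
    mean_tc: float
    frac_below: float
    cut: float
    mode: str            # "exact" | "sampled"
    n_pairs_evaluated: int
    seed: int | None = None


def diversity_stats(fm: FeatureMatrix, cut: float = 0.6, mode: str = "exact",
                    max_pairs: int = 1_000_000,
                    seed: int = 0) -> DiversityReport:
    """Mean pairwise Tanimoto and the fraction of pairs below ``cut``.

    ``mode="exact"`` evaluates all n(n−1)/2 pairs; ``mode="sampled"`` draws
    ``max_pairs`` distinct pairs uniformly without replacement (seeded),
    the desk-scale default for libraries of tens of thousands of molecules.
    """
    if fm.kind != "fingerprint":
        raise ValueError("diversity_stats requires a fingerprint matrix")
    n = fm.n
    if n < 2:
        raise ValueError("need at least two molecules")
    X = fm.values.astype(bool)
    n_all = n * (n - 1) // 2
    if mode == "exact" or max_pairs >= n_all:
        # |a∧b| via boolean matmul; |a∨b| = |a|+|b|−|a∧b|
        Xi = X.astype(np.float64)
        inter = Xi @ Xi.T
        counts = Xi.sum(axis=1)
        union = counts[:, None] + counts[None, :] - inter
        iu, ju = np.triu_indices(n, k=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tc = np.where(union[iu, ju] > 0, inter[iu, ju] / union[iu, ju], 0.0)
        return DiversityReport(n, float(tc.mean()), float((tc < cut).mean()),
                               cut, "exact", n_all, None)
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_all, size=max_pairs, replace=False)
    # invert the upper-triangle linear index
    i = (n - 2 - np.floor(
        np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    inter = np.logical_and(X[i], X[j]).sum(axis=1)
    union = np.logical_or(X[i], X[j]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / union, 0.0)
    return DiversityReport(n, float(tc.mean()), float((tc < cut).mean()),
                           cut, "sampled", max_pairs, seed)


def murcko(smiles: str) -> str:
    """Murcko scaffold SMILES: ring systems + linkers, side chains removed.

    Acyclic molecules have an empty scaffold ("").
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def physchem_profile(records: list[MoleculeRecord]) -> pd.DataFrame:
    """MW and estimated LogP (Crippen atom-contribution) per molecule."""
    rows = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        rows.append({"id": rec.id, "mw": Descriptors.MolWt(mol),
                     "logp": Crippen.MolLogP(mol)})
    return pd.DataFrame(rows)


class ScaffoldClusterer(BaseEstimator):
    """K-means clustering of Murcko scaffolds in a 2-D t-SNE embedding.

    Scaffolds are characterized by 1024-bit ECFP4 fingerprints, embedded in
    two dimensions by t-SNE, then partitioned by K-means; set
    ``cluster_in_fingerprint_space=True`` to run K-means on the raw
    fingerprints instead (the embedding is then for display only).
    """

    def __init__(self, k: int = 11, random_state: int = 0,
                 cluster_in_fingerprint_space: bool = False):
        self.k = k
        self.random_state = random_state
        self.cluster_in_fingerprint_space = cluster_in_fingerprint_space

    def fit(self, X: list[MoleculeRecord], y=None):
        scaffolds = [murcko(r.smiles) for r in X]
        distinct = {s for s in scaffolds if s}
        if len(distinct) < self.k:
            raise ValueError(
                f"{len(distinct)} distinct non-empty scaffolds < k={self.k}")
        scaffold_records = [
            MoleculeRecord(id=r.id, smiles=s or r.smiles)
            for r, s in zip(X, scaffolds)
        ]
        fps = fingerprints(scaffold_records, "ecfp4_1024")
        n = fps.n
        perplexity = min(30.0, max(2.0, (n - 1) / 3))
        tsne = TSNE(n_components=2, random_state=self.random_state,
                    perplexity=perplexity, init="pca")
        self.embedding_ = tsne.fit_transform(fps.values)
        km_X = fps.values if self.cluster_in_fingerprint_space else self.embedding_
        km = KMeans(n_clusters=self.k, random_state=self.random_state,
                    n_init=10)
        self.labels_ = km.fit_predict(km_X)
        self.scaffolds_ = scaffolds
        return self

    def to_dataframe(self, records: list[MoleculeRecord]) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in records],
            "scaffold": self.scaffolds_,
            "x": self.embedding_[:, 0],
            "y": self.embedding_[:, 1],
            "cluster": self.labels_,
        })


def cluster_scaffolds(records: list[MoleculeRecord], k: int = 11,
                      seed: int = 0, **kwargs):
    """Cluster labels and 2-D embedding for the records' Murcko scaffolds."""
    est = ScaffoldClusterer(k=k, random_state=seed, **kwargs).fit(records)
    return est.labels_, est.embedding_


def top_scaffolds(records: list[MoleculeRecord], n: int = 20) -> pd.DataFrame:
    """Top-N Murcko scaffold frequency table.

    Sorted by descending count, ties by scaffold SMILES; percents are
    relative to molecules with a non-empty scaffold.
    """
    counts = Counter(s for r in records if (s := murcko(r.smiles)))
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(
        [{"scaffold": s, "count": c, "percent": 100.0 * c / total}
         for s, c in rows]
    )
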