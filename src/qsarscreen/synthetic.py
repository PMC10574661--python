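"""Synthetic structure–activity benchmark generator.

Molecules are built by attaching substituents to ring scaffolds; their pIC50
is a linear function of substructure indicators plus Gaussian noise:

    pIC50_i = β0 + Σ_k β_k · 1[substructure k present in molecule i] + ε_i

with ε ~ N(0, σ²) and IC50 (μM) = 10^(6 − pIC50). Effect substructures are
SMARTS patterns that circular/key fingerprints and fragment-count
descriptors can detect, standing in for a real structure–activity signal.
Strong effects (≥ 1.5 pIC50 units each) are stacked on "active-type"
molecules so the high/weak classes of a gapped labeling scheme are
structurally well separated; decoy substituents carry zero or small
effects. Defaults: baseline β0 = 4 (IC50 100 μM), noise σ = 0.2, so
noiseless pIC50 spans roughly 4–9.5, matching the potency range a curated
inhibitor set covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .datasets import SCHEMES, ActivityDataset, LabelScheme, label
from .molecule_io import MoleculeRecord, deduplicate, standardize

DEFAULT_SCAFFOLDS = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2[nH]ccc2c1",    # indole
)

#: Substituents carrying a strong activity effect (attachment at [*]).
STRONG_SUBSTITUENTS = (
    "[*]S(N)(=O)=O",       # primary sulfonamide
    "[*]C(F)(F)F",         # trifluoromethyl
    "[*][N+](=O)[O-]",     # nitro
    "[*]C#N",              # nitrile
)

#: Decoy substituents with zero or small effects.
DECOY_SUBSTITUENTS = (
    "[*]C", "[*]CC", "[*]OC", "[*]O", "[*]Cl", "[*]N",
)

#: SMARTS → pIC50 effect β_k (indicator, not count).
DEFAULT_EFFECTS = {
    "S(=O)(=O)N": 2.0,         # sulfonamide
    "C(F)(F)F": 1.7,           # trifluoromethyl
    "[N+](=O)[O-]": 1.6,       # nitro
    "C#N": 1.8,                # nitrile
    "Cl": 0.3,                 # chloro
    "[OX2H][c]": -0.4,         # phenol
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of one synthetic library + activity model."""

    n_molecules: int = 2000
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    strong_pool: tuple[str, ...] = STRONG_SUBSTITUENTS
    decoy_pool: tuple[str, ...] = DECOY_SUBSTITUENTS
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline: float = 4.0
    noise_sd: float = 0.2
    p_active: float = 0.4       # fraction of active-type molecules
    p_mid: float = 0.1          # one strong group: lands in the gap
    max_substituents: int = 3
    seed: int = 0
    label_scheme: LabelScheme = SCHEMES["cox2_gap"]
    source: str = "synthetic"


def _attach(mol: Chem.Mol, sub_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Attach a [*]-anchored substituent to a random substitutable atom."""
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetTotalNumHs() >= 1 and a.GetIsAromatic()]
    if not sites:
        return None
    site = int(rng.choice(sites))
    sub = Chem.MolFromSmiles(sub_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    offset = mol.GetNumAtoms()
    dummy = next(a.GetIdx() for a in combo.GetAtoms()
                 if a.GetAtomicNum() == 0 and a.GetIdx() >= offset)
    anchor = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combo.AddBond(site, anchor, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _build_molecule(spec: SyntheticSpec, rng: np.random.Generator,
                    max_retries: int = 20) -> str:
    """One scaffold + substituent assembly; retries invalid combinations."""
    for _ in range(max_retries):
        mol = Chem.MolFromSmiles(str(rng.choice(spec.scaffolds)))
        kind = rng.random()
        if kind < spec.p_active:
            n_strong = int(rng.integers(2, min(4, len(spec.strong_pool) + 1)))
            subs = list(rng.choice(spec.strong_pool, size=n_strong,
                                   replace=False))
            n_decoy = int(rng.integers(0, 2))
        elif kind < spec.p_active + spec.p_mid:
            subs = [str(rng.choice(spec.strong_pool))]
            n_decoy = int(rng.integers(0, 2))
        else:
            subs = []
            n_decoy = int(rng.integers(1, spec.max_substituents + 1))
        subs += list(rng.choice(spec.decoy_pool, size=n_decoy, replace=False))
        ok = True
        for sub in subs:
            mol = _attach(mol, str(sub), rng)
            if mol is None:
                ok = False
                break
        if ok:
            return Chem.MolToSmiles(mol)
    raise RuntimeError("could not assemble a valid molecule within retry cap")


def generate_library(spec: SyntheticSpec,
                     id_prefix: str = "syn") -> list[MoleculeRecord]:
    """Generate an unlabeled, standardized library (seeded, reproducible)."""
    if not spec.scaffolds or not (spec.strong_pool or spec.decoy_pool):
        raise ValueError("scaffold and substituent pools must be non-empty")
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_molecules):
        smiles = _build_molecule(spec, rng)
        records.append(standardize(smiles, id=f"{id_prefix}_{i:05d}",
                                   source=spec.source))
    return records


def true_pic50(record: MoleculeRecord, spec: SyntheticSpec) -> float:
    """Noiseless pIC50 of a molecule under the spec's activity model."""
    mol = Chem.MolFromSmiles(record.smiles)
    value = spec.baseline
    for smarts, beta in spec.effects.items():
        if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts)):
            value += beta
    return value


def assign_activity(records: list[MoleculeRecord],
                    spec: SyntheticSpec) -> ActivityDataset:
    """Attach noisy activities; returns a regression dataset (pIC50).

    ε is drawn once per molecule from N(0, σ²) with the spec's seed; with
    σ = 0 the activity is a deterministic function of structure.
    """
    rng = np.random.default_rng(spec.seed + 10_000)
    eps = rng.normal(0.0, spec.noise_sd, size=len(records))
    labeled = []
    for rec, e in zip(records, eps):
        p = true_pic50(rec, spec) + float(e)
        labeled.append(MoleculeRecord(rec.id, rec.smiles, rec.source,
                                      ic50_um=10.0 ** (6.0 - p), pic50=p))
    return ActivityDataset.build(labeled, target="synthetic",
                                 task="regression")


@dataclass
class Benchmark:
    """A complete synthetic study with known ground truth."""

    classification: ActivityDataset     # labeled under the spec's scheme
    regression: ActivityDataset         # same molecules, pIC50 response
    external_classification: ActivityDataset
    external_regression: ActivityDataset
    screening_library: list[MoleculeRecord]   # unlabeled
    ground_truth: "object"              # DataFrame: id, true_pic50, planted
    spec_train: SyntheticSpec
    spec_screen: SyntheticSpec


def _planted_status(p: float, scheme: LabelScheme) -> str:
    lab = label(10.0 ** (6.0 - p), scheme)
    return {"high": "active", "weak": "inactive"}.get(lab, "mid")


def generate_benchmark(spec_train: SyntheticSpec | None = None,
                       spec_screen: SyntheticSpec | None = None,
                       n_external: int = 300) -> Benchmark:
    """Labeled dataset + external set + screening library + ground truth.

    The screening library's ground-truth table records, for every molecule,
    its noiseless pIC50 and whether it is a planted active (noiseless
    activity meets the high rule), a planted inactive (meets the weak rule)
    or mid-range.
    """
    import pandas as pd

    spec_train = spec_train or SyntheticSpec()
    spec_screen = spec_screen or replace(
        spec_train, n_molecules=500, p_active=0.15, p_mid=0.1,
        seed=spec_train.seed + 777)
    if spec_train.effects != spec_screen.effects or \
            spec_train.baseline != spec_screen.baseline:
        raise ValueError("train and screen specs must share the activity model")
    if spec_train.p_active > 0 and not spec_train.strong_pool:
        raise ValueError("class balance unattainable: no strong substituents")

    train_records = deduplicate(generate_library(spec_train, id_prefix="trn"))
    regression = assign_activity(train_records, spec_train)
    classification = ActivityDataset.build(
        regression.records, target="synthetic", task="classification",
        scheme=spec_train.label_scheme)

    spec_ext = replace(spec_train, n_molecules=n_external,
                       seed=spec_train.seed + 555)
    ext_records = deduplicate(generate_library(spec_ext, id_prefix="ext"))
    ext_regression = assign_activity(ext_records, spec_ext)
    ext_classification = ActivityDataset.build(
        ext_regression.records, target="synthetic", task="classification",
        scheme=spec_train.label_scheme)

    screen = deduplicate(generate_library(spec_screen, id_prefix="scr"))
    truth = pd.DataFrame([{
        "id": rec.id,
        "true_pic50": (p := true_pic50(rec, spec_train)),
        "true_ic50_um": 10.0 ** (6.0 - p),
        "planted": _planted_status(p, spec_train.label_scheme),
    } for rec in screen])

    return Benchmark(classification, regression, ext_classification,
                     ext_regression, screen, truth, spec_train, spec_screen)
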