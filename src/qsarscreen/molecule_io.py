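"""Reading, standardizing, deduplicating and writing compound libraries.

Compounds enter the pipeline as SMILES (CSV tables) or SD files, are
standardized (salt stripping, largest-organic-fragment selection, canonical
isomeric SMILES) and deduplicated on the canonical isomeric SMILES string.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Alkali / alkaline-earth cations treated as salt partners of simple salts.
_SALT_METALS = frozenset(
    ["Li", "Na", "K", "Rb", "Cs", "Be", "Mg", "Ca", "Sr", "Ba"]
)


class StandardizationError(ValueError):
    """Raised when a raw SMILES cannot be standardized.

    ``reason`` is ``"parse_error"`` for unparsable input and ``"inorganic"``
    when no organic fragment remains after salt stripping.
    """

    def __init__(self, reason: str, raw_smiles: str):
        self.reason = reason
        self.raw_smiles = raw_smiles
        super().__init__(f"{reason}: {raw_smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized compound.

    Parameters
    ----------
    id : str
        Opaque identifier.
    smiles : str
        Canonical isomeric SMILES (canonicalization is idempotent).
    source : str
        Free provenance tag (e.g. ``"synthetic"``).
    ic50_um : float or None
        IC50 in micromolar, strictly positive if present.
    pic50 : float or None
        Negative log10 of the molar IC50 (pIC50 = 6 − log10(IC50 μM)).
    """

    id: str
    smiles: str
    source: str = ""
    ic50_um: float | None = None
    pic50: float | None = None

    def __post_init__(self):
        if self.ic50_um is not None and not self.ic50_um > 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50_um}")


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Pick the organic fragment with the most heavy atoms.

    Metal counter-ions of simple salts are dropped; among remaining fragments
    the one with most heavy atoms wins, ties broken by longer canonical
    SMILES, then lexicographically.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    candidates = []
    for frag in frags:
        symbols = {a.GetSymbol() for a in frag.GetAtoms()}
        if symbols <= _SALT_METALS and len(frags) > 1:
            continue  # bare metal counter-ion
        if "C" not in symbols and "c" not in symbols:
            continue  # inorganic fragment
        candidates.append(frag)
    if not candidates:
        return None

    def key(frag: Chem.Mol):
        smi = Chem.MolToSmiles(frag)
        return (frag.GetNumHeavyAtoms(), len(smi), smi)

    return max(candidates, key=key)


def standardize(raw_smiles: str, id: str = "", source: str = "",
                ic50_um: float | None = None,
                pic50: float | None = None) -> MoleculeRecord:
    """Standardize a raw SMILES into a :class:`MoleculeRecord`.

    Disconnects metal counter-ions of simple salts, keeps only the largest
    organic fragment and emits the canonical isomeric SMILES. Charged acids
    are not neutralized.

    Raises
    ------
    StandardizationError
        With ``reason="parse_error"`` on unparsable input and
        ``reason="inorganic"`` when no organic fragment remains.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise StandardizationError("parse_error", raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise StandardizationError("parse_error", raw_smiles)
    frag = _largest_organic_fragment(mol)
    if frag is None:
        raise StandardizationError("inorganic", raw_smiles)
    smiles = Chem.MolToSmiles(frag)  # canonical isomeric by default
    return MoleculeRecord(id=id, smiles=smiles, source=source,
                          ic50_um=ic50_um, pic50=pic50)


def deduplicate(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep the first record per distinct canonical isomeric SMILES.

    The key is stereo-aware: E/Z and R/S isomers are distinct compounds.
    Input order is otherwise preserved.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.smiles not in seen:
            seen.add(rec.smiles)
            out.append(rec)
    return out


@dataclass
class ReadReport:
    """Outcome of a library read: records kept plus per-row skips."""

    records: list[MoleculeRecord] = field(default_factory=list)
    n_skipped: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)


def _parse_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    return float(s)


def read_library(path: str | Path, format: str | None = None,
                 smiles_column: str = "smiles") -> ReadReport:
    """Read a compound library from CSV or SDF, standardizing every row.

    CSV columns: ``id``, ``smiles`` (required), optional ``ic50_um``,
    ``pic50``, ``source``. SDF molecules may carry ``IC50_uM`` / ``pIC50``
    properties. Rows that fail to parse are logged, counted and skipped.
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    report = ReadReport()
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise ValueError(
                    f"CSV {path} lacks a {smiles_column!r} column "
                    f"(found {reader.fieldnames})"
                )
            for i, row in enumerate(reader):
                rid = row.get("id") or f"row{i}"
                try:
                    rec = standardize(
                        row[smiles_column], id=rid,
                        source=row.get("source", "") or "",
                        ic50_um=_parse_float(row.get("ic50_um")),
                        pic50=_parse_float(row.get("pic50")),
                    )
                except (StandardizationError, ValueError) as exc:
                    report.n_skipped += 1
                    report.skipped.append((rid, str(exc)))
                    logger.warning("skipping row %s: %s", rid, exc)
                    continue
                report.records.append(rec)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            rid = f"mol{i}"
            if mol is None:
                report.n_skipped += 1
                report.skipped.append((rid, "parse_error"))
                continue
            if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rid = mol.GetProp("_Name").strip()
            props = mol.GetPropsAsDict()
            try:
                rec = standardize(
                    Chem.MolToSmiles(mol), id=rid,
                    source=str(props.get("source", "")),
                    ic50_um=_parse_float(props.get("IC50_uM")),
                    pic50=_parse_float(props.get("pIC50")),
                )
            except (StandardizationError, ValueError) as exc:
                report.n_skipped += 1
                report.skipped.append((rid, str(exc)))
                continue
            report.records.append(rec)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if report.n_skipped:
        logger.info("read %d records, skipped %d rows",
                    len(report.records), report.n_skipped)
    return report


def write_library(records: list[MoleculeRecord], path: str | Path,
                  format: str | None = None) -> None:
    """Write records to CSV or SDF; write→read round-trips id/smiles/activity."""
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "ic50_um", "pic50", "source"])
            for rec in records:
                writer.writerow([
                    rec.id, rec.smiles,
                    "" if rec.ic50_um is None else repr(rec.ic50_um),
                    "" if rec.pic50 is None else repr(rec.pic50),
                    rec.source,
                ])
    elif format == "sdf":
        with Chem.SDWriter(str(path)) as writer:
            for rec in records:
                mol = Chem.MolFromSmiles(rec.smiles)
                mol.SetProp("_Name", rec.id)
                if rec.source:
                    mol.SetProp("source", rec.source)
                if rec.ic50_um is not None:
                    mol.SetProp("IC50_uM", repr(rec.ic50_um))
                if rec.pic50 is not None:
                    mol.SetProp("pIC50", repr(rec.pic50))
                writer.write(mol)
    else:
        raise ValueError(f"unsupported format {format!r}")


def to_mols(records: list[MoleculeRecord]) -> list[Chem.Mol]:
    """RDKit molecules for standardized records (all parse by invariant)."""
    return [Chem.MolFromSmiles(r.smiles) for r in records]
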