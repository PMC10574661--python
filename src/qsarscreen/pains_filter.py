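"""Known-aggregator matching for promiscuous-compound (PAINS-style) filtering.

Candidates are compared against a reference list of known small-molecule
aggregators. The default rule flags a candidate only on exact structural
identity (canonical isomeric SMILES match, equivalently MACCS Tanimoto of
1.0); a lower similarity threshold turns the filter into an advisory
nearest-aggregator report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemspace import tanimoto
from .featurize import FeatureMatrix, fingerprints
from .molecule_io import MoleculeRecord, deduplicate, read_library, standardize

logger = logging.getLogger(__name__)


@dataclass
class AggregatorSet:
    """Standardized, deduplicated aggregator references with MACCS cache."""

    records: list[MoleculeRecord]
    fingerprints: FeatureMatrix  # MACCS, one row per record

    @property
    def n(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, records: list[MoleculeRecord]) -> "AggregatorSet":
        records = deduplicate(records)
        return cls(records, fingerprints(records, "maccs166"))


def load_aggregators(path) -> AggregatorSet:
    """Load an aggregator SMILES table; unparsable rows are logged/skipped."""
    report = read_library(path, format="csv")
    if not report.records:
        raise ValueError(f"no valid aggregator molecules in {path}")
    aggset = AggregatorSet.from_records(report.records)
    logger.info("loaded %d aggregators (%d rows skipped)",
                aggset.n, report.n_skipped)
    return aggset


def flag_aggregator(candidate: MoleculeRecord, aggset: AggregatorSet,
                    threshold: float = 1.0) -> tuple[bool, str | None, float]:
    """(flag, best_match_id, best_similarity) against the aggregator set.

    Flags iff the candidate's canonical SMILES is identical to an
    aggregator's, or its best MACCS Tanimoto reaches ``threshold``.
    """
    if aggset.n == 0:
        return False, None, 0.0
    cand_fp = fingerprints([candidate], "maccs166").values[0]
    sims = np.array([tanimoto(cand_fp, row)
                     for row in aggset.fingerprints.values])
    best = int(np.argmax(sims))
    best_sim = float(sims[best])
    identical = any(candidate.smiles == r.smiles for r in aggset.records)
    flag = identical or best_sim >= threshold
    return flag, aggset.records[best].id, best_sim


def flag_table(candidates: list[MoleculeRecord], aggset: AggregatorSet,
               threshold: float = 1.0) -> pd.DataFrame:
    """Per-candidate aggregator flags as a table."""
    rows = []
    for rec in candidates:
        flag, match, sim = flag_aggregator(rec, aggset, threshold)
        rows.append({"id": rec.id, "aggregator_flag": flag,
                     "best_match": match, "similarity": sim})
    return pd.DataFrame(rows)
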