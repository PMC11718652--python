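"""Fingerprint similarity metrics and the library-vs-query Tanimoto profile.

All metrics operate on on-bit sets rather than dense 0/1 vectors, which
keeps the per-comparison cost proportional to the number of set bits — the
property that makes screening million-compound libraries tractable.  The
values are identical to the dense-vector definitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .chem_graph import MolecularGraph, SmilesParseError, parse_smiles
from .fingerprints import Fingerprint, morgan_fingerprint, pharmacophore_fingerprint

__all__ = [
    "ParseFailure",
    "SimilarityTable",
    "tanimoto",
    "cosine_similarity",
    "euclidean_distance",
    "similarity_profile",
]

logger = logging.getLogger(__name__)


def _check_comparable(a: Fingerprint, b: Fingerprint) -> None:
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B| of the on-bit sets.

    Two all-zero fingerprints score 0.0: an empty bit pattern carries no
    evidence of similarity.
    """
    _check_comparable(a, b)
    sa, sb = a.bit_set, b.bit_set
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def cosine_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Cosine of the angle between the binary vectors: |A∩B| / sqrt(|A||B|)."""
    _check_comparable(a, b)
    sa, sb = a.bit_set, b.bit_set
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


def euclidean_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Euclidean distance between the binary vectors: sqrt(|A Δ B|)."""
    _check_comparable(a, b)
    return math.sqrt(len(a.bit_set ^ b.bit_set))


@dataclass(frozen=True)
class ParseFailure:
    """One library compound that could not be parsed."""

    compound_id: str
    row_number: int
    smiles: str
    reason: str


@dataclass
class SimilarityTable:
    """Per-compound Tanimoto similarities to the query, both fingerprints.

    ``frame`` columns: id, smiles, tanimoto_morgan, tanimoto_pharmacophore,
    one row per successfully parsed compound in input order.  Parse failures
    are kept in ``failures`` — logged, never silently dropped.
    """

    frame: pd.DataFrame
    query_id: str
    failures: list[ParseFailure] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def similarity_profile(library, query: MolecularGraph | str,
                       query_id: str = "query", radius: int = 2,
                       n_bits: int = 2048) -> SimilarityTable:
    """Compute the dual Tanimoto profile of a library against one query.

    Parameters
    ----------
    library
        Iterable of records carrying ``id`` and ``smiles`` attributes, or
        plain ``(id, smiles)`` pairs.
    query
        The reference molecule (graph or SMILES).  A query parse failure
        aborts; per-compound failures are recorded and skipped.
    """
    if isinstance(query, str):
        query = parse_smiles(query)  # propagate: the query must parse
    q_morgan = morgan_fingerprint(query, radius, n_bits)
    q_pharm = pharmacophore_fingerprint(query)

    rows = []
    failures: list[ParseFailure] = []
    n_seen = 0
    for row_number, rec in enumerate(library):
        n_seen += 1
        if hasattr(rec, "smiles"):
            cid, smi = rec.id, rec.smiles
        else:
            cid, smi = rec
        try:
            g = parse_smiles(smi)
        except SmilesParseError as exc:
            failures.append(ParseFailure(cid, row_number, smi, str(exc)))
            logger.warning("skipping %s (row %d): %s", cid, row_number, exc)
            continue
        rows.append({
            "id": cid,
            "smiles": smi,
            "tanimoto_morgan": tanimoto(
                q_morgan, morgan_fingerprint(g, radius, n_bits)),
            "tanimoto_pharmacophore": tanimoto(
                q_pharm, pharmacophore_fingerprint(g)),
        })
    if n_seen == 0:
        raise ValueError("library is empty")
    frame = pd.DataFrame(
        rows, columns=["id", "smiles", "tanimoto_morgan",
                       "tanimoto_pharmacophore"])
    logger.info("similarity profile: %d/%d compounds parsed (%d failures)",
                len(frame), n_seen, len(failures))
    return SimilarityTable(frame=frame, query_id=query_id, failures=failures)
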