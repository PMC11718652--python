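"""Deterministic synthetic screening libraries with planted query analogs.

A synthetic library emulates the similarity structure a ligand-based screen
assumes: a small series of close analogs of the query (generated by
decorating the query scaffold with common substituents) hidden among
structurally unrelated drug-like decoys drawn from a fixed scaffold pool.
Labels (analog vs decoy) are carried separately from the screen's input so
recovery can be evaluated without leaking them into the pipeline.

Everything is a pure function of the generation spec: same spec, same
library, byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .chem_graph import MolecularGraph, parse_smiles

__all__ = [
    "DEFAULT_QUERY_SMILES",
    "SUBSTITUENTS",
    "DECOY_SCAFFOLDS",
    "SyntheticLibrarySpec",
    "LibraryEntry",
    "generate_analogs",
    "generate_decoys",
    "generate_library",
]

#: A drug-like 1,4-benzodiazepin-2-one query (diazepam): two aromatic
#: rings, an amide, a ring nitrogen and a chlorine — enough substructure
#: for both fingerprint types to be informative.
DEFAULT_QUERY_SMILES = "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21"

#: Substituent palette appended at substitutable positions.
SUBSTITUENTS = ("C", "O", "F", "N", "OC")

#: Diverse drug-like decoy scaffolds, deliberately unrelated to the
#: benzodiazepinone query: chains, saturated rings, small heteroaromatics.
DECOY_SCAFFOLDS = (
    "CCCCCC", "CCCCCCCC", "CCCCCCCCCC", "CC(C)CCCC", "CC(C)CC(C)C",
    "CCCCO", "CCCCCO", "CCCCN", "CCCCCN", "CCCCC(=O)O", "CCCC(=O)OC",
    "CCCC(=O)N", "CC(=O)CCCC", "CCOCC", "CCOCCOCC", "CCSCC",
    "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "CC1CCCCC1", "C1CCOCC1",
    "C1CCNCC1", "C1CCSCC1", "O1CCOCC1", "C1CCCCC1C1CCCCC1",
    "C1CCCCC1CCCC", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1ccncc1",
    "c1ccoc1CCC", "c1ccsc1CC", "CCc1ccncc1", "C1CCNCC1C(=O)O",
    "OC1CCCCC1", "NC1CCCCC1",
)

_RING_CLOSURE_RE = re.compile(r"[-=#:]?(?:\d|%\d\d)")


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of one synthetic library; generation is pure in these."""

    query_smiles: str = DEFAULT_QUERY_SMILES
    n_analogs: int = 20
    n_decoys: int = 200
    seed: int = 7
    depth: int = 1

    def __post_init__(self):
        if self.n_analogs < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if self.n_analogs + self.n_decoys < 2:
            raise ValueError("library must contain at least 2 compounds")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class LibraryEntry:
    """One library record; ``is_analog`` is evaluation-only ground truth."""

    id: str
    smiles: str
    is_analog: bool


def _substitutable_positions(graph: MolecularGraph) -> list[int]:
    """Atoms where a branch can be spliced into the source string.

    Requires a spare implicit hydrogen; bracket atoms are excluded because
    splicing a branch after ``[nH]`` would invalidate the written H count.
    """
    out = []
    for atom, (start, _) in zip(graph.atoms, graph.atom_spans):
        if atom.implicit_h >= 1 and graph.source_smiles[start] != "[":
            out.append(atom.index)
    return out


def _insertion_point(smiles: str, span_end: int) -> int:
    """Skip ring-closure tokens trailing an atom token."""
    i = span_end
    while True:
        m = _RING_CLOSURE_RE.match(smiles, i)
        if m is None:
            return i
        i = m.end()


def _decorate_once(smiles: str, rng: np.random.Generator) -> str:
    graph = parse_smiles(smiles)
    positions = _substitutable_positions(graph)
    if not positions:
        raise ValueError(
            f"no substitutable position (atom with a spare implicit H) "
            f"in {smiles!r}")
    atom = positions[int(rng.integers(len(positions)))]
    sub = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
    at = _insertion_point(smiles, graph.atom_spans[atom][1])
    return f"{smiles[:at]}({sub}){smiles[at:]}"


def generate_analogs(query: MolecularGraph | str, n: int, depth: int,
                     seed: int) -> list[str]:
    """``n`` analogs of the query, each with up to ``depth`` decorations.

    Every analog parses and contains the query's heavy-atom scaffold as a
    subgraph by construction; ``depth=0`` returns plain copies.
    """
    if isinstance(query, str):
        query = parse_smiles(query)
    if depth > 0 and not _substitutable_positions(query):
        raise ValueError("query has no substitutable position")
    rng = np.random.default_rng([seed, 1])
    out = []
    for _ in range(n):
        smi = query.source_smiles.strip()
        for _ in range(depth):
            try:
                smi = _decorate_once(smi, rng)
            except ValueError:
                break  # fully decorated: keep what we have
        parse_smiles(smi)  # construction guarantee, cheap to enforce
        out.append(smi)
    return out


def generate_decoys(n: int, seed: int) -> list[str]:
    """``n`` decoys sampled from the scaffold pool, half of them decorated."""
    rng = np.random.default_rng([seed, 2])
    out = []
    for _ in range(n):
        smi = DECOY_SCAFFOLDS[int(rng.integers(len(DECOY_SCAFFOLDS)))]
        if rng.random() < 0.5:
            try:
                smi = _decorate_once(smi, rng)
            except ValueError:
                pass
        out.append(smi)
    return out


def generate_library(spec: SyntheticLibrarySpec) -> list[LibraryEntry]:
    """Analogs + decoys, seed-shuffled, with evaluation labels retained.

    Identifiers are positional (``cmpd_00042``) and carry no information
    about the label; the screen input is (id, smiles) only.
    """
    analogs = generate_analogs(spec.query_smiles, spec.n_analogs, spec.depth,
                               spec.seed)
    decoys = generate_decoys(spec.n_decoys, spec.seed)
    labeled = [(smi, True) for smi in analogs] + [(smi, False)
                                                  for smi in decoys]
    rng = np.random.default_rng([spec.seed, 3])
    order = rng.permutation(len(labeled))
    return [LibraryEntry(id=f"cmpd_{pos:05d}", smiles=labeled[i][0],
                         is_analog=labeled[i][1])
            for pos, i in enumerate(order)]
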