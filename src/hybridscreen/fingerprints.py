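"""Morgan (ECFP-style) and 2D pharmacophore pair fingerprints.

Both fingerprint generators are implemented natively on the package's own
molecular graph; no third-party cheminformatics code is involved.  All
hashing uses an explicit 32-bit polynomial mix so that bit patterns are
stable across platforms and runs.

The Morgan fingerprint iteratively rehashes each atom's identifier from its
previous identifier and its sorted (bond order, neighbor identifier) list,
pools the identifiers of all rounds 0..radius, and folds them modulo the
bit-vector length (default radius 2, 2048 bits — the usual ECFP4
conventions).

The pharmacophore fingerprint assigns feature families (donor, acceptor,
aromatic ring, hydrophobe, positive/negative ionizable) by explicit rules,
then sets one exact bit per unordered family pair and binned topological
distance: 21 family pairs x 6 distance bins = 126 bits, no hashing and
hence no collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .chem_graph import (
    AROMATIC,
    DOUBLE,
    MolecularGraph,
    ring_info,
    topological_distances,
    UNREACHABLE,
)

__all__ = [
    "Fingerprint",
    "PharmacophoreFeature",
    "FAMILIES",
    "N_FAMILY_PAIRS",
    "DISTANCE_BIN_EDGES",
    "N_DISTANCE_BINS",
    "PHARMACOPHORE_N_BITS",
    "atom_invariants",
    "morgan_identifiers",
    "morgan_fingerprint",
    "assign_pharmacophore_features",
    "pharmacophore_fingerprint",
    "fold_bits",
    "pair_rank",
    "decode_pharmacophore_bit",
    "distance_bin",
]

_MOD = 1 << 32


def _mix(values: Iterable[int]) -> int:
    """Stable 32-bit polynomial hash: h = 17; h <- (31*h + c) mod 2^32."""
    h = 17
    for c in values:
        h = (h * 31 + c) % _MOD
    return h


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint stored as its sorted on-bit indices."""

    kind: str  # "morgan" | "pharmacophore"
    n_bits: int
    on_bits: tuple[int, ...]
    params: tuple = ()

    def __post_init__(self):
        bits = tuple(self.on_bits)
        if any(b1 >= b2 for b1, b2 in zip(bits, bits[1:])):
            object.__setattr__(self, "on_bits", tuple(sorted(set(bits))))
        if bits and (bits[0] < 0 or max(bits) >= self.n_bits):
            raise ValueError("on-bit index out of range")

    @property
    def bit_set(self) -> frozenset[int]:
        return frozenset(self.on_bits)

    def density(self) -> float:
        return len(self.on_bits) / self.n_bits


# ---------------------------------------------------------------------------
# Morgan / ECFP

def atom_invariants(graph: MolecularGraph) -> list[int]:
    """Initial per-atom identifiers.

    Each atom's tuple (atomic number, heavy-atom degree, total H count,
    formal charge, aromatic flag, ring flag) is hashed with the stable mix.
    """
    adj = graph.adjacency()
    out = []
    for atom in graph.atoms:
        tup = (atom.atomic_number, len(adj[atom.index]), atom.total_h,
               atom.formal_charge, int(atom.aromatic), int(atom.in_ring))
        out.append(_mix(tup))
    return out


def morgan_identifiers(graph: MolecularGraph, radius: int) -> set[int]:
    """Pooled environment identifiers of rounds 0..radius, deduplicated.

    Degree-zero atoms contribute only their round-0 identifier: with no
    neighbors there is no larger environment to encode.
    """
    if radius < 0 or radius > 6:
        raise ValueError("radius must be in [0, 6]")
    adj = graph.adjacency()
    ids = atom_invariants(graph)
    pool: set[int] = set(ids)
    current = list(ids)
    for _ in range(radius):
        nxt = []
        for idx in range(graph.n_atoms):
            if not adj[idx]:
                nxt.append(current[idx])
                continue
            nbrs = sorted((order, current[nb]) for nb, order in adj[idx])
            flat = [current[idx]]
            for order, nid in nbrs:
                flat.append(order)
                flat.append(nid)
            nxt.append(_mix(flat))
        current = nxt
        pool.update(x for idx, x in enumerate(current) if adj[idx])
    return pool


def fold_bits(identifiers: Iterable[int], n_bits: int) -> set[int]:
    """Fold 32-bit identifiers into bit indices by ``id mod n_bits``."""
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    return {i % n_bits for i in identifiers}


def morgan_fingerprint(graph: MolecularGraph, radius: int = 2,
                       n_bits: int = 2048) -> Fingerprint:
    """ECFP-style circular fingerprint of the molecule."""
    if n_bits <= 0 or n_bits & (n_bits - 1):
        raise ValueError("n_bits must be a positive power of two")
    pool = morgan_identifiers(graph, radius)
    return Fingerprint("morgan", n_bits, tuple(sorted(fold_bits(pool, n_bits))),
                       params=(("radius", radius),))


# ---------------------------------------------------------------------------
# Pharmacophore features

FAMILIES = ("donor", "acceptor", "aromatic", "hydrophobe",
            "pos_ionizable", "neg_ionizable")
_FAMILY_INDEX = {f: i for i, f in enumerate(FAMILIES)}
N_FAMILY_PAIRS = len(FAMILIES) * (len(FAMILIES) + 1) // 2  # 21 unordered

#: Lower edges of the topological-distance bins (bond counts);
#: the last bin is open-ended.
DISTANCE_BIN_EDGES = (0, 1, 2, 4, 6, 8)
N_DISTANCE_BINS = len(DISTANCE_BIN_EDGES)
PHARMACOPHORE_N_BITS = N_FAMILY_PAIRS * N_DISTANCE_BINS  # 126


@dataclass(frozen=True)
class PharmacophoreFeature:
    family: str
    atom_indices: tuple[int, ...]

    def __post_init__(self):
        if self.family not in _FAMILY_INDEX:
            raise ValueError(f"unknown feature family {self.family!r}")
        if not self.atom_indices:
            raise ValueError("feature with no atoms")


def _halogen(el: str) -> bool:
    return el in ("F", "Cl", "Br", "I")


def assign_pharmacophore_features(
        graph: MolecularGraph) -> list[PharmacophoreFeature]:
    """Rule-based feature assignment on the heavy-atom graph.

    donor: N/O with >=1 H and charge >= 0.
    acceptor: N/O with charge <= 0, except aromatic N-H.
    aromatic: one feature per aromatic ring (full atom set).
    hydrophobe: halogen, or a non-aromatic carbon all of whose neighbors
        are carbon (aromatic carbons are already covered by the ring
        feature; including them would make every benzene carbon a
        hydrophobe).
    pos_ionizable: positive formal charge, or an aliphatic amine N (only
        C/H neighbors, not adjacent to a carbonyl carbon).
    neg_ionizable: negative formal charge, or the hydroxyl O of a
        carboxylic acid.
    """
    adj = graph.adjacency()
    atoms = graph.atoms

    def neighbor_atoms(i):
        return [(atoms[nb], order) for nb, order in adj[i]]

    def adjacent_carbonyl_carbon(i):
        for nb, _ in adj[i]:
            if atoms[nb].element != "C":
                continue
            for nb2, order2 in adj[nb]:
                if order2 == DOUBLE and atoms[nb2].element == "O":
                    return True
        return False

    feats: list[PharmacophoreFeature] = []
    for atom in atoms:
        i = atom.index
        el = atom.element
        if el in ("N", "O"):
            if atom.total_h >= 1 and atom.formal_charge >= 0:
                feats.append(PharmacophoreFeature("donor", (i,)))
            if atom.formal_charge <= 0 and not (
                    el == "N" and atom.aromatic and atom.total_h >= 1):
                feats.append(PharmacophoreFeature("acceptor", (i,)))
        if _halogen(el) or (
                el == "C" and not atom.aromatic and adj[i]
                and all(a.element == "C" for a, _ in neighbor_atoms(i))):
            feats.append(PharmacophoreFeature("hydrophobe", (i,)))
        if atom.formal_charge > 0 or (
                el == "N" and not atom.aromatic
                and all(a.element == "C" for a, _ in neighbor_atoms(i))
                and not adjacent_carbonyl_carbon(i)):
            feats.append(PharmacophoreFeature("pos_ionizable", (i,)))
        if atom.formal_charge < 0:
            feats.append(PharmacophoreFeature("neg_ionizable", (i,)))
        elif (el == "O" and atom.total_h >= 1
              and adjacent_carbonyl_carbon(i)):
            feats.append(PharmacophoreFeature("neg_ionizable", (i,)))
    _, aromatic_rings = ring_info(graph)
    for ring in aromatic_rings:
        feats.append(PharmacophoreFeature("aromatic", tuple(sorted(ring))))
    feats.sort(key=lambda f: (_FAMILY_INDEX[f.family], min(f.atom_indices),
                              f.atom_indices))
    return feats


def pair_rank(family_a: str, family_b: str) -> int:
    """Lexicographic rank of an unordered family pair among the 21 pairs."""
    i, j = sorted((_FAMILY_INDEX[family_a], _FAMILY_INDEX[family_b]))
    nf = len(FAMILIES)
    return i * nf - i * (i - 1) // 2 + (j - i)


def distance_bin(d: int) -> int:
    """Bin a bond-count distance: [0], [1], [2-3], [4-5], [6-7], [8,inf)."""
    if d < 0:
        raise ValueError("negative distance")
    for b in range(N_DISTANCE_BINS - 1, -1, -1):
        if d >= DISTANCE_BIN_EDGES[b]:
            return b
    raise AssertionError


def decode_pharmacophore_bit(bit: int) -> tuple[tuple[str, str], int]:
    """Inverse of the pair-rank/bin encoding: bit -> (family pair, bin)."""
    rank, b = divmod(bit, N_DISTANCE_BINS)
    nf = len(FAMILIES)
    for i in range(nf):
        row = nf - i
        if rank < row:
            return (FAMILIES[i], FAMILIES[i + rank]), b
        rank -= row
    raise ValueError(f"bit {bit} out of range")


def pharmacophore_fingerprint(graph: MolecularGraph) -> Fingerprint:
    """Exact 126-bit feature-pair / distance-bin fingerprint.

    The distance between two features is the minimum bond-count distance
    between their atom sets; pairs spanning disconnected components are
    skipped.
    """
    feats = assign_pharmacophore_features(graph)
    bits: set[int] = set()
    if len(feats) >= 2:
        dist = topological_distances(graph)
        for a in range(len(feats)):
            fa = feats[a]
            for b in range(a + 1, len(feats)):
                fb = feats[b]
                reachable = [int(dist[i, j])
                             for i in fa.atom_indices
                             for j in fb.atom_indices
                             if dist[i, j] != UNREACHABLE]
                if not reachable:
                    continue  # features on different components
                bits.add(pair_rank(fa.family, fb.family) * N_DISTANCE_BINS
                         + distance_bin(min(reachable)))
    return Fingerprint("pharmacophore", PHARMACOPHORE_N_BITS,
                       tuple(sorted(bits)))
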