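"""SMILES parsing into molecular graphs.

Supports the organic-subset dialect common to large screening libraries
(ZINC-style aromatic SMILES): atoms B C N O P S F Cl Br I, aromatic
b c n o p s, bracket atoms with charge / explicit hydrogen counts,
branches, ring closures (digits and ``%nn``), bond symbols ``- = # :``
and dot-disconnection.  Stereo markers (``/ \\ @``) and isotopes are
accepted and ignored: every downstream fingerprint here is stereo-agnostic.

Aromaticity is taken from the input (lowercase atoms / ``:`` bonds); no
independent aromaticity perception is performed.  Implicit hydrogens are
assigned from default valences (B 3, C 4, N 3, O 2, P 3, S 2, halogens 1),
with P allowed to promote to 5 and S to 4 or 6 when the explicit bond-order
sum demands it.  For aromatic atoms the bond-order sum counts each aromatic
bond as 1 plus 1 for the delocalised system, so a benzene carbon gets one
hydrogen and a pyridine nitrogen none, without kekulisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "SmilesParseError",
    "RingClosureError",
    "ParenthesisError",
    "UnknownElementError",
    "ValenceError",
    "AromaticityError",
    "parse_smiles",
    "topological_distances",
    "ring_info",
    "UNREACHABLE",
]

# ---------------------------------------------------------------------------
# Errors

class SmilesParseError(ValueError):
    """Malformed SMILES. ``position`` is the 0-based offset of the offence."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class RingClosureError(SmilesParseError):
    """Ring-closure label opened but never closed, or closed inconsistently."""


class ParenthesisError(SmilesParseError):
    """Unbalanced branch parentheses."""


class UnknownElementError(SmilesParseError):
    """Token is not an element of the supported dialect."""


class ValenceError(SmilesParseError):
    """Bond-order sum exceeds the allowed valence of an atom."""


class AromaticityError(SmilesParseError):
    """Aromatic atom not part of any cycle of aromatic bonds."""


# ---------------------------------------------------------------------------
# Domain types

SINGLE, DOUBLE, TRIPLE, AROMATIC = 1, 2, 3, 4

#: Marker for pairs of atoms in different connected components.
UNREACHABLE = -1

_ATOMIC_NUMBER = {
    "B": 5, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "F": 9, "Cl": 17, "Br": 35, "I": 53,
}
_DEFAULT_VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}
# hypervalent promotion ladders for the third row
_PROMOTED_VALENCES = {"P": (3, 5), "S": (2, 4, 6)}

_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = set("BCNOPSFI")
_AROMATIC_ONE = set("bcnops")
_BOND_CHARS = {"-": SINGLE, "=": DOUBLE, "#": TRIPLE, ":": AROMATIC,
               "/": SINGLE, "\\": SINGLE}

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?"
    r"(?P<element>Cl|Br|[BCNOPSFI]|[bcnops])"
    r"(?P<chiral>@{1,2})?"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+{1,3}|-{1,3}|\+\d|-\d)?"
    r"(?::(?P<map>\d+))?"
    r"\]"
)


@dataclass(frozen=True)
class Atom:
    """A heavy atom of the molecular graph.

    ``explicit_h`` is the bracket hydrogen count (−1 when the source did
    not specify one); ``implicit_h`` is the valence-derived count and is 0
    for atoms whose bracket fixed the hydrogens explicitly.
    """

    index: int
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    explicit_h: int = -1
    implicit_h: int = 0
    in_ring: bool = False

    @property
    def atomic_number(self) -> int:
        return _ATOMIC_NUMBER[self.element]

    @property
    def total_h(self) -> int:
        """Hydrogens attached to this atom, implicit plus explicit."""
        return self.implicit_h + max(self.explicit_h, 0)


@dataclass(frozen=True)
class Bond:
    atom_a: int
    atom_b: int
    order_code: int  # 1 single, 2 double, 3 triple, 4 aromatic
    in_ring: bool = False

    def other(self, idx: int) -> int:
        return self.atom_b if idx == self.atom_a else self.atom_a


@dataclass(frozen=True)
class MolecularGraph:
    """Parsed molecule: atoms in SMILES token order, bonds, source string.

    ``atom_spans`` records each atom's token span in ``source_smiles``
    (used by the analog generator to splice substituents in place).
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    source_smiles: str
    atom_spans: tuple[tuple[int, int], ...] = field(default=(), compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order_code) pairs for one atom."""
        out = []
        for b in self.bonds:
            if b.atom_a == idx:
                out.append((b.atom_b, b.order_code))
            elif b.atom_b == idx:
                out.append((b.atom_a, b.order_code))
        return out

    def adjacency(self) -> list[list[tuple[int, int]]]:
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.atom_a].append((b.atom_b, b.order_code))
            adj[b.atom_b].append((b.atom_a, b.order_code))
        return adj


# ---------------------------------------------------------------------------
# Tokenizer / parser

@dataclass
class _PendingAtom:
    element: str
    aromatic: bool
    charge: int
    explicit_h: int
    bracket: bool
    span: tuple[int, int]


def _parse_bracket(s: str, i: int) -> tuple[_PendingAtom, int]:
    m = _BRACKET_RE.match(s, i)
    if m is None:
        # find something to blame: the element token inside the bracket
        raise UnknownElementError(
            f"cannot read bracket atom {s[i:i + 12]!r}", i)
    elem = m.group("element")
    aromatic = elem.islower()
    hcount = -1
    if m.group("hcount") is not None:
        digits = m.group("hcount")[1:]
        hcount = int(digits) if digits else 1
    charge = 0
    cg = m.group("charge")
    if cg:
        if cg[-1].isdigit():
            charge = int(cg[1:]) * (1 if cg[0] == "+" else -1)
        else:
            charge = len(cg) * (1 if cg[0] == "+" else -1)
    return _PendingAtom(elem.capitalize() if aromatic else elem,
                        aromatic, charge, hcount, True,
                        (i, m.end())), m.end()


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises a subclass of :class:`SmilesParseError` naming the offending
    position for unmatched ring closures, unbalanced parentheses, unknown
    element tokens and valence deficits.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string", 0)
    s = smiles.strip()

    atoms: list[_PendingAtom] = []
    bonds: list[tuple[int, int, int | None, int]] = []  # a, b, order, pos
    stack: list[int] = []
    prev: int | None = None
    pending_bond: int | None = None
    pending_bond_pos = -1
    ring_open: dict[int, tuple[int, int | None, int]] = {}

    def add_atom(pa: _PendingAtom) -> None:
        nonlocal prev, pending_bond
        idx = len(atoms)
        atoms.append(pa)
        if prev is not None:
            bonds.append((prev, idx, pending_bond, pa.span[0]))
        pending_bond = None
        prev = idx

    def close_ring(label: int, pos: int) -> None:
        nonlocal pending_bond
        if prev is None:
            raise RingClosureError("ring closure before any atom", pos)
        if label in ring_open:
            other, bond_there, pos_there = ring_open.pop(label)
            if other == prev:
                raise RingClosureError(
                    f"ring closure {label} bonds an atom to itself", pos)
            order = pending_bond if pending_bond is not None else bond_there
            if (pending_bond is not None and bond_there is not None
                    and pending_bond != bond_there):
                raise RingClosureError(
                    f"conflicting bond orders on ring closure {label}", pos)
            bonds.append((other, prev, order, pos))
            pending_bond = None
        else:
            ring_open[label] = (prev, pending_bond, pos)
            pending_bond = None

    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == "(":
            if prev is None:
                raise ParenthesisError("branch before any atom", i)
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise ParenthesisError("unmatched closing parenthesis", i)
            prev = stack.pop()
            i += 1
        elif c == ".":
            prev = None
            pending_bond = None
            i += 1
        elif c in _BOND_CHARS:
            pending_bond = _BOND_CHARS[c]
            pending_bond_pos = i
            i += 1
        elif c.isdigit():
            close_ring(int(c), i)
            i += 1
        elif c == "%":
            if i + 2 >= n + 1 or not s[i + 1:i + 3].isdigit():
                raise RingClosureError("malformed %nn ring label", i)
            close_ring(int(s[i + 1:i + 3]), i)
            i += 3
        elif c == "[":
            pa, j = _parse_bracket(s, i)
            add_atom(pa)
            i = j
        elif s[i:i + 2] in _ORGANIC_TWO:
            add_atom(_PendingAtom(s[i:i + 2], False, 0, -1, False, (i, i + 2)))
            i += 2
        elif c in _ORGANIC_ONE:
            add_atom(_PendingAtom(c, False, 0, -1, False, (i, i + 1)))
            i += 1
        elif c in _AROMATIC_ONE:
            add_atom(_PendingAtom(c.upper(), True, 0, -1, False, (i, i + 1)))
            i += 1
        else:
            raise UnknownElementError(f"unknown token {c!r}", i)

    if stack:
        raise ParenthesisError(
            f"{len(stack)} unclosed parenthesis(es) at end of string", n)
    if ring_open:
        label, (_, _, pos) = next(iter(ring_open.items()))
        raise RingClosureError(f"unmatched ring-closure label {label}", pos)
    if not atoms:
        raise SmilesParseError("no atoms in SMILES string", 0)
    del pending_bond_pos

    # resolve bond orders: unspecified bonds between two aromatic atoms are
    # aromatic, otherwise single; ':' demands aromatic endpoints
    resolved: list[Bond] = []
    seen_pairs: set[tuple[int, int]] = set()
    for a, b, order, pos in bonds:
        pair = (min(a, b), max(a, b))
        if pair in seen_pairs:
            raise SmilesParseError(f"duplicate bond between atoms {a} and {b}",
                                   pos)
        seen_pairs.add(pair)
        both_aromatic = atoms[a].aromatic and atoms[b].aromatic
        if order is None:
            order = AROMATIC if both_aromatic else SINGLE
        if order == AROMATIC and not both_aromatic:
            raise AromaticityError(
                "':' bond requires two aromatic atoms", pos)
        resolved.append(Bond(a, b, order))

    ring_bond_flags = _ring_bond_flags(len(atoms), resolved)
    _check_aromatic_rings(atoms, resolved)

    final_atoms = []
    atom_in_ring = [False] * len(atoms)
    for b, flag in zip(resolved, ring_bond_flags):
        if flag:
            atom_in_ring[b.atom_a] = True
            atom_in_ring[b.atom_b] = True
    final_bonds = tuple(
        Bond(b.atom_a, b.atom_b, b.order_code, in_ring=flag)
        for b, flag in zip(resolved, ring_bond_flags))

    # bond-order sums for valence bookkeeping
    order_sum = [0.0] * len(atoms)
    arom_count = [0] * len(atoms)
    for b in resolved:
        for end in (b.atom_a, b.atom_b):
            if b.order_code == AROMATIC:
                arom_count[end] += 1
            else:
                order_sum[end] += b.order_code

    for idx, pa in enumerate(atoms):
        bsum = order_sum[idx] + arom_count[idx]
        if pa.aromatic and pa.element not in ("O", "S"):
            # the delocalised system contributes one bond equivalent; an
            # aromatic O/S donates a lone pair instead (furan, thiophene)
            bsum += 1
        implicit = _implicit_h(pa, int(bsum), idx)
        final_atoms.append(Atom(
            index=idx, element=pa.element, formal_charge=pa.charge,
            aromatic=pa.aromatic, explicit_h=pa.explicit_h,
            implicit_h=implicit, in_ring=atom_in_ring[idx]))

    return MolecularGraph(
        atoms=tuple(final_atoms), bonds=final_bonds, source_smiles=smiles,
        atom_spans=tuple(pa.span for pa in atoms))


def _implicit_h(pa: _PendingAtom, bond_sum: int, idx: int) -> int:
    """Valence-rule implicit hydrogen count for one atom."""
    if pa.explicit_h >= 0:
        return 0  # bracket count is authoritative
    valence = _DEFAULT_VALENCE[pa.element]
    if pa.element in _PROMOTED_VALENCES and not pa.aromatic:
        for v in _PROMOTED_VALENCES[pa.element]:
            if bond_sum <= v:
                valence = v
                break
        else:
            valence = _PROMOTED_VALENCES[pa.element][-1]
    if pa.charge:
        if pa.element in ("N", "P"):
            valence += pa.charge
        elif pa.element in ("O", "S") and pa.charge < 0:
            valence -= abs(pa.charge)
    h = valence - bond_sum
    if h < 0:
        if pa.bracket:
            return 0  # charged/bracket exotica: trust the source
        raise ValenceError(
            f"bond-order sum {bond_sum} exceeds valence {valence} for "
            f"{pa.element} atom {idx}", pa.span[0])
    return h


# ---------------------------------------------------------------------------
# Graph analyses

def _nx_graph(n_atoms: int, bonds: list[Bond] | tuple[Bond, ...]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from((b.atom_a, b.atom_b) for b in bonds)
    return g


def _ring_bond_flags(n_atoms: int, bonds: list[Bond]) -> list[bool]:
    """A bond is in a ring iff it is not a bridge of the graph."""
    g = _nx_graph(n_atoms, bonds)
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return [frozenset((b.atom_a, b.atom_b)) not in bridges for b in bonds]


def _check_aromatic_rings(atoms: list[_PendingAtom],
                          bonds: list[Bond]) -> None:
    """Every aromatic atom must lie on a cycle of aromatic bonds."""
    arom_bonds = [b for b in bonds if b.order_code == AROMATIC]
    on_cycle = [False] * len(atoms)
    if arom_bonds:
        flags = _ring_bond_flags(len(atoms), arom_bonds)
        for b, f in zip(arom_bonds, flags):
            if f:
                on_cycle[b.atom_a] = True
                on_cycle[b.atom_b] = True
    for idx, pa in enumerate(atoms):
        if pa.aromatic and not on_cycle[idx]:
            raise AromaticityError(
                f"aromatic atom {idx} ({pa.element.lower()}) is not on a "
                f"cycle of aromatic bonds", pa.span[0])


def topological_distances(graph: MolecularGraph):
    """All-pairs shortest-path distances in bond counts (BFS).

    Returns an ``(n, n)`` integer matrix; entries between disconnected
    components are :data:`UNREACHABLE` (−1); the diagonal is zero.
    """
    import numpy as np

    n = graph.n_atoms
    adj = [[nb for nb, _ in nbrs] for nbrs in graph.adjacency()]
    dist = np.full((n, n), UNREACHABLE, dtype=np.int32)
    for src in range(n):
        dist[src, src] = 0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[src, v] == UNREACHABLE:
                        dist[src, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def ring_info(graph: MolecularGraph) -> tuple[list[list[int]], list[list[int]]]:
    """Minimum cycle basis of the molecule and its aromatic-ring subset.

    Aromatic rings are basis cycles of size 5–7 whose bonds all carry the
    aromatic order code.
    """
    g = _nx_graph(graph.n_atoms, graph.bonds)
    order = {}
    for b in graph.bonds:
        order[frozenset((b.atom_a, b.atom_b))] = b.order_code
    rings = [sorted(c) for c in nx.minimum_cycle_basis(g)]
    rings.sort(key=lambda r: (len(r), r))
    aromatic_rings = []
    for ring in rings:
        if not 5 <= len(ring) <= 7:
            continue
        members = set(ring)
        ring_edges = [e for e in order
                      if e <= members]
        # the cycle's own edges: each ring atom has exactly two within the set
        if all(order[e] == AROMATIC for e in ring_edges):
            aromatic_rings.append(ring)
    return rings, aromatic_rings
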