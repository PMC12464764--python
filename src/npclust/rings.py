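"""Macrocyclic-lactone detection and substructure presence annotation.

A macrolactone is a large ring closed through an ester: the ring contains
both the ester oxygen and the carbonyl carbon, with the carbonyl oxygen
exocyclic.  Ring size counts both ester atoms.  Detection cannot rely on the
smallest-set-of-smallest-rings: a macrocycle bridged by smaller fused rings
is invisible there, so the search enumerates simple cycles directly —
anchored at each ester O–C bond, it looks for a simple path of the right
length closing that bond, which bounds the search and avoids combinatorial
blowup on fused polycyclics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem

from .network import ClusterAssignment, SimilarityEdge, connected_components
from .records import CompoundError, CompoundSet

DEFAULT_RING_SIZE = 16
DEFAULT_MAX_RING_SIZE = 72
DEFAULT_MIN_CLASS_SIZE = 3

# ester: sp3 oxygen single-bonded to a carbonyl carbon
_ESTER = Chem.MolFromSmarts("[OX2][CX3]=[OX1]")


@dataclass(frozen=True)
class RingMatch:
    compound_id: str
    ring_size: int
    n_matching_rings: int
    is_macrolactone: bool = True


@dataclass
class SubstructureAnnotation:
    query_name: str
    presence: dict[str, bool]  # compound_id -> pattern present


@dataclass
class MatchClasses:
    """Macrolactone matches partitioned by similarity within the matched set."""

    classes: list[list[str]]  # >= min_class_size members, decreasing size
    minor_groups: list[list[str]]


def _ester_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(ester O, carbonyl C) atom-index pairs, one per ester unit."""
    return [(o, c) for o, c, _od in mol.GetSubstructMatches(_ESTER)]


def _cycles_through_bond(
    mol: Chem.Mol, a: int, b: int, size: int
) -> set[frozenset[int]]:
    """Atom sets of simple cycles of exactly `size` atoms containing bond a-b.

    DFS for simple paths a -> b of `size` atoms that avoid the direct a-b
    bond; the bond then closes each path into a cycle.  Depth is bounded by
    `size`, so the search stays cheap even on fused ring systems.
    """
    adj: dict[int, list[int]] = {
        atom.GetIdx(): [n.GetIdx() for n in atom.GetNeighbors()]
        for atom in mol.GetAtoms()
    }
    found: set[frozenset[int]] = set()
    path = [a]
    on_path = {a}

    def dfs(current: int) -> None:
        for nxt in adj[current]:
            if nxt == b:
                # b is only admissible as the final atom; stepping a->b
                # directly would reuse the closing bond itself
                if current != a and len(path) == size - 1:
                    found.add(frozenset(path) | {b})
                continue
            if nxt in on_path or len(path) >= size - 1:
                continue
            path.append(nxt)
            on_path.add(nxt)
            dfs(nxt)
            on_path.discard(nxt)
            path.pop()

    dfs(a)
    return found


def molecule_macrolactone_rings(
    mol: Chem.Mol, ring_size: int = DEFAULT_RING_SIZE
) -> set[frozenset[int]]:
    """Atom sets of `ring_size`-membered rings containing an ester unit."""
    rings: set[frozenset[int]] = set()
    for o_idx, c_idx in _ester_bonds(mol):
        rings |= _cycles_through_bond(mol, o_idx, c_idx, ring_size)
    return rings


def find_macrolactones(
    compounds: CompoundSet,
    ring_size: int = DEFAULT_RING_SIZE,
    max_ring_size: int = DEFAULT_MAX_RING_SIZE,
) -> list[RingMatch]:
    """Census of compounds containing an N-membered macrolactone ring.

    A compound matches when at least one simple cycle of exactly
    ``ring_size`` atoms contains an –O–C(=O)– ester with both the oxygen
    and the carbonyl carbon in the cycle (the carbonyl oxygen, having
    degree 1, is necessarily exocyclic).  A compound with several distinct
    matching rings counts once; ``n_matching_rings`` records multiplicity.
    """
    if not 3 <= ring_size <= max_ring_size:
        raise ValueError(
            f"ring_size {ring_size} outside [3, max_ring_size={max_ring_size}]"
        )
    matches: list[RingMatch] = []
    for rec in compounds:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:  # records were validated on read; belt and braces
            continue
        rings = molecule_macrolactone_rings(mol, ring_size)
        if rings:
            matches.append(
                RingMatch(
                    compound_id=rec.compound_id,
                    ring_size=ring_size,
                    n_matching_rings=len(rings),
                )
            )
    return matches


def annotate_substructure_presence(
    cluster_members: CompoundSet,
    query: str,
    query_name: str,
) -> SubstructureAnnotation:
    """Flag each compound for presence of a SMARTS substructure pattern."""
    pattern = Chem.MolFromSmarts(query)
    if pattern is None:
        raise CompoundError(f"invalid substructure pattern: {query!r}")
    presence = {}
    for rec in cluster_members:
        mol = Chem.MolFromSmiles(rec.smiles)
        presence[rec.compound_id] = bool(mol is not None and mol.HasSubstructMatch(pattern))
    return SubstructureAnnotation(query_name=query_name, presence=presence)


def group_matches(
    matches: Sequence[RingMatch],
    edges: Sequence[SimilarityEdge],
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> MatchClasses:
    """Partition ring matches into compound classes by similarity.

    Connected components are re-run over the matched compounds only (edges
    restricted to pairs where both endpoints matched), so a class is a
    similarity family *within* the macrolactone census.  Components smaller
    than ``min_class_size`` are reported separately as minor groups.
    """
    matched = sorted({m.compound_id for m in matches})
    if not matched:
        return MatchClasses(classes=[], minor_groups=[])
    matched_set = set(matched)
    sub_edges = [e for e in edges if e.id_a in matched_set and e.id_b in matched_set]
    assignment = connected_components(sub_edges, matched)
    groups = sorted(
        assignment.members().values(), key=lambda ms: (-len(ms), min(ms))
    )
    return MatchClasses(
        classes=[g for g in groups if len(g) >= min_class_size],
        minor_groups=[g for g in groups if len(g) < min_class_size],
    )


def write_ring_matches(matches: Sequence[RingMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tring_size\tn_matching_rings\tis_macrolactone\n")
        for m in matches:
            fh.write(
                f"{m.compound_id}\t{m.ring_size}\t{m.n_matching_rings}\t"
                f"{int(m.is_macrolactone)}\n"
            )


def write_annotation(annotation: SubstructureAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tquery_name\tpresent\n")
        for cid in sorted(annotation.presence):
            fh.write(f"{cid}\t{annotation.query_name}\t{int(annotation.presence[cid])}\n")
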