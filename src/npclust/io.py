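"""Reading compound tables (CSV/TSV/SDF), deduplication, and network export.

Input tables need at least an identifier column and a SMILES column; rows
whose SMILES fail to parse are rejected individually (with a reason) rather
than aborting the read.  Networks are written as GraphML or a TSV edge list,
both loadable in Cytoscape and other standard viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem

from .records import CompoundError, CompoundRecord, CompoundSet

log = logging.getLogger(__name__)

#: Default mapping of semantic field -> source column (CSV/TSV) or SD tag.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "name": "name",
    "kingdom": "kingdom",
    "year": "year",
}

MANDATORY_FIELDS = ("compound_id", "smiles")


@dataclass(frozen=True)
class Rejection:
    """One rejected input row: its identifier (or row number) and the reason."""

    compound_id: str
    reason: str


@dataclass
class ReadResult:
    compounds: CompoundSet
    rejections: list[Rejection]


def _records_from_rows(
    rows: Sequence[dict], provenance: str
) -> ReadResult:
    records: list[CompoundRecord] = []
    rejections: list[Rejection] = []
    seen_ids: set[str] = set()
    for row in rows:
        cid = str(row["compound_id"])
        if cid in seen_ids:
            raise CompoundError(f"duplicate compound identifier: {cid!r}")
        seen_ids.add(cid)
        try:
            rec = CompoundRecord.from_fields(
                compound_id=cid,
                smiles=row["smiles"],
                name=row.get("name"),
                kingdom=row.get("kingdom"),
                year=row.get("year"),
            )
        except CompoundError as exc:
            rejections.append(Rejection(cid, str(exc)))
            continue
        records.append(rec)
    if rejections:
        log.warning("rejected %d of %d input rows", len(rejections), len(rows))
    return ReadResult(CompoundSet(records, provenance=provenance), rejections)


def _rows_from_table(df: pd.DataFrame, column_map: Mapping[str, str]) -> list[dict]:
    for field in MANDATORY_FIELDS:
        col = column_map.get(field)
        if col is None or col not in df.columns:
            raise CompoundError(f"missing mandatory column for {field!r}: {col!r}")
    rows = []
    for _, r in df.iterrows():
        row: dict = {}
        for field, col in column_map.items():
            if col in df.columns:
                val = r[col]
                row[field] = None if pd.isna(val) else val
        rows.append(row)
    return rows


def _rows_from_sdf(path: Path, column_map: Mapping[str, str]) -> list[dict]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    rows = []
    for i, mol in enumerate(supplier):
        if mol is None:
            # no structure -> synthesise an id from the record index so the
            # rejection is reportable
            rows.append({"compound_id": f"<record {i}>", "smiles": "<unparseable SDF record>"})
            continue
        row = {"smiles": Chem.MolToSmiles(mol)}
        for field, tag in column_map.items():
            if field == "smiles":
                continue
            if mol.HasProp(tag):
                row[field] = mol.GetProp(tag)
        if "compound_id" not in row:
            raise CompoundError(f"SDF record {i} lacks identifier tag {column_map['compound_id']!r}")
        rows.append(row)
    return rows


def read_compound_table(
    path: str | Path,
    format: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> ReadResult:
    """Read a compound table and return accepted records plus rejections.

    Parameters
    ----------
    path:
        CSV, TSV or SDF (V2000) file.  Must exist.
    format:
        ``csv``, ``tsv`` or ``sdf``; inferred from the suffix when omitted.
    column_map:
        Mapping of semantic field (``compound_id``, ``smiles``, ``name``,
        ``kingdom``, ``year``) to the source column name or SD tag.

    Accepted records plus rejections always account for every input row.
    A duplicate identifier is a fatal error, not a rejection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if format == "csv":
        rows = _rows_from_table(pd.read_csv(path), cmap)
    elif format == "tsv":
        rows = _rows_from_table(pd.read_csv(path, sep="\t"), cmap)
    elif format == "sdf":
        rows = _rows_from_sdf(path, cmap)
    else:
        raise CompoundError(f"unknown input format: {format!r}")
    return _records_from_rows(rows, provenance=str(path))


def write_compound_table(compounds: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet back out as CSV with the default column names."""
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in compounds],
            "smiles": [r.smiles for r in compounds],
            "name": [r.name for r in compounds],
            "kingdom": [r.kingdom for r in compounds],
            "year": [r.year for r in compounds],
        }
    )
    df.to_csv(path, index=False)


def deduplicate(compounds: CompoundSet) -> CompoundSet:
    """Keep the first record per canonical structure key.

    Notational variants of the same molecule ("OCC" vs "CCO") collapse onto
    one record; stereoisomers do not, because the key keeps stereo layers.
    """
    seen: set[str] = set()
    kept: list[CompoundRecord] = []
    for rec in compounds:
        if rec.structure_key in seen:
            continue
        seen.add(rec.structure_key)
        kept.append(rec)
    removed = len(compounds) - len(kept)
    if removed:
        log.info("deduplicate: removed %d duplicate structures", removed)
    return CompoundSet(kept, provenance=compounds.provenance)


def _as_graph(edges, assignment, compounds: Optional[CompoundSet]) -> nx.Graph:
    graph = nx.Graph()
    for cid, cluster_id in assignment.clusters.items():
        attrs: dict = {"cluster_id": int(cluster_id)}
        if compounds is not None and cid in compounds:
            rec = compounds[cid]
            attrs["kingdom"] = rec.kingdom
            if rec.year is not None:
                attrs["year"] = int(rec.year)
        graph.add_node(cid, **attrs)
    for e in edges:
        if e.id_a not in graph or e.id_b not in graph:
            raise CompoundError(f"edge references unknown node: {e.id_a!r}-{e.id_b!r}")
        graph.add_edge(e.id_a, e.id_b, score=float(e.score))
    return graph


def write_network(
    edges,
    assignment,
    path: str | Path,
    format: str = "graphml",
    compounds: Optional[CompoundSet] = None,
) -> None:
    """Write the thresholded similarity network to GraphML or a TSV edge list.

    GraphML carries kingdom/year/cluster_id node attributes (when a
    CompoundSet is supplied) and the similarity score on each edge;
    the TSV edge list has columns source, target, score (4 decimal places).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_as_graph(edges, assignment, compounds), str(path))
    elif format == "edge_list_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tscore\n")
            for e in edges:
                fh.write(f"{e.id_a}\t{e.id_b}\t{e.score:.4f}\n")
    else:
        raise CompoundError(f"unknown network format: {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Load a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(str(path))
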