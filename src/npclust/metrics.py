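"""Per-cluster and dataset-level statistics for a similarity network.

For each cluster: size, the median over members of their within-cluster
degree ("median edge count" — high values flag near-complete
interconnectivity, as in densely decorated compound families), the dominant
origin kingdom and taxonomic purity.  Dataset summaries count clusters of
two or more members, clusters of five or more, singletons, and clusters
passing a purity threshold (default 0.95, inclusive).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .network import ClusterAssignment, SimilarityEdge
from .records import CompoundSet

DEFAULT_PURITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class ClusterStats:
    cluster_id: int
    size: int
    median_edge_count: float
    dominant_kingdom: Optional[str]  # None when every member's kingdom is unknown
    purity: Optional[float]  # fraction of known-kingdom members in the dominant one
    n_unknown_kingdom: int


@dataclass(frozen=True)
class DatasetSummary:
    n_compounds: int
    n_clusters_ge2: int
    n_compounds_in_clusters_ge2: int
    pct_in_clusters: float
    median_cluster_size_ge2: Optional[float]
    median_cluster_size_all: float  # secondary: singletons included
    n_clusters_ge5: int
    n_singletons: int
    pct_singletons: float
    n_pure_clusters: int  # clusters >= 2 with bacterial/fungal purity >= threshold


def cluster_stats(
    assignment: ClusterAssignment,
    edges: Sequence[SimilarityEdge],
    compounds: CompoundSet,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> list[ClusterStats]:
    """One :class:`ClusterStats` per cluster, ordered by cluster_id.

    The median edge count is taken over each member's count of incident
    within-cluster edges (all edges are within-cluster by construction of
    connected components); even-sized medians use the midpoint.  Purity is
    computed over members with a known kingdom only; a cluster whose members
    are all unknown has undefined purity (``None``).
    """
    degree: dict[str, int] = {cid: 0 for cid in assignment.clusters}
    for e in edges:
        degree[e.id_a] += 1
        degree[e.id_b] += 1

    out: list[ClusterStats] = []
    for k, members in sorted(assignment.members().items()):
        med = float(statistics.median(degree[m] for m in members))
        known = [
            compounds[m].kingdom for m in members if compounds[m].kingdom != "unknown"
        ]
        n_unknown = len(members) - len(known)
        if known:
            counts: dict[str, int] = {}
            for kd in known:
                counts[kd] = counts.get(kd, 0) + 1
            # deterministic tie-break: most frequent, then alphabetical
            dominant = min(counts, key=lambda kd: (-counts[kd], kd))
            purity: Optional[float] = counts[dominant] / len(known)
        else:
            dominant, purity = None, None
        out.append(
            ClusterStats(
                cluster_id=k,
                size=len(members),
                median_edge_count=med,
                dominant_kingdom=dominant,
                purity=purity,
                n_unknown_kingdom=n_unknown,
            )
        )
    return out


def dataset_summary(
    stats: Sequence[ClusterStats],
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> DatasetSummary:
    """Collection-level counts derived from per-cluster statistics.

    The primary median cluster size is over clusters of two or more members;
    the singleton-inclusive median is also reported, clearly labelled.
    Percentages are rounded to one decimal place.
    """
    if not stats:
        raise ValueError("no cluster statistics supplied")
    n_compounds = sum(s.size for s in stats)
    ge2 = [s for s in stats if s.size >= 2]
    n_in_ge2 = sum(s.size for s in ge2)
    n_singletons = n_compounds - n_in_ge2
    n_pure = sum(
        1
        for s in ge2
        if s.purity is not None
        and s.dominant_kingdom in ("bacterium", "fungus")
        and s.purity >= purity_threshold
    )
    return DatasetSummary(
        n_compounds=n_compounds,
        n_clusters_ge2=len(ge2),
        n_compounds_in_clusters_ge2=n_in_ge2,
        pct_in_clusters=round(100.0 * n_in_ge2 / n_compounds, 1),
        median_cluster_size_ge2=(
            float(statistics.median(s.size for s in ge2)) if ge2 else None
        ),
        median_cluster_size_all=float(statistics.median(s.size for s in stats)),
        n_clusters_ge5=sum(1 for s in stats if s.size >= 5),
        n_singletons=n_singletons,
        pct_singletons=round(100.0 * n_singletons / n_compounds, 1),
        n_pure_clusters=n_pure,
    )


def write_cluster_stats(stats: Sequence[ClusterStats], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in stats],
            "size": [s.size for s in stats],
            "median_edge_count": [s.median_edge_count for s in stats],
            "dominant_kingdom": [s.dominant_kingdom or "" for s in stats],
            "purity": ["" if s.purity is None else f"{s.purity:.4f}" for s in stats],
            "n_unknown_kingdom": [s.n_unknown_kingdom for s in stats],
        }
    ).to_csv(path, sep="\t", index=False)


def write_summary(summary: DatasetSummary, path: str | Path) -> None:
    """Summary as a two-column key-value TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, val in vars(summary).items():
            fh.write(f"{key}\t{'' if val is None else val}\n")
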