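"""Rank-similarity profiles: how sharply a cluster separates from the rest.

For a query compound, every other compound in the collection is ranked by
descending Dice similarity.  For members of well-separated families the
profile shows a steep drop where the cluster ends; :func:`boundary_drop`
reports that drop as (worst within-cluster score) − (best outside score).
A negative drop flags a non-member outranking a member.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .fingerprints import Fingerprint, dice_similarity
from .network import ClusterAssignment

DEFAULT_TOP_N = 500


@dataclass(frozen=True)
class RankedEntry:
    compound_id: str
    score: float
    in_same_cluster: bool


@dataclass
class SimilarityProfile:
    query_id: str
    ranked: list[RankedEntry]  # descending score; self excluded
    top_n: int


@dataclass(frozen=True)
class BoundaryDrop:
    query_id: str
    last_in_cluster_score: float
    first_out_cluster_score: float

    @property
    def drop(self) -> float:
        return self.last_in_cluster_score - self.first_out_cluster_score


class NoBoundaryError(ValueError):
    """The profile has no cluster boundary (singleton query, or no outsiders)."""


def rank_profile(
    query_id: str,
    fps: Sequence[Fingerprint],
    assignment: ClusterAssignment,
    top_n: int = DEFAULT_TOP_N,
) -> SimilarityProfile:
    """Rank the whole collection against one query by descending similarity.

    The query itself is excluded; ties on score break by ascending
    compound_id, so the ordering is deterministic.  The profile is truncated
    to the top ``top_n`` entries (or n − 1 if shorter).
    """
    by_id = {fp.compound_id: fp for fp in fps}
    if query_id not in by_id:
        raise KeyError(f"unknown query compound: {query_id!r}")
    if query_id not in assignment.clusters:
        raise KeyError(f"query not in cluster assignment: {query_id!r}")
    qfp = by_id[query_id]
    qcluster = assignment.clusters[query_id]
    scored = [
        (dice_similarity(qfp, fp), fp.compound_id)
        for fp in fps
        if fp.compound_id != query_id
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    ranked = [
        RankedEntry(cid, score, assignment.clusters.get(cid) == qcluster)
        for score, cid in scored[:top_n]
    ]
    return SimilarityProfile(query_id=query_id, ranked=ranked, top_n=top_n)


def boundary_drop(profile: SimilarityProfile, assignment: ClusterAssignment) -> BoundaryDrop:
    """Score drop at the cluster boundary of a profile.

    ``last_in_cluster_score`` is the minimum score among same-cluster
    entries; ``first_out_cluster_score`` the maximum among non-members.
    All cluster members must be within the profile's window, so use a
    ``top_n`` at least the cluster size when drops matter.
    """
    members = [e for e in profile.ranked if e.in_same_cluster]
    outsiders = [e for e in profile.ranked if not e.in_same_cluster]
    if not members:
        raise NoBoundaryError(
            f"{profile.query_id!r} is a singleton: no cluster boundary"
        )
    if not outsiders:
        raise NoBoundaryError(
            f"profile of {profile.query_id!r} contains no non-member"
        )
    return BoundaryDrop(
        query_id=profile.query_id,
        last_in_cluster_score=min(e.score for e in members),
        first_out_cluster_score=max(e.score for e in outsiders),
    )


def write_profile(profile: SimilarityProfile, path: str | Path) -> None:
    """Plot-ready TSV: rank, compound_id, score, in_cluster."""
    with open(path, "w") as fh:
        fh.write("rank\tcompound_id\tscore\tin_cluster\n")
        for rank, e in enumerate(profile.ranked, start=1):
            fh.write(f"{rank}\t{e.compound_id}\t{e.score:.4f}\t{int(e.in_same_cluster)}\n")


def cluster_profiles(
    cluster_id: int,
    fps: Sequence[Fingerprint],
    assignment: ClusterAssignment,
    top_n: int = DEFAULT_TOP_N,
) -> list[SimilarityProfile]:
    """Batch mode: one profile per member of the named cluster."""
    members = assignment.members().get(cluster_id)
    if not members:
        raise KeyError(f"no such cluster: {cluster_id}")
    return [rank_profile(m, fps, assignment, top_n=top_n) for m in members]
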