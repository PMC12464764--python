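"""Year-stratified structural novelty: contemporary vs current singletons.

A compound first reported in year *y* is a **contemporary singleton** when
nothing reported in a strictly earlier year is similar to it (Dice >= cutoff)
— it looked novel at the time of discovery.  It is a **current singleton**
when nothing in the whole collection is similar to it — it still looks novel
today, i.e. it is a size-1 cluster of the similarity network.  Current
singletons are always a subset of contemporary ones, so per-year current
percentages can never exceed contemporary ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fingerprints import Fingerprint, pack_fingerprints, popcounts
from .network import DEFAULT_CUTOFF
from .records import CompoundSet


@dataclass(frozen=True)
class YearRecord:
    year: int
    n_discovered: int
    n_contemporary_singletons: int
    n_current_singletons: int
    pct_contemporary: float
    pct_current: float


@dataclass
class NoveltyTimeline:
    years: list[YearRecord]
    excluded_ids: list[str]  # records without a year, left out of the analysis


def _neighbor_matrix(fps: Sequence[Fingerprint], cutoff: float) -> np.ndarray:
    """Boolean n×n matrix of Dice >= cutoff (diagonal False)."""
    packed = pack_fingerprints(fps)
    counts = popcounts(packed)
    n = len(fps)
    adj = np.zeros((n, n), dtype=bool)
    block = 512
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        inter = np.bitwise_count(packed[i0:i1, None, :] & packed[None, :, :]).sum(
            axis=2, dtype=np.int64
        )
        denom = counts[i0:i1, None] + counts[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            dice = np.where(denom > 0, 2.0 * inter / denom, 0.0)
        adj[i0:i1] = dice >= cutoff
    np.fill_diagonal(adj, False)
    return adj


def _split_by_year(compounds: CompoundSet, fps: Sequence[Fingerprint]):
    by_id = {fp.compound_id: fp for fp in fps}
    dated, excluded = [], []
    for rec in compounds:
        if rec.compound_id not in by_id:
            raise KeyError(f"no fingerprint for {rec.compound_id!r}")
        if rec.year is None:
            excluded.append(rec.compound_id)
        else:
            dated.append(rec)
    return dated, excluded, by_id


def contemporary_singletons(
    compounds: CompoundSet,
    fps: Sequence[Fingerprint],
    cutoff: float = DEFAULT_CUTOFF,
    include_same_year: bool = False,
) -> dict[int, list[str]]:
    """Per-year lists of compounds with no similar predecessor.

    The comparison set for a compound of year *y* is every dated compound of
    year < *y* (strictly earlier; same-year compounds are not compared to
    each other unless ``include_same_year``).  Records without a year are
    excluded from both sides of the comparison.
    """
    dated, _excluded, by_id = _split_by_year(compounds, fps)
    sub_fps = [by_id[r.compound_id] for r in dated]
    adj = _neighbor_matrix(sub_fps, cutoff)
    years = np.array([r.year for r in dated])
    out: dict[int, list[str]] = {}
    for i, rec in enumerate(dated):
        earlier = years < years[i]
        if include_same_year:
            earlier = earlier | ((years == years[i]) & (np.arange(len(dated)) != i))
        if not adj[i, earlier].any():
            out.setdefault(int(years[i]), []).append(rec.compound_id)
    return {y: sorted(ids) for y, ids in sorted(out.items())}


def current_singletons(
    compounds: CompoundSet,
    fps: Sequence[Fingerprint],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[int, list[str]]:
    """Per-year lists of compounds similar to nothing else in the collection.

    The comparison set is every other compound regardless of year (dated or
    not), so a current singleton is exactly a size-1 cluster of the
    similarity network; only dated compounds are grouped into years.
    """
    dated, _excluded, by_id = _split_by_year(compounds, fps)
    adj = _neighbor_matrix(list(fps), cutoff)
    idx = {fp.compound_id: i for i, fp in enumerate(fps)}
    out: dict[int, list[str]] = {}
    for rec in dated:
        if not adj[idx[rec.compound_id]].any():
            out.setdefault(rec.year, []).append(rec.compound_id)
    return {y: sorted(ids) for y, ids in sorted(out.items())}


def novelty_timeline(
    compounds: CompoundSet,
    fps: Sequence[Fingerprint],
    cutoff: float = DEFAULT_CUTOFF,
    include_same_year: bool = False,
) -> NoveltyTimeline:
    """Assemble the per-year novelty table (years with discoveries only)."""
    dated, excluded, _ = _split_by_year(compounds, fps)
    if not dated:
        return NoveltyTimeline(years=[], excluded_ids=excluded)
    contemp = contemporary_singletons(
        compounds, fps, cutoff, include_same_year=include_same_year
    )
    current = current_singletons(compounds, fps, cutoff)
    per_year: dict[int, int] = {}
    for rec in dated:
        per_year[rec.year] = per_year.get(rec.year, 0) + 1
    years = []
    for y in sorted(per_year):
        n = per_year[y]
        n_contemp = len(contemp.get(y, []))
        n_curr = len(current.get(y, []))
        years.append(
            YearRecord(
                year=y,
                n_discovered=n,
                n_contemporary_singletons=n_contemp,
                n_current_singletons=n_curr,
                pct_contemporary=round(100.0 * n_contemp / n, 1),
                pct_current=round(100.0 * n_curr / n, 1),
            )
        )
    return NoveltyTimeline(years=years, excluded_ids=excluded)


def write_timeline(timeline: NoveltyTimeline, path: str | Path) -> None:
    """Plot-ready TSV, one row per year with discoveries."""
    with open(path, "w") as fh:
        fh.write(
            "year\tn_discovered\tn_contemporary\tn_current\t"
            "pct_contemporary\tpct_current\n"
        )
        for yr in timeline.years:
            fh.write(
                f"{yr.year}\t{yr.n_discovered}\t{yr.n_contemporary_singletons}\t"
                f"{yr.n_current_singletons}\t{yr.pct_contemporary}\t{yr.pct_current}\n"
            )
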