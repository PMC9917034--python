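"""Immunodominant core regions: merge overlapping 9–10-mer ligand candidates
into consensus intervals ranked by summed TIC-relative abundance.

Clustering is single-linkage on interval overlap: two candidates join the
same region when they share at least ``min_overlap`` residues (default 7, the
minimum overlap of two 9-mers sharing a binding core). Per cluster the region
is the union of member intervals and the core is their intersection;
"immunodominance" is operationalized as rank by summed abundance — no hard
significance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigError
from .io_tables import SubstrateRecord
from .mapping import LocatedPeptide


@dataclass(frozen=True)
class CoreRegion:
    """A merged interval of overlapping ligand candidates."""

    start: int  # union interval
    end: int
    core_start: int  # intersection (consensus) interval
    core_end: int
    core_sequence: str
    members: tuple[LocatedPeptide, ...]
    summed_abundance: float

    @property
    def n_members(self) -> int:
        return len(self.members)


def _abundance(lp: LocatedPeptide) -> float:
    if lp.relative_abundance is not None:
        return lp.relative_abundance
    return lp.intensity if lp.intensity is not None else lp.count_weight


def _overlap(a: LocatedPeptide, b: LocatedPeptide) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def _core_interval(members: Sequence[LocatedPeptide]) -> tuple[int, int]:
    """Intersection of member intervals; falls back to the maximally covered
    span (leftmost on ties) when single-linkage chaining empties it."""
    lo = max(m.start for m in members)
    hi = min(m.end for m in members)
    if lo <= hi:
        return lo, hi
    # chained cluster: use the positions covered by the most members
    start, end = min(m.start for m in members), max(m.end for m in members)
    coverage = {p: 0 for p in range(start, end + 1)}
    for m in members:
        for p in range(m.start, m.end + 1):
            coverage[p] += 1
    best = max(coverage.values())
    positions = sorted(p for p, c in coverage.items() if c == best)
    # leftmost contiguous run of maximal coverage
    run_end = positions[0]
    while run_end + 1 in coverage and coverage[run_end + 1] == best:
        run_end += 1
    return positions[0], run_end


def extract_core_regions(
    candidates: Sequence[LocatedPeptide],
    min_overlap: int = 7,
    min_total_abundance: float = 0.0,
) -> list[CoreRegion]:
    """Cluster candidate intervals and return regions sorted by summed
    abundance (descending; ties broken by start position).

    ``min_overlap`` above 10 can never cluster 9–10-mers and is rejected.
    Clusters whose summed abundance falls below ``min_total_abundance`` are
    dropped.
    """
    if min_overlap > 10:
        raise ConfigError(f"min_overlap={min_overlap} can never cluster 9-10-mers")
    if min_overlap < 1:
        raise ConfigError("min_overlap must be >= 1")
    if not candidates:
        return []
    substrates = {lp.substrate_id for lp in candidates}
    if len(substrates) > 1:
        raise ConfigError(f"candidates span multiple substrates: {sorted(substrates)}")

    # union-find single linkage
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if _overlap(candidates[i], candidates[j]) >= min_overlap:
                parent[find(i)] = find(j)

    clusters: dict[int, list[LocatedPeptide]] = {}
    for i, lp in enumerate(candidates):
        clusters.setdefault(find(i), []).append(lp)

    regions = []
    for members in clusters.values():
        members = tuple(sorted(members, key=lambda m: (m.start, m.end)))
        total = sum(_abundance(m) for m in members)
        if total < min_total_abundance:
            continue
        core_start, core_end = _core_interval(members)
        # core sits inside some member; slice its germline sequence
        carrier = next(m for m in members
                       if m.start <= core_start and m.end >= core_end)
        core_seq = carrier.germline_sequence[
            core_start - carrier.start: core_end - carrier.start + 1
        ]
        regions.append(CoreRegion(
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            core_start=core_start,
            core_end=core_end,
            core_sequence=core_seq,
            members=members,
            summed_abundance=total,
        ))
    regions.sort(key=lambda r: (-r.summed_abundance, r.start))
    return regions


def region_table(regions: Sequence[CoreRegion]) -> pd.DataFrame:
    rows = [{
        "rank": i,
        "start": r.start,
        "end": r.end,
        "core_sequence": r.core_sequence,
        "n_members": r.n_members,
        "summed_abundance_pct": r.summed_abundance,
    } for i, r in enumerate(regions, start=1)]
    return pd.DataFrame(rows, columns=["rank", "start", "end", "core_sequence",
                                       "n_members", "summed_abundance_pct"])


def region_report(
    regions: Sequence[CoreRegion], substrate: SubstrateRecord
) -> tuple[str, pd.DataFrame]:
    """Annotated sequence map: the substrate with region spans bracketed
    (``AA[KFAA]Q``), plus the machine-readable region table.

    Overlapping regions render with nested brackets, opened in start order and
    closed last-in-first-out.
    """
    opens: dict[int, int] = {}
    closes: dict[int, list[int]] = {}
    for idx, r in enumerate(sorted(regions, key=lambda r: (r.start, r.end))):
        opens[r.start] = opens.get(r.start, 0) + 1
        closes.setdefault(r.end, []).append(idx)
    parts = []
    for pos, ch in enumerate(substrate.sequence, start=1):
        parts.append("[" * opens.get(pos, 0))
        parts.append(ch)
        parts.append("]" * len(closes.get(pos, [])))
    return "".join(parts), region_table(regions)
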