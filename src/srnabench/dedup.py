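"""UMI-based duplicate removal with directional clustering.

Reads are grouped by their assigned reference (liberal grouping: canonical
reads and isomiRs of the same reference fall into one group, so an isomiR
sharing a UMI with its reference collapses with it).  Within a group, UMIs
are clustered with the *directional* algorithm: a directed edge a→b exists
when the two UMIs differ at exactly one position and
``count(a) >= 2*count(b) - 1``; clusters are grown by breadth-first search
from unvisited nodes in decreasing-count order (ties broken
lexicographically).  The deduplicated count of a reference is its number of
clusters.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASES = "ACGT"


@dataclass
class UmiGroup:
    reference_id: str
    umi_counts: dict[str, int]
    n_clusters: int | None = None
    representatives: list[str] | None = None


def split_umi(read_id: str) -> tuple[str, str]:
    """Split the underscore-suffix UMI dialect ``<id>_<UMI>``."""
    base, sep, umi = read_id.rpartition("_")
    if not sep or not umi or not set(umi) <= set(_BASES):
        raise ValueError(f"read id {read_id!r} carries no underscore-suffix UMI")
    return base, umi


def group_reads_by_reference(
    assigned: list[tuple[str, str]],
) -> dict[str, UmiGroup]:
    """Group ``(read_id_with_umi, reference_id)`` pairs into per-reference UMI tallies."""
    counts: dict[str, Counter] = {}
    for read_id, ref in assigned:
        _base, umi = split_umi(read_id)
        counts.setdefault(ref, Counter())[umi] += 1
    return {ref: UmiGroup(ref, dict(c)) for ref, c in counts.items()}


def _hamming1_neighbors(umi: str):
    for i, c in enumerate(umi):
        for b in _BASES:
            if b != c:
                yield umi[:i] + b + umi[i + 1 :]


def directional_cluster(umi_counts: dict[str, int]) -> tuple[int, list[str]]:
    """Cluster UMIs with the directional algorithm.

    Returns ``(number_of_clusters, representative_umis)``; the representative
    of a cluster is its seed (highest count, ties lexicographic).
    """
    if not umi_counts:
        return 0, []
    lengths = {len(u) for u in umi_counts}
    if len(lengths) != 1:
        raise ValueError(f"UMIs of unequal length: {sorted(lengths)}")
    if any(c < 1 for c in umi_counts.values()):
        raise ValueError("UMI counts must be >= 1")
    # adjacency via neighbour enumeration: O(n * 3L) dictionary lookups
    adj: dict[str, list[str]] = {}
    for u, cu in umi_counts.items():
        edges = []
        for v in _hamming1_neighbors(u):
            cv = umi_counts.get(v)
            if cv is not None and cu >= 2 * cv - 1:
                edges.append(v)
        adj[u] = edges
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    visited: set[str] = set()
    reps: list[str] = []
    for seed in order:
        if seed in visited:
            continue
        reps.append(seed)
        queue = deque([seed])
        visited.add(seed)
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in visited:
                    visited.add(v)
                    queue.append(v)
    return len(reps), reps


def dedup_counts(groups: dict[str, UmiGroup]) -> pd.Series:
    """Deduplicated count per reference = directional cluster count.

    Always <= the raw read count of the group.
    """
    out = {}
    for ref, g in groups.items():
        n, reps = directional_cluster(g.umi_counts)
        g.n_clusters, g.representatives = n, reps
        out[ref] = n
    return pd.Series(out, dtype="int64").sort_index()


def subsample_reads(
    reads: list, fraction: float, seed: int
) -> list:
    """Keep each read independently with probability ``fraction`` (seeded).

    Emulates the random 5% subset control used to separate the effect of
    UMI collapsing from the effect of simply having fewer reads.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def expected_distinct_umis(molecules: int, umi_space: int = 65536) -> float:
    """Closed form E[#distinct labels] = U * (1 - (1 - 1/U)^m)."""
    return umi_space * (1.0 - (1.0 - 1.0 / umi_space) ** molecules)
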