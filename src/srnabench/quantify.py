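"""Assignment of trimmed inserts to reference sequences.

An insert is *canonical* when it equals a reference sequence exactly;
otherwise it may be assigned as an *isomiR* of the reference minimising an
explicit edit cost (5' offset + 3' offset + internal mismatches +
non-templated 3' additions) within configurable bounds.  isomiRs are keyed
by their full insert sequence.  Ties break by smallest cost, then
lexicographically smallest reference id, making assignment deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .pool import ReferencePool


@dataclass
class AssignmentPolicy:
    """Bounds of the isomiR assignment cost model (all nonnegative)."""

    max_5p_offset: int = 4
    max_3p_offset: int = 4
    max_internal_mismatch: int = 2
    max_nt_additions3: int = 3
    min_overlap: int = 10  # aligned bases required between insert and reference

    def __post_init__(self) -> None:
        for f in ("max_5p_offset", "max_3p_offset", "max_internal_mismatch",
                  "max_nt_additions3", "min_overlap"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


def score_against(insert: str, ref: str, policy: AssignmentPolicy) -> int | None:
    """Minimal edit cost of explaining ``insert`` as a variant of ``ref``.

    Alignments place the insert at an integer shift ``s`` relative to the
    reference 5' end (|s| <= max_5p_offset; s > 0 is a 5' truncation, s < 0 a
    5' extension).  Insert bases hanging past the reference 3' end are
    non-templated additions; reference bases not covered at the 3' end are
    the 3' offset.  Returns ``None`` when no alignment fits the bounds.
    """
    best = None
    for s in range(-policy.max_5p_offset, policy.max_5p_offset + 1):
        i0 = max(0, -s)          # first insert base aligned inside the reference
        r0 = max(0, s)
        end_in_ref = s + len(insert)
        additions = max(0, end_in_ref - len(ref))
        if additions > policy.max_nt_additions3:
            continue
        off3 = max(0, len(ref) - end_in_ref)
        if off3 > policy.max_3p_offset:
            continue
        ov = len(insert) - i0 - additions
        if ov < policy.min_overlap or ov <= 0:
            continue
        mism = 0
        seg_i = insert[i0 : i0 + ov]
        seg_r = ref[r0 : r0 + ov]
        for a, b in zip(seg_i, seg_r):
            if a != b:
                mism += 1
                if mism > policy.max_internal_mismatch:
                    break
        if mism > policy.max_internal_mismatch:
            continue
        cost = abs(s) + off3 + mism + additions
        if best is None or cost < best:
            best = cost
    return best


class Quantifier:
    """Assigns inserts to a reference pool under an :class:`AssignmentPolicy`."""

    def __init__(self, pool: ReferencePool, policy: AssignmentPolicy | None = None):
        self.pool = pool
        self.policy = policy or AssignmentPolicy()
        self._exact = {s: i for i, s in enumerate(pool.sequences)}
        # candidate pruning: only references of compatible length can score
        self._by_length: dict[int, list[int]] = {}
        for i, s in enumerate(pool.sequences):
            self._by_length.setdefault(len(s), []).append(i)

    def assign_read(self, insert: str) -> tuple[str, bool] | None:
        """Return ``(reference_id, is_canonical)`` or ``None`` (unassigned)."""
        hit = self._exact.get(insert)
        if hit is not None:
            return self.pool.ids[hit], True
        p = self.policy
        lo = len(insert) - p.max_5p_offset - p.max_nt_additions3
        hi = len(insert) + p.max_5p_offset + p.max_3p_offset
        best_cost, best_id = None, None
        for L in range(lo, hi + 1):
            for i in self._by_length.get(L, ()):
                c = score_against(insert, self.pool.sequences[i], p)
                if c is None:
                    continue
                rid = self.pool.ids[i]
                if best_cost is None or c < best_cost or (c == best_cost and rid < best_id):
                    best_cost, best_id = c, rid
        if best_id is None:
            return None
        return best_id, False


@dataclass
class CountMatrix:
    """Canonical and isomiR counts for a set of samples, with metadata.

    ``canonical``: reference id x sample integer counts.
    ``isomirs``: (parent id, isomiR sequence) x sample integer counts.
    ``metadata``: per-sample (method, input_ng, batch, replicate).
    ``unassigned``: reads assigned to no reference, per sample.
    """

    canonical: pd.DataFrame
    isomirs: pd.DataFrame
    metadata: pd.DataFrame
    unassigned: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.canonical.columns)

    def to_tsv(self, prefix: str) -> None:
        self.canonical.to_csv(f"{prefix}.canonical.tsv", sep="\t")
        self.isomirs.to_csv(f"{prefix}.isomir.tsv", sep="\t")

    def to_triplets(self, path) -> None:
        """Sparse triplet export (feature, sample, count), nonzero canonical cells."""
        long = self.canonical.stack()
        long = long[long > 0].rename("count").reset_index()
        long.columns = ["feature", "sample", "count"]
        long.to_csv(path, sep="\t", index=False)


def quantify_sample(
    inserts: list[tuple[str, str]], quantifier: Quantifier
) -> tuple[Counter, Counter, int]:
    """Count canonical / isomiR assignments for one sample's inserts."""
    canonical: Counter = Counter()
    isomirs: Counter = Counter()
    unassigned = 0
    cache: dict[str, tuple[str, bool] | None] = {}
    for _rid, ins in inserts:
        res = cache.get(ins, "__miss__")
        if res == "__miss__":
            res = quantifier.assign_read(ins)
            cache[ins] = res
        if res is None:
            unassigned += 1
        else:
            rid, is_canon = res
            if is_canon:
                canonical[rid] += 1
            else:
                isomirs[(rid, ins)] += 1
    return canonical, isomirs, unassigned


def build_count_matrix(
    per_sample: dict[str, tuple[Counter, Counter, int]],
    pool: ReferencePool,
    metadata: pd.DataFrame | None = None,
) -> CountMatrix:
    """Assemble per-sample assignment counters into a :class:`CountMatrix`.

    ``per_sample`` maps sample name → the triple from :func:`quantify_sample`.
    Sample names must be unique (dict keys enforce this; an explicit check
    guards metadata too).
    """
    samples = list(per_sample)
    canonical = pd.DataFrame(
        {s: pd.Series(per_sample[s][0], dtype="int64") for s in samples}
    ).reindex(pool.ids).fillna(0).astype("int64")
    canonical.index.name = "reference_id"
    iso_keys = sorted({k for s in samples for k in per_sample[s][1]})
    if iso_keys:
        idx = pd.MultiIndex.from_tuples(iso_keys, names=["parent_id", "isomir_seq"])
        isomirs = pd.DataFrame(
            {s: [per_sample[s][1].get(k, 0) for k in iso_keys] for s in samples},
            index=idx,
            dtype="int64",
        )
    else:
        isomirs = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["parent_id", "isomir_seq"]),
            columns=samples,
            dtype="int64",
        )
    unassigned = pd.Series({s: per_sample[s][2] for s in samples}, dtype="int64")
    if metadata is None:
        metadata = pd.DataFrame(index=pd.Index(samples, name="sample"))
    else:
        if metadata.index.has_duplicates:
            raise ValueError("duplicate sample names in metadata")
        metadata = metadata.loc[samples]
    return CountMatrix(canonical=canonical, isomirs=isomirs, metadata=metadata, unassigned=unassigned)


def classify_rna_classes(
    reads: list[tuple[str, str]],
    class_fasta: dict[str, list[tuple[str, str]]],
    seed_length: int = 28,
) -> pd.DataFrame:
    """Classify reads among labelled small-RNA classes by exact seed match.

    ``class_fasta`` maps class label → list of ``(entry_id, sequence)``.  A
    read matches an entry when its first ``min(seed_length, len(read))``
    bases occur exactly (forward strand) as a substring of the entry.  At
    reference build time, piRNA entries whose sequence equals a miRNA entry
    are removed (miRNA takes precedence).  Reads matching no entry are
    counted as ``Undetermined``.  Returns per-class counts and percentages.
    """
    if not class_fasta or all(not v for v in class_fasta.values()):
        raise ValueError("empty class reference")
    mirna_seqs = {s for _i, s in class_fasta.get("miRNA", [])}
    cleaned: dict[str, list[str]] = {}
    for label, entries in class_fasta.items():
        seqs = [s for _i, s in entries]
        if label == "piRNA":
            seqs = [s for s in seqs if s not in mirna_seqs]
        cleaned[label] = seqs
    labels = list(cleaned)
    counts = Counter()
    for _rid, read in reads:
        seed = read[: min(seed_length, len(read))]
        hit = None
        for label in labels:
            if any(seed in entry for entry in cleaned[label]):
                hit = label
                break
        counts[hit if hit else "Undetermined"] += 1
    total = max(1, len(reads))
    rows = labels + ["Undetermined"]
    return pd.DataFrame(
        {
            "count": [counts.get(r, 0) for r in rows],
            "percent": [100.0 * counts.get(r, 0) / total for r in rows],
        },
        index=pd.Index(rows, name="rna_class"),
    )
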