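"""Median-of-ratios normalization and the benchmarking metric suite.

Metrics operate on normalized count matrices (features x samples):

* **accuracy error** — for an equimolar pool, ``log2(|x_i - mean(x)| + 1)``
  per feature (the +1 pseudocount maps a zero difference to zero error).
* **detection / inconsistency** — a feature is detected when strictly above
  a normalized-count threshold (10 for miRNAs, 100 for isomiRs) in every
  replicate; a replicate's inconsistency is ``(U_X - U_123)/U_X * 100``.
* **false isomiRs** — any isomiR detected in an equimolar synthetic pool is
  a false positive by construction.
* **similarity** — MA statistics between method means after a >1-in-all-
  samples filter, and top-N abundance-rank overlap.
* **consistency** — batch error and triplicate error as log2 absolute
  deviations (+1 pseudocount).
* **UMI saturation** — starting-molecule estimation from read counts under
  an assumed per-cycle PCR efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Strict detection thresholds on normalized counts.
MIRNA_DETECTION_THRESHOLD = 10.0
ISOMIR_DETECTION_THRESHOLD = 100.0
SIMILARITY_FILTER_THRESHOLD = 1.0

UMI_SPACE_DEFAULT = 65536


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per feature, the geometric mean across samples is computed over features
    with strictly positive counts in every sample; the factor of sample *j*
    is the median over those features of ``raw[i, j] / geomean_i``.
    """
    if raw.shape[1] < 2:
        raise ValueError("size factors require at least 2 samples")
    positive = (raw > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with all-positive counts across samples; "
            "median-of-ratios size factors are undefined"
        )
    sub = raw.loc[positive].astype(float)
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors.name = "size_factor"
    return factors


def normalize_counts(raw: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Scale each sample by its median-of-ratios size factor."""
    if factors is None:
        factors = size_factors(raw)
    return raw.astype(float).div(factors, axis=1)


def accuracy_error(values: pd.Series | np.ndarray) -> pd.Series:
    """Equimolar accuracy error per feature: ``log2(|x - mean(x)| + 1)``."""
    x = pd.Series(values, dtype=float)
    if len(x) < 2:
        raise ValueError("accuracy error needs at least 2 features")
    return np.log2((x - x.mean()).abs() + 1.0)


@dataclass
class DetectionSet:
    """Per-replicate detected feature sets and their consensus."""

    replicate_sets: dict[str, set]
    threshold: float

    @property
    def consensus(self) -> set:
        sets = list(self.replicate_sets.values())
        return set.intersection(*sets) if sets else set()

    @property
    def cardinalities(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.replicate_sets.items()}


def detect(normalized: pd.DataFrame, threshold: float, replicates: list[str] | None = None) -> DetectionSet:
    """Detection sets under a strict ``> threshold`` rule, per replicate column."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cols = replicates if replicates is not None else list(normalized.columns)
    sets = {c: set(normalized.index[normalized[c] > threshold]) for c in cols}
    return DetectionSet(replicate_sets=sets, threshold=threshold)


def detection_inconsistency(ds: DetectionSet) -> pd.Series:
    """Per-replicate inconsistency percentage, ``(U_X - U_123)/U_X * 100``.

    Replicates detecting nothing (U_X = 0) are reported as NaN.
    """
    u123 = len(ds.consensus)
    out = {}
    for rep, s in ds.replicate_sets.items():
        ux = len(s)
        out[rep] = np.nan if ux == 0 else (ux - u123) / ux * 100.0
    return pd.Series(out, name="inconsistency_pct")


def false_isomirs(
    isomir_normalized: pd.DataFrame,
    threshold: float = ISOMIR_DETECTION_THRESHOLD,
    replicates: list[str] | None = None,
) -> dict:
    """Summarise false-isomiR detections in an equimolar synthetic run.

    The pool contains no designed isomiRs, so every isomiR strictly above
    ``threshold`` normalized reads (in all requested replicates) is a false
    positive.  Returns the three comparison axes: total unique false
    isomiRs, per-parent counts, and the normalized expression of each
    detected false isomiR (mean across replicates).
    """
    cols = replicates if replicates is not None else list(isomir_normalized.columns)
    if isomir_normalized.empty:
        detected = isomir_normalized.index[:0]
    else:
        mask = (isomir_normalized[cols] > threshold).all(axis=1)
        detected = isomir_normalized.index[mask]
    sub = isomir_normalized.loc[detected, cols]
    per_parent = (
        pd.Series(1, index=detected).groupby(level="parent_id").sum()
        if len(detected)
        else pd.Series(dtype="int64")
    )
    return {
        "total_unique": int(len(detected)),
        "per_parent": per_parent,
        "expression": sub.mean(axis=1) if len(detected) else pd.Series(dtype=float),
    }


def similarity_filter(normalized: pd.DataFrame, threshold: float = SIMILARITY_FILTER_THRESHOLD) -> pd.Index:
    """Features with normalized counts strictly greater than ``threshold`` in all samples."""
    return normalized.index[(normalized > threshold).all(axis=1)]


def ma_statistics(mean_a: pd.Series, mean_b: pd.Series) -> pd.DataFrame:
    """Per-feature MA records between two methods' mean normalized counts.

    ``M = log2(mean_a) - log2(mean_b)``; ``A = (log2(mean_a) + log2(mean_b)) / 2``.
    Callers should pre-filter features with :func:`similarity_filter`.
    """
    common = mean_a.index.intersection(mean_b.index)
    la = np.log2(mean_a.loc[common].astype(float))
    lb = np.log2(mean_b.loc[common].astype(float))
    return pd.DataFrame({"A": (la + lb) / 2.0, "M": la - lb})


def topn_overlap(method_means: dict[str, pd.Series], n: int = 20) -> dict:
    """Overlap of the top-``n`` most abundant features across methods.

    Ranking is by decreasing mean; ties at rank ``n`` break by lexicographic
    feature id.  Returns the global overlap fraction (|intersection| / n)
    and the pairwise fraction matrix.
    """
    tops = {}
    for m, means in method_means.items():
        if n > len(means):
            raise ValueError(f"n={n} exceeds feature count for method {m!r}")
        order = sorted(means.index, key=lambda f: (-means[f], f))
        tops[m] = set(order[:n])
    methods = list(tops)
    global_overlap = len(set.intersection(*tops.values())) / n if methods else 0.0
    pairwise = pd.DataFrame(
        [[len(tops[a] & tops[b]) / n for b in methods] for a in methods],
        index=methods,
        columns=methods,
    )
    return {"global": global_overlap, "pairwise": pairwise, "top_sets": tops}


def batch_error(
    batch1: pd.DataFrame,
    batch2: pd.Series,
    filter_threshold: float = MIRNA_DETECTION_THRESHOLD,
) -> pd.Series:
    """Per-feature batch error ``log2(|mean(batch1) - batch2| + 1)``.

    Features must exceed ``filter_threshold`` normalized counts in every
    batch-1 replicate and the batch-2 sample.
    """
    ok = (batch1 > filter_threshold).all(axis=1) & (batch2 > filter_threshold)
    b1 = batch1.loc[ok].mean(axis=1)
    return np.log2((b1 - batch2.loc[ok]).abs() + 1.0).rename("batch_error")


def triplicate_error(replicates: pd.DataFrame) -> pd.Series:
    """Per-feature mean of ``log2(|x - row mean| + 1)`` across replicates."""
    if replicates.shape[1] < 2:
        raise ValueError("triplicate error needs at least 2 replicates")
    dev = replicates.sub(replicates.mean(axis=1), axis=0).abs()
    return np.log2(dev + 1.0).mean(axis=1).rename("triplicate_error")


def estimate_starting_molecules(
    reads: float,
    efficiency: float = 0.625,
    cycles: int = 18,
    umi_space: int = UMI_SPACE_DEFAULT,
    saturation_ratio: float = 0.2,
) -> tuple[float, bool]:
    """Estimate pre-PCR molecules as ``reads / (1 + e)^c``.

    The conservative default efficiency of 62.5% gives an upper-bound
    estimate of starting molecules.  The flag marks estimates approaching
    the UMI label space (ratio above ``saturation_ratio``), where UMI
    collisions would make deduplicated counts under-estimate molecules.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    if cycles < 0:
        raise ValueError("cycles must be nonnegative")
    n0 = reads / (1.0 + efficiency) ** cycles
    return n0, bool(n0 / umi_space > saturation_ratio)
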