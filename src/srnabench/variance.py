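"""Sequence-feature extraction and type-II sum-of-squares variance partitioning.

``sequence_features`` computes, per reference sequence: GC content, length,
fold free energy (supplied or Nussinov proxy), the identities of the first
and last two bases (16-level categoricals), individual base counts, and
repeat flags (any duplet of identical adjacent bases; any homopolymer
quadruplet).

``percent_variance`` decomposes the variance of a per-feature response into
percent explained per factor using type-II sums of squares under ordinary
least squares: ``SS_factor = RSS(model without the factor) - RSS(full
model)``, ``percent = SS_factor / SS_total * 100``.  Categorical factors use
treatment coding with the lexicographically first level as reference.  In
orthogonal designs the factor percentages plus the residual sum to 100;
in non-orthogonal designs negative type-II components are floored at zero
with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bias import nussinov_energy

_VALID = set("ACGT")

SEQUENCE_FACTORS = [
    "gc_content", "length", "fold_g", "first2", "last2",
    "nA", "nC", "nG", "nT", "has_duplet", "has_quadruplet",
]


def sequence_features(sequence: str, fold_g: float | None = None) -> dict:
    """Feature row for one sequence; ``fold_g`` defaults to the Nussinov proxy."""
    seq = sequence.upper().replace("U", "T")
    if not set(seq) <= _VALID:
        raise ValueError(f"invalid alphabet in {sequence!r}")
    if len(seq) < 16:
        raise ValueError(f"sequence shorter than 16 nt: {sequence!r}")
    counts = {b: seq.count(b) for b in "ACGT"}
    has_duplet = any(seq[i] == seq[i + 1] for i in range(len(seq) - 1))
    has_quad = any(seq[i : i + 4] == seq[i] * 4 for i in range(len(seq) - 3))
    return {
        "gc_content": (counts["G"] + counts["C"]) / len(seq),
        "length": len(seq),
        "fold_g": nussinov_energy(seq) if fold_g is None else float(fold_g),
        "fold_g_is_proxy": fold_g is None,
        "first2": seq[:2],
        "last2": seq[-2:],
        "nA": counts["A"],
        "nC": counts["C"],
        "nG": counts["G"],
        "nT": counts["T"],
        "has_duplet": has_duplet,
        "has_quadruplet": has_quad,
    }


def feature_table(pool, fold_energies: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-reference :func:`sequence_features` rows for a whole pool."""
    rows = {
        rid: sequence_features(
            seq, None if fold_energies is None else fold_energies.get(rid)
        )
        for rid, seq in zip(pool.ids, pool.sequences)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reference_id"
    return df


def _encode_factor(col: pd.Series) -> np.ndarray:
    """Design-matrix block for one factor (treatment coding for categoricals)."""
    if col.dtype == bool:
        return col.astype(float).to_numpy()[:, None]
    if col.dtype.kind in "if":
        return col.astype(float).to_numpy()[:, None]
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {col.name!r} has fewer than 2 observed levels")
    # drop the lexicographically first level (reference)
    blocks = [(col.astype(str) == lv).astype(float).to_numpy() for lv in levels[1:]]
    return np.column_stack(blocks)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def percent_variance(
    response: pd.Series, factors: pd.DataFrame, warn_negative: bool = True
) -> pd.Series:
    """Type-II percent-variance decomposition of ``response`` by ``factors``.

    Returns a Series with one entry per factor column plus ``residual``.
    Raises on rank deficiency, naming the aliased factors.
    """
    y = response.astype(float).to_numpy()
    n = len(y)
    blocks = {name: _encode_factor(factors[name]) for name in factors.columns}
    p_total = 1 + sum(b.shape[1] for b in blocks.values())
    if n <= p_total:
        raise ValueError(f"need more observations ({n}) than parameters ({p_total})")
    intercept = np.ones((n, 1))
    X_full = np.column_stack([intercept] + [blocks[f] for f in factors.columns])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        aliased = []
        base_rank = np.linalg.matrix_rank(intercept)
        cols = [intercept]
        for f in factors.columns:
            cand = np.column_stack(cols + [blocks[f]])
            r = np.linalg.matrix_rank(cand)
            if r < base_rank + blocks[f].shape[1]:
                aliased.append(f)
            else:
                cols.append(blocks[f])
                base_rank = r
        raise ValueError(f"rank-deficient design; aliased factors: {aliased}")
    rss_full = _rss(X_full, y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("response has zero variance")
    shares = {}
    for f in factors.columns:
        X_red = np.column_stack(
            [intercept] + [blocks[g] for g in factors.columns if g != f]
        )
        ss = _rss(X_red, y) - rss_full
        if ss < 0:
            if ss < -1e-8 * ss_total and warn_negative:
                warnings.warn(
                    f"negative type-II share for factor {f!r} floored at 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            ss = 0.0
        shares[f] = ss / ss_total * 100.0
    shares["residual"] = rss_full / ss_total * 100.0
    return pd.Series(shares, name="percent_variance")


def weighted_percent_variance(
    decompositions: dict[str, pd.Series], method_variances: dict[str, float]
) -> pd.DataFrame:
    """Weight each method's percent-variance shares by its overall variance.

    ``weighted(method, factor) = percent(method, factor) * var(method) /
    max_m var(m)``.  With equal variances the weighted view equals the
    unweighted one.
    """
    if set(decompositions) != set(method_variances):
        raise ValueError("decompositions and variances must cover the same methods")
    vmax = max(method_variances.values())
    if vmax <= 0:
        raise ValueError("method variances must be positive")
    out = {
        m: dec * (method_variances[m] / vmax) for m, dec in decompositions.items()
    }
    return pd.DataFrame(out)
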