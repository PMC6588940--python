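"""Kit-aware adapter trimming, UMI extraction and length filtering.

Three layouts are supported:

* ``nextflex`` — exact-prefix 3' adapter trimming, then the first and last
  four bases (the degenerate adapter bases) are removed and concatenated
  into an 8-mer UMI appended to the read id as ``<id>_<UMI>``.  Reads whose
  UMI contains a non-ACGT base are dropped.
* ``clontech`` — the first three template-switch bases are dropped, then the
  read is truncated at the first run of >= 10 consecutive 'A' (the poly-A
  tail); applying the rule literally means an internal 10-A run inside a
  genuine insert also truncates it — a known failure mode of the chemistry's
  informatics, kept deliberately.
* ``plain`` — 3' adapter trimming only.

A minimum insert length of 16 nt is used for synthetic-pool libraries (the
shortest pool sequence) and 18 nt for biological libraries.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .bias import DEFAULT_ADAPTER3

_VALID = set("ACGT")


@dataclass
class TrimConfig:
    layout: str = "nextflex"
    adapter3: str = DEFAULT_ADAPTER3
    min_length: int = 16       # 16 for synthetic-pool mode, 18 for biological mode
    min_overlap: int = 5       # shortest adapter prefix accepted at the 3' end
    polyA_min_run: int = 10    # clontech poly-A truncation rule
    umi_len: int = 4           # per end, nextflex

    def __post_init__(self) -> None:
        if self.layout not in ("nextflex", "clontech", "plain"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.layout in ("nextflex", "plain") and not self.adapter3:
            raise ValueError(f"{self.layout} layout requires a 3' adapter sequence")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")


def trim_3prime_adapter(seq: str, adapter3: str, min_overlap: int = 5) -> str:
    """Remove the leftmost 3' adapter occurrence and everything after it.

    Matching is exact: the full adapter anywhere in the read, or an adapter
    prefix of length >= ``min_overlap`` ending exactly at the read's 3' end.
    Reads with no hit are returned unchanged.
    """
    pos = seq.find(adapter3)
    if pos != -1:
        return seq[:pos]
    max_ov = min(len(adapter3) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter3[:ov]):
            return seq[: len(seq) - ov]
    return seq


def extract_umi_nextflex(
    read_id: str, trimmed: str, umi_len: int = 4
) -> tuple[str, str, str] | None:
    """Split a trimmed nextflex read into (new_read_id, insert, umi).

    The UMI is the concatenation of the first and last ``umi_len`` bases;
    it is appended to the read id as an underscore suffix.  Returns ``None``
    (drop) when the read is too short to contain both UMI halves plus a
    nonempty insert, or when the UMI contains a non-ACGT base.
    """
    if len(trimmed) < 2 * umi_len + 1:
        return None
    umi = trimmed[:umi_len] + trimmed[-umi_len:]
    if not set(umi) <= _VALID:
        return None
    insert = trimmed[umi_len:-umi_len]
    return f"{read_id}_{umi}", insert, umi


def trim_clontech(seq: str, ts_bases: int = 3, polyA_min_run: int = 10) -> str:
    """Drop the template-switch bases and truncate at the first poly-A run."""
    rest = seq[ts_bases:]
    m = re.search("A{%d,}" % polyA_min_run, rest)
    return rest[: m.start()] if m else rest


def length_filter(inserts, min_length: int):
    """Partition ``(read_id, insert)`` pairs by the minimum-length rule."""
    kept, n_short = [], 0
    for rid, ins in inserts:
        if len(ins) >= min_length:
            kept.append((rid, ins))
        else:
            n_short += 1
    return kept, n_short


def trim_reads(
    reads: list[tuple[str, str, str]], config: TrimConfig
) -> tuple[list[tuple[str, str]], Counter]:
    """Trim a read set; returns retained ``(read_id, insert)`` and a discard tally.

    Every input read ends up exactly once in the output or in the tally
    (reasons: ``too_short``, ``bad_umi``, ``empty_insert``).
    """
    kept: list[tuple[str, str]] = []
    tally: Counter = Counter()
    for rid, seq, _qual in reads:
        if config.layout == "clontech":
            insert = trim_clontech(seq, polyA_min_run=config.polyA_min_run)
            new_id = rid
        else:
            trimmed = trim_3prime_adapter(seq, config.adapter3, config.min_overlap)
            if config.layout == "nextflex":
                res = extract_umi_nextflex(rid, trimmed, config.umi_len)
                if res is None:
                    if len(trimmed) < 2 * config.umi_len + 1:
                        tally["empty_insert"] += 1
                    else:
                        tally["bad_umi"] += 1
                    continue
                new_id, insert, _umi = res
            else:
                insert, new_id = trimmed, rid
        if len(insert) < config.min_length:
            tally["too_short"] += 1
            continue
        kept.append((new_id, insert))
    tally["retained"] = len(kept)
    return kept, tally
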