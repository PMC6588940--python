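"""Reference pools of mature small-RNA sequences.

A :class:`ReferencePool` is the ground-truth universe for a benchmarking run:
the set of mature miRNA (or miRNA-like) sequences present in the sample
together with their molar fractions.  The default builder emulates an
equimolar pool of 962 synthetic sequences of 16-28 nt, the standard
commercial universal-reference design used for accuracy benchmarking of
small RNA-seq library preparations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = "ACGT"

MIN_REF_LENGTH = 16
MAX_REF_LENGTH = 30


@dataclass
class ReferencePool:
    """A set of mature small-RNA reference sequences with molar fractions.

    Parameters
    ----------
    ids
        Unique sequence identifiers.
    sequences
        DNA-alphabet sequences (``A/C/G/T``), unique, each 16-30 nt.
    fractions
        Molar fraction of each sequence in the pool; must sum to 1.
    source
        Free-text label describing where the pool came from.
    """

    ids: list[str]
    sequences: list[str]
    fractions: np.ndarray
    source: str = "synthetic"
    _index: dict[str, int] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.ids) != len(self.sequences) or len(self.ids) != len(self.fractions):
            raise ValueError("ids, sequences and fractions must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("reference ids must be unique")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("reference sequences must be unique")
        for seq in self.sequences:
            if not set(seq) <= set(_BASES):
                raise ValueError(f"invalid alphabet in sequence {seq!r}")
            if not MIN_REF_LENGTH <= len(seq) <= MAX_REF_LENGTH:
                raise ValueError(
                    f"sequence length {len(seq)} outside [{MIN_REF_LENGTH}, {MAX_REF_LENGTH}]"
                )
        if np.any(self.fractions <= 0):
            raise ValueError("molar fractions must be positive")
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("molar fractions must sum to 1 within 1e-9")
        self._index = {s: i for i, s in enumerate(self.sequences)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of_sequence(self, seq: str) -> int | None:
        return self._index.get(seq)

    @property
    def gc_content(self) -> np.ndarray:
        return np.array(
            [(s.count("G") + s.count("C")) / len(s) for s in self.sequences]
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description=f"fraction={f:.6g}")
            for i, s, f in zip(self.ids, self.sequences, self.fractions)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, source: str = "fasta") -> "ReferencePool":
        ids, seqs = [], []
        for rec in SeqIO.parse(path, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper().replace("U", "T"))
        if not ids:
            raise ValueError(f"no sequences in {path}")
        n = len(ids)
        return cls(ids, seqs, np.full(n, 1.0 / n), source=source)


def build_reference_pool(
    n: int = 962,
    length_range: tuple[int, int] = (16, 28),
    gc_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 7,
) -> ReferencePool:
    """Generate an equimolar pool of ``n`` unique random reference sequences.

    Lengths are drawn uniformly from ``length_range`` and sequences are
    rejected until their GC content falls inside ``gc_range``.  Deterministic
    given ``seed``.  The defaults emulate an equimolar 962-sequence synthetic
    miRNA universal reference pool.

    Raises
    ------
    ValueError
        If the constraints cannot yield ``n`` unique sequences
        (``n > 4**min_length``) or the ranges are malformed.
    """
    lo, hi = length_range
    if lo < MIN_REF_LENGTH or hi > MAX_REF_LENGTH or lo > hi:
        raise ValueError(
            f"length_range {length_range} outside allowed [{MIN_REF_LENGTH}, {MAX_REF_LENGTH}]"
        )
    if n < 1:
        raise ValueError("n must be positive")
    if n > 4**lo:
        raise ValueError(
            f"cannot build {n} unique sequences of minimum length {lo}: "
            f"only 4^{lo} = {4**lo} exist"
        )
    gc_lo, gc_hi = gc_range
    if not (0.0 <= gc_lo <= gc_hi <= 1.0):
        raise ValueError(f"invalid gc_range {gc_range}")
    # Feasibility of the GC window for every candidate length: there must be
    # an integer GC count inside [gc_lo*L, gc_hi*L] for at least one length.
    feasible = [
        L for L in range(lo, hi + 1) if math.floor(gc_hi * L) >= math.ceil(gc_lo * L)
    ]
    if not feasible:
        raise ValueError(f"gc_range {gc_range} admits no sequence length in {length_range}")

    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    seqs: list[str] = []
    max_tries = 1000 * n + 10000
    tries = 0
    while len(seqs) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not build {n} unique sequences within constraints "
                f"length_range={length_range}, gc_range={gc_range}"
            )
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=L))
        gc = (seq.count("G") + seq.count("C")) / L
        if not (gc_lo <= gc <= gc_hi):
            continue
        if seq in seen:
            continue
        seen.add(seq)
        seqs.append(seq)
    ids = [f"syn-{i + 1:04d}" for i in range(n)]
    return ReferencePool(ids, seqs, np.full(n, 1.0 / n), source="simulated equimolar pool")
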