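"""Ground-truth simulator for small RNA-seq libraries.

The simulator follows the physical order of library preparation:

1. ``sample_molecules`` — multinomial draw of pre-amplification molecules
   from the pool, tilted by ligation/RT selection weights; UMIs are attached
   here (degenerate adapter bases ligate before reverse transcription and
   PCR, so every PCR copy inherits its parent's UMI).
2. ``inject_isomir_artifacts`` — chemistry artifacts that create apparent
   isomiRs (3' trims, non-templated 3' additions and, for template-switch
   chemistry, 5' strand invasion and template-switch-oligo concatamers).
3. ``amplify`` — per-cycle stochastic duplication with GC-dependent
   efficiency and optional homopolymer stutter.
4. ``sequence_reads`` — fixed-length single-end reads through the
   kit-specific adapter layout with per-base substitution errors.

Everything is logged into a :class:`TruthTable` so downstream recovery
(trimming, quantification, UMI deduplication) can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import BiasModel, total_bias_weights
from .pool import ReferencePool

_BASES = "ACGT"

ARTIFACT_NONE = 0
ARTIFACT_BITS = {"trim3": 1, "ext3": 2, "strand_invasion5": 4, "concatamer5": 8}
_BIT_NAMES = {v: k for k, v in ARTIFACT_BITS.items()}

#: Fixed bases prepended by the template-switching reverse transcriptase.
CLONTECH_TS_BASES = "GGG"


def encode_umi(umi: str) -> int:
    code = 0
    for b in umi:
        code = code * 4 + _BASES.index(b)
    return code


def decode_umi(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def artifact_kind_name(code: int) -> str:
    if code == ARTIFACT_NONE:
        return ""
    return "+".join(name for bit, name in sorted(_BIT_NAMES.items()) if code & bit)


@dataclass
class MoleculeSet:
    """A multiset of molecules as parallel arrays.

    ``seq_id`` indexes ``seqs``; distinct molecules may share a sequence
    entry.  ``umi`` holds base-4 encoded UMI labels (-1 when the chemistry
    carries no UMI).
    """

    pool: ReferencePool
    parent: np.ndarray      # int index into pool
    seq_id: np.ndarray      # int index into seqs
    umi: np.ndarray         # int64 code or -1
    artifact: np.ndarray    # uint8 bitmask
    seqs: list[str]         # sequence table
    umi_total_len: int      # 2 * per-end UMI length

    def __len__(self) -> int:
        return len(self.parent)

    def sequence_of(self, i: int) -> str:
        return self.seqs[self.seq_id[i]]

    @property
    def gc_of_seqs(self) -> np.ndarray:
        return np.array(
            [(s.count("G") + s.count("C")) / len(s) if s else 0.0 for s in self.seqs]
        )


@dataclass
class TruthTable:
    """Ground truth for one simulated library."""

    true_molecules: pd.Series          # pre-PCR molecule count per reference id
    molecules: pd.DataFrame            # per pre-PCR molecule: parent_id, umi, is_artifact, artifact_kind
    reads: pd.DataFrame                # per emitted read: read_id, parent_id, umi, is_artifact, artifact_kind
    artifact_counts: pd.DataFrame      # parent_id, kind, count

    def distinct_umis_per_reference(self) -> pd.Series:
        """Number of distinct UMI labels among pre-PCR molecules, per reference."""
        m = self.molecules
        return m.groupby("parent_id", sort=True)["umi"].nunique()

    def to_tsv(self, prefix: str) -> None:
        self.true_molecules.rename("true_molecules_pre_pcr").to_csv(
            f"{prefix}.true_molecules.tsv", sep="\t"
        )
        self.reads.to_csv(f"{prefix}.reads.tsv", sep="\t", index=False)
        self.artifact_counts.to_csv(f"{prefix}.artifacts.tsv", sep="\t", index=False)


def sample_molecules(
    pool: ReferencePool,
    weights: np.ndarray,
    total_molecules: int,
    umi_length_each_end: int,
    rng: np.random.Generator,
) -> MoleculeSet:
    """Draw the pre-amplification molecule population.

    Multinomial over ``molar_fraction * weight`` (renormalised); every
    molecule receives an independent uniform UMI over the
    ``4**(2*umi_length_each_end)`` label space.
    """
    if total_molecules < 1:
        raise ValueError("total_molecules must be >= 1")
    p = pool.fractions * np.asarray(weights, dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(total_molecules, p)
    parent = np.repeat(np.arange(len(pool), dtype=np.int64), counts)
    n = len(parent)
    if umi_length_each_end > 0:
        space = 4 ** (2 * umi_length_each_end)
        umi = rng.integers(0, space, size=n, dtype=np.int64)
    else:
        umi = np.full(n, -1, dtype=np.int64)
    return MoleculeSet(
        pool=pool,
        parent=parent,
        seq_id=parent.copy(),
        umi=umi,
        artifact=np.zeros(n, dtype=np.uint8),
        seqs=list(pool.sequences),
        umi_total_len=2 * umi_length_each_end,
    )


def _first_homopolymer_run(seq: str, min_run: int = 4) -> tuple[int, int] | None:
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            return i, j
        i = j
    return None


def amplify(mols: MoleculeSet, model: BiasModel, rng: np.random.Generator) -> MoleculeSet:
    """Stochastic PCR: each cycle every molecule spawns one copy with
    probability ``e_i = clamp(base + gc_coeff * (GC_i - 0.5), (0, 1])``.

    Copies inherit the parent UMI.  With probability ``stutter_prob`` a copy
    whose sequence contains a homopolymer run of length >= 4 contracts or
    expands that run by one base (fair coin).  Expected copies per molecule
    after ``c`` cycles: ``(1 + e_i) ** c``.
    """
    if model.pcr_cycles == 0:
        return mols
    seqs = list(mols.seqs)
    gc = list(mols.gc_of_seqs)

    def efficiency(sid: np.ndarray) -> np.ndarray:
        g = np.asarray(gc)[sid]
        e = model.pcr_efficiency_base + model.pcr_efficiency_gc_coeff * (g - 0.5)
        return np.clip(e, 1e-12, 1.0)

    parent, seq_id, umi, art = mols.parent, mols.seq_id, mols.umi, mols.artifact
    for _ in range(model.pcr_cycles):
        e = efficiency(seq_id)
        hit = rng.random(len(parent)) < e
        idx = np.nonzero(hit)[0]
        if len(idx) == 0:
            continue
        c_parent = parent[idx]
        c_seq = seq_id[idx].copy()
        c_umi = umi[idx]
        c_art = art[idx].copy()
        if model.stutter_prob > 0.0:
            st = np.nonzero(rng.random(len(idx)) < model.stutter_prob)[0]
            for k in st:
                s = seqs[c_seq[k]]
                run = _first_homopolymer_run(s)
                if run is None:
                    continue
                i0, j0 = run
                if rng.random() < 0.5 and j0 - i0 > 1:
                    new = s[:i0] + s[i0 : j0 - 1] + s[j0:]
                else:
                    new = s[:i0] + s[i0] * (j0 - i0 + 1) + s[j0:]
                seqs.append(new)
                gc.append((new.count("G") + new.count("C")) / len(new))
                c_seq[k] = len(seqs) - 1
        parent = np.concatenate([parent, c_parent])
        seq_id = np.concatenate([seq_id, c_seq])
        umi = np.concatenate([umi, c_umi])
        art = np.concatenate([art, c_art])
    return MoleculeSet(
        pool=mols.pool,
        parent=parent,
        seq_id=seq_id,
        umi=umi,
        artifact=art,
        seqs=seqs,
        umi_total_len=mols.umi_total_len,
    )


def inject_isomir_artifacts(
    mols: MoleculeSet, model: BiasModel, rng: np.random.Generator
) -> MoleculeSet:
    """Apply isomiR-generating chemistry artifacts, independently per molecule.

    3' trim (1-2 nt) and non-templated 3' addition (1-2 nt from {A, T}) can
    occur in any layout; 5' truncation (strand invasion, 1-3 nt) and 5'
    extension (template-switch oligo concatamer, 1-3 G bases) only occur in
    the clontech (template-switch) layout — the rates are ignored elsewhere.
    """
    n = len(mols)
    seqs = list(mols.seqs)
    seq_id = mols.seq_id.copy()
    art = mols.artifact.copy()
    clontech = model.kit_layout == "clontech"
    events = [
        ("trim3", model.trim3_rate, True),
        ("ext3", model.ext3_rate, True),
        ("strand_invasion5", model.strand_invasion5_rate if clontech else 0.0, clontech),
        ("concatamer5", model.concatamer5_rate if clontech else 0.0, clontech),
    ]
    for kind, rate, active in events:
        if not active or rate <= 0.0:
            continue
        hits = np.nonzero(rng.random(n) < rate)[0]
        bit = ARTIFACT_BITS[kind]
        for i in hits:
            s = seqs[seq_id[i]]
            if kind == "trim3":
                k = int(rng.integers(1, 3))
                if len(s) - k < 1:
                    continue
                new = s[:-k]
            elif kind == "ext3":
                k = int(rng.integers(1, 3))
                new = s + "".join(rng.choice(["A", "T"], size=k))
            elif kind == "strand_invasion5":
                k = int(rng.integers(1, 4))
                if len(s) - k < 1:
                    continue
                new = s[k:]
            else:  # concatamer5
                k = int(rng.integers(1, 4))
                new = "G" * k + s
            seqs.append(new)
            seq_id[i] = len(seqs) - 1
            art[i] |= bit
    return MoleculeSet(
        pool=mols.pool,
        parent=mols.parent,
        seq_id=seq_id,
        umi=mols.umi,
        artifact=art,
        seqs=seqs,
        umi_total_len=mols.umi_total_len,
    )


def sequence_reads(
    mols: MoleculeSet,
    model: BiasModel,
    rng: np.random.Generator,
    n_reads: int | None = None,
    read_length: int | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit fixed-length single-end reads through the kit adapter layout.

    nextflex: ``[5' UMI][insert][3' UMI][3' adapter...]``;
    clontech: ``[GGG template-switch bases][insert][poly-A...]``;
    plain:    ``[insert][3' adapter...]``.
    Short constructs read through into the decoration and are padded with
    'A' to ``read_length``; long constructs are truncated.  Per-base
    substitution errors (uniform over the 3 alternatives) apply to the whole
    read, UMI bases included.  Returns the reads and a per-read truth frame.
    """
    L = read_length if read_length is not None else model.read_length
    n = len(mols)
    if n_reads is None:
        idx = np.arange(n)
    else:
        idx = rng.choice(n, size=n_reads, replace=n_reads > n)
    half = mols.umi_total_len // 2
    layout = model.kit_layout
    adapter = model.adapter3
    qual = model.quality_char * L
    err = model.seq_error_rate
    reads: list[tuple[str, str, str]] = []
    truth_rows = {
        "read_id": [],
        "parent_id": [],
        "umi": [],
        "is_artifact": [],
        "artifact_kind": [],
    }
    pool_ids = mols.pool.ids
    for rank, i in enumerate(idx):
        insert = mols.seqs[mols.seq_id[i]]
        if layout == "nextflex":
            u = decode_umi(int(mols.umi[i]), mols.umi_total_len)
            u5, u3 = u[:half], u[half:]
            raw = u5 + insert + u3 + adapter
            umi_str = u
        elif layout == "clontech":
            raw = CLONTECH_TS_BASES + insert + "A" * model.polya_run
            umi_str = ""
        elif layout == "plain":
            raw = insert + adapter
            umi_str = ""
        else:  # pragma: no cover - BiasModel validates the layout
            raise ValueError(f"unknown layout {layout!r}")
        read = (raw + "A" * L)[:L] if len(raw) < L else raw[:L]
        if err > 0.0:
            k = rng.binomial(L, err)
            if k:
                pos = rng.choice(L, size=k, replace=False)
                chars = list(read)
                for p in pos:
                    alts = [b for b in _BASES if b != chars[p]]
                    chars[p] = alts[int(rng.integers(0, 3))]
                read = "".join(chars)
        rid = f"read{rank:08d}"
        reads.append((rid, read, qual))
        truth_rows["read_id"].append(rid)
        truth_rows["parent_id"].append(pool_ids[mols.parent[i]])
        truth_rows["umi"].append(umi_str)
        truth_rows["is_artifact"].append(bool(mols.artifact[i]))
        truth_rows["artifact_kind"].append(artifact_kind_name(int(mols.artifact[i])))
    return reads, pd.DataFrame(truth_rows)


def _truth_from(
    pool: ReferencePool, pre_pcr: MoleculeSet, read_truth: pd.DataFrame
) -> TruthTable:
    counts = np.bincount(pre_pcr.parent, minlength=len(pool))
    true_molecules = pd.Series(counts, index=pd.Index(pool.ids, name="reference_id"))
    half = pre_pcr.umi_total_len
    molecules = pd.DataFrame(
        {
            "parent_id": [pool.ids[p] for p in pre_pcr.parent],
            "umi": [
                decode_umi(int(u), half) if u >= 0 else "" for u in pre_pcr.umi
            ],
            "is_artifact": pre_pcr.artifact.astype(bool),
            "artifact_kind": [artifact_kind_name(int(a)) for a in pre_pcr.artifact],
        }
    )
    ledger = (
        molecules[molecules["is_artifact"]]
        .groupby(["parent_id", "artifact_kind"])
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"artifact_kind": "kind"})
    )
    return TruthTable(
        true_molecules=true_molecules,
        molecules=molecules,
        reads=read_truth,
        artifact_counts=ledger,
    )


def simulate_library(
    pool: ReferencePool,
    model: BiasModel,
    total_molecules: int,
    seed: int,
    n_reads: int | None = None,
    fold_energies: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Run the full simulator: sample → inject artifacts → amplify → sequence.

    Returns FASTQ-ready read tuples ``(id, sequence, quality)`` and the
    :class:`TruthTable`.  Byte-identical outputs for identical inputs and
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    weights = total_bias_weights(pool, model, fold_energies)
    mols = sample_molecules(pool, weights, total_molecules, model.umi_length_each_end, rng)
    pre_pcr = inject_isomir_artifacts(mols, model, rng)
    amplified = amplify(pre_pcr, model, rng)
    reads, read_truth = sequence_reads(amplified, model, rng, n_reads=n_reads)
    return reads, _truth_from(pool, pre_pcr, read_truth)


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    """Write 4-line FASTQ records (``.gz`` suffix → gzip)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ into ``(id, sequence, quality)`` tuples."""
    import gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]
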