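# srnabench

Small RNA sequencing quantifies miRNAs by ligating adapters to short RNA
inserts, reverse-transcribing, amplifying and sequencing them — and every
one of those steps distorts the result. Adapter-ligation preferences,
reverse-transcription structure bias, GC-dependent PCR efficiency, PCR
stutter and chemistry-specific artifacts (template-switch strand invasion
and oligo concatamers) skew abundance estimates and create *false isomiRs*:
apparent sequence variants of a miRNA that were never in the sample.

`srnabench` is a benchmarking toolkit for these effects, aimed at people
developing or evaluating small RNA-seq protocols and pipelines. It
provides:

* a **ground-truth simulator** of equimolar (or skewed) synthetic miRNA
  pools read through kit-specific adapter layouts (degenerate-adapter/UMI,
  template-switch + poly-A, plain ligation), with configurable bias and
  artifact models and a complete truth table;
* **kit-aware preprocessing** (exact adapter trimming, UMI extraction into
  the read id, minimum-length filtering at 16 nt for synthetic pools /
  18 nt for biological libraries);
* **isomiR-aware quantification** under an explicit, deterministic
  assignment policy;
* **directional UMI deduplication** (collapse UMIs differing at one base
  when `count(a) >= 2*count(b) - 1`), plus the random 5% subsample control;
* **median-of-ratios normalization** and the benchmarking metric suite:
  equimolar accuracy error `log2(|x_i - mean(x)| + 1)`, detection at strict
  thresholds (>10 normalized reads for miRNAs, >100 for isomiRs), the
  detection-inconsistency percentage `(U_X - U_123)/U_X * 100`, false-isomiR
  tallies, MA statistics and top-20 overlap, batch and triplicate error, and
  starting-molecule estimation `N0 = reads/(1+e)^c` against the 65,536-label
  UMI space;
* **type-II sum-of-squares variance decomposition** of any per-sequence
  response over sequence characteristics (GC content, length, fold energy,
  terminal dinucleotides, base counts, repeat flags).

Because every read in a simulated library has known provenance (parent
sequence, UMI, artifact status), recovery can be checked exactly: e.g. under
error-free GC-biased PCR at 62.5% base efficiency and 18 cycles, directional
deduplication returns precisely the distinct pre-amplification UMIs.

## Worked example

Simulate a 100-sequence equimolar pool through a degenerate-adapter (UMI)
library with strong GC-dependent amplification bias, then compare raw
versus UMI-deduplicated quantification:

```python
import numpy as np
from srnabench import (
    BiasModel, Quantifier, build_count_matrix, build_reference_pool,
    dedup_counts, group_reads_by_reference, normalize_counts,
    accuracy_error, simulate_library, trim_reads, TrimConfig,
)

pool = build_reference_pool(n=100, length_range=(16, 28), gc_range=(0.2, 0.8), seed=7)
model = BiasModel(
    kit_layout="nextflex",
    pcr_efficiency_base=0.625,   # conservative per-cycle duplication probability
    pcr_efficiency_gc_coeff=0.5, # GC-dependent amplification bias
    pcr_cycles=5,
)
reads, truth = simulate_library(pool, model, total_molecules=10_000, seed=1)
kept, tally = trim_reads(reads, TrimConfig(layout="nextflex", min_length=16))
q = Quantifier(pool)
assigned = [(rid, q.assign_read(ins)[0]) for rid, ins in kept]
raw = {}
for _rid, ref in assigned:
    raw[ref] = raw.get(ref, 0) + 1
deduped = dedup_counts(group_reads_by_reference(assigned))
cm = build_count_matrix({"raw": (raw, {}, 0), "dedup": (dict(deduped), {}, 0)}, pool)
norm = normalize_counts(cm.canonical)
print(f"mean accuracy error  raw: {accuracy_error(norm['raw']).mean():.3f}")
print(f"mean accuracy error dedup: {accuracy_error(norm['dedup']).mean():.3f}")
```

Output:

```
simulated 113525 reads from 10000 molecules
retained 113525 inserts after trimming
raw reads per reference (mean): 1135.2
deduplicated counts (sum): 9930 vs true molecules: 10000
mean accuracy error  raw: 5.276
mean accuracy error dedup: 4.286
```

The 10,000 molecules amplified to ~113k reads; deduplication recovers 9,930
of the 10,000 starting molecules (the shortfall is UMI label collisions),
and the mean equimolar accuracy error — the log2 absolute deviation of each
sequence's normalized count from the pool mean — drops by about one log2
unit once the GC-driven amplification bias is collapsed away.

A full multi-kit comparison (four kit profiles, each in triplicate, plus
derived `deduped` and `fivepercent` samples) runs from the command line:

```
srnabench run --out bench_out --seed 1
```

which writes count matrices, normalized counts, metric reports and a
checksum manifest under `bench_out/`.

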