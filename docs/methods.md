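# Methods

## The simulation model

The simulator follows the physical order of small RNA library preparation.
A *reference pool* is a set of unique 16-30 nt sequences with molar
fractions (default: 962 unique random sequences, 16-28 nt, GC 0.2-0.8,
equimolar — the shape of a commercial universal-reference pool). The
library is then built in four stages, each seeded from one generator so a
configuration plus a seed reproduces the FASTQ byte-for-byte.

**1. Molecule sampling (ligation/RT selection).** Pre-amplification
molecule counts are a single multinomial draw over
`fraction_i * w_i` with selection weight

```
w_i = exp( lig5[first2_i] + lig3[last2_i] + b_struct * FoldG_i + sum_b c_b * n_b(i) )
```

— terminal-dinucleotide ligation log-weights, a structure term on the fold
free energy (kcal/mol) and per-base composition terms. A separate
reverse-transcription tilt `exp(b_rt * FoldG_i)` multiplies onto `w_i`
(kept out of the ligation formula so the two mechanisms remain individually
switchable). With all coefficients zero every weight is exactly 1 and the
library is multinomial-equimolar. Fold energies are supplied per id or
default to a Nussinov maximum-base-pairing proxy (−1.0 per nested pair,
minimum loop 3, GU wobble allowed), always flagged `proxy`; it preserves
the *ordering* of structuredness but is not a thermodynamic MFE.

No quantitative per-dinucleotide ligation bias magnitudes are established
for these chemistries; the kit profiles ship illustrative log-weights with
|log w| ≤ 0.2 for the randomized-adapter kit and ≤ 0.8 for plain-ligation
kits. They reproduce the qualitative ranking of the chemistries, nothing
more.

**2. UMI tagging.** Degenerate-adapter chemistry attaches 4 random bases on
each adapter end *before* reverse transcription and PCR, so UMIs are
assigned at molecule sampling — uniform over the 4^8 = 65,536 labels — and
every PCR copy inherits its parent's UMI exactly. UMI errors therefore
arise only from sequencing error. Template-switch and plain layouts carry
no UMI (enforced by the model).

**3. Amplification.** Each PCR cycle, every molecule spawns one copy with
probability `e_i = clamp(e_base + e_gc * (GC_i - 0.5), (0, 1])`; expected
copies after `c` cycles are `(1+e_i)^c`. GC content is the carrier of
amplification bias, the mechanism classically implicated for it. The
default base efficiency is the conservative 62.5% used for starting-molecule
estimation; kit profiles use protocol cycle counts (7/11/15/18 for the
template-switch, plain-ligation x2 and degenerate-adapter kits on a
synthetic pool). With probability `stutter_prob`, a copy whose sequence
contains a homopolymer run of ≥ 4 bases contracts or expands the *first*
such run by one base (fair coin) — the simplest testable reading of PCR
stutter on low-complexity sequence.

**4. Artifacts and sequencing.** Before amplification, four isomiR-creating
artifact channels act independently per molecule: 3' trim (1-2 nt), 3'
non-templated addition (1-2 nt of A/T), and — only in the template-switch
layout — 5' truncation by strand invasion (1-3 nt) and 5' extension by
template-switch-oligo concatamers (1-3 G). Reads are fixed-length (default
51 nt) through the layout: `[UMI4][insert][UMI4][adapter...]`,
`[GGG][insert][polyA...]` or `[insert][adapter...]`, padded with A on
read-through and subject to uniform per-base substitution error over the
whole read, UMI bases included. Qualities are a constant character
(default 'I'); no quality model is simulated because no downstream metric
uses qualities.

### What the generator does and does not emulate

It emulates: composition-dependent selection, GC-dependent amplification,
UMI-faithful duplication, kit-specific read anatomy, isomiR artifact
channels, stutter, substitution error. It does **not** emulate: indels in
sequencing, quality-score structure, non-miRNA biological RNA classes,
cross-contamination, synthesis errors in the pool itself, or adapter-dimer
reads. Passing tests therefore demonstrate correctness of the *pipeline
machinery and metric definitions* under controlled bias, not that any real
kit has a particular bias magnitude.

## Preprocessing

Adapter matching is exact: the leftmost full-adapter occurrence, else the
longest adapter *prefix* (≥ 5 nt) flush with the read's 3' end. Exactness
keeps the stage deterministic; error-tolerant matching is deliberately out
of scope. UMI extraction takes the first and last 4 bases of the trimmed
read (UMI = first4+last4, appended to the read id as `_<UMI>`; reads with
non-ACGT UMI bases are dropped). The template-switch rule drops the first
3 bases and truncates at the first run of ≥ 10 A — applied literally, so a
genuine internal 10-A run also truncates, a known failure mode of that
chemistry's informatics that is kept intentionally. Minimum insert length
is 16 nt (synthetic-pool mode; the shortest pool sequence) or 18 nt
(biological mode).

## Quantification

An insert equal to a reference is canonical. Otherwise the insert is
assigned to the reference minimizing `|5' shift| + 3' offset + internal
mismatches + non-templated 3' additions` within bounds (defaults 4/4/2/3;
the aligned overlap must be ≥ 10 nt), ties broken by cost then
lexicographic reference id. isomiRs are keyed by their full insert
sequence. The policy is an explicit, configurable stand-in for aligner
heuristics whose exact rules are not published; a brute-force enumeration
oracle checks it property-wise in the tests.

## Deduplication

Grouping is per assigned reference (isomiRs group with their parent), so an
isomiR sharing a UMI with its reference collapses with it. Clustering is
the directional method: edge a→b iff Hamming distance 1 and
`count(a) ≥ 2*count(b) − 1`; clusters grow by BFS from count-sorted seeds
(ties lexicographic); the deduplicated count is the cluster count, and a
cluster's representative is its seed. Both the Hamming radius and the
count threshold are exposed in code. Per-reference grouping (rather than
genomic position after liberal alignment) is adopted and stated as a
design choice.

## Normalization and metrics

Size factors are median-of-ratios: features with any zero are excluded from
the per-feature geometric means; `factor_j = median_i raw[i,j]/geomean_i`.
Note the exact invariance: multiplying one sample by *k* multiplies its
factor *relative to the others* by *k* (each factor also absorbs a common
`k^(1/m)` from the geometric means), and the normalized matrix changes only
by that global constant.

All error metrics use a +1 pseudocount inside the log: `log2(|Δ| + 1)`.
This maps a zero difference to exactly zero error and is monotone in |Δ|;
it is a deliberate regularization of a definition that is otherwise
undefined at Δ = 0. Detection thresholds are strict inequalities: > 1
(similarity filter), > 10 (miRNA detection), > 100 (isomiR detection).
The inconsistency of replicate X is `(U_X − U_123)/U_X × 100`, undefined
(NaN) when U_X = 0. Top-N overlap ranks by decreasing mean with
lexicographic tie-break at rank N. Starting molecules are estimated as
`N0 = reads/(1+e)^c` — the natural inversion of expected PCR growth under
an assumed efficiency — flagged "saturating" when N0 exceeds 20% of the
65,536-label UMI space.

## Variance decomposition

Per-sequence characteristics: GC content, length, fold energy (input or
proxy), first/last dinucleotide (16-level categoricals, treatment-coded
against the lexicographically first level), base counts, and two repeat
flags (any adjacent duplet; any homopolymer quadruplet — two flags rather
than one combined factor). Type-II sums of squares are computed as
`SS_f = RSS(model without f) − RSS(full model)` under ordinary least
squares; shares are `SS_f/SS_total × 100` plus a residual share. In
orthogonal designs shares + residual sum to 100 and equal sequential
shares; in non-orthogonal designs negative components are floored at 0
with a warning. The method-weighted view multiplies each method's shares
by `var(method)/max_m var(m)` — an interpretation of "weighted by overall
variance" chosen so equal-variance methods are unchanged and the weighting
is scale-free. Note that in realistic pools the duplet flag is almost
always constant (nearly every 16-28 nt sequence has an adjacent repeat);
the pipeline drops single-level or aliased factors before decomposing.

## Problem sizes in tests and the acceptance script

All empirical checks run on synthetic data generated at call time; sizes
were chosen so each check sits in the statistical regime it is about:

* Pool recovery uses the default 962-sequence pool at 120x mean coverage —
  deep enough that the probability of missing any reference under a
  multinomial is negligible (≈ 962·e^−120).
* The UMI-recovery check uses 120 molecules over 12 references at 62.5%
  efficiency and 18 cycles. Exact equality between directional cluster
  counts and distinct pre-PCR UMIs requires that no two molecules of one
  reference carry Hamming-1 UMIs (family-size ratios at this efficiency
  have CV ≈ 0.48, enough to trigger merges); the expected number of such
  pairs, `R·C(m,2)·24/65536 ≈ 0.2` at ~10 molecules/reference, makes the
  no-merge regime near-certain while staying well under UMI saturation.
* The dedup direction check (accuracy error and count variance, raw vs
  deduplicated) uses 100 molecules/reference, 5 cycles and a GC-efficiency
  coefficient of 0.5. At desk-scale depth the collapse removes
  amplification bias but *adds* molecule-sampling noise (CV ≈ 1/√m), so
  the comparison is only informative where bias dominates noise; these
  sizes put it firmly in that regime, which is also the regime of real
  libraries (thousands of molecules per miRNA).
* The false-isomiR direction check runs at 3,000 reads/reference so that
  template-switch 5' artifact classes clear the strict >100
  normalized-read detection threshold; the artifact rates (12% strand
  invasion, 6% concatamer, 1% 3' trim) are illustrative magnitudes.
* Direction checks run over 20 seeds and require ≥ 19/20 agreement.

## Known limitations

* The Nussinov proxy is not an MFE; supply real fold energies for any
  analysis where absolute energies matter.
* Exact-match trimming will miss adapters containing sequencing errors;
  at the simulator's default error rates this loss is small but nonzero.
* The assignment policy is a declared model, not a reimplementation of any
  particular aligner's (unpublished) isomiR rules.
* Kit profiles are qualitative: they rank chemistries as expected but
  their coefficients are not fitted to data.
* The batch model (seed + depth jitter) emulates run-to-run variation
  only; it has no reagent-lot or operator structure.
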