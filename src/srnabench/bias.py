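"""Bias models for small RNA-seq library preparation.

Library preparation distorts an equimolar pool through several mechanisms:

* **Adapter ligation bias** — the efficiency of joining adapters to an
  insert depends on the insert's terminal dinucleotides, its secondary
  structure (fold free energy) and base composition.  Randomised-adapter
  chemistries dilute this effect; ligation-free (template-switch) chemistry
  avoids it.
* **Reverse-transcription bias** — structured templates reverse-transcribe
  less efficiently.
* **PCR amplification bias** — per-cycle duplication efficiency varies with
  GC content, and low-complexity runs may stutter (contract/expand) during
  copying.
* **Kit-specific artifacts** — template-switch chemistry can produce
  5'-truncated inserts (strand invasion) and 5'-extended inserts
  (template-switch oligo concatamers); any chemistry can produce 3' trims
  and non-templated 3' additions.

A :class:`BiasModel` bundles the knobs for all of these; the neutral default
(all coefficients zero) reproduces an unbiased equimolar library.  The
per-dinucleotide ligation log-weights shipped with the kit profiles are
illustrative order-of-magnitude choices (|log-weight| <= 1), not fitted
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pool import ReferencePool

KIT_LAYOUTS = ("nextflex", "clontech", "plain")

#: Standard small-RNA 3' sequencing adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_BASES = "ACGT"


@dataclass
class BiasModel:
    """Configuration of every bias/artifact mechanism in the simulator.

    All log-weights default to zero and all rates to zero: the default
    model is perfectly neutral.  ``pcr_efficiency_base`` defaults to the
    conservative 62.5% per-cycle duplication probability used for
    starting-molecule estimation; ``pcr_cycles`` defaults to 0 (no
    amplification) so that neutrality also means "no PCR".
    """

    kit_layout: str = "nextflex"
    lig5_weights: dict[str, float] = field(default_factory=dict)
    lig3_weights: dict[str, float] = field(default_factory=dict)
    struct_coeff: float = 0.0  # per kcal/mol on fold free energy
    base_count_coeffs: dict[str, float] = field(default_factory=dict)
    rt_struct_coeff: float = 0.0
    pcr_efficiency_base: float = 0.625
    pcr_efficiency_gc_coeff: float = 0.0
    pcr_cycles: int = 0
    stutter_prob: float = 0.0
    trim3_rate: float = 0.0
    ext3_rate: float = 0.0
    strand_invasion5_rate: float = 0.0
    concatamer5_rate: float = 0.0
    seq_error_rate: float = 0.0
    adapter3: str = DEFAULT_ADAPTER3
    umi_length_each_end: int = 4
    read_length: int = 51
    polya_run: int = 15  # clontech poly-A tail emitted after the insert
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.kit_layout not in KIT_LAYOUTS:
            raise ValueError(f"unknown kit layout {self.kit_layout!r}; expected one of {KIT_LAYOUTS}")
        for name in ("stutter_prob", "trim3_rate", "ext3_rate",
                     "strand_invasion5_rate", "concatamer5_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.pcr_efficiency_base <= 1.0:
            raise ValueError("pcr_efficiency_base must be in (0, 1]")
        # GC runs over [0,1] so the adjustment magnitude is |coeff|/2 at the extremes
        hi = self.pcr_efficiency_base + abs(self.pcr_efficiency_gc_coeff) * 0.5
        if hi > 1.0:
            raise ValueError(
                "pcr_efficiency_base plus the maximal GC adjustment exceeds 1; "
                "reduce pcr_efficiency_gc_coeff"
            )
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be nonnegative")
        # UMI tagging is a property of the chemistry: degenerate-adapter
        # layouts carry UMIs, template-switch and plain ligation do not.
        if self.kit_layout == "nextflex":
            if self.umi_length_each_end <= 0:
                raise ValueError("nextflex layout requires UMI tagging (umi_length_each_end > 0)")
        else:
            self.umi_length_each_end = 0

    @property
    def umi_space(self) -> int:
        """Number of distinct UMI labels (4^(2*per-end length))."""
        return 4 ** (2 * self.umi_length_each_end)

    def with_(self, **kwargs) -> "BiasModel":
        return replace(self, **kwargs)


def nussinov_energy(seq: str, min_loop: int = 3, pair_energy: float = -1.0) -> float:
    """Maximum-base-pairing fold energy proxy (Nussinov dynamic program).

    Returns ``pair_energy`` times the maximum number of nested Watson-Crick
    (+ GU wobble) pairs with a minimum hairpin loop of ``min_loop`` bases.
    This is a structure *proxy*, not a thermodynamic minimum free energy;
    supply measured energies where available.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            b = best[i + 1][j - 1] + 1 if (s[i], s[j]) in pairs else 0
            b = max(b, best[i + 1][j], best[i][j - 1])
            for k in range(i + 1, j):
                b = max(b, best[i][k] + best[k + 1][j])
            best[i][j] = b
    return pair_energy * best[0][n - 1] if n else 0.0


def proxy_fold_energies(pool: ReferencePool) -> dict[str, float]:
    """Nussinov proxy energies for every pool sequence (flagged 'proxy')."""
    return {i: nussinov_energy(s) for i, s in zip(pool.ids, pool.sequences)}


def selection_weights(
    pool: ReferencePool,
    model: BiasModel,
    fold_energies: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-reference ligation/structure selection weight.

    ``w_i = exp(lig5[first2_i] + lig3[last2_i] + struct_coeff * FoldG_i
    + sum_b coeff_b * count_b(i))``.  With all coefficients zero every
    weight is exactly 1.  ``fold_energies`` must cover every pool id when
    ``struct_coeff`` is nonzero; omit it to use the Nussinov proxy.
    """
    if model.struct_coeff != 0.0 or model.rt_struct_coeff != 0.0:
        if fold_energies is None:
            fold_energies = proxy_fold_energies(pool)
        missing = [i for i in pool.ids if i not in fold_energies]
        if missing:
            raise KeyError(f"fold energies missing for ids: {missing}")
    log_w = np.zeros(len(pool))
    for k, (rid, seq) in enumerate(zip(pool.ids, pool.sequences)):
        lw = model.lig5_weights.get(seq[:2], 0.0) + model.lig3_weights.get(seq[-2:], 0.0)
        if model.struct_coeff != 0.0:
            lw += model.struct_coeff * fold_energies[rid]
        for b, c in model.base_count_coeffs.items():
            lw += c * seq.count(b)
        log_w[k] = lw
    w = np.exp(log_w)
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("selection weights must be finite and positive")
    return w


def total_bias_weights(
    pool: ReferencePool,
    model: BiasModel,
    fold_energies: dict[str, float] | None = None,
) -> np.ndarray:
    """Ligation weights combined with the reverse-transcription structure tilt.

    The RT step is modelled as a second exponential tilt on fold energy,
    ``exp(rt_struct_coeff * FoldG_i)``, multiplied onto the ligation-stage
    selection weights.
    """
    w = selection_weights(pool, model, fold_energies)
    if model.rt_struct_coeff != 0.0:
        if fold_energies is None:
            fold_energies = proxy_fold_energies(pool)
        fg = np.array([fold_energies[i] for i in pool.ids])
        w = w * np.exp(model.rt_struct_coeff * fg)
    return w


def _illustrative_dinuc_weights(scale: float, seed: int) -> dict[str, float]:
    # reproducible illustrative ligation preferences, |log-weight| <= scale
    rng = np.random.default_rng(seed)
    dinucs = [a + b for a in _BASES for b in _BASES]
    return {d: float(w) for d, w in zip(dinucs, rng.uniform(-scale, scale, 16))}


def kit_profile(name: str, **overrides) -> BiasModel:
    """Illustrative simulator parameterisation for a named kit style.

    Profiles reflect the qualitative behaviour of the four chemistry
    families benchmarked on equimolar synthetic pools: plain-ligation kits
    (``illumina_like``, ``neb_like``) carry strong terminal-dinucleotide
    ligation bias; the randomised-adapter kit (``nextflex``) carries a
    diluted version plus UMIs; the template-switch kit (``clontech``) has no
    ligation bias but RT structure bias and 5' strand-invasion/concatamer
    artifacts.  PCR cycle counts follow the synthetic-pool protocol values
    (Clontech 7, Illumina 11, NEB 15, NEXTflex 18).  The magnitudes are
    illustrative, not fitted.
    """
    profiles = {
        "nextflex": dict(
            kit_layout="nextflex",
            lig5_weights=_illustrative_dinuc_weights(0.2, 11),
            lig3_weights=_illustrative_dinuc_weights(0.2, 12),
            pcr_cycles=18,
            pcr_efficiency_gc_coeff=0.15,
            trim3_rate=0.01,
            ext3_rate=0.005,
        ),
        "clontech": dict(
            kit_layout="clontech",
            rt_struct_coeff=0.05,
            pcr_cycles=7,
            pcr_efficiency_gc_coeff=0.15,
            trim3_rate=0.01,
            ext3_rate=0.005,
            strand_invasion5_rate=0.04,
            concatamer5_rate=0.02,
        ),
        "illumina_like": dict(
            kit_layout="plain",
            lig5_weights=_illustrative_dinuc_weights(0.8, 21),
            lig3_weights=_illustrative_dinuc_weights(0.8, 22),
            struct_coeff=0.05,
            pcr_cycles=11,
            pcr_efficiency_gc_coeff=0.15,
            trim3_rate=0.015,
            ext3_rate=0.01,
        ),
        "neb_like": dict(
            kit_layout="plain",
            lig5_weights=_illustrative_dinuc_weights(0.7, 31),
            lig3_weights=_illustrative_dinuc_weights(0.7, 32),
            struct_coeff=0.04,
            pcr_cycles=15,
            pcr_efficiency_gc_coeff=0.15,
            trim3_rate=0.02,
            ext3_rate=0.015,
        ),
    }
    key = name.replace("-", "_")
    if key not in profiles:
        raise KeyError(f"unknown kit profile {name!r}; expected one of {sorted(profiles)}")
    cfg = dict(profiles[key])
    cfg.update(overrides)
    return BiasModel(**cfg)
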