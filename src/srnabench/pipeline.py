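"""End-to-end benchmarking pipeline: simulate → trim → quantify → dedup →
normalize → metrics → variance, driven by a flat YAML config.

The pipeline emulates a multi-kit benchmarking study on one equimolar
synthetic pool: each *sample* in the design is a simulator parameterisation
(kit profile + replicate seed), with optional derived samples — ``deduped``
(UMI-collapsed counts of a nextflex parent) and ``fivepercent`` (a random
5% read subset of the same parent, the control separating the effect of
collapsing from the effect of depth).  Batches are emulated as distinct
seed offsets plus a small multiplicative depth jitter.  Outputs are
FASTA/FASTQ/TSV/JSON with a checksum manifest; reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .bias import kit_profile
from .dedup import dedup_counts, group_reads_by_reference, subsample_reads
from .pool import build_reference_pool
from .preprocess import TrimConfig, trim_reads
from .quantify import Quantifier, build_count_matrix, quantify_sample
from .simulate import simulate_library, write_fastq
from .variance import feature_table, percent_variance, weighted_percent_variance

KIT_METHODS = ("clontech", "illumina_like", "neb_like", "nextflex")
DERIVED_METHODS = ("deduped", "fivepercent")

#: Desk-scale PCR cycle counts per kit (full-protocol values are
#: clontech 7 / illumina 11 / neb 15 / nextflex 18).
DEMO_CYCLES = {"clontech": 3, "illumina_like": 4, "neb_like": 5, "nextflex": 6}


@dataclass
class SampleSpec:
    name: str
    method: str
    input_ng: float = 300.0
    batch: int = 1
    replicate: int = 1
    parent: str | None = None  # required for deduped / fivepercent


@dataclass
class PipelineConfig:
    seed: int = 1
    n_references: int = 60
    length_range: tuple[int, int] = (16, 28)
    gc_range: tuple[float, float] = (0.2, 0.8)
    pool_seed: int = 7
    total_molecules: int = 3000
    n_reads: int = 20000
    fivepercent_fraction: float = 0.05
    batch_depth_jitter: float = 0.05
    pcr_cycles: dict = field(default_factory=lambda: dict(DEMO_CYCLES))
    design: list[SampleSpec] = field(default_factory=list)
    write_fastq: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        design = [SampleSpec(**s) for s in raw.pop("design", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "design"}, design=design)
        cfg.length_range = tuple(cfg.length_range)
        cfg.gc_range = tuple(cfg.gc_range)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["length_range"] = list(self.length_range)
        raw["gc_range"] = list(self.gc_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violated invariant (empty list = valid)."""
    errors = []
    names = [s.name for s in config.design]
    if len(set(names)) != len(names):
        errors.append("duplicate sample names in design")
    by_name = {s.name: s for s in config.design}
    for s in config.design:
        if s.method not in KIT_METHODS + DERIVED_METHODS:
            errors.append(f"sample {s.name}: unknown method {s.method!r}")
        if s.method in DERIVED_METHODS:
            parent = by_name.get(s.parent)
            if parent is None or parent.method != "nextflex":
                errors.append(
                    f"sample {s.name}: method {s.method!r} requires a nextflex parent sample"
                )
    if config.n_reads < 1:
        errors.append("n_reads must be positive")
    if config.total_molecules < 1:
        errors.append("total_molecules must be positive")
    if not 0 < config.fivepercent_fraction <= 1:
        errors.append("fivepercent_fraction must be in (0, 1]")
    lo, hi = config.length_range
    if not (16 <= lo <= hi <= 30):
        errors.append(f"length_range {config.length_range} outside [16, 30]")
    return errors


def demo_config(seed: int = 1) -> PipelineConfig:
    """The bundled demo: 6 emulated methods x 3 replicates on one pool."""
    design = []
    for method in KIT_METHODS:
        for rep in (1, 2, 3):
            design.append(SampleSpec(name=f"{method}-r{rep}", method=method, replicate=rep))
    for rep in (1, 2, 3):
        design.append(
            SampleSpec(name=f"deduped-r{rep}", method="deduped", parent=f"nextflex-r{rep}", replicate=rep)
        )
        design.append(
            SampleSpec(name=f"fivepercent-r{rep}", method="fivepercent", parent=f"nextflex-r{rep}", replicate=rep)
        )
    return PipelineConfig(seed=seed, design=design)


def _sample_seed(config: PipelineConfig, idx: int) -> int:
    return int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline; returns the in-memory report bundle.

    Writes the reference FASTA, per-sample counts, normalized counts, the
    metric report TSV/JSON files and a checksum manifest under ``outdir``.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    pool = build_reference_pool(
        config.n_references, config.length_range, config.gc_range, config.pool_seed
    )
    pool.to_fasta(out / "pool.fasta")
    quantifier = Quantifier(pool)

    kit_samples = [s for s in config.design if s.method in KIT_METHODS]
    derived = [s for s in config.design if s.method in DERIVED_METHODS]

    per_sample: dict[str, tuple] = {}
    meta_rows: dict[str, dict] = {}
    trimmed_store: dict[str, list] = {}
    assigned_store: dict[str, list] = {}
    for idx, spec in enumerate(kit_samples):
        seed = _sample_seed(config, idx)
        model = kit_profile(spec.method, pcr_cycles=config.pcr_cycles[spec.method])
        jitter_rng = np.random.default_rng([config.seed, 9999, spec.batch])
        depth = int(round(
            config.n_reads * float(np.exp(jitter_rng.normal(0.0, config.batch_depth_jitter)))
        ))
        reads, truth = simulate_library(
            pool, model, config.total_molecules, seed=seed, n_reads=depth
        )
        if config.write_fastq:
            write_fastq(reads, out / f"{spec.name}.fastq")
        trimmed, _tally = trim_reads(reads, TrimConfig(layout=model.kit_layout))
        trimmed_store[spec.name] = trimmed
        per_sample[spec.name] = quantify_sample(trimmed, quantifier)
        meta_rows[spec.name] = dict(
            method=spec.method, input_ng=spec.input_ng, batch=spec.batch, replicate=spec.replicate
        )
        if any(d.parent == spec.name for d in derived):
            assigned = []
            for rid, ins in trimmed:
                res = quantifier.assign_read(ins)
                if res is not None:
                    assigned.append((rid, res[0]))
            assigned_store[spec.name] = assigned

    for didx, spec in enumerate(derived):
        if spec.method == "deduped":
            groups = group_reads_by_reference(assigned_store[spec.parent])
            counts = dedup_counts(groups)
            from collections import Counter

            per_sample[spec.name] = (Counter(counts.to_dict()), Counter(), 0)
        else:  # fivepercent
            sub = subsample_reads(
                trimmed_store[spec.parent], config.fivepercent_fraction,
                seed=_sample_seed(config, 10000 + didx),
            )
            per_sample[spec.name] = quantify_sample(sub, quantifier)
        meta_rows[spec.name] = dict(
            method=spec.method, input_ng=spec.input_ng,
            batch=next(s.batch for s in kit_samples if s.name == spec.parent),
            replicate=spec.replicate,
        )

    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    metadata.index.name = "sample"
    cm = build_count_matrix(per_sample, pool, metadata)
    cm.canonical.to_csv(out / "counts_canonical.tsv", sep="\t")
    cm.isomirs.to_csv(out / "counts_isomir.tsv", sep="\t")

    factors = M.size_factors(cm.canonical)
    norm = M.normalize_counts(cm.canonical, factors)
    norm.to_csv(out / "counts_normalized.tsv", sep="\t")
    iso_norm = cm.isomirs.astype(float).div(factors, axis=1) if len(cm.isomirs) else cm.isomirs

    methods = metadata["method"].unique()
    report: dict = {"size_factors": factors.to_dict()}

    acc_rows, trip_rows, inconsistency_rows, falseiso_rows = {}, {}, {}, {}
    method_means = {}
    for method in methods:
        cols = metadata.index[metadata["method"] == method].tolist()
        mean_norm = norm[cols].mean(axis=1)
        method_means[method] = mean_norm
        acc = M.accuracy_error(mean_norm)
        acc_rows[method] = float(acc.mean())
        if len(cols) >= 2:
            trip = M.triplicate_error(norm[cols])
            trip_rows[method] = float(trip.mean())
            ds = M.detect(norm, M.MIRNA_DETECTION_THRESHOLD, cols)
            inconsistency_rows[method] = M.detection_inconsistency(ds).mean()
        if len(iso_norm):
            fi = M.false_isomirs(iso_norm, replicates=cols)
            falseiso_rows[method] = fi["total_unique"]
    report["mean_accuracy_error"] = acc_rows
    report["mean_triplicate_error"] = trip_rows
    report["mean_detection_inconsistency_pct"] = {
        k: float(v) for k, v in inconsistency_rows.items()
    }
    report["false_isomirs_total"] = falseiso_rows
    overlap = M.topn_overlap(method_means, n=min(20, len(pool)))
    report["top20_overlap_global"] = overlap["global"]
    overlap["pairwise"].to_csv(out / "top20_overlap.tsv", sep="\t")

    # sequence-feature variance decomposition of per-method accuracy error;
    # degenerate factors (single observed level, aliased) are dropped so
    # small pools still decompose over the informative features
    ftab = feature_table(pool)
    fac_cols = [
        c for c in ["gc_content", "length", "fold_g", "first2", "last2",
                    "nA", "nC", "nG", "has_duplet", "has_quadruplet"]
        if ftab[c].nunique() > 1
    ]
    decomps, variances = {}, {}
    for method in methods:
        resp = np.log2(method_means[method] + 1.0)
        cols = list(fac_cols)
        while cols:
            try:
                decomps[method] = percent_variance(resp, ftab[cols], warn_negative=False)
                break
            except ValueError as exc:
                msg = str(exc)
                dropped = [c for c in cols if c in msg]
                if not dropped:
                    break
                cols = [c for c in cols if c not in dropped]
        if method in decomps:
            variances[method] = float(np.var(method_means[method].to_numpy(), ddof=1))
    if decomps:
        dec_df = pd.DataFrame(decomps)
        dec_df.to_csv(out / "variance_decomposition.tsv", sep="\t")
        weighted_percent_variance(decomps, variances).to_csv(
            out / "variance_decomposition_weighted.tsv", sep="\t"
        )

    with open(out / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)

    manifest = {
        "seed": config.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "pool": pool,
        "count_matrix": cm,
        "normalized": norm,
        "report": report,
        "manifest": manifest,
    }
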