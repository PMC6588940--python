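import numpy as np
import pytest
from scipy import stats

from srnabench.bias import BiasModel
from srnabench.pool import ReferencePool, build_reference_pool
from srnabench.simulate import (
    MoleculeSet,
    amplify,
    decode_umi,
    encode_umi,
    inject_isomir_artifacts,
    sample_molecules,
    sequence_reads,
    simulate_library,
)


def _single_seq_pool(seq="ACGTACGTACGTACGTACGT"):
    return ReferencePool(["m1"], [seq], np.array([1.0]))


def test_umi_codec_round_trip(rng):
    for _ in range(50):
        code = int(rng.integers(0, 4**8))
        assert encode_umi(decode_umi(code, 8)) == code


def test_sample_molecules_single_molecule(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 1, 4, rng)
    assert len(mols) == 1
    assert 0 <= mols.umi[0] < 65536


def test_equimolar_sampling_within_binomial_noise(rng):
    # 10^6 molecules over 100 equimolar refs: each count within 5 SD of 10,000
    pool = build_reference_pool(100, (16, 28), (0.2, 0.8), seed=3)
    mols = sample_molecules(pool, np.ones(100), 10**6, 0, rng)
    counts = np.bincount(mols.parent, minlength=100)
    sd = np.sqrt(10**6 * 0.01 * 0.99)
    assert np.all(np.abs(counts - 10_000) < 5 * sd)


def test_neutral_equimolarity_chi_square():
    # zero-bias sampling is multinomial-equimolar: seed-averaged GOF p > 0.001
    pool = build_reference_pool(100, (16, 28), (0.2, 0.8), seed=3)
    pvals = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        mols = sample_molecules(pool, np.ones(100), 10**6, 0, rng)
        counts = np.bincount(mols.parent, minlength=100)
        pvals.append(stats.chisquare(counts).pvalue)
    assert np.mean(pvals) > 0.001


def test_amplify_zero_cycles_is_identity(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 10, 4, rng)
    out = amplify(mols, BiasModel(pcr_cycles=0), rng)
    assert out is mols


def test_amplify_family_size_matches_closed_form():
    # E[copies] = (1+e)^c; 200 molecules x 10 seeds, mean within 5%
    pool = _single_seq_pool()
    model = BiasModel(pcr_efficiency_base=0.625, pcr_cycles=18)
    expected = 1.625**18
    means = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        mols = sample_molecules(pool, np.ones(1), 200, 4, rng)
        out = amplify(mols, model, rng)
        means.append(len(out) / 200)
    assert np.mean(means) == pytest.approx(expected, rel=0.05)
    # single-run Monte-Carlo check at the looser 10% band
    assert means[0] == pytest.approx(expected, rel=0.10)


def test_amplify_without_stutter_preserves_sequences(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 20, 4, rng)
    out = amplify(mols, BiasModel(pcr_cycles=5, stutter_prob=0.0), rng)
    assert all(out.seqs[s] == pool.sequences[0] for s in out.seq_id)


def test_stutter_contracts_or_expands_homopolymer(rng):
    pool = _single_seq_pool("ACGTAAAAACGTACGTACGT")  # run of 5 A at pos 4
    mols = sample_molecules(pool, np.ones(1), 50, 4, rng)
    out = amplify(mols, BiasModel(pcr_cycles=6, stutter_prob=0.5), rng)
    observed = {out.seqs[s] for s in out.seq_id}
    assert len(observed) > 1  # stutter produced at least one variant
    # every variant is the parent with its A-run contracted or expanded
    assert all(set(s) == {"A", "C", "G", "T"} and s.startswith("ACGTAA") for s in observed)
    assert {len(s) for s in observed} != {20}


def test_stutter_skips_sequences_without_homopolymers(rng):
    pool = _single_seq_pool("ACGTACGTACGTACGTACGT")
    mols = sample_molecules(pool, np.ones(1), 50, 4, rng)
    out = amplify(mols, BiasModel(pcr_cycles=6, stutter_prob=1.0), rng)
    assert all(out.seqs[s] == pool.sequences[0] for s in out.seq_id)


def test_gc_dependent_efficiency_orders_family_sizes():
    low = ReferencePool(["lo"], ["ATATATATATATATAT"], np.array([1.0]))
    high = ReferencePool(["hi"], ["GCGCGCGCGCGCGCGC"], np.array([1.0]))
    model = BiasModel(pcr_efficiency_base=0.6, pcr_efficiency_gc_coeff=0.4, pcr_cycles=10)
    sizes = {}
    for name, pool in [("lo", low), ("hi", high)]:
        rng = np.random.default_rng(7)
        mols = sample_molecules(pool, np.ones(1), 100, 4, rng)
        sizes[name] = len(amplify(mols, model, rng))
    assert sizes["hi"] > sizes["lo"]


def test_artifact_rates_zero_means_no_artifacts(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 100, 4, rng)
    out = inject_isomir_artifacts(mols, BiasModel(), rng)
    assert not out.artifact.any()


def test_trim3_artifact_count_within_binomial_noise(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 10**5, 4, rng)
    out = inject_isomir_artifacts(mols, BiasModel(trim3_rate=0.1), rng)
    n_art = int(out.artifact.astype(bool).sum())
    sd = np.sqrt(10**5 * 0.1 * 0.9)
    assert abs(n_art - 10**4) < 5 * sd


def test_5prime_artifacts_gated_to_clontech(rng):
    pool = _single_seq_pool()
    mols = sample_molecules(pool, np.ones(1), 1000, 4, rng)
    nf = inject_isomir_artifacts(
        mols, BiasModel(kit_layout="nextflex", strand_invasion5_rate=0.5, concatamer5_rate=0.5), rng
    )
    assert not nf.artifact.any()
    mols2 = sample_molecules(pool, np.ones(1), 1000, 0, rng)
    cl = inject_isomir_artifacts(
        mols2, BiasModel(kit_layout="clontech", strand_invasion5_rate=0.5), rng
    )
    assert cl.artifact.any()


def test_nextflex_read_construction_by_layout(rng):
    insert = "ACGTACGTACGTACGTACGT"
    pool = _single_seq_pool(insert)
    mols = MoleculeSet(
        pool=pool,
        parent=np.array([0]),
        seq_id=np.array([0]),
        umi=np.array([encode_umi("AAAATTTT")]),
        artifact=np.zeros(1, dtype=np.uint8),
        seqs=[insert],
        umi_total_len=8,
    )
    model = BiasModel(kit_layout="nextflex", seq_error_rate=0.0, adapter3="TGGAATTCTCGG")
    reads, truth = sequence_reads(mols, model, rng)
    _rid, seq, qual = reads[0]
    assert len(seq) == 51 and len(qual) == 51
    assert seq.startswith("AAAA" + "ACGT")
    assert seq[24:28] == "TTTT"               # 3' UMI right after the 20-nt insert
    assert seq[28:].startswith("TGGAATTCTCGG")
    assert truth.iloc[0]["umi"] == "AAAATTTT"


def test_default_raw_read_length_is_51(small_pool):
    reads, _ = simulate_library(small_pool, BiasModel(), 500, seed=2)
    assert all(len(seq) == 51 for _i, seq, _q in reads)


def test_sequencing_error_rate_within_binomial_noise(small_pool):
    model = BiasModel(kit_layout="plain", seq_error_rate=0.01)
    rng = np.random.default_rng(8)
    from srnabench.bias import total_bias_weights

    mols = sample_molecules(small_pool, np.ones(20), 2000, 0, rng)
    clean, _ = sequence_reads(mols, model.with_(seq_error_rate=0.0), np.random.default_rng(9))
    noisy, _ = sequence_reads(mols, model, np.random.default_rng(9))
    mismatches = sum(
        sum(a != b for a, b in zip(s1, s2)) for (_, s1, _), (_, s2, _) in zip(clean, noisy)
    )
    n_bases = 2000 * 51
    expected = n_bases * 0.01
    sd = np.sqrt(n_bases * 0.01 * 0.99)
    assert abs(mismatches - expected) < 5 * sd


def test_simulation_deterministic_given_seed(small_pool):
    model = BiasModel(pcr_cycles=3, seq_error_rate=0.005, trim3_rate=0.02)
    r1, t1 = simulate_library(small_pool, model, 500, seed=42)
    r2, t2 = simulate_library(small_pool, model, 500, seed=42)
    assert r1 == r2
    assert t1.reads.equals(t2.reads)
    assert t1.true_molecules.equals(t2.true_molecules)


def test_truth_conservation(small_pool):
    model = BiasModel(pcr_cycles=2, trim3_rate=0.05)
    reads, truth = simulate_library(small_pool, model, 1000, seed=3)
    assert truth.true_molecules.sum() == 1000
    assert truth.reads["read_id"].is_unique
    assert len(truth.reads) == len(reads)
    # artifact ledger never exceeds the molecule count per kind
    assert truth.artifact_counts["count"].sum() <= 1000


def test_expected_distinct_umis_closed_form():
    # m=1000 molecules over U=65536 labels: E[distinct] = U(1-(1-1/U)^m) ~ 992.4
    from srnabench.dedup import expected_distinct_umis

    expected = expected_distinct_umis(1000, 65536)
    assert expected == pytest.approx(992.4, abs=0.1)
    pool = _single_seq_pool()
    distinct = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        mols = sample_molecules(pool, np.ones(1), 1000, 4, rng)
        distinct.append(len(np.unique(mols.umi)))
    # collisions are ~Poisson(m^2/2U): sd ~ 2.8
    assert abs(np.mean(distinct) - expected) < 3 * 2.8
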