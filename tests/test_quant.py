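"""Clone and read methylation calling: round-trips against the simulator."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from qbgs.quant import (
    AlignmentQualityError,
    ClonePattern,
    MethylationMatrix,
    call_clone_pattern,
    filter_clones,
    matrix_from_reads,
    pileup_call,
    proportions_from_clones,
)
from qbgs.reference import ReferenceSequence, enumerate_cpgs
from qbgs.simulate import render_clone_sequence, simulate_clones, simulate_reads


def _pattern(sample, calls, eff=1.0, clone=""):
    return ClonePattern(
        sample_id=sample,
        clone_id=clone or f"{sample}.{np.random.default_rng(0).integers(1e6)}",
        labels=tuple(range(1, len(calls) + 1)),
        calls=np.array(calls, dtype=np.int8),
        conversion_efficiency=eff,
    )


def test_call_clone_pattern_direct_readout():
    ref = ReferenceSequence("r", "AACGAACAA")
    cmap = enumerate_cpgs(ref)
    assert cmap.positions == (3,)
    pat = call_clone_pattern("AACGAATAA", ref, cmap)
    assert pat.calls.tolist() == [1]  # methylated
    assert pat.conversion_efficiency == 1.0  # the lone non-CpG C read as T
    pat_u = call_clone_pattern("AATGAATAA", ref, cmap)
    assert pat_u.calls.tolist() == [0]


def test_call_clone_pattern_unconverted_c_lowers_efficiency():
    ref = ReferenceSequence("r", "AACGAACAA")
    cmap = enumerate_cpgs(ref)
    pat = call_clone_pattern("AACGAACAA", ref, cmap)  # non-CpG C kept as C
    assert pat.conversion_efficiency == 0.0


def test_call_clone_pattern_rejects_garbage():
    ref = ReferenceSequence("r", "AACGAACAATTGGAACCTTGGAACC")
    cmap = enumerate_cpgs(ref)
    with pytest.raises(AlignmentQualityError):
        call_clone_pattern("G" * 25, ref, cmap, min_identity=0.8)


def test_clone_roundtrip_recovers_simulated_patterns(toy_ref, toy_map):
    rng = np.random.default_rng(4)
    profile = rng.random(toy_map.n_analyzed)
    clones = simulate_clones(profile, 20, rng, sample_id="S1")
    for pat in clones:
        seq = render_clone_sequence(pat, toy_ref, toy_map)
        called = call_clone_pattern(seq, toy_ref, toy_map, sample_id="S1")
        assert called.calls.tolist() == pat.calls.tolist()
        assert called.conversion_efficiency == 1.0


def test_clone_roundtrip_reverse_complement(toy_ref, toy_map):
    rng = np.random.default_rng(9)
    pat = simulate_clones(rng.random(toy_map.n_analyzed), 1, rng)[0]
    seq = render_clone_sequence(pat, toy_ref, toy_map)
    rc = str(Seq(seq).reverse_complement())
    called = call_clone_pattern(rc, toy_ref, toy_map)
    assert called.calls.tolist() == pat.calls.tolist()


def test_filter_clones_threshold_and_identity():
    pats = [_pattern("a", [1], eff=1.0, clone="c1"), _pattern("a", [1], eff=0.9, clone="c2")]
    assert len(filter_clones(pats, 0.95)) == 1
    assert filter_clones(pats, 0.0) == pats
    with pytest.raises(ValueError):
        filter_clones(pats, 1.5)


def test_filter_clones_retention_under_conversion_failure(toy_ref, toy_map):
    """Strict threshold 1.0 with failure rate 0.05 per non-CpG C: retention
    matches (1 - 0.05)^k within binomial error."""
    rng = np.random.default_rng(12)
    n_non_cpg_c = sum(
        1
        for i, b in enumerate(toy_ref.sequence, start=1)
        if b == "C" and i not in toy_map.positions
    )
    pats = simulate_clones(np.full(toy_map.n_analyzed, 0.5), 400, rng, "S1")
    reads = simulate_reads(pats, toy_ref, toy_map, depth=400, conversion_failure=0.05, rng=rng)
    called = [
        call_clone_pattern(str(r.seq), toy_ref, toy_map, sample_id="S1", clone_id=r.id)
        for r in reads
    ]
    kept = filter_clones(called, min_conversion=1.0)
    expected = 0.95 ** n_non_cpg_c
    se = np.sqrt(expected * (1 - expected) / 400)
    assert abs(len(kept) / 400 - expected) <= 3 * se


def test_proportions_from_clones_fraction_and_missing():
    pats = [_pattern("s", [c], clone=f"c{i}") for i, c in enumerate([1, 1, 1, 0])]
    mat = proportions_from_clones(pats)
    assert mat.proportions.iloc[0, 0] == 0.75
    assert mat.denominators.iloc[0, 0] == 4
    pats2 = [_pattern("s", [c], clone=f"c{i}") for i, c in enumerate([1, -1, 0])]
    mat2 = proportions_from_clones(pats2)
    assert mat2.proportions.iloc[0, 0] == 0.5
    assert mat2.denominators.iloc[0, 0] == 2


def test_proportions_denominator_conservation_and_order_invariance():
    rng = np.random.default_rng(6)
    pats = []
    for i in range(30):
        calls = rng.choice([1, 0, -1], size=5, p=[0.4, 0.4, 0.2])
        pats.append(_pattern("s", calls, clone=f"c{i}"))
    mat = proportions_from_clones(pats)
    calls = np.stack([p.calls for p in pats])
    for j in range(5):
        n_m = (calls[:, j] == 1).sum()
        n_u = (calls[:, j] == 0).sum()
        n_miss = (calls[:, j] == -1).sum()
        assert n_m + n_u + n_miss == 30
        assert mat.denominators.iloc[0, j] == n_m + n_u
    shuffled = [pats[i] for i in rng.permutation(30)]
    assert proportions_from_clones(shuffled).proportions.equals(mat.proportions)


def test_clone_sampling_concentration():
    """i.i.d. Bernoulli(0.3) clones: realized fractions concentrate at 3 SE."""
    rng = np.random.default_rng(14)
    n_clones, n_sites, reps = 50, 10, 100
    se = np.sqrt(0.3 * 0.7 / n_clones)
    within = 0
    for _ in range(reps):
        draws = rng.random((n_clones, n_sites)) < 0.3
        within += (np.abs(draws.mean(0) - 0.3) <= 3 * se).sum()
    assert within / (reps * n_sites) >= 0.99 - 3 * np.sqrt(0.01 * 0.99 / (reps * n_sites))


def _reads_from_counts(toy_ref, toy_map, n_meth, n_unmeth):
    all_m = _pattern("s", [1] * toy_map.n_analyzed)
    all_u = _pattern("s", [0] * toy_map.n_analyzed)
    seq_m = render_clone_sequence(all_m, toy_ref, toy_map)
    seq_u = render_clone_sequence(all_u, toy_ref, toy_map)
    return [seq_m] * n_meth + [seq_u] * n_unmeth


def test_pileup_count_ratio(toy_ref, toy_map):
    reads = _reads_from_counts(toy_ref, toy_map, 7, 3)
    counts, props, depth = pileup_call(reads, toy_ref, toy_map, min_depth=1)
    assert np.allclose(props.to_numpy(), 0.7)
    assert (counts.depth == 10).all()
    # below min_depth the cell is missing, not zero
    _, props4, depth4 = pileup_call(reads[:4], toy_ref, toy_map, min_depth=5)
    assert props4.isna().all()
    assert (depth4 == 0).all()


def test_pileup_min_baseq_filters_bases(toy_ref, toy_map):
    seq = _reads_from_counts(toy_ref, toy_map, 1, 0)[0]
    quals = [40] * len(seq)
    low_pos = toy_map.analyzed_positions()[0] - 1
    quals[low_pos] = 5  # first CpG unreadable in this read
    rec = SeqRecord(Seq(seq), id="r1")
    rec.letter_annotations["phred_quality"] = quals
    counts, props, _ = pileup_call([rec], toy_ref, toy_map, min_depth=1)
    assert counts.depth[0] == 0 and np.isnan(props.iloc[0])
    assert counts.depth[1] == 1


def test_read_and_clone_paths_agree_exactly(toy_ref, toy_map):
    """One error-free read per clone reproduces the clone matrix exactly."""
    rng = np.random.default_rng(18)
    clones, reads_by_sample = [], {}
    for sid in ("S1", "S2", "S3"):
        pats = simulate_clones(rng.random(toy_map.n_analyzed), 15, rng, sid)
        clones.extend(pats)
        reads_by_sample[sid] = [
            render_clone_sequence(p, toy_ref, toy_map) for p in pats
        ]
    clone_mat = proportions_from_clones(clones)
    read_mat = matrix_from_reads(reads_by_sample, toy_ref, toy_map, min_depth=1)
    assert np.array_equal(
        clone_mat.proportions.to_numpy(), read_mat.proportions.to_numpy()
    )
    assert np.array_equal(
        clone_mat.denominators.to_numpy(), read_mat.denominators.to_numpy()
    )


def test_export_clone_patterns_lollipop(tmp_path):
    from qbgs.quant import export_clone_patterns

    pats = [_pattern("s", [1, 0, -1], clone="c1"), _pattern("s", [0, 0, 1], clone="c2")]
    path = tmp_path / "lollipop.tsv"
    export_clone_patterns(pats, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["sample_id", "clone_id", "CpG1", "CpG2", "CpG3"]
    assert lines[1].split("\t")[2:] == ["M", "U", "."]
    assert lines[2].split("\t")[2:] == ["U", "U", "M"]


def test_matrix_validation_and_tsv_roundtrip(tmp_path):
    p = pd.DataFrame([[0.5, np.nan]], index=["s1"], columns=[1, 2])
    d = pd.DataFrame([[10, 0]], index=["s1"], columns=[1, 2])
    mat = MethylationMatrix(p, d)
    pp, dp = tmp_path / "p.tsv", tmp_path / "d.tsv"
    mat.to_tsv(pp, dp)
    back = MethylationMatrix.from_tsv(pp, dp)
    assert back.proportions.equals(mat.proportions)
    with pytest.raises(ValueError):
        MethylationMatrix(p, d.iloc[:, :1])
    bad = p.copy()
    bad.iloc[0, 0] = 1.5
    with pytest.raises(ValueError):
        MethylationMatrix(bad, d)
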