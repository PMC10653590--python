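"""Profile building, genome scanning and redundancy clustering."""
import numpy as np
import pytest

from ormine import (
    FAMILIES,
    GenomeHit,
    SeedFamilySet,
    build_family_profiles,
    dedup_cluster,
    load_profiles,
    save_profiles,
    scan_genome,
    simulate,
)
from ormine.profiles import global_nt_identity, reverse_complement, translate_seed


def test_complete_build_yields_13_profiles(profiles):
    assert len(profiles) == 13
    assert {p.family_id for p in profiles} == set(FAMILIES)


def test_single_933nt_seed_gives_310_column_model():
    cds = simulate.family_template_cds("4")
    assert len(cds) == 933
    prof = build_family_profiles([SeedFamilySet("4", [("s0", cds)])])[0]
    assert prof.model_length == 310


def test_identical_seeds_consensus_and_selfscore():
    cds = simulate.family_template_cds("6")
    prof = build_family_profiles([SeedFamilySet("6", [("a", cds), ("b", cds), ("c", cds)])])[0]
    prot = translate_seed("a", cds)
    assert prof.consensus == prot
    rng = np.random.default_rng(0)
    shuffled = "".join(rng.permutation(list(prot)))
    assert prof.score_protein(prot) > prof.score_protein(shuffled)
    assert prof.score_protein(prot) > 0


def test_build_errors_name_the_culprit():
    with pytest.raises(ValueError, match="51"):
        build_family_profiles([SeedFamilySet("51", [])])
    bad = simulate.family_template_cds("4")
    bad = bad[:30] + "TGA" + bad[33:]
    with pytest.raises(ValueError, match="badseed"):
        build_family_profiles([SeedFamilySet("4", [("badseed", bad)])])


def test_profile_serialization_roundtrip_bit_identical(profiles, tmp_path):
    path = tmp_path / "profiles.json"
    save_profiles(profiles, path)
    loaded = load_profiles(path)
    assert len(loaded) == len(profiles)
    for a, b in zip(profiles, loaded):
        assert a.family_id == b.family_id
        assert np.array_equal(a.emissions, b.emissions)
        assert a.consensus == b.consensus


def test_scan_random_background_has_no_hits(profiles):
    genome, truth = simulate.make_genome([], background_length=10_000, gc=0.5, seed=1)
    assert truth.empty
    assert scan_genome(profiles, genome) == []


def test_scan_recovers_intact_plant_as_single_hit(profiles):
    genome, truth = simulate.make_genome(
        [simulate.PlantSpec("4", 0.0, "none", start=40_000)],
        background_length=100_000,
        seed=2,
    )
    hits = scan_genome(profiles, genome)
    assert len(hits) == 1
    h, row = hits[0], truth.iloc[0]
    overlap = max(0, min(h.end, row.end) - max(h.start, row.start))
    assert overlap / (row.end - row.start) >= 0.90
    assert h.family == "4"


def test_scan_reverse_complement_strand_and_extraction(profiles):
    genome, truth = simulate.make_genome(
        [simulate.PlantSpec("6", 0.0, "reverse_complement", start=40_000)],
        background_length=100_000,
        seed=3,
    )
    hits = [h for h in scan_genome(profiles, genome) if h.strand == "-"]
    assert len(hits) == 1
    row = truth.iloc[0]
    planted_coding = reverse_complement(genome["chr1"][row.start : row.end])
    assert hits[0].sequence in planted_coding
    assert len(hits[0].sequence) >= 0.9 * (row.end - row.start)


def test_scan_recall_at_20pct_divergence(profiles):
    plants = [
        simulate.PlantSpec(f, 0.20, "none", seed=i)
        for i, f in enumerate(["51", "10", "14"])
    ]
    genome, truth = simulate.make_genome(plants, background_length=80_000, seed=4)
    hits = scan_genome(profiles, genome)
    for _, row in truth.iterrows():
        assert any(
            max(0, min(h.end, row.end) - max(h.start, row.start)) > 0 for h in hits
        )


def test_scan_determinism(profiles):
    genome, _ = simulate.make_genome(
        [simulate.PlantSpec("12", 0.05, "none", seed=9)],
        background_length=50_000,
        seed=5,
    )
    h1 = scan_genome(profiles, genome)
    h2 = scan_genome(profiles, genome)
    assert [(h.contig, h.start, h.end, h.strand, h.family, h.score, h.sequence) for h in h1] == [
        (h.contig, h.start, h.end, h.strand, h.family, h.score, h.sequence) for h in h2
    ]


def test_malformed_fasta_reports_line(tmp_path):
    bad = tmp_path / "bad.fa"
    bad.write_text("ACGTACGT\n>seq1\nACGT\n")
    with pytest.raises(ValueError, match="line 1"):
        scan_genome([], bad)


# ----------------------------------------------------------------------
# dedup clustering


def _hit(seq: str, i: int) -> GenomeHit:
    return GenomeHit("c", 1000 * i, 1000 * i + len(seq), "+", "4", 100.0, 0.0, seq)


def _mutated_copy(seq: str, frac: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for pos in rng.choice(len(seq), size=int(round(frac * len(seq))), replace=False):
        out[int(pos)] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[int(pos)]]
    return "".join(out)


def test_dedup_merges_alleles_at_99pct_identity():
    base = simulate.family_template_cds("4")
    allele = _mutated_copy(base, 0.01, seed=7)
    assert global_nt_identity(base, allele) >= 0.98
    res = dedup_cluster([_hit(base, 0), _hit(allele, 1)], threshold=0.98)
    assert len(res.representatives) == 1
    assert len(res.member_map) == 2


def test_dedup_identical_sequences_single_representative():
    base = simulate.family_template_cds("10")
    hits = [_hit(base, i) for i in range(5)]
    res = dedup_cluster(hits)
    assert len(res.representatives) == 1
    rep_key = res.representatives[0].key
    assert all(v == rep_key for v in res.member_map.values())


def test_dedup_pair_below_threshold_stays_separate():
    base = simulate.family_template_cds("11")
    far = _mutated_copy(base, 0.05, seed=8)
    res = dedup_cluster([_hit(base, 0), _hit(far, 1)], threshold=0.98)
    assert len(res.representatives) == 2


def test_dedup_matches_all_pairs_oracle_and_partitions():
    base = simulate.family_template_cds("51")
    rng = np.random.default_rng(42)
    hits = [
        _hit(_mutated_copy(base, float(rng.uniform(0, 0.06)), seed=100 + i), i)
        for i in range(12)
    ]
    res = dedup_cluster(hits, threshold=0.98)
    # representatives must be mutually below the threshold (greedy oracle)
    reps = res.representatives
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            assert global_nt_identity(reps[i].sequence, reps[j].sequence) < 0.98
    # clusters partition the input
    assert len(res.member_map) == len(hits)
    assert set(res.member_map.values()) == {r.key for r in reps}
    # every representative maps to itself
    for r in reps:
        assert res.member_map[r.key] == r.key


@pytest.mark.parametrize("thresholds", [(1.0, 0.98, 0.95, 0.90)])
def test_dedup_threshold_monotonicity(thresholds):
    base = simulate.family_template_cds("2-13")
    hits = [_hit(_mutated_copy(base, 0.01 * i, seed=i), i) for i in range(8)]
    sizes = [len(dedup_cluster(hits, t).representatives) for t in thresholds]
    assert sizes == sorted(sizes, reverse=True)


def test_dedup_threshold_validation():
    with pytest.raises(ValueError):
        dedup_cluster([], threshold=0.0)
    assert dedup_cluster([], threshold=0.98).representatives == []
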