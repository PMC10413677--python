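import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiguide.prediction import (
    MatchStatus,
    PredictionTable,
    SpeciesPrediction,
    aggregate,
    classify_species,
    find_perfect_sites,
    flank_identity,
    min_mismatch_scan,
)
from multiguide.msa import progressive_align
from multiguide.conservation import enumerate_guides, find_conserved_runs
from multiguide.seq_core import GenomicSite, NucSequence, reverse_complement
from multiguide.synthetic_data import (
    GRNA_CTRL,
    FamilySpec,
    ParalogSpec,
    evolve_family,
    generate_ancestor,
    plant_paralog,
)

from conftest import random_dna

GUIDE = "GGTGCTTCATGAAAAAGAAG"


def embed(rng, guide, pam="TGG", strand="+", flank=40):
    left, right = random_dna(rng, flank), random_dna(rng, flank)
    insert = guide + pam
    if strand == "-":
        insert = reverse_complement(insert)
    return left + insert + right, len(left)


# ---------------------------------------------------------------------------
# find_perfect_sites


def test_perfect_site_by_construction(rng):
    residues, offset = embed(rng, GUIDE)
    target = NucSequence(id="t", residues=residues)
    sites = find_perfect_sites(GUIDE, target)
    assert [(s.start, s.end, s.strand) for s in sites] == [
        (offset, offset + 20, "+")
    ]


def test_control_guide_absent_from_family(small_family):
    _, _, family = small_family
    for seq in family:
        assert find_perfect_sites(GRNA_CTRL, seq, require_pam=False) == []


def test_minus_strand_planting(rng):
    residues, offset = embed(rng, GUIDE, strand="-")
    target = NucSequence(id="t", residues=residues)
    sites = find_perfect_sites(GUIDE, target)
    # revcomp(guide+PAM): PAM occupies the first 3 top-strand positions
    assert [(s.start, s.end, s.strand) for s in sites] == [
        (offset + 3, offset + 23, "-")
    ]
    # brute-force oracle over both strands
    oracle = []
    rc = reverse_complement(GUIDE)
    for i in range(len(residues) - 19):
        win = residues[i : i + 20]
        if win == GUIDE and residues[i + 21 : i + 23] == "GG":
            oracle.append((i, i + 20, "+"))
        if win == rc and i >= 3 and residues[i - 3 : i - 1] == "CC":
            oracle.append((i, i + 20, "-"))
    assert [(s.start, s.end, s.strand) for s in sites] == oracle


def test_pam_required_excludes_edge_sites(rng):
    left = random_dna(rng, 30)
    target = NucSequence(id="t", residues=left + GUIDE)  # no room for a PAM
    assert find_perfect_sites(GUIDE, target, require_pam=True) == []
    sites = find_perfect_sites(GUIDE, target, require_pam=False)
    assert len(sites) == 1


def test_perfect_sites_equal_zero_mismatch_scan(rng):
    """Dual-route: perfect-site search == mismatch scan restricted to k=0."""
    for _ in range(10):
        residues, _ = embed(rng, GUIDE, flank=200)
        target = NucSequence(id="t", residues=residues)
        perfect = find_perfect_sites(GUIDE, target, require_pam=False)
        k_min, hits = min_mismatch_scan(GUIDE, target, pam_mode="ignored")
        assert k_min == 0
        assert {(s.start, s.strand) for s in perfect} == {
            (h.site.start, h.site.strand) for h in hits
        }


# ---------------------------------------------------------------------------
# min_mismatch_scan


def hamming_oracle(guide, residues):
    """Exhaustive per-offset Hamming oracle over both strands."""
    best = len(guide)
    rc = reverse_complement(guide)
    for g in (guide, rc):
        for i in range(len(residues) - len(guide) + 1):
            k = sum(a != b for a, b in zip(g, residues[i : i + len(guide)]))
            best = min(best, k)
    return best


def test_scan_own_site_zero(rng):
    residues, _ = embed(rng, GUIDE)
    k_min, hits = min_mismatch_scan(GUIDE, NucSequence(id="t", residues=residues))
    assert k_min == 0
    assert all(h.k == 0 for h in hits)


def test_planted_paralog_k2(rng):
    residues, offset = embed(rng, GUIDE, flank=100)
    source = NucSequence(id="src", residues=residues)
    site = GenomicSite("src", offset, offset + 20, "+")
    paralog = plant_paralog(
        ParalogSpec(source=source, guide_site=site, k=2, background_divergence=0.0, seed=5)
    )
    k_min, hits = min_mismatch_scan(GUIDE, paralog, pam_mode="ignored")
    assert k_min == 2
    assert hamming_oracle(GUIDE, paralog.residues) == 2


def test_scan_matches_oracle_on_random(rng):
    for _ in range(5):
        residues = random_dna(rng, 5000)
        target = NucSequence(id="t", residues=residues)
        k_min, hits = min_mismatch_scan(GUIDE, target, pam_mode="ignored")
        assert k_min == hamming_oracle(GUIDE, residues)
        for h in hits:
            window = residues[h.site.start : h.site.end]
            if h.site.strand == "-":
                window = reverse_complement(window)
            assert sum(a != b for a, b in zip(GUIDE, window)) == h.k


def test_scan_pam_required_restricts(rng):
    # guide followed by ATT: perfect protospacer but no PAM-adjacent offset
    residues, offset = embed(rng, GUIDE, pam="ATT")
    target = NucSequence(id="t", residues=residues)
    k_ign, _ = min_mismatch_scan(GUIDE, target, pam_mode="ignored")
    k_req, hits_req = min_mismatch_scan(GUIDE, target, pam_mode="required")
    assert k_ign == 0
    assert k_req > 0 or all(h.site.start != offset for h in hits_req)


def test_scan_target_shorter_than_guide():
    with pytest.raises(ValueError):
        min_mismatch_scan(GUIDE, NucSequence(id="t", residues="ACGT"))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_mutation_monotonicity(seed):
    """Mutating one protospacer base changes k_min by at most +1, never down."""
    rng = np.random.default_rng(seed)
    residues, offset = embed(rng, GUIDE, flank=60)
    target = NucSequence(id="t", residues=residues)
    k0, _ = min_mismatch_scan(GUIDE, target, pam_mode="ignored")
    pos = int(rng.integers(offset, offset + 20))
    old = residues[pos]
    new = rng.choice([b for b in "ACGT" if b != old])
    mutated = NucSequence(id="t", residues=residues[:pos] + new + residues[pos + 1 :])
    k1, _ = min_mismatch_scan(GUIDE, mutated, pam_mode="ignored")
    assert k0 <= k1 <= k0 + 1


# ---------------------------------------------------------------------------
# classify_species


def test_classify_design_family_functional(small_family):
    spec, _, family = small_family
    members = [s for s in family if s.id not in spec.pam_knockout]
    aln = progressive_align(members)
    cands = enumerate_guides(aln, find_conserved_runs(aln, 20))
    assert cands
    for cand in cands:
        for seq in members:
            pred = classify_species(cand.protospacer, [seq], guide_id=cand.guide_id)
            assert pred.status.kind == "predicted_functional"
            assert pred.site is not None


def test_classify_pam_mutated_is_pam_absent(rng):
    residues, _ = embed(rng, GUIDE, pam="ATT")
    pred = classify_species(GUIDE, [NucSequence(id="t", residues=residues, species="sp")])
    assert pred.status.kind == "pam_absent"


def test_classify_mismatched_low_k(rng):
    residues, offset = embed(rng, GUIDE, flank=100)
    source = NucSequence(id="src", residues=residues, species="sp")
    site = GenomicSite("src", offset, offset + 20, "+")
    for k in (1, 3):
        paralog = plant_paralog(
            ParalogSpec(source=source, guide_site=site, k=k,
                        background_divergence=0.0, seed=k)
        )
        pred = classify_species(GUIDE, [paralog])
        assert pred.status == MatchStatus("mismatched", k=k)


def test_classify_threshold_boundary():
    # Short target (guide + PAM only) so the planted mismatch count is the
    # global minimum; long random flanks would beat a high planted k by
    # chance. Seeds chosen so the planted k survives self-overlap offsets.
    source = NucSequence(id="src", residues=GUIDE + "TGG", species="sp")
    site = GenomicSite("src", 0, 20, "+")
    k10 = plant_paralog(
        ParalogSpec(source=source, guide_site=site, k=10,
                    background_divergence=0.0, seed=0)
    )
    pred = classify_species(GUIDE, [k10])
    assert pred.status == MatchStatus("mismatched", k=10)
    k11 = plant_paralog(
        ParalogSpec(source=source, guide_site=site, k=11,
                    background_divergence=0.0, seed=1)
    )
    pred = classify_species(GUIDE, [k11])
    assert pred.status.kind == "absent"
    assert pred.site is None


def test_classify_best_status_wins(rng):
    good, _ = embed(rng, GUIDE)
    bad = random_dna(rng, 100)
    seqs = [
        NucSequence(id="scaffold1", residues=bad, species="sp"),
        NucSequence(id="scaffold2", residues=good, species="sp"),
    ]
    pred = classify_species(GUIDE, seqs)
    assert pred.status.kind == "predicted_functional"


def test_classify_empty_set_rejected():
    with pytest.raises(ValueError):
        classify_species(GUIDE, [])


# ---------------------------------------------------------------------------
# flank_identity


def test_flank_identity_hit_in_reference_itself(rng):
    residues, offset = embed(rng, GUIDE, flank=80)
    seq = NucSequence(id="ref", residues=residues)
    site = GenomicSite("ref", offset, offset + 20, "+")
    result = flank_identity(site, seq, seq, flank_len=50)
    assert result.percent == pytest.approx(100.0)
    assert not result.clipped


def test_flank_identity_random_flanks_near_25(rng):
    pcts = []
    for _ in range(20):
        left_a, right_a = random_dna(rng, 50), random_dna(rng, 50)
        left_b, right_b = random_dna(rng, 50), random_dna(rng, 50)
        target = NucSequence(id="t", residues=left_a + GUIDE + right_a)
        ref = NucSequence(id="r", residues=left_b + GUIDE + right_b)
        site = GenomicSite("t", 50, 70, "+")
        # identity computed without alignment gaps would be ~25%; the global
        # aligner inflates it slightly, so compare against a generous band
        params_pct = flank_identity(site, target, ref, flank_len=50).percent
        pcts.append(params_pct)
    mean = sum(pcts) / len(pcts)
    assert 15 < mean < 45


def test_flank_identity_diverged_orthologs_near_90(rng):
    pcts = []
    for i in range(10):
        core, offset = embed(rng, GUIDE, flank=60)
        src = NucSequence(id="src", residues=core, species="a")
        spec = FamilySpec(n_species=2, length=len(core), divergence=0.1, seed=i)
        fam = evolve_family(NucSequence(id="anc", residues=core), spec)
        # restore the guide region so both carry the hit exactly
        sp = fam[0]
        fixed = (
            sp.residues[:offset] + GUIDE + sp.residues[offset + 20 :]
        )
        target = NucSequence(id="t", residues=fixed)
        site = GenomicSite("t", offset, offset + 20, "+")
        pcts.append(flank_identity(site, target, src, flank_len=50).percent)
    mean = sum(pcts) / len(pcts)
    assert 80 < mean < 97


def test_flank_identity_clipped_flag(rng):
    residues, offset = embed(rng, GUIDE, flank=10)
    seq = NucSequence(id="ref", residues=residues)
    site = GenomicSite("ref", offset, offset + 20, "+")
    result = flank_identity(site, seq, seq, flank_len=50)
    assert result.clipped
    assert result.percent == pytest.approx(100.0)


def test_flank_identity_missing_guide_rejected(rng):
    residues, offset = embed(rng, GUIDE)
    target = NucSequence(id="t", residues=residues)
    ref = NucSequence(id="r", residues=random_dna(rng, 200))
    with pytest.raises(ValueError):
        flank_identity(GenomicSite("t", offset, offset + 20, "+"), target, ref)


# ---------------------------------------------------------------------------
# PredictionTable / aggregate


def make_table(cells):
    """cells: dict (guide, species) -> bool functional."""
    guides = sorted({g for g, _ in cells})
    species = sorted({s for _, s in cells})
    preds = [
        SpeciesPrediction(
            species=s,
            guide_id=g,
            status=MatchStatus("predicted_functional") if v else MatchStatus("absent"),
            site=GenomicSite(s, 0, 1, "+") if v else None,
        )
        for (g, s), v in cells.items()
    ]
    return PredictionTable(guides, species, preds)


def test_aggregate_counts_and_union():
    table = make_table(
        {
            ("g1", "a"): True,
            ("g1", "b"): False,
            ("g2", "a"): True,
            ("g2", "b"): True,
        }
    )
    summary = aggregate(table)
    assert summary["per_guide"] == {"g1": 1, "g2": 2}
    assert summary["union"] == 2


def test_aggregate_single_cell():
    summary = aggregate(make_table({("g1", "a"): True}))
    assert summary["per_guide"] == {"g1": 1}
    assert summary["union"] == 1


def test_aggregate_empty_table():
    table = PredictionTable([], [], [])
    summary = aggregate(table)
    assert summary["per_guide"] == {}
    assert summary["union"] == 0


def test_aggregate_union_bounds(small_family):
    table = make_table(
        {(g, s): bool((hash((g, s)) >> 2) & 1) for g in "gh" for s in "abcde"}
    )
    summary = aggregate(table)
    assert summary["union"] >= max(summary["per_guide"].values())
    assert summary["union"] <= len(table.species)


def test_table_completeness_enforced():
    with pytest.raises(ValueError, match="incomplete"):
        PredictionTable(
            ["g1"],
            ["a", "b"],
            [
                SpeciesPrediction(
                    species="a", guide_id="g1", status=MatchStatus("absent")
                )
            ],
        )


def test_table_tsv_round_trip(tmp_path):
    table = make_table(
        {("g1", "a"): True, ("g1", "b"): False, ("g2", "a"): False, ("g2", "b"): True}
    )
    path = tmp_path / "table.tsv"
    table.to_tsv(path)
    back = PredictionTable.from_tsv(path)
    for g in table.guide_ids:
        for s in table.species:
            assert (
                back.get(g, s).status.functional
                == table.get(g, s).status.functional
            )


def test_table_json_output(tmp_path):
    import json

    table = make_table({("g1", "a"): True, ("g1", "b"): False})
    path = tmp_path / "table.json"
    table.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["guides"] == ["g1"]
    statuses = {p["species"]: p["status"] for p in payload["predictions"]}
    assert statuses == {"a": "predicted_functional", "b": "absent"}
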