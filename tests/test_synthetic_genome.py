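import math

import numpy as np
import pytest

from ervatlas.dating import k2p_distance
from ervatlas.genome_io import ContigSet
from ervatlas.synthetic_genome import (GenomeSimulator, PlacementError,
                                       SubstitutionParams, build_pair_demo,
                                       derive_rng, make_background,
                                       make_template, mutate_k2p, plant,
                                       simulate_species_pair)

PARAMS = SubstitutionParams(rate=2.2e-9, kappa=2.0)


# ---------------------------------------------------------------------------
# background

def test_background_is_reproducible_for_fixed_seed():
    assert make_background(10000, 0.5, 7) == make_background(10000, 0.5, 7)


def test_background_gc_within_three_binomial_sd():
    seq = make_background(100000, 0.5, 3)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    sd = math.sqrt(0.25 / 100000)
    assert abs(gc - 0.5) < 3 * sd


def test_zero_gc_background_is_pure_at():
    assert set(make_background(5000, 0.0, 1)) <= {"A", "T"}


def test_background_rejects_bad_arguments():
    with pytest.raises(ValueError):
        make_background(0, 0.5, 1)
    with pytest.raises(ValueError):
        make_background(10, 1.5, 1)


# ---------------------------------------------------------------------------
# K2P forward process

def test_zero_time_changes_nothing():
    rng = np.random.default_rng(0)
    seq = make_background(500, 0.5, rng)
    assert mutate_k2p(seq, PARAMS, 0.0, rng) == seq


def test_mean_mismatch_matches_poisson_expectation():
    """600-bp sequences at 10 Myr: raw mismatch ~ 1 - exp(-R t)."""
    rng = np.random.default_rng(1)
    seq = make_background(600, 0.5, rng)
    expected = 1 - math.exp(-2.2e-9 * 1e7)
    fracs = []
    for _ in range(400):
        mut = mutate_k2p(seq, PARAMS, 10.0, rng)
        fracs.append(sum(a != b for a, b in zip(seq, mut)) / 600)
    mc_sd = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
    assert abs(np.mean(fracs) - expected) < 3 * mc_sd + 1e-4


def test_huge_kappa_yields_only_transitions():
    rng = np.random.default_rng(2)
    seq = make_background(2000, 0.5, rng)
    params = SubstitutionParams(rate=2.2e-9, kappa=1e6)
    mut = mutate_k2p(seq, params, 100.0, rng)
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for a, b in zip(seq, mut):
        if a != b:
            assert (a, b) in transitions


def test_observed_ts_tv_ratio_converges_to_kappa():
    rng = np.random.default_rng(3)
    seq = make_background(200000, 0.5, rng)
    mut = mutate_k2p(seq, PARAMS, 20.0, rng)
    ts = tv = 0
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for a, b in zip(seq, mut):
        if a != b:
            if (a, b) in transitions:
                ts += 1
            else:
                tv += 1
    ratio = ts / tv
    se = ratio * math.sqrt(1 / ts + 1 / tv)
    assert abs(ratio - PARAMS.kappa) < 3 * se


def test_n_sites_are_inert():
    seq = "N" * 100
    rng = np.random.default_rng(4)
    assert mutate_k2p(seq, PARAMS, 1000.0, rng) == seq


def test_labeled_rng_streams_are_stable_and_distinct():
    a = derive_rng(5, "x").integers(0, 1 << 30, 4)
    b = derive_rng(5, "x").integers(0, 1 << 30, 4)
    c = derive_rng(5, "y").integers(0, 1 << 30, 4)
    assert (a == b).all()
    assert (a != c).any()


# ---------------------------------------------------------------------------
# planting

@pytest.fixture(scope="module")
def template():
    return make_template(np.random.default_rng(10), lineage_id="Gamma.a",
                         genus="Gamma", pbs_trna="Pro", tsd_len=5)


@pytest.fixture()
def bg_genome():
    return ContigSet({"c1": make_background(30000, 0.45, 11)}, "sim")


def test_template_geometry_is_within_the_detection_window(template):
    total = len(template.element)
    assert 2 * len(template.ltr) + 1000 <= total <= 15000 + len(template.ltr)
    assert len(template.pbs) == 18
    assert len(template.ppt) >= 10
    purines = sum(c in "AG" for c in template.ppt) / len(template.ppt)
    assert purines >= 0.9


def test_age_zero_plant_has_identical_ltrs_and_flanking_tsd(
        template, bg_genome):
    genome, row = plant(bg_genome, template, "c1", 12000, 0.0, "intact",
                        PARAMS, seed=1)
    seq = genome["c1"]
    ltr5 = seq[row.ltr5.start:row.ltr5.end]
    ltr3 = seq[row.ltr3.start:row.ltr3.end]
    assert ltr5 == ltr3 == template.ltr
    L = len(row.tsd)
    assert seq[row.locus.start - L:row.locus.start] == row.tsd
    assert seq[row.locus.end:row.locus.end + L] == row.tsd


def test_plant_leaves_flanks_untouched(template, bg_genome):
    before = bg_genome["c1"]
    genome, row = plant(bg_genome, template, "c1", 12000, 3.0, "intact",
                        PARAMS, seed=2)
    after = genome["c1"]
    L = len(row.tsd)
    assert after[:row.locus.start - L] == before[:row.locus.start - L]
    inserted = row.locus.end - (row.locus.start - L)
    assert after[row.locus.end:] == before[row.locus.end - inserted:]


def test_ltr_divergence_matches_twice_rate_times_age(template, bg_genome):
    """50 plants at 10 Myr: mean K2P distance of the LTR pair ~ 2 R t."""
    ds = []
    for i in range(50):
        genome, row = plant(bg_genome, template, "c1", 12000, 10.0,
                            "intact", PARAMS, seed=100 + i)
        seq = genome["c1"]
        est = k2p_distance(seq[row.ltr5.start:row.ltr5.end],
                           seq[row.ltr3.start:row.ltr3.end])
        ds.append(est.D)
    se = np.std(ds, ddof=1) / math.sqrt(len(ds))
    assert abs(np.mean(ds) - 0.044) < 3 * se


def test_solo_plant_is_a_lone_ltr(template, bg_genome):
    genome, row = plant(bg_genome, template, "c1", 12000, 2.0, "solo",
                        PARAMS, seed=3)
    assert row.state == "solo"
    assert row.ltr3 is None
    assert len(row.locus) == len(template.ltr)
    # no internal ORF sequence anywhere near the solo LTR
    window = genome["c1"][max(0, row.locus.start - 15000):
                          row.locus.end + 15000]
    assert template.gag_nt[:50] not in window


def test_degraded_plant_carries_premature_stops(template, bg_genome):
    genome, row = plant(bg_genome, template, "c1", 12000, 0.0, "degraded",
                        PARAMS, seed=4)
    seq = genome["c1"]
    internal = seq[row.ltr5.start + len(template.ltr):row.ltr3.start]
    offs = template.internal_orf_offsets
    for gene, orf_nt in (("GAG", template.gag_nt), ("POL", template.pol_nt),
                         ("ENV", template.env_nt)):
        mid = offs[gene] + 3 * ((len(orf_nt) // 3) // 2)
        assert internal[mid:mid + 3] == "TAA"


def test_nested_plant_interrupts_between_env_and_3prime_ltr(
        template, bg_genome):
    genome, row = plant(bg_genome, template, "c1", 12000, 0.0, "nested",
                        PARAMS, seed=5)
    assert len(row.locus) > len(template.element) + 2000
    seq = genome["c1"]
    # PPT (end of internal region) still abuts the 3' LTR
    ppt = seq[row.ltr3.start - len(template.ppt):row.ltr3.start]
    assert ppt == template.ppt


def test_overlapping_plants_are_refused(template, bg_genome):
    sim = GenomeSimulator(bg_genome, PARAMS, 6)
    sim.plant(template, "c1", 12000, 1.0, "intact")
    with pytest.raises(PlacementError):
        sim.plant(template, "c1", 12500, 1.0, "intact")


def test_unknown_state_is_rejected(template, bg_genome):
    sim = GenomeSimulator(bg_genome, PARAMS, 7)
    with pytest.raises(ValueError):
        sim.plant(template, "c1", 12000, 1.0, "weird")


# ---------------------------------------------------------------------------
# species pair

def _tiny_ancestor(seed=8):
    contigs = {f"a{i}": make_background(24000, 0.45, seed + i)
               for i in range(3)}
    sim = GenomeSimulator(ContigSet(contigs, "anc"), PARAMS, seed,
                          species_tag="anc")
    tpl = make_template(derive_rng(seed, "tpl"))
    for i in range(2):
        sim.plant(tpl, f"a{i}", 10000, 1.0, "intact")
    return sim, tpl


def test_zero_speciation_time_gives_identical_genomes():
    anc, _ = _tiny_ancestor()
    ga, gb, _ = simulate_species_pair(anc, 0.0)
    assert ga.contigs == gb.contigs


def test_truth_table_bookkeeping_of_shared_and_private_elements():
    anc, tpl = _tiny_ancestor()
    private = [(tpl, "Mpen", "a2", 10000, 0.5, "intact")]
    ga, gb, truth = simulate_species_pair(anc, 2.0, private=private)
    shared_groups = {r.ortholog_group for r in truth if r.ortholog_group}
    assert len(shared_groups) == 2
    assert len(truth.for_species("Mpen")) == 3
    assert len(truth.for_species("Mjav")) == 2
    for r in truth:
        if r.ortholog_group:
            assert r.true_age_myr == pytest.approx(1.0 + 2.0)


def test_descendant_flank_divergence_matches_the_clock():
    """Orthologous flanks after a 16.4 Myr split: raw mismatch fraction per
    site ~ 2 (1 - exp(-R * 16.4e6)) ~ 0.0696 (before multiple-hit effects)."""
    anc, _ = _tiny_ancestor()
    ga, gb, truth = simulate_species_pair(anc, 16.4)
    a = ga["a0"]
    b = gb["a0"]
    mism = sum(x != y for x, y in zip(a, b)) / len(a)
    one_side = 1 - math.exp(-2.2e-9 * 16.4e6)
    expected = 2 * one_side * (1 - one_side / 2)  # overlap of the two paths
    sd = math.sqrt(expected * (1 - expected) / len(a))
    assert abs(mism - expected) < 4 * sd + 2e-3


def test_pair_demo_is_reproducible_and_well_formed():
    ga1, gb1, t1, _ = build_pair_demo(99)
    ga2, gb2, t2, _ = build_pair_demo(99)
    assert ga1.contigs == ga2.contigs
    assert gb1.contigs == gb2.contigs
    assert [r.to_record() for r in t1] == [r.to_record() for r in t2]
    shared = {r.ortholog_group for r in t1 if r.ortholog_group}
    assert len(shared) == 5
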