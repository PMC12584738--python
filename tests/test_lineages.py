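import numpy as np
import pytest

from ervatlas import alignment as al
from ervatlas import lineages as lin
from ervatlas.genome_io import ContigSet, Locus, extract
from ervatlas.synthetic_genome import (GenomeSimulator, SubstitutionParams,
                                       make_background, make_template,
                                       mutate_k2p)

PARAMS = SubstitutionParams()


@pytest.fixture(scope="module")
def five_copy_genome():
    """One lineage planted five times at ages <= 10 Myr."""
    tpl = make_template(np.random.default_rng(50), pbs_trna="Pro")
    genome = ContigSet({"c1": make_background(150000, 0.45, 51)}, "t")
    sim = GenomeSimulator(genome, PARAMS, 52)
    rows = [sim.plant(tpl, "c1", 12000 + 26000 * i, float(2 * i), "intact")
            for i in range(5)]
    return sim.as_contigset(), tpl, rows


def test_all_five_planted_copies_are_recovered(five_copy_genome):
    genome, tpl, rows = five_copy_genome
    query, _, _ = extract(genome, rows[0].locus)
    copies = lin.find_copies(query, genome)
    assert len(copies) == 5
    for row, copy in zip(rows, copies):
        assert copy.locus.overlaps(row.locus)
        assert copy.aligned_len > 4000
        assert copy.identity >= 0.80


def test_short_query_is_rejected(five_copy_genome):
    genome, _, _ = five_copy_genome
    with pytest.raises(al.ParameterError):
        lin.find_copies("ACGT" * 700, genome)


def test_distantly_related_sequence_is_not_a_copy(five_copy_genome):
    genome, tpl, rows = five_copy_genome
    rng = np.random.default_rng(53)
    # ~40% divergence: far below the 80% identity gate
    far = mutate_k2p(tpl.element, PARAMS, 270.0, rng)
    copies = lin.find_copies(far, genome)
    assert all(c.identity >= 0.80 for c in copies)
    assert len(copies) == 0


def test_truncated_copy_fails_the_4kb_gate(five_copy_genome):
    genome, tpl, _ = five_copy_genome
    fragment = tpl.element[:3000]
    bg = ContigSet({"c1": make_background(30000, 0.45, 54)[:12000]
                    + fragment
                    + make_background(30000, 0.45, 55)[:12000]})
    copies = lin.find_copies(tpl.element, bg)
    assert copies == []


# ---------------------------------------------------------------------------
# clustering

def _mutant(seq, divergence_myr, seed):
    return mutate_k2p(seq, PARAMS, divergence_myr, np.random.default_rng(seed))


def test_two_lineages_at_low_cross_identity_form_two_clusters():
    a = make_background(2000, 0.45, 60)
    b = make_background(2000, 0.45, 61)   # unrelated, ~25% identity
    clusters = lin.cluster_lineages([a, _mutant(a, 5, 62), b,
                                     _mutant(b, 5, 63)])
    assert sorted(map(sorted, clusters)) == [[0, 1], [2, 3]]


def test_singleton_cluster(five_copy_genome):
    _, tpl, _ = five_copy_genome
    assert lin.cluster_lineages([tpl.element]) == [[0]]


def test_single_linkage_chains_through_intermediates():
    # a~b and b~c above 90%, a~c below: single linkage joins all three
    base = make_background(3000, 0.45, 64)
    a = base
    b = _mutant(base, 40, 65)    # ~8.4% divergence from a
    c = _mutant(b, 40, 66)       # ~8.4% from b, ~16% from a
    assert lin.global_identity(a, b) > 0.90
    assert lin.global_identity(b, c) > 0.90
    assert lin.global_identity(a, c) < 0.90
    assert lin.cluster_lineages([a, b, c]) == [[0, 1, 2]]


# ---------------------------------------------------------------------------
# consensus

def test_consensus_of_identical_copies_is_the_copy():
    seq = make_background(1000, 0.45, 70)
    assert lin.build_consensus([seq, seq, seq]) == seq


def test_majority_vote_column():
    assert lin.build_consensus(["AAT", "AAT", "GAT"]) == "AAT"


def test_consensus_recovers_the_ancestor_from_diverged_copies():
    """Ten copies at ~2% divergence each: majority vote recovers the
    ancestral sequence to >= 99.9% identity."""
    ancestor = make_background(4000, 0.45, 71)
    copies = [_mutant(ancestor, 9.2, 72 + i) for i in range(10)]
    cons = lin.build_consensus(copies)
    assert lin.global_identity(cons, ancestor) >= 0.999


# ---------------------------------------------------------------------------
# nomenclature

def _copy(contig, start, end):
    return lin.CopyHit(Locus(contig, start, end), end - start, 1.0)


def test_name_scheme_letters_by_copy_number_and_numbers_by_position():
    big = [_copy("c1", 1000 * i, 1000 * i + 500) for i in range(7)]
    small = [_copy("c2", 1000 * i, 1000 * i + 500) for i in range(3)]
    named = lin.assign_names([small, big], ["X", "X"], ["Gamma", "Gamma"],
                             "Msyn")
    by_letter = {l.letter: l for l in named}
    assert by_letter["a"].copies is not None
    assert len(by_letter["a"].copies) == 7
    assert by_letter["a"].copy_names[0] == "ERV-Gamma.a1-Msyn"
    assert by_letter["a"].copy_names[-1] == "ERV-Gamma.a7-Msyn"
    assert by_letter["b"].copy_names == [
        f"ERV-Gamma.b{i}-Msyn" for i in (1, 2, 3)]


def test_solo_lineages_use_the_solo_prefix():
    cl = [[_copy("c1", i * 1000, i * 1000 + 300) for i in range(4)]]
    named = lin.assign_names(cl, ["X"], ["Gamma"], "Msyn", solo=True)
    assert named[0].copy_names == [
        f"SoloLTR-Gamma.a{i}-Msyn" for i in (1, 2, 3, 4)]


def test_equal_size_tie_broken_by_leftmost_coordinate():
    left = [_copy("c1", 100, 600), _copy("c1", 5000, 5500)]
    right = [_copy("c1", 2000, 2500), _copy("c1", 9000, 9500)]
    named = lin.assign_names([right, left], ["X", "X"], ["Beta", "Beta"],
                             "H")
    by_letter = {l.letter: l.copies[0].locus.start for l in named}
    assert by_letter["a"] == 100
    assert by_letter["b"] == 2000


def test_names_parse_back_under_the_scheme():
    parsed = lin.parse_name("ERV-Gamma.aa12-Mpen")
    assert parsed == {"prefix": "ERV", "genus": "Gamma", "letter": "aa",
                      "number": "12", "host": "Mpen"}
    parsed = lin.parse_name("SoloLTR-Beta.b3-Mjav")
    assert parsed["prefix"] == "SoloLTR"
    with pytest.raises(ValueError):
        lin.parse_name("LINE1-x")


def test_more_than_26_lineages_get_extended_letters():
    assert lin._letter(0) == "a"
    assert lin._letter(25) == "z"
    assert lin._letter(26) == "aa"
    assert lin._letter(27) == "ab"


# ---------------------------------------------------------------------------
# solo classification

@pytest.fixture(scope="module")
def solo_genome():
    tpl = make_template(np.random.default_rng(80), pbs_trna="Pro")
    genome = ContigSet({"c1": make_background(120000, 0.45, 81)}, "t")
    sim = GenomeSimulator(genome, PARAMS, 82)
    intact = sim.plant(tpl, "c1", 15000, 2.0, "intact")
    solo = sim.plant(tpl, "c1", 60000, 2.0, "solo")
    # a bare POL remnant (no LTR) 10 kb from a planted extra LTR copy
    g = sim.as_contigset().contigs["c1"]
    remnant = tpl.pol_nt[:2000]
    lone_ltr = tpl.ltr
    g = g + make_background(4000, 0.45, 83) + lone_ltr \
        + make_background(10000, 0.45, 84) + remnant \
        + make_background(5000, 0.45, 85)
    genome = ContigSet({"c1": g}, "t")
    return genome, tpl, intact, solo


def test_solo_rule_separates_solo_from_provirus_and_remnant_ltrs(
        solo_genome):
    genome, tpl, intact, solo = solo_genome
    solos = lin.classify_solo_ltrs(
        {"LTR_q": tpl.ltr}, genome, {"INT_q": tpl.internal},
        host_suffix="Msyn", genus_of={"LTR_q": "Gamma"})
    # only the planted solo LTR qualifies: provirus LTRs have a pair within
    # 15 kb, the lone LTR near the POL remnant is excluded by the remnant
    # rule
    assert len(solos) == 1
    assert solos[0].locus.overlaps(solo.locus)
    assert solos[0].lineage_name.startswith("SoloLTR-Gamma.a1")
    assert solos[0].identity_to_consensus > 0.90
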