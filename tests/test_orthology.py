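import numpy as np
import pytest

from ervatlas import orthology as orth
from ervatlas.genome_io import ContigSet, Locus
from ervatlas.synthetic_genome import (GenomeSimulator, PairDemoSpec,
                                       SubstitutionParams, build_pair_demo,
                                       derive_rng, make_background,
                                       make_template, simulate_species_pair)

PARAMS = SubstitutionParams()


def _small_pair(seed, speciation_myr):
    """One shared + one private element in small genomes (8 kb flanks)."""
    contigs = {f"a{i}": make_background(22000, 0.45, seed + i)
               for i in range(2)}
    anc = GenomeSimulator(ContigSet(contigs, "anc"), PARAMS, seed,
                          species_tag="anc")
    tpl = make_template(derive_rng(seed, "tpl"))
    shared = anc.plant(tpl, "a0", 11000, 1.0, "intact")
    private = [(tpl, "Mpen", "a1", 11000, 1.0, "intact")]
    ga, gb, truth = simulate_species_pair(anc, speciation_myr,
                                          private=private)
    return ga, gb, truth, tpl


def test_flank_pair_extraction_clips_at_contig_ends():
    ga = ContigSet({"c": "ACGT" * 3000})
    loc = Locus("c", 100, 600)
    pair = orth.extract_flank_pair(ga, loc, ga, loc, flank=1000)
    assert len(pair.leftA) == 100
    assert len(pair.rightA) == 1000
    assert pair.insertionA == ga["c"][100:600]


def test_zero_flank_extracts_insertions_only():
    ga = ContigSet({"c": "ACGT" * 3000})
    loc = Locus("c", 100, 600)
    pair = orth.extract_flank_pair(ga, loc, ga, loc, flank=0)
    assert pair.leftA == pair.rightA == ""
    assert pair.flank_lenA == 0


def test_swapping_genomes_mirrors_the_extraction():
    ga = ContigSet({"c": make_background(5000, 0.4, 1)})
    gb = ContigSet({"d": make_background(5000, 0.4, 2)})
    la, lb = Locus("c", 2000, 2500), Locus("d", 1000, 1500)
    ab = orth.extract_flank_pair(ga, la, gb, lb, flank=800)
    ba = orth.extract_flank_pair(gb, lb, ga, la, flank=800)
    assert ab.insertionA == ba.insertionB
    assert ab.leftA == ba.leftB
    assert ab.rightA == ba.rightB


@pytest.mark.parametrize("speciation", [2.0, 8.0, 16.0])
def test_shared_insertion_is_called_ortholog(speciation):
    ga, gb, truth, _ = _small_pair(200, speciation)
    rows = {r.species_tag: [x for x in truth.for_species(r.species_tag)
                            if x.ortholog_group]
            for r in truth}
    locA = rows["Mpen"][0].locus
    locB = rows["Mjav"][0].locus
    params = orth.OrthologyParams(flank=8000)
    pair = orth.extract_flank_pair(ga, locA, gb, locB, flank=params.flank)
    call = orth.call_ortholog(pair, params)
    assert call.verdict == "ortholog"
    assert call.insertion_identity >= 0.85
    assert call.flank_coverage >= 0.50
    # post-hoc audit: every retained alignment respects the length/E gates
    for a in call.flank_alignments:
        assert a.length >= 500
        assert a.evalue <= 1e-5


def test_private_insertion_fails_the_flank_rule():
    ga, gb, truth, _ = _small_pair(210, 8.0)
    priv = [r for r in truth.for_species("Mpen") if not r.ortholog_group][0]
    shared_b = [r for r in truth.for_species("Mjav")
                if r.ortholog_group][0]
    params = orth.OrthologyParams(flank=8000)
    pair = orth.extract_flank_pair(ga, priv.locus, gb, shared_b.locus,
                                   flank=params.flank)
    call = orth.call_ortholog(pair, params)
    # same lineage, so the inserted sequences resemble each other, but the
    # flanks are unrelated: rule (ii) rejects the pair
    assert call.verdict == "not_ortholog"
    assert call.flank_coverage < 0.50


def test_random_flanks_defeat_identical_insertions():
    seq = make_background(2000, 0.45, 3)
    pair = orth.FlankPair(
        locusA=Locus("a", 0, 2000), locusB=Locus("b", 0, 2000),
        insertionA=seq, insertionB=seq,
        leftA=make_background(6000, 0.45, 4),
        rightA=make_background(6000, 0.45, 5),
        leftB=make_background(6000, 0.45, 6),
        rightB=make_background(6000, 0.45, 7),
    )
    call = orth.call_ortholog(pair, orth.OrthologyParams(flank=6000))
    assert call.insertion_identity >= 0.85
    assert call.verdict == "not_ortholog"


def test_verdicts_are_symmetric_under_genome_swap():
    ga, gb, truth, _ = _small_pair(220, 8.0)
    locA = [r for r in truth.for_species("Mpen") if r.ortholog_group][0].locus
    locB = [r for r in truth.for_species("Mjav") if r.ortholog_group][0].locus
    params = orth.OrthologyParams(flank=8000)
    fwd = orth.call_ortholog(
        orth.extract_flank_pair(ga, locA, gb, locB, params.flank), params)
    rev = orth.call_ortholog(
        orth.extract_flank_pair(gb, locB, ga, locA, params.flank), params)
    assert fwd.verdict == rev.verdict == "ortholog"


def test_survey_counts_exactly_the_shared_insertions(pair_demo):
    """Bundled pair demo: five shared ancestral insertions -> exactly five
    ortholog verdicts; private insertions are rejected."""
    ga, gb, truth, _ = pair_demo
    loci_a = [(r.element_id, r.locus) for r in truth.for_species("Mpen")
              if r.state != "solo"]
    cand_b = [r.locus for r in truth.for_species("Mjav")
              if r.state != "solo"]
    calls = orth.survey_orthologs(loci_a, ga, gb, cand_b)
    verdicts = {eid: c.is_ortholog for eid, c in calls}
    shared = {r.element_id for r in truth.for_species("Mpen")
              if r.ortholog_group and r.state != "solo"}
    assert sum(verdicts.values()) == 5
    assert {eid for eid, ok in verdicts.items() if ok} == shared
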