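import numpy as np
import pytest

from ervatlas import ltr_structure as ls
from ervatlas.genome_io import ContigSet, Locus
from ervatlas.synthetic_genome import (GenomeSimulator, SubstitutionParams,
                                       make_background, make_template, plant)

PARAMS = SubstitutionParams()


class FakeCandidate:
    def __init__(self, locus, stage="pol_screen"):
        self.locus = locus
        self.stage = stage


def _planted(seed, age, state="intact", tsd_len=5):
    tpl = make_template(np.random.default_rng(seed), tsd_len=tsd_len,
                        pbs_trna="Pro")
    genome = ContigSet({"c1": make_background(30000, 0.45, seed + 1)}, "t")
    genome, row = plant(genome, tpl, "c1", 12000, age, state, PARAMS,
                        seed + 2)
    return genome, tpl, row


# ---------------------------------------------------------------------------
# find_ltr_pairs

def test_age_zero_provirus_gives_one_perfect_pair():
    genome, tpl, row = _planted(40, 0.0)
    window = genome["c1"]
    pairs = ls.find_ltr_pairs(window, contig="c1")
    assert len(pairs) == 1
    p = pairs[0]
    assert p.similarity == 1.0
    assert (p.ltr5.start, p.ltr5.end) == (row.ltr5.start, row.ltr5.end)
    assert (p.ltr3.start, p.ltr3.end) == (row.ltr3.start, row.ltr3.end)


def test_old_pairs_fall_below_the_similarity_floor():
    """At 40 Myr the expected LTR divergence (~0.176 raw) sits below the
    0.85 similarity floor, so most replicates are rejected."""
    rejected = 0
    n = 30
    for i in range(n):
        genome, _, row = _planted(600 + 3 * i, 40.0)
        pairs = ls.find_ltr_pairs(genome["c1"], contig="c1")
        containing = [p for p in pairs
                      if p.element_span.start <= row.locus.start + 100
                      and row.locus.end - 100 <= p.element_span.end]
        if not containing:
            rejected += 1
    assert rejected / n > 0.5


def test_background_window_has_no_pairs():
    for seed in range(50, 55):
        window = make_background(20000, 0.45, seed)
        assert ls.find_ltr_pairs(window) == []


def test_emitted_pairs_satisfy_the_geometry_invariants():
    params = ls.LtrParams()
    for seed, age in ((60, 0.0), (61, 5.0), (62, 10.0)):
        genome, _, _ = _planted(seed, age)
        for p in ls.find_ltr_pairs(genome["c1"], params, contig="c1"):
            assert params.min_ltr_len <= len(p.ltr5) <= params.max_ltr_len
            assert len(p.ltr5) == len(p.ltr3)
            d = p.ltr3.start - p.ltr5.start
            assert params.min_dist <= d <= params.max_dist
            assert p.similarity >= params.min_similarity
            assert p.ltr5.strand == p.ltr3.strand


def test_reported_similarity_equals_local_alignment_identity():
    genome, _, _ = _planted(70, 8.0)
    cs = ContigSet({"c1": genome["c1"]})
    for p in ls.find_ltr_pairs(genome["c1"], contig="c1"):
        assert ls.pair_similarity_by_alignment(cs, p) == \
            pytest.approx(p.similarity)


# ---------------------------------------------------------------------------
# find_tsd

def test_planted_tsd_is_recovered_on_both_sides():
    genome, _, row = _planted(80, 0.0)
    tsd = ls.find_tsd(genome, row.locus)
    assert tsd is not None
    assert tsd.sequence == row.tsd
    assert tsd.left.end == row.locus.start
    assert tsd.right.start == row.locus.end


def test_no_duplication_means_no_tsd():
    genome = ContigSet({"c1": "ACGTACGTAA" + "G" * 20 + "TTTTCCCCAA"})
    assert ls.find_tsd(genome, Locus("c1", 10, 30)) is None


def test_longer_duplication_wins_ties():
    # both a 6-mer (ACGTAC) and its 4-mer prefix flank the element
    el = "G" * 1200
    genome = ContigSet({"c1": "TTTTTT" + "ACGTAC" + el + "ACGTAC" + "TTTTTT"})
    tsd = ls.find_tsd(genome, Locus("c1", 12, 12 + 1200))
    assert tsd.sequence == "ACGTAC"


# ---------------------------------------------------------------------------
# find_pbs / find_ppt

def test_planted_pbs_found_with_zero_mismatches():
    genome, tpl, row = _planted(90, 0.0)
    element = genome["c1"][row.locus.start:row.locus.end]
    hit = ls.find_pbs(element, row.ltr5.end - row.locus.start)
    assert hit is not None
    assert hit.trna_label == "Pro"
    assert hit.mismatches == 0


def test_mutated_pbs_found_within_mismatch_budget():
    genome, tpl, row = _planted(91, 0.0)
    element = list(genome["c1"][row.locus.start:row.locus.end])
    off = row.ltr5.end - row.locus.start
    element[off] = "A" if element[off] != "A" else "C"
    element[off + 5] = "A" if element[off + 5] != "A" else "C"
    hit = ls.find_pbs("".join(element), off)
    assert hit is not None
    assert hit.mismatches == 2


def test_deleted_pbs_gives_none():
    genome, tpl, row = _planted(92, 0.0)
    element = genome["c1"][row.locus.start:row.locus.end]
    off = row.ltr5.end - row.locus.start
    gutted = element[:off] + "T" * 18 + element[off + 18:]
    assert ls.find_pbs(gutted, off) is None


def test_planted_ppt_detected_with_full_purine_fraction():
    genome, tpl, row = _planted(93, 0.0)
    element = genome["c1"][row.locus.start:row.locus.end]
    ltr3_off = row.ltr3.start - row.locus.start
    hit = ls.find_ppt(element, ltr3_off)
    assert hit is not None
    assert hit.purine_fraction == 1.0


def test_pyrimidine_junction_has_no_ppt():
    element = "ACGT" * 100 + "CTCTCTCTCTCTCTCTCTCT" + "G" * 600
    assert ls.find_ppt(element, 420) is None


def test_ppt_tie_goes_to_the_tract_closest_to_the_ltr():
    tract = "AGGAAGGGGA"
    element = "C" * 300 + tract + "CCCC" + tract + "G" * 600
    hit = ls.find_ppt(element, 324, contig="e")
    assert hit.locus.start == 314
    assert hit.locus.end == 324


# ---------------------------------------------------------------------------
# assembly

def test_intact_element_assembles_full_length_with_all_features():
    genome, tpl, row = _planted(94, 1.0)
    cand = FakeCandidate(Locus("c1", row.locus.start + 1000,
                               row.locus.end - 1000))
    pv = ls.annotate_candidate(genome, cand, element_id="e1")
    assert pv is not None
    assert pv.full_length
    assert pv.tsd is not None and pv.pbs is not None and pv.ppt is not None
    assert pv.internal is not None


def test_solo_ltr_cannot_be_assembled():
    genome, tpl, row = _planted(95, 1.0, state="solo")
    cand = FakeCandidate(Locus("c1", row.locus.start, row.locus.end))
    assert ls.annotate_candidate(genome, cand) is None


def test_pbs_is_optional_for_full_length_status():
    genome, tpl, row = _planted(96, 0.0)
    cand = FakeCandidate(Locus("c1", row.locus.start + 1000,
                               row.locus.end - 1000))
    pv = ls.annotate_candidate(genome, cand,
                               trna_lib={"Zzz": "T" * 18})
    assert pv is not None
    assert pv.full_length
    assert pv.pbs is None


def test_pair_not_containing_candidate_is_rejected():
    genome, tpl, row = _planted(97, 0.0)
    pairs = ls.find_ltr_pairs(genome["c1"], contig="c1")
    outside = FakeCandidate(Locus("c1", 100, 200))
    with pytest.raises(ls.AssemblyError):
        ls.assemble_provirus(outside, pairs[0])
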