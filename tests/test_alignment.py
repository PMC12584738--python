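import math

import numpy as np
import pytest

from ervatlas import alignment as al
from ervatlas.genome_io import ContigSet, revcomp
from ervatlas.synthetic_genome import SubstitutionParams, make_background, \
    mutate_k2p

from .oracles import brute_force_local_score


# ---------------------------------------------------------------------------
# translation

def test_translate_standard_code_and_stop():
    frames = al.translate_six_frames("ATGAAATAG")
    assert frames[0].protein == "MK*"


def test_minus_frames_equal_plus_frames_of_revcomp():
    nt = "ATGAAATAGCCGT"
    rc = revcomp(nt)
    frames = {f.frame: f.protein for f in al.translate_six_frames(nt)}
    rc_frames = {f.frame: f.protein for f in al.translate_six_frames(rc)}
    for f in (1, 2, 3):
        assert frames[-f] == rc_frames[f]


def test_codons_with_n_translate_to_x():
    assert al.translate("ATGNAA") == "MX"


def test_protein_positions_map_back_to_exact_nucleotide_spans():
    nt = "GATGAAATAGCC"
    for ft in al.translate_six_frames(nt):
        for ps in range(len(ft.protein)):
            lo, hi, strand = ft.nt_span(ps, ps + 1)
            codon = nt[lo:hi] if strand == "+" else revcomp(nt[lo:hi])
            assert al.translate(codon) == ft.protein[ps]


# ---------------------------------------------------------------------------
# optimal local alignment

def test_identical_sequences_align_perfectly():
    scoring = al.nucleotide_scoring(match=1, mismatch=-1, gap_open=2,
                                    gap_extend=1)
    aln = al.local_align("ACGTACGTAC", "ACGTACGTAC", scoring=scoring)
    assert aln.score == 10
    assert aln.identity == 1.0


def test_disjoint_alphabets_give_the_empty_alignment():
    scoring = al.nucleotide_scoring(match=1, mismatch=-1, gap_open=2,
                                    gap_extend=1)
    aln = al.local_align("AAAA", "GGGG", scoring=scoring)
    assert aln.is_empty
    assert aln.score == 0


def test_local_score_is_symmetric():
    a, b = "ACGTTGCA", "ACGTCA"
    assert al.local_align(a, b).score == al.local_align(b, a).score


def test_smith_waterman_matches_exhaustive_enumeration():
    """20 random 8-mer pairs against a brute-force oracle that enumerates
    every substring pair under the same affine scheme."""
    rng = np.random.default_rng(42)
    scoring = al.nucleotide_scoring()

    def sub(x, y):
        return scoring.substitution(x, y)

    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), 8))
        b = "".join(rng.choice(list("ACGT"), 8))
        expected = brute_force_local_score(a, b, sub, scoring.gap_open,
                                           scoring.gap_extend)
        assert al.local_align(a, b, scoring=scoring).score == expected


def test_n_never_counts_as_identity():
    aln = al.local_align("ACGTNACGT", "ACGTNACGT")
    assert aln.n_ident <= 8


# ---------------------------------------------------------------------------
# E-values

def test_evalue_is_linear_in_database_length():
    e1 = al.estimate_evalue(50, 100, 1000, "blosum62")
    e2 = al.estimate_evalue(50, 100, 2000, "blosum62")
    assert e2 == pytest.approx(2 * e1)


def test_evalue_decreases_monotonically_with_score():
    evs = [al.estimate_evalue(s, 100, 1000, "blosum62")
           for s in range(0, 200, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


def test_evalue_closed_form():
    al.KARLIN_PARAMS["unit_test"] = (math.log(2), 1.0)
    try:
        assert al.estimate_evalue(10, 1, 1, "unit_test") == \
            pytest.approx(2.0 ** -10)
    finally:
        del al.KARLIN_PARAMS["unit_test"]


def test_unknown_scheme_is_a_parameter_error():
    with pytest.raises(al.ParameterError):
        al.estimate_evalue(10, 1, 1, "nonsense")


# ---------------------------------------------------------------------------
# seeded search

@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    bg = make_background(40000, 0.45, rng)
    query = make_background(600, 0.45, rng)
    genome = ContigSet({"c1": bg[:15000] + query + bg[15000:]}, "t")
    return query, genome


def test_verbatim_query_gives_one_perfect_hit(planted):
    query, genome = planted
    hits = al.seeded_search(query, genome, al.SearchParams.nucleotide())
    assert len(hits) == 1
    h = hits[0]
    assert h.identity == 1.0
    assert h.coverage == 1.0
    assert (h.subject_locus.start, h.subject_locus.end) == (15000, 15600)


def test_minus_strand_hit_reports_forward_locus(planted):
    query, genome = planted
    rc_genome = ContigSet({"c1": revcomp(genome["c1"])})
    hits = al.seeded_search(query, rc_genome, al.SearchParams.nucleotide())
    assert len(hits) == 1
    h = hits[0]
    assert h.subject_locus.strand == "-"
    extracted = revcomp(
        rc_genome["c1"][h.subject_locus.start:h.subject_locus.end])
    assert extracted == query


def test_absent_query_finds_nothing(planted):
    _, genome = planted
    rng = np.random.default_rng(13)
    misses = 0
    for _ in range(20):
        decoy = make_background(600, 0.45, rng)
        if not al.seeded_search(decoy, genome,
                                al.SearchParams.nucleotide()):
            misses += 1
    assert misses >= 19


def test_sensitivity_to_85_percent_identity_queries(planted):
    """Recall >= 0.95 for planted queries mutated to ~85% identity."""
    _, genome = planted
    rng = np.random.default_rng(99)
    params = SubstitutionParams(kappa=2.0)
    found = 0
    n = 40
    for _ in range(n):
        query = genome["c1"][15000:15600]
        mutated = mutate_k2p(query, params, 74.0, rng)  # ~15% divergence
        hits = al.seeded_search(mutated, genome,
                                al.SearchParams.nucleotide())
        if any(h.subject_locus.start < 15600
               and h.subject_locus.end > 15000 and h.coverage > 0.5
               for h in hits):
            found += 1
    assert found / n >= 0.95


def test_hits_rescored_by_local_align_are_self_consistent(planted):
    """Reported identity/score of re-scored hits equal the optimal local
    alignment of the reported ranges."""
    _, genome = planted
    rng = np.random.default_rng(5)
    params = SubstitutionParams(kappa=2.0)
    query = mutate_k2p(genome["c1"][15000:15600], params, 30.0, rng)
    hits = al.seeded_search(query, genome, al.SearchParams.nucleotide())
    assert hits
    for h in hits:
        if h.query_span > 3000 or h.subject_locus.strand != "+":
            continue
        sub = genome[h.subject_locus.contig][
            h.subject_locus.start:h.subject_locus.end]
        aln = al.local_align(query[h.query_start:h.query_end], sub)
        assert aln.score == pytest.approx(h.score)
        assert aln.identity == pytest.approx(h.identity)


def test_protein_query_on_minus_strand_reports_frame_and_locus():
    rng = np.random.default_rng(21)
    protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), 120))
    from ervatlas.synthetic_genome import _reverse_translate
    cds = _reverse_translate(list(protein), rng)
    bg = make_background(8000, 0.45, rng)
    genome = ContigSet({"c1": bg[:3000] + revcomp(cds) + bg[3000:]})
    hits = al.seeded_search(protein, genome, al.SearchParams.protein())
    assert hits
    best = hits[0]
    assert best.frame < 0
    assert best.subject_locus.strand == "-"
    assert best.subject_locus.start >= 3000 - 3
    assert best.subject_locus.end <= 3000 + len(cds) + 3
    assert best.identity == 1.0


def test_degenerate_seed_parameters_are_rejected(planted):
    _, genome = planted
    with pytest.raises(al.ParameterError):
        al.seeded_search("ACGT", genome, al.SearchParams.nucleotide())
    with pytest.raises(al.ParameterError):
        al.seeded_search("", genome, al.SearchParams.nucleotide())
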