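"""Orthologous-insertion calling between two genomes.

Two insertions are orthologous — evidence that the element integrated in a
common ancestor and was inherited vertically — when the inserted sequences
match and the host DNA around them is syntenic. Operationally: extract the
insertion regions plus 30,000 bp of flanking sequence on each side, run a
discontiguous-seed nucleotide search between them (the dc-megablast
dialect), discard alignments shorter than 500 bp or weaker than E = 1e-5,
and call ortholog iff (i) insertion identity >= 85% and (ii) the retained
flank alignments cover >= 50% of the achieved flank length (union over both
flanks, computed on genome A's coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import alignment as al
from .genome_io import ContigSet, Locus, extract
from .lineages import global_identity


@dataclass
class OrthologyParams:
    flank: int = 30000
    min_insertion_identity: float = 0.85
    min_flank_coverage: float = 0.50
    min_aln_len: int = 500
    evalue_cutoff: float = 1e-5
    prefilter_identity: float = 0.50    # cheap gate before the full search


@dataclass
class FlankPair:
    """Insertion regions and flanks of a candidate ortholog pair."""

    locusA: Locus
    locusB: Locus
    insertionA: str
    insertionB: str
    leftA: str
    rightA: str
    leftB: str
    rightB: str

    @property
    def flank_lenA(self) -> int:
        return len(self.leftA) + len(self.rightA)


@dataclass
class FlankAlignment:
    sideA: str              # left | right
    rangeA: tuple[int, int]  # within that A flank
    rangeB: tuple[int, int]
    identity: float
    length: int
    evalue: float


@dataclass
class OrthologCall:
    locusA: Locus
    locusB: Locus
    insertion_identity: float
    flank_coverage: float
    flank_alignments: list[FlankAlignment]
    verdict: str            # ortholog | not_ortholog

    @property
    def is_ortholog(self) -> bool:
        return self.verdict == "ortholog"

    def to_record(self) -> dict[str, object]:
        return {
            "contigA": self.locusA.contig, "startA": self.locusA.start,
            "endA": self.locusA.end,
            "contigB": self.locusB.contig, "startB": self.locusB.start,
            "endB": self.locusB.end,
            "insertion_identity": f"{self.insertion_identity:.4f}",
            "flank_coverage": f"{self.flank_coverage:.4f}",
            "n_flank_alignments": len(self.flank_alignments),
            "verdict": self.verdict,
        }


def extract_flank_pair(genomeA: ContigSet, locusA: Locus,
                       genomeB: ContigSet, locusB: Locus,
                       flank: int = 30000) -> FlankPair:
    """Insertion regions plus up-to-``flank`` bp of context, clipped at
    contig ends (achieved lengths are simply the returned string lengths)."""
    genomeA.validate(locusA)
    genomeB.validate(locusB)

    def parts(genome: ContigSet, locus: Locus) -> tuple[str, str, str]:
        seq = genome[locus.contig]
        left = seq[max(0, locus.start - flank):locus.start]
        right = seq[locus.end:locus.end + flank]
        return left, seq[locus.start:locus.end], right

    la, ia, ra = parts(genomeA, locusA)
    lb, ib, rb = parts(genomeB, locusB)
    return FlankPair(locusA=locusA, locusB=locusB, insertionA=ia,
                     insertionB=ib, leftA=la, rightA=ra, leftB=lb, rightB=rb)


def _best_chained_identity(a: str, b: str, params: OrthologyParams) -> float:
    """Identity of the best chained dc-megablast alignment of two regions."""
    if not a or not b:
        return 0.0
    if len(a) < 28 or len(b) < 28:
        return global_identity(a, b)
    sp = al.SearchParams.dc_megablast(evalue_cutoff=params.evalue_cutoff,
                                      rescore_cap=0)
    subject = ContigSet({"region": b})
    try:
        hits = al.seeded_search(a, subject, sp, "insertion")
    except al.ParameterError:
        return global_identity(a, b)
    if not hits:
        return 0.0
    best = max(hits, key=lambda h: h.score)
    return best.identity


def call_ortholog(pair: FlankPair, params: OrthologyParams | None = None,
                  ) -> OrthologCall:
    """Apply the flank-homology decision rule to one extracted pair."""
    params = params or OrthologyParams()
    ins_ident = _best_chained_identity(pair.insertionA, pair.insertionB,
                                       params)

    sp = al.SearchParams.dc_megablast(evalue_cutoff=params.evalue_cutoff,
                                      rescore_cap=0)
    alignments: list[FlankAlignment] = []
    covered: dict[str, set[tuple[int, int]]] = {"left": set(), "right": set()}
    for sideA, flankA in (("left", pair.leftA), ("right", pair.rightA)):
        if len(flankA) < 28:
            continue
        subject_contigs = {}
        if len(pair.leftB) >= 28:
            subject_contigs["left"] = pair.leftB
        if len(pair.rightB) >= 28:
            subject_contigs["right"] = pair.rightB
        if not subject_contigs:
            continue
        subject = ContigSet(subject_contigs)
        for h in al.seeded_search(flankA, subject, sp, f"flank_{sideA}"):
            if h.aln_cols < params.min_aln_len or \
                    h.evalue > params.evalue_cutoff:
                continue
            alignments.append(FlankAlignment(
                sideA=sideA,
                rangeA=(h.query_start, h.query_end),
                rangeB=(h.subject_locus.start, h.subject_locus.end),
                identity=h.identity, length=h.aln_cols, evalue=h.evalue))
            covered[sideA].add((h.query_start, h.query_end))

    total_flank = pair.flank_lenA
    covered_len = 0
    for side in ("left", "right"):
        ranges = sorted(covered[side])
        last_end = -1
        for s, e in ranges:
            s = max(s, last_end)
            if e > s:
                covered_len += e - s
                last_end = e
    coverage = covered_len / total_flank if total_flank else 0.0
    verdict = ("ortholog"
               if ins_ident >= params.min_insertion_identity
               and coverage >= params.min_flank_coverage
               else "not_ortholog")
    return OrthologCall(
        locusA=pair.locusA, locusB=pair.locusB,
        insertion_identity=ins_ident, flank_coverage=coverage,
        flank_alignments=alignments, verdict=verdict,
    )


def survey_orthologs(lociA: list[tuple[str, Locus]], genomeA: ContigSet,
                     genomeB: ContigSet, candidatesB: list[Locus],
                     params: OrthologyParams | None = None,
                     ) -> list[tuple[str, OrthologCall]]:
    """Pair every A element against B candidate loci; report the best
    partner per A element (highest flank coverage, then insertion identity).

    A cheap insertion-identity prefilter skips pairs that cannot reach the
    85% rule before running the full flank search.
    """
    params = params or OrthologyParams()
    results: list[tuple[str, OrthologCall]] = []
    for element_id, locA in lociA:
        best: OrthologCall | None = None
        insA = genomeA[locA.contig][locA.start:locA.end]
        for locB in candidatesB:
            insB = genomeB[locB.contig][locB.start:locB.end]
            ratio = min(len(insA), len(insB)) / max(len(insA), len(insB))
            if ratio < 0.5 or \
                    global_identity(insA, insB) < params.prefilter_identity:
                continue
            pair = extract_flank_pair(genomeA, locA, genomeB, locB,
                                      flank=params.flank)
            call = call_ortholog(pair, params)
            if best is None or (call.flank_coverage,
                                call.insertion_identity) > \
                    (best.flank_coverage, best.insertion_identity):
                best = call
        if best is not None:
            results.append((element_id, best))
    return results
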