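"""Two-stage candidate screening for ERV loci.

Stage one mirrors a Diamond-BLASTx/tBLASTn screen: retroviral POL protein
probes searched against the translated genome, keeping hits with >=30%
identity covering >=40% of the probe at E <= 1e-5. Stage two mirrors the
cross-species BLASTn step: an RT (reverse transcriptase) consensus searched
against a second genome at >=80% identity over >=80% of the query. Raw hits
within a merge gap on the same strand are merged into one candidate locus;
overlapping redundant hits are deduplicated automatically (best E-value
wins), replacing the manual curation a human screener would do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import alignment as al
from .genome_io import ContigSet, Locus


@dataclass
class ScreenParams:
    """Filters of the two screening stages."""

    min_identity: float = 0.30      # POL protein screen
    min_coverage: float = 0.40
    evalue_cutoff: float = 1e-5
    merge_gap: int = 1000           # same-strand hit merging
    rt_min_identity: float = 0.80   # cross-species RT stage
    rt_min_coverage: float = 0.80
    rt_min_len: int = 200


@dataclass
class CandidateLocus:
    """A merged cluster of screening hits marking one putative ERV locus."""

    locus: Locus
    supporting_hits: list[al.AlignmentHit]
    best_query_id: str
    stage: str = "pol_screen"

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.supporting_hits)


def _merge_hits(hits: list[al.AlignmentHit], merge_gap: int,
                stage: str) -> list[CandidateLocus]:
    """Merge hits within ``merge_gap`` bp on the same contig+strand."""
    hits = sorted(hits, key=lambda h: (h.subject_locus.contig,
                                       h.subject_locus.strand,
                                       h.subject_locus.start,
                                       h.subject_locus.end))
    out: list[CandidateLocus] = []
    group: list[al.AlignmentHit] = []

    def flush() -> None:
        if not group:
            return
        start = min(h.subject_locus.start for h in group)
        end = max(h.subject_locus.end for h in group)
        best = min(group, key=lambda h: (h.evalue, -h.score))
        out.append(CandidateLocus(
            locus=Locus(group[0].subject_locus.contig, start, end,
                        group[0].subject_locus.strand),
            supporting_hits=list(group),
            best_query_id=best.query_id,
            stage=stage,
        ))

    for h in hits:
        if group and (
                h.subject_locus.contig == group[-1].subject_locus.contig
                and h.subject_locus.strand == group[-1].subject_locus.strand
                and h.subject_locus.start
                - max(g.subject_locus.end for g in group) <= merge_gap):
            group.append(h)
        else:
            flush()
            group = [h]
    flush()
    out.sort(key=lambda c: (c.locus.contig, c.locus.start))
    return out


def screen_genome(pol_queries: dict[str, str], genome: ContigSet,
                  params: ScreenParams | None = None,
                  search_params: al.SearchParams | None = None,
                  ) -> list[CandidateLocus]:
    """Translated-homology screen of protein probes against a genome.

    ``pol_queries`` maps probe ids to protein sequences. Hits passing the
    identity/coverage/E-value filters are merged into candidate loci; each
    candidate records all supporting hits and the id of its best probe.
    """
    if not pol_queries:
        raise al.ParameterError("screen_genome needs at least one probe")
    params = params or ScreenParams()
    sp = search_params or al.SearchParams.protein(
        evalue_cutoff=params.evalue_cutoff)
    kept: list[al.AlignmentHit] = []
    for qid, protein in sorted(pol_queries.items()):
        for h in al.seeded_search(protein, genome, sp, query_id=qid):
            if (h.identity >= params.min_identity
                    and h.coverage >= params.min_coverage
                    and h.evalue <= params.evalue_cutoff):
                kept.append(h)
    return _merge_hits(kept, params.merge_gap, stage="pol_screen")


def rt_cross_species_search(rt_consensus: str, other_genome: ContigSet,
                            params: ScreenParams | None = None,
                            search_params: al.SearchParams | None = None,
                            query_id: str = "RT_consensus",
                            ) -> list[CandidateLocus]:
    """Nucleotide search of an RT consensus in a second species' genome.

    Retains hits with >=80% identity covering >=80% of the query; each
    retained hit cluster becomes one candidate locus.
    """
    params = params or ScreenParams()
    if len(rt_consensus) < params.rt_min_len:
        raise al.ParameterError(
            f"RT consensus must be >= {params.rt_min_len} bp")
    sp = search_params or al.SearchParams.nucleotide(
        evalue_cutoff=params.evalue_cutoff)
    kept = [
        h for h in al.seeded_search(rt_consensus, other_genome, sp,
                                    query_id=query_id)
        if h.identity >= params.rt_min_identity
        and h.coverage >= params.rt_min_coverage
    ]
    return _merge_hits(kept, params.merge_gap, stage="rt_cross_species")
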