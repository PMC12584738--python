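"""Lineage assembly: genome-wide copy retrieval, clustering at >90%
identity, consensus construction, solo-LTR classification and nomenclature.

A lineage is a family of insertions descending from one endogenization
event. Full-length elements are used as queries to retrieve copies (chained
aligned length > 4 kb at >= 80% identity); copies are clustered by
single-linkage at > 90% pairwise identity and summarized by a per-column
majority consensus. Solo LTRs — the scar left when LTR–LTR recombination
deletes the internal region and one LTR — are LTR-consensus hits with no
paired LTR partner and no internal-region remnant within 15,000 bp.

Names follow the ERV nomenclature scheme ERV-<Genus>.<letter><n>-<host>:
letters rank lineages by descending copy number (ties by leftmost copy),
copies are numbered in genomic order, and solo lineages carry the SoloLTR-
prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from . import alignment as al
from .genome_io import ContigSet, Locus, extract


@dataclass
class LineageParams:
    min_copy_len: int = 4000        # chained aligned length gate
    min_copy_identity: float = 0.80
    cluster_identity: float = 0.90  # single-linkage threshold (exclusive)
    copy_merge_gap: int = 2000      # chaining window for one locus
    evalue_cutoff: float = 1e-5
    solo_min_coverage: float = 0.10
    solo_min_identity: float = 0.80
    solo_window: int = 15000        # no pair / no remnant within this
    pair_min_dist: int = 1000
    pair_max_dist: int = 15000
    max_consensus_gap_fraction: float = 0.5


# ---------------------------------------------------------------------------
# pairwise identity (global, edit-distance based)

def global_identity(a: str, b: str) -> float:
    """Global alignment identity of two sequences, 1 - edits/alignment_len."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    dist = res["editDistance"]
    return max(0.0, 1.0 - dist / max(len(a), len(b)))


# ---------------------------------------------------------------------------
# copy retrieval

@dataclass
class CopyHit:
    """One genomic copy of a lineage query: chained hit cluster on a locus."""

    locus: Locus
    aligned_len: int
    identity: float


def find_copies(full_length_query: str, genome: ContigSet,
                params: LineageParams | None = None,
                search_params: al.SearchParams | None = None,
                ) -> list[CopyHit]:
    """Genome-wide copies of a full-length element.

    Hits are chained per locus (same contig/strand within the merge gap);
    loci whose chained aligned length exceeds 4 kb at >= 80% identity
    (computed over aligned columns, gaps excluded) are copies.
    """
    params = params or LineageParams()
    if len(full_length_query) < params.min_copy_len:
        raise al.ParameterError(
            f"lineage query must be >= {params.min_copy_len} bp")
    sp = search_params or al.SearchParams.nucleotide(
        evalue_cutoff=params.evalue_cutoff, rescore_cap=0)
    hits = al.seeded_search(full_length_query, genome, sp, "lineage_query")
    hits.sort(key=lambda h: (h.subject_locus.contig, h.subject_locus.strand,
                             h.subject_locus.start))
    out: list[CopyHit] = []
    group: list[al.AlignmentHit] = []

    def flush() -> None:
        if not group:
            return
        aligned = sum(h.aln_cols for h in group)
        n_ident = sum(h.n_ident for h in group)
        if aligned > params.min_copy_len and \
                n_ident / aligned >= params.min_copy_identity:
            start = min(h.subject_locus.start for h in group)
            end = max(h.subject_locus.end for h in group)
            out.append(CopyHit(
                locus=Locus(group[0].subject_locus.contig, start, end,
                            group[0].subject_locus.strand),
                aligned_len=aligned, identity=n_ident / aligned))

    for h in hits:
        if group and (
                h.subject_locus.contig == group[-1].subject_locus.contig
                and h.subject_locus.strand == group[-1].subject_locus.strand
                and h.subject_locus.start
                - max(g.subject_locus.end for g in group)
                <= params.copy_merge_gap):
            group.append(h)
        else:
            flush()
            group = [h]
    flush()
    out.sort(key=lambda c: (c.locus.contig, c.locus.start))
    return out


# ---------------------------------------------------------------------------
# clustering & consensus

def cluster_lineages(copies: list[str],
                     params: LineageParams | None = None) -> list[list[int]]:
    """Single-linkage partition of copy sequences at > 90% global identity.

    Returns index lists; clusters are ordered by their smallest member index
    (which is genomic order when callers pass copies in genomic order).
    """
    params = params or LineageParams()
    if not copies:
        raise al.ParameterError("cluster_lineages needs at least one copy")
    n = len(copies)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if global_identity(copies[i], copies[j]) > params.cluster_identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def _edlib_columns(seq: str, ref: str) -> list[str]:
    """Per-ref-column characters of ``seq`` aligned globally to ``ref``.

    Star-alignment helper: columns are the reference positions; characters
    of ``seq`` inserted relative to the reference are dropped, deletions
    appear as '-'.
    """
    res = edlib.align(seq, ref, task="path")
    cigar = res["cigar"]
    cols: list[str] = []
    qi = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "M", "X"):
            cols.extend(seq[qi:qi + n])
            qi += n
        elif ch == "I":       # in seq, absent from ref
            qi += n
        elif ch == "D":       # absent from seq
            cols.extend("-" * n)
    return cols


def build_consensus(cluster: list[str],
                    params: LineageParams | None = None) -> str:
    """Majority-vote consensus of a cluster (star alignment to the longest
    member; ties at a column go to the earliest copy; columns gapped in more
    than half the rows are dropped). Singletons pass through unchanged."""
    params = params or LineageParams()
    if not cluster:
        raise al.ParameterError("empty cluster")
    if len(cluster) == 1:
        return cluster[0]
    ref_idx = max(range(len(cluster)), key=lambda i: (len(cluster[i]), -i))
    ref = cluster[ref_idx]
    rows: list[list[str]] = []
    for i, seq in enumerate(cluster):
        rows.append(list(ref) if i == ref_idx else _edlib_columns(seq, ref))
    out: list[str] = []
    n_rows = len(rows)
    for col in range(len(ref)):
        votes: dict[str, int] = {}
        order: dict[str, int] = {}
        for ri, row in enumerate(rows):
            c = row[col]
            votes[c] = votes.get(c, 0) + 1
            order.setdefault(c, ri)
        if votes.get("-", 0) / n_rows > params.max_consensus_gap_fraction:
            continue
        votes.pop("-", None)
        if not votes:
            continue
        best = max(votes, key=lambda c: (votes[c], -order[c]))
        out.append(best)
    return "".join(out)


# ---------------------------------------------------------------------------
# nomenclature

def _letter(rank: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, 27 -> ab, ..."""
    letters = ""
    rank += 1
    while rank > 0:
        rank, rem = divmod(rank - 1, 26)
        letters = chr(ord("a") + rem) + letters
    return letters


@dataclass
class Lineage:
    """A named ERV family: its copies, consensus, and genus assignment."""

    name: str                       # e.g. ERV-Gamma.a-Msyn
    genus_label: str
    letter: str
    host: str
    copies: list[CopyHit]
    consensus: str
    copy_names: list[str] = field(default_factory=list)
    solo: bool = False


def assign_names(clusters: list[list[CopyHit]], consensuses: list[str],
                 genus_labels: list[str], host_suffix: str,
                 solo: bool = False) -> list[Lineage]:
    """Apply the ERV-<Genus>.<letter><n>-<host> scheme to clusters.

    Within each genus, letters a, b, c, ... rank clusters by descending copy
    number (ties by leftmost genomic coordinate); copies are numbered 1..n in
    genomic order. Solo lineages use the SoloLTR- prefix.
    """
    if not (len(clusters) == len(consensuses) == len(genus_labels)):
        raise al.ParameterError("clusters/consensuses/labels length mismatch")
    prefix = "SoloLTR" if solo else "ERV"
    order = sorted(
        range(len(clusters)),
        key=lambda i: (genus_labels[i], -len(clusters[i]),
                       min((c.locus.contig, c.locus.start)
                           for c in clusters[i])),
    )
    rank_in_genus: dict[str, int] = {}
    lineages: list[Lineage] = []
    for i in order:
        genus = genus_labels[i]
        rank = rank_in_genus.get(genus, 0)
        rank_in_genus[genus] = rank + 1
        letter = _letter(rank)
        copies = sorted(clusters[i],
                        key=lambda c: (c.locus.contig, c.locus.start))
        name = f"{prefix}-{genus}.{letter}-{host_suffix}"
        copy_names = [f"{prefix}-{genus}.{letter}{n + 1}-{host_suffix}"
                      for n in range(len(copies))]
        lineages.append(Lineage(
            name=name, genus_label=genus, letter=letter, host=host_suffix,
            copies=copies, consensus=consensuses[i], copy_names=copy_names,
            solo=solo,
        ))
    lineages.sort(key=lambda l: (l.genus_label, l.letter))
    return lineages


def parse_name(name: str) -> dict[str, str]:
    """Split an ERV/SoloLTR name back into its scheme components."""
    prefix, _, rest = name.partition("-")
    if prefix not in ("ERV", "SoloLTR") or "." not in rest:
        raise ValueError(f"not an ERV nomenclature name: {name!r}")
    genus, _, tail = rest.partition(".")
    letter_n, _, host = tail.partition("-")
    letter = letter_n.rstrip("0123456789")
    number = letter_n[len(letter):]
    return {"prefix": prefix, "genus": genus, "letter": letter,
            "number": number, "host": host}


# ---------------------------------------------------------------------------
# solo LTR classification

@dataclass
class SoloLtr:
    locus: Locus
    lineage_name: str
    identity_to_consensus: float


def classify_solo_ltrs(ltr_queries: dict[str, str], genome: ContigSet,
                       internal_queries: dict[str, str],
                       params: LineageParams | None = None,
                       host_suffix: str = "host",
                       genus_of: dict[str, str] | None = None,
                       ) -> list[SoloLtr]:
    """Classify lone LTR hits as solo LTRs.

    LTR-consensus hits at E <= 1e-5 with > 10% coverage and > 80% identity
    are solo iff (i) no second qualifying LTR hit forms a valid pair
    (same strand, start distance within [1000, 15000] bp) and (ii) no
    internal-region remnant hit lies within 15,000 bp on either side.
    Survivors are grouped at > 90% identity into named SoloLTR lineages.
    """
    params = params or LineageParams()
    sp = al.SearchParams.nucleotide(evalue_cutoff=params.evalue_cutoff)

    ltr_hits: list[tuple[str, al.AlignmentHit]] = []
    for qid, seq in sorted(ltr_queries.items()):
        for h in al.seeded_search(seq, genome, sp, query_id=qid):
            if (h.evalue <= params.evalue_cutoff
                    and h.coverage > params.solo_min_coverage
                    and h.identity > params.solo_min_identity):
                ltr_hits.append((qid, h))
    # deduplicate overlapping hits from different LTR queries (keep best)
    ltr_hits.sort(key=lambda t: (t[1].subject_locus.contig,
                                 t[1].subject_locus.start, t[1].evalue))
    dedup: list[tuple[str, al.AlignmentHit]] = []
    for qid, h in ltr_hits:
        if dedup and dedup[-1][1].subject_locus.overlaps(h.subject_locus):
            continue
        dedup.append((qid, h))

    remnants: list[Locus] = []
    for qid, seq in sorted(internal_queries.items()):
        for h in al.seeded_search(seq, genome, sp, query_id=qid):
            if h.evalue <= params.evalue_cutoff and h.aln_cols >= 100:
                remnants.append(h.subject_locus)

    solos: list[tuple[str, al.AlignmentHit]] = []
    for qid, h in dedup:
        loc = h.subject_locus
        paired = False
        for qid2, h2 in dedup:
            if h2 is h:
                continue
            loc2 = h2.subject_locus
            if loc2.contig != loc.contig or loc2.strand != loc.strand:
                continue
            d = abs(loc2.start - loc.start)
            if params.pair_min_dist <= d <= params.pair_max_dist:
                paired = True
                break
        if paired:
            continue
        near_remnant = any(
            r.contig == loc.contig and r.start < loc.end + params.solo_window
            and loc.start - params.solo_window < r.end
            for r in remnants)
        if near_remnant:
            continue
        solos.append((qid, h))

    if not solos:
        return []

    seqs = [extract(genome, h.subject_locus)[0] for _, h in solos]
    clusters = cluster_lineages(seqs, params)
    cluster_hits = [[CopyHit(solos[i][1].subject_locus,
                             solos[i][1].aln_cols, solos[i][1].identity)
                     for i in idxs] for idxs in clusters]
    consensuses = [build_consensus([seqs[i] for i in idxs], params)
                   for idxs in clusters]
    genus_of = genus_of or {}
    labels = [genus_of.get(solos[idxs[0]][0], "unassigned")
              for idxs in clusters]
    named = assign_names(cluster_hits, consensuses, labels, host_suffix,
                         solo=True)
    out: list[SoloLtr] = []
    for lineage in named:
        for copy, cname in zip(lineage.copies, lineage.copy_names):
            seq, _, _ = extract(genome, copy.locus)
            out.append(SoloLtr(
                locus=copy.locus, lineage_name=cname,
                identity_to_consensus=global_identity(seq, lineage.consensus),
            ))
    out.sort(key=lambda s: (s.locus.contig, s.locus.start))
    return out
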