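"""Paired-LTR detection and PBS/PPT/TSD annotation around candidate loci.

This is the native stand-in for the LTR_FINDER / LTR_harvest stage. Geometry
follows the canonical parameter set for retroviral elements: LTR length in
[100, 7000] bp, distance between the LTR starts in [1000, 15000] bp, and a
similarity floor of 0.85 between the two LTRs of one element. Pairs are found
by seeded self-comparison restricted to same-strand direct repeats, with
ungapped X-drop extension fixing the boundaries; PBS, PPT and TSD are
annotations, not gating requirements — only paired LTRs plus an internal
region make an element full-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alignment as al
from .genome_io import ContigSet, Locus, extract, revcomp
from .trna_library import SYNTHETIC_TRNA_3P_18MERS


@dataclass
class LtrParams:
    """Geometry and annotation thresholds of the structural caller."""

    min_ltr_len: int = 100
    max_ltr_len: int = 7000
    min_dist: int = 1000          # distance between 5' and 3' LTR starts
    max_dist: int = 15000
    min_similarity: float = 0.85
    seed_len: int = 12
    seed_window: int = 150        # two-hit chaining window on one diagonal
    xdrop: float = 25.0
    tsd_min: int = 4
    tsd_max: int = 6
    pbs_offset_max: int = 20
    pbs_mismatch_max: int = 2
    ppt_offset_max: int = 20
    ppt_min_len: int = 10
    ppt_max_len: int = 40
    ppt_purine_fraction: float = 0.9
    window_flank: int = 8000      # context extracted around a candidate


@dataclass(frozen=True)
class LtrPair:
    """Two same-strand direct repeats forming the LTRs of one element."""

    ltr5: Locus
    ltr3: Locus
    similarity: float

    @property
    def element_span(self) -> Locus:
        return Locus(self.ltr5.contig, self.ltr5.start, self.ltr3.end,
                     self.ltr5.strand)

    @property
    def ltr_len(self) -> int:
        return len(self.ltr5)


@dataclass(frozen=True)
class PbsHit:
    locus: Locus
    trna_label: str
    mismatches: int


@dataclass(frozen=True)
class PptHit:
    locus: Locus
    purine_fraction: float


@dataclass(frozen=True)
class Tsd:
    left: Locus
    right: Locus
    sequence: str


class AssemblyError(ValueError):
    """Candidate and LTR pair cannot be combined into one provirus."""


# ---------------------------------------------------------------------------
# paired-LTR search

def find_ltr_pairs(window: str, params: LtrParams | None = None,
                   contig: str = "window", origin: int = 0) -> list[LtrPair]:
    """Direct-repeat pairs in ``window`` satisfying the LTR geometry.

    Seeded self-comparison: exact k-mer matches at diagonal offsets within
    [min_dist, max_dist] are chained per diagonal and extended ungapped with
    X-drop; endpoints maximize the extension score, which refines the
    boundaries to matching columns. Overlapping candidates are resolved by
    (highest similarity, longest LTR, leftmost). Coordinates are reported on
    ``contig`` shifted by ``origin``.
    """
    params = params or LtrParams()
    if len(window) < 1200:
        return []
    arr = al.encode_nt(window)
    k = params.seed_len
    words = al._contiguous_words(arr, k, 4)
    index = al._index_words(words)
    scoring = al.nucleotide_scoring()
    mat = scoring.matrix

    qpos_list, spos_list = [], []
    for w, positions in index.items():
        if len(positions) < 2:
            continue
        pos = np.sort(positions)
        # all ordered pairs within the allowed diagonal band
        for i_idx in range(len(pos) - 1):
            i = int(pos[i_idx])
            js = pos[i_idx + 1:]
            js = js[(js - i >= params.min_dist) & (js - i <= params.max_dist)]
            if len(js):
                qpos_list.append(np.full(len(js), i, dtype=np.int64))
                spos_list.append(js.astype(np.int64))
    if not qpos_list:
        return []
    qpos = np.concatenate(qpos_list)
    spos = np.concatenate(spos_list)
    clusters = al._two_hit_clusters(qpos, spos, params.seed_window)

    raw: list[tuple[int, int, int, float, int]] = []  # q0, q1, diag, sim, nid
    seen: set[tuple[int, int, int]] = set()
    for diag, qf, ql in clusters:
        q0, q1, _ = al._xdrop_extend(arr, arr, mat, qf, ql + k, diag,
                                     params.xdrop)
        # a repeat cannot run into its own partner copy
        if q1 > q0 + diag:
            q1 = q0 + diag
        if q1 - q0 < params.min_ltr_len or q1 - q0 > params.max_ltr_len:
            continue
        key = (diag, q0, q1)
        if key in seen:
            continue
        seen.add(key)
        a = arr[q0:q1]
        b = arr[q0 + diag:q1 + diag]
        n_ident = int(np.sum((a == b) & (a != 4)))
        sim = n_ident / (q1 - q0)
        if sim < params.min_similarity:
            continue
        raw.append((q0, q1, diag, sim, n_ident))

    # resolve overlaps: best similarity, then longest, then leftmost
    raw.sort(key=lambda r: (-r[3], -(r[1] - r[0]), r[0]))
    chosen: list[tuple[int, int, int, float]] = []
    occupied: list[tuple[int, int]] = []
    for q0, q1, diag, sim, _ in raw:
        span = (q0, q1 + diag)
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        occupied.append(span)
        chosen.append((q0, q1, diag, sim))

    pairs = []
    for q0, q1, diag, sim in sorted(chosen):
        # reported similarity is the optimal local-alignment identity of the
        # two reported LTR sequences (internal consistency contract)
        sw = al.local_align(window[q0:q1], window[q0 + diag:q1 + diag])
        if sw.identity < params.min_similarity:
            continue
        pairs.append(LtrPair(
            ltr5=Locus(contig, origin + q0, origin + q1),
            ltr3=Locus(contig, origin + q0 + diag, origin + q1 + diag),
            similarity=sw.identity,
        ))
    return pairs


def pair_similarity_by_alignment(genome: ContigSet, pair: LtrPair) -> float:
    """Smith–Waterman identity of the two reported LTR sequences."""
    a, _, _ = extract(genome, pair.ltr5)
    b, _, _ = extract(genome, pair.ltr3)
    return al.local_align(a, b).identity


# ---------------------------------------------------------------------------
# TSD / PBS / PPT

def find_tsd(genome: ContigSet, element_span: Locus,
             params: LtrParams | None = None) -> Tsd | None:
    """Longest exact 4–6 bp duplication immediately flanking the element."""
    params = params or LtrParams()
    seq = genome[element_span.contig]
    if element_span.start < params.tsd_max or \
            element_span.end + params.tsd_max > len(seq):
        return None
    for L in range(params.tsd_max, params.tsd_min - 1, -1):
        left = seq[element_span.start - L:element_span.start]
        right = seq[element_span.end:element_span.end + L]
        if left == right and "N" not in left:
            return Tsd(
                left=Locus(element_span.contig, element_span.start - L,
                           element_span.start),
                right=Locus(element_span.contig, element_span.end,
                            element_span.end + L),
                sequence=left,
            )
    return None


def refine_pair_by_tsd(genome: ContigSet, pair: LtrPair,
                       params: LtrParams | None = None,
                       max_shift: int = 7) -> tuple[LtrPair, Tsd | None]:
    """Nudge pair boundaries (a few bp) to where an exact TSD flanks them.

    Ungapped extension fixes boundaries at maximal exact-match ends, which
    can over- or under-shoot the integration site by a few bases when
    flanking bases coincide by chance or terminal LTR bases have mutated.
    Both LTR starts move together (the pair lies on one diagonal), as do both
    ends. The smallest total shift producing an exact 4–6 bp duplication
    wins; without one the pair is returned unchanged.
    """
    params = params or LtrParams()
    contig_len = genome.length_of(pair.ltr5.contig)
    best: tuple[tuple[int, int, int, int], LtrPair, Tsd] | None = None
    for s in range(-4, max_shift + 1):
        for e in range(-4, max_shift + 1):
            start = pair.ltr5.start + s
            end = pair.ltr3.end - e
            if not (0 <= start < end <= contig_len):
                continue
            new_len = len(pair.ltr5) - s - e
            if not (params.min_ltr_len <= new_len <= params.max_ltr_len):
                continue
            span = Locus(pair.ltr5.contig, start, end, pair.ltr5.strand)
            tsd = find_tsd(genome, span, params)
            if tsd is None:
                continue
            # prefer the longest duplication, then the smallest move
            key = (-len(tsd.sequence), abs(s) + abs(e), abs(s), abs(e))
            if best is None or key < best[0]:
                new_pair = LtrPair(
                    ltr5=Locus(pair.ltr5.contig, pair.ltr5.start + s,
                               pair.ltr5.end - e, pair.ltr5.strand),
                    ltr3=Locus(pair.ltr3.contig, pair.ltr3.start + s,
                               pair.ltr3.end - e, pair.ltr3.strand),
                    similarity=pair.similarity,
                )
                best = (key, new_pair, tsd)
    if best is None:
        return pair, None
    return best[1], best[2]


def find_pbs(element: str, ltr5_end: int,
             trna_lib: dict[str, str] | None = None,
             params: LtrParams | None = None,
             contig: str = "element", origin: int = 0) -> PbsHit | None:
    """Primer binding site: revcomp of a tRNA 3' 18-mer just after the 5' LTR.

    The best hit (fewest mismatches, then closest to the LTR) within
    ``pbs_offset_max`` of the LTR end and at most ``pbs_mismatch_max``
    mismatches is reported with its tRNA label.
    """
    params = params or LtrParams()
    lib = trna_lib or SYNTHETIC_TRNA_3P_18MERS
    if not lib:
        raise al.ParameterError("empty tRNA library")
    best: tuple[int, int, str] | None = None   # (mismatches, offset, label)
    for label, trna in sorted(lib.items()):
        target = revcomp(trna)
        L = len(target)
        for off in range(params.pbs_offset_max):
            p = ltr5_end + off
            seg = element[p:p + L]
            if len(seg) < L:
                break
            mm = sum(1 for x, y in zip(seg, target) if x != y or x == "N")
            if mm <= params.pbs_mismatch_max:
                cand = (mm, off, label)
                if best is None or cand[:2] < best[:2]:
                    best = cand
    if best is None:
        return None
    mm, off, label = best
    p = ltr5_end + off
    return PbsHit(
        locus=Locus(contig, origin + p, origin + p + len(lib[label])),
        trna_label=label, mismatches=mm,
    )


def find_ppt(element: str, ltr3_start: int,
             params: LtrParams | None = None,
             contig: str = "element", origin: int = 0) -> PptHit | None:
    """Polypurine tract: the longest >=90%-purine window of >=10 nt ending
    within ``ppt_offset_max`` of the 3' LTR start (ties go to the window
    closest to the LTR)."""
    params = params or LtrParams()
    if ltr3_start <= params.ppt_min_len:
        raise al.ParameterError("ltr3_start leaves no room for a PPT")
    is_purine = [c in "AG" for c in element]
    best: tuple[int, int, int, float] | None = None  # (-len, dist, start, frac)
    for end in range(ltr3_start, max(params.ppt_min_len,
                                     ltr3_start - params.ppt_offset_max) - 1,
                     -1):
        if not is_purine[end - 1]:
            continue    # a tract ends on a purine
        dist = ltr3_start - end
        lo = max(0, end - params.ppt_max_len)
        for start in range(lo, end - params.ppt_min_len + 1):
            if not is_purine[start]:
                continue    # and starts on one
            n = end - start
            frac = sum(is_purine[start:end]) / n
            if frac >= params.ppt_purine_fraction:
                cand = (-n, dist, start, frac)
                if best is None or cand[:2] < best[:2]:
                    best = cand
                break  # longest window for this end found
    if best is None:
        return None
    neg_len, dist, start, frac = best
    end = start - neg_len
    return PptHit(locus=Locus(contig, origin + start, origin + end),
                  purine_fraction=frac)


# ---------------------------------------------------------------------------
# provirus assembly

@dataclass
class ProvirusCandidate:
    """An assembled element: paired LTRs, internal region and annotations."""

    element_id: str
    span: Locus
    ltr5: Locus
    ltr3: Locus | None
    similarity: float | None
    internal: Locus | None
    full_length: bool
    pbs: PbsHit | None = None
    ppt: PptHit | None = None
    tsd: Tsd | None = None
    lineage_name: str = ""
    stage: str = "pol_screen"

    def to_record(self) -> dict[str, object]:
        return {
            "element_id": self.element_id,
            "contig": self.span.contig,
            "start": self.span.start,
            "end": self.span.end,
            "strand": self.span.strand,
            "full_length": int(self.full_length),
            "ltr5_start": self.ltr5.start,
            "ltr5_end": self.ltr5.end,
            "ltr3_start": self.ltr3.start if self.ltr3 else "",
            "ltr3_end": self.ltr3.end if self.ltr3 else "",
            "ltr_similarity": (f"{self.similarity:.4f}"
                               if self.similarity is not None else ""),
            "pbs": self.pbs.trna_label if self.pbs else "",
            "pbs_mismatches": self.pbs.mismatches if self.pbs else "",
            "ppt": (f"{self.ppt.purine_fraction:.2f}" if self.ppt else ""),
            "tsd": self.tsd.sequence if self.tsd else "",
            "lineage": self.lineage_name,
        }


def assemble_provirus(candidate, pair: LtrPair,
                      pbs: PbsHit | None = None, ppt: PptHit | None = None,
                      tsd: Tsd | None = None,
                      element_id: str = "candidate") -> ProvirusCandidate:
    """Combine an internal-region candidate with its LTR pair.

    Full-length status requires paired LTRs plus an internal region; PBS,
    PPT and TSD are recorded but optional. The pair must contain the
    candidate's supporting hit span.
    """
    span = pair.element_span
    if not (span.start <= candidate.locus.start
            and candidate.locus.end <= span.end):
        raise AssemblyError(
            f"LTR pair {span} does not contain candidate {candidate.locus}")
    internal = None
    if pair.ltr3.start > pair.ltr5.end:
        internal = Locus(span.contig, pair.ltr5.end, pair.ltr3.start,
                         span.strand)
    return ProvirusCandidate(
        element_id=element_id, span=span, ltr5=pair.ltr5, ltr3=pair.ltr3,
        similarity=pair.similarity, internal=internal,
        full_length=internal is not None,
        pbs=pbs, ppt=ppt, tsd=tsd,
        stage=getattr(candidate, "stage", "pol_screen"),
    )


def annotate_candidate(genome: ContigSet, candidate, params: LtrParams | None
                       = None, trna_lib: dict[str, str] | None = None,
                       element_id: str = "candidate",
                       ) -> ProvirusCandidate | None:
    """Full structural annotation of one candidate locus.

    Extracts a window around the candidate, finds the best containing LTR
    pair, annotates TSD/PBS/PPT and assembles the provirus; returns None when
    no pair satisfying the geometry contains the candidate.
    """
    params = params or LtrParams()
    loc = candidate.locus
    window, left, _ = extract(
        genome, Locus(loc.contig, loc.start, loc.end, "+"),
        flank=params.window_flank)
    origin = loc.start - left
    pairs = find_ltr_pairs(window, params, contig=loc.contig, origin=origin)
    containing = [p for p in pairs
                  if p.element_span.start <= loc.start
                  and loc.end <= p.element_span.end]
    if not containing:
        return None
    pair = max(containing, key=lambda p: (p.similarity, p.ltr_len,
                                          -p.element_span.start))
    pair, tsd = refine_pair_by_tsd(genome, pair, params)
    el_start = pair.element_span.start
    element_seq = genome[loc.contig][el_start:pair.element_span.end]
    pbs = find_pbs(element_seq, pair.ltr5.end - el_start, trna_lib, params,
                   contig=loc.contig, origin=el_start)
    ppt = find_ppt(element_seq, pair.ltr3.start - el_start, params,
                   contig=loc.contig, origin=el_start)
    return assemble_provirus(candidate, pair, pbs, ppt, tsd,
                             element_id=element_id)
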