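"""Alignment kernels standing in for BLASTx/tBLASTn/BLASTn/dc-megablast.

Three layers:

* :func:`local_align` — optimal Smith–Waterman local alignment (affine gaps)
  on top of Biopython's ``PairwiseAligner``; the ground-truth kernel that
  seeded hits are re-scored against.
* :func:`seeded_search` — BLAST-style heuristic search of a query against a
  :class:`~ervatlas.genome_io.ContigSet`: word seeding (exact contiguous
  k-mers, one fixed spaced seed for the discontiguous-megablast dialect, or
  BLOSUM62 neighborhood words for protein-vs-translated search), two-hit
  diagonal chaining, ungapped X-drop extension, and gapped joining of nearby
  chains. Hits short enough are re-scored with :func:`local_align` so their
  reported score/identity are exactly those of the optimal local alignment
  of the reported ranges.
* :func:`estimate_evalue` — Karlin–Altschul E = K·m·n·exp(−λ·score) with
  shipped (K, λ) pairs per scoring scheme. These are documented
  approximations: the pipeline's contracts are identity/coverage/E-value
  *thresholds*, not raw E-value agreement with any particular BLAST build.

N is a hard wildcard-that-never-matches: it scores as a mismatch against
everything including itself and is never counted as an identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .genome_io import ContigSet, Locus, revcomp

# ---------------------------------------------------------------------------
# alphabets / encodings

NT_ALPHABET = "ACGTN"
_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}
_N_CODE = 4

PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_INDEX = {c: i for i, c in enumerate(PROT_ALPHABET)}
_X_CODE = _PROT_INDEX["X"]
_STOP_CODE = _PROT_INDEX["*"]


def encode_nt(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, _N_CODE, dtype=np.int8)
    for c, i in _NT_INDEX.items():
        lut[ord(c)] = i
    return lut[out].astype(np.int64)


def encode_prot(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, _X_CODE, dtype=np.int8)
    for c, i in _PROT_INDEX.items():
        lut[ord(c)] = i
    return lut[out].astype(np.int64)


class ParameterError(ValueError):
    """Degenerate or unknown search/scoring parameters."""


# ---------------------------------------------------------------------------
# scoring schemes

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _blosum62_array() -> np.ndarray:
    m = np.zeros((len(PROT_ALPHABET), len(PROT_ALPHABET)))
    for i, a in enumerate(PROT_ALPHABET):
        for j, b in enumerate(PROT_ALPHABET):
            m[i, j] = _BLOSUM62[a][b]
    return m


def _nt_array(match: float, mismatch: float) -> np.ndarray:
    m = np.full((5, 5), mismatch)
    for i in range(4):
        m[i, i] = match
    # N scores as mismatch against everything, including N
    m[_N_CODE, :] = mismatch
    m[:, _N_CODE] = mismatch
    return m


@dataclass(frozen=True)
class Scoring:
    """A substitution matrix plus affine gap penalties (cost = open + extend·len)."""

    name: str
    matrix: np.ndarray
    alphabet: str
    gap_open: float
    gap_extend: float

    def substitution(self, a: str, b: str) -> float:
        idx = _PROT_INDEX if self.alphabet is PROT_ALPHABET else _NT_INDEX
        return float(self.matrix[idx[a], idx[b]])


def nucleotide_scoring(match: float = 2.0, mismatch: float = -3.0,
                       gap_open: float = 5.0, gap_extend: float = 2.0) -> Scoring:
    name = f"nt{match:+g}/{mismatch:+g}go{gap_open:g}ge{gap_extend:g}"
    return Scoring(name, _nt_array(match, mismatch), NT_ALPHABET, gap_open, gap_extend)


def protein_scoring(gap_open: float = 11.0, gap_extend: float = 1.0) -> Scoring:
    return Scoring("blosum62", _blosum62_array(), PROT_ALPHABET, gap_open, gap_extend)


# Karlin–Altschul parameters per scheme name prefix. Shipped approximations
# for the two schemes the pipeline uses; thresholds, not E-values, are the
# behavioural contract.
KARLIN_PARAMS: dict[str, tuple[float, float]] = {
    "nt+2/-3go5ge2": (0.625, 0.41),
    "blosum62": (0.267, 0.041),
}


def estimate_evalue(score: float, query_len: int, db_len: int,
                    scheme: str | Scoring) -> float:
    """Karlin–Altschul expected number of chance hits at ``score`` or better."""
    if score < 0:
        raise ParameterError("score must be non-negative")
    name = scheme.name if isinstance(scheme, Scoring) else scheme
    if name not in KARLIN_PARAMS:
        raise ParameterError(f"no Karlin parameters for scoring scheme {name!r}")
    lam, k = KARLIN_PARAMS[name]
    return k * query_len * db_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# six-frame translation

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"


def translate(nt: str) -> str:
    """Translate a + frame; codons containing N give 'X', stops give '*'."""
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        out.append(_CODON_MAP.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a nucleotide sequence with coordinate bookkeeping."""

    frame: int          # +1,+2,+3,-1,-2,-3
    protein: str
    nt_len: int

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def nt_span(self, prot_start: int, prot_end: int) -> tuple[int, int, str]:
        """Map a protein slice back to forward-strand nucleotide coordinates."""
        off = self.offset
        lo = off + 3 * prot_start
        hi = off + 3 * prot_end
        if self.frame > 0:
            return lo, hi, "+"
        return self.nt_len - hi, self.nt_len - lo, "-"


def translate_six_frames(nt: str) -> list[FrameTranslation]:
    """All six reading frames with exact protein-to-nucleotide mapping."""
    if len(nt) < 3:
        raise ParameterError("need at least one codon to translate")
    rc = revcomp(nt)
    frames = []
    for f in (1, 2, 3):
        frames.append(FrameTranslation(f, translate(nt[f - 1:]), len(nt)))
    for f in (1, 2, 3):
        frames.append(FrameTranslation(-f, translate(rc[f - 1:]), len(nt)))
    return frames


# ---------------------------------------------------------------------------
# optimal local alignment

@dataclass(frozen=True)
class LocalAlignment:
    """Result of a Smith–Waterman local alignment (0-based half-open ranges)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float
    n_ident: int
    aln_cols: int       # aligned non-gap columns
    blocks: tuple[tuple[int, int, int, int], ...]  # (a0, a1, b0, b1) ungapped runs

    @property
    def identity(self) -> float:
        return self.n_ident / self.aln_cols if self.aln_cols else 0.0

    @property
    def is_empty(self) -> bool:
        return self.aln_cols == 0


_EMPTY_ALIGNMENT = LocalAlignment(0, 0, 0, 0, 0.0, 0, 0, ())


_ALIGNER_CACHE: dict[tuple[str, str], Align.PairwiseAligner] = {}


def _make_aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    key = (scoring.name, mode)
    cached = _ALIGNER_CACHE.get(key)
    if cached is not None:
        return cached
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=scoring.alphabet, dims=2, data=scoring.matrix)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    _ALIGNER_CACHE[key] = aligner
    return aligner


def _ident_char(a: str, b: str, alphabet: str) -> bool:
    if a != b:
        return False
    if alphabet is NT_ALPHABET or alphabet == NT_ALPHABET:
        return a != "N"
    return a not in ("X", "*")


def _alignment_from_biopython(aln, a: str, b: str, scoring: Scoring) -> LocalAlignment:
    blocks = []
    n_ident = 0
    aln_cols = 0
    a_blocks, b_blocks = aln.aligned
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        blocks.append((int(a0), int(a1), int(b0), int(b1)))
        aln_cols += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if _ident_char(x, y, scoring.alphabet):
                n_ident += 1
    if not blocks:
        return _EMPTY_ALIGNMENT
    return LocalAlignment(
        a_start=blocks[0][0], a_end=blocks[-1][1],
        b_start=blocks[0][2], b_end=blocks[-1][3],
        score=float(aln.score), n_ident=n_ident, aln_cols=aln_cols,
        blocks=tuple(blocks),
    )


def local_align(a: str, b: str, scoring: Scoring | None = None,
                mode: str = "nucleotide") -> LocalAlignment:
    """Optimal Smith–Waterman local alignment of ``a`` vs ``b``.

    ``mode`` selects the default scoring scheme ("nucleotide": +2/−3 with
    affine gaps 5/2; "protein": BLOSUM62 11/1) unless ``scoring`` is given.
    Returns the empty alignment when no positive-scoring alignment exists.
    """
    if not a or not b:
        raise ParameterError("local_align requires non-empty sequences")
    if scoring is None:
        scoring = protein_scoring() if mode == "protein" else nucleotide_scoring()
    aligner = _make_aligner(scoring, "local")
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return _EMPTY_ALIGNMENT
    return _alignment_from_biopython(alns[0], a, b, scoring)


def global_align(a: str, b: str, scoring: Scoring | None = None,
                 mode: str = "nucleotide") -> LocalAlignment:
    """Needleman–Wunsch global alignment, same bookkeeping as local_align."""
    if not a or not b:
        raise ParameterError("global_align requires non-empty sequences")
    if scoring is None:
        scoring = protein_scoring() if mode == "protein" else nucleotide_scoring()
    aligner = _make_aligner(scoring, "global")
    alns = aligner.align(a, b)
    return _alignment_from_biopython(alns[0], a, b, scoring)


# ---------------------------------------------------------------------------
# seeded heuristic search

# one fixed coding-pattern spaced seed (weight 21 of length 28) emulating the
# dc-megablast sensitivity class: third codon positions of the first seven
# codons are wildcards.
DC_SEED_PATTERN = "1101101101101101101101111111"
assert len(DC_SEED_PATTERN) == 28 and DC_SEED_PATTERN.count("1") == 21


@dataclass
class SearchParams:
    """Tunables for :func:`seeded_search`."""

    mode: str = "nucleotide"            # nucleotide | dc | protein
    seed_len: int = 11                  # contiguous seed width (nt/protein word)
    spaced_pattern: str | None = None   # dc mode only
    neighbor_threshold: float = 11.0    # protein neighborhood word cutoff
    max_seed_gap: int = 100             # two-hit window on one diagonal
    xdrop: float = 20.0
    merge_gap: int = 30                 # same-diagonal merge distance
    join_gap: int = 50                  # max gap bridged by gapped joining
    join_band: int = 20                 # max diagonal shift bridged
    evalue_cutoff: float = 1e-5
    min_score: float = 0.0
    rescore_cap: int = 3000             # re-score hits with local_align up to this span
    scoring: Scoring | None = None

    @staticmethod
    def nucleotide(**kw) -> "SearchParams":
        return SearchParams(mode="nucleotide", **kw)

    @staticmethod
    def dc_megablast(**kw) -> "SearchParams":
        return SearchParams(mode="dc", spaced_pattern=DC_SEED_PATTERN,
                            seed_len=28, **kw)

    @staticmethod
    def protein(**kw) -> "SearchParams":
        kw.setdefault("neighbor_threshold", 13.0)
        return SearchParams(mode="protein", seed_len=3, xdrop=18.0,
                            max_seed_gap=40, **kw)

    def resolved_scoring(self) -> Scoring:
        if self.scoring is not None:
            return self.scoring
        return protein_scoring() if self.mode == "protein" else nucleotide_scoring()


@dataclass
class AlignmentHit:
    """One reported hit of a query against a genome.

    ``query_range`` is 0-based half-open in query units (nt or aa);
    ``subject_locus`` is always in forward nucleotide coordinates. ``frame``
    is ±1/±2/±3 for translated searches and 0 otherwise.
    """

    query_id: str
    query_start: int
    query_end: int
    subject_locus: Locus
    frame: int
    identity: float
    coverage: float
    score: float
    evalue: float
    n_ident: int = 0
    aln_cols: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


# -- seed words --------------------------------------------------------------

def _contiguous_words(arr: np.ndarray, k: int, alpha: int) -> np.ndarray:
    """Hash every k-mer; windows containing the wildcard code hash to -1."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = arr[j:j + n]
        h = h * alpha + np.minimum(col, alpha - 1)
        valid &= col < alpha
    h[~valid] = -1
    return h


def _spaced_words(arr: np.ndarray, pattern: str) -> np.ndarray:
    n = len(arr) - len(pattern) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j, bit in enumerate(pattern):
        if bit == "1":
            col = arr[j:j + n]
            h = h * 4 + np.minimum(col, 3)
            valid &= col < 4
    h[~valid] = -1
    return h


def _index_words(words: np.ndarray) -> dict[int, np.ndarray]:
    order = np.argsort(words, kind="stable")
    sorted_w = words[order]
    keep = sorted_w >= 0
    sorted_w, order = sorted_w[keep], order[keep]
    index: dict[int, np.ndarray] = {}
    if len(sorted_w) == 0:
        return index
    bounds = np.flatnonzero(np.diff(sorted_w)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(sorted_w)]))
    for s, e in zip(starts, ends):
        index[int(sorted_w[s])] = order[s:e]
    return index


# -- diagonal chaining & extension -------------------------------------------

def _two_hit_clusters(qpos: np.ndarray, spos: np.ndarray, window: int,
                      require_two: bool = True) -> list[tuple[int, int, int]]:
    """Group seed positions by diagonal; return (diag, q_first, q_last) clusters."""
    if len(qpos) == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    diag, qpos = diag[order], qpos[order]
    clusters = []
    d0, q_first, q_last, count = int(diag[0]), int(qpos[0]), int(qpos[0]), 1
    for d, q in zip(diag[1:], qpos[1:]):
        d, q = int(d), int(q)
        if d == d0 and q - q_last <= window:
            q_last = q
            count += 1
        else:
            if count >= 2 or not require_two:
                clusters.append((d0, q_first, q_last))
            d0, q_first, q_last, count = d, q, q, 1
    if count >= 2 or not require_two:
        clusters.append((d0, q_first, q_last))
    return clusters


def _xdrop_extend(qarr: np.ndarray, sarr: np.ndarray, mat: np.ndarray,
                  q0: int, q1: int, diag: int, xdrop: float,
                  ) -> tuple[int, int, float]:
    """Ungapped X-drop extension of the core [q0, q1) along ``diag``.

    Returns the extended (q_start, q_end, score); endpoints maximize score.
    """
    s0 = q0 + diag
    core = mat[qarr[q0:q1], sarr[s0:s0 + (q1 - q0)]]
    score = float(core.sum())

    # left extension
    left_len = min(q0, s0)
    ls = 0
    if left_len > 0:
        qs = qarr[q0 - left_len:q0][::-1]
        ss = sarr[s0 - left_len:s0][::-1]
        steps = mat[qs, ss]
        cum = np.cumsum(steps)
        runmax = np.maximum.accumulate(cum)
        dead = np.flatnonzero(runmax - cum > xdrop)
        stop = int(dead[0]) if len(dead) else len(cum)
        if stop > 0:
            best = int(np.argmax(cum[:stop]))
            if cum[best] > 0:
                ls = best + 1
                score += float(cum[best])

    # right extension
    s1 = s0 + (q1 - q0)
    right_len = min(len(qarr) - q1, len(sarr) - s1)
    rs = 0
    if right_len > 0:
        qs = qarr[q1:q1 + right_len]
        ss = sarr[s1:s1 + right_len]
        steps = mat[qs, ss]
        cum = np.cumsum(steps)
        runmax = np.maximum.accumulate(cum)
        dead = np.flatnonzero(runmax - cum > xdrop)
        stop = int(dead[0]) if len(dead) else len(cum)
        if stop > 0:
            best = int(np.argmax(cum[:stop]))
            if cum[best] > 0:
                rs = best + 1
                score += float(cum[best])

    return q0 - ls, q1 + rs, score


def _span_stats(qarr: np.ndarray, sarr: np.ndarray, mat: np.ndarray,
                ident_ok: np.ndarray, q0: int, q1: int, diag: int,
                ) -> tuple[float, int]:
    qs = qarr[q0:q1]
    ss = sarr[q0 + diag:q1 + diag]
    score = float(mat[qs, ss].sum())
    n_ident = int(np.sum((qs == ss) & ident_ok[qs]))
    return score, n_ident


@dataclass
class _RawHit:
    diag: int
    q0: int
    q1: int
    score: float
    n_ident: int
    aln_cols: int
    gap_opens: int = 0
    s0: int = -1  # subject start; defaults to q0+diag for ungapped hits

    def subject_range(self) -> tuple[int, int]:
        if self.s0 >= 0:
            return self.s0, self.s0 + (self.aln_cols_sub or 0)
        return self.q0 + self.diag, self.q1 + self.diag

    aln_cols_sub: int | None = None


def _search_one_strand(qarr: np.ndarray, sarr: np.ndarray,
                       sindex: dict[int, np.ndarray], params: SearchParams,
                       mat: np.ndarray, ident_ok: np.ndarray,
                       qwords: np.ndarray, word_span: int) -> list[_RawHit]:
    # collect seed hits
    qpos_list, spos_list = [], []
    for qp in range(len(qwords)):
        w = int(qwords[qp])
        if w < 0:
            continue
        hits = sindex.get(w)
        if hits is not None:
            qpos_list.append(np.full(len(hits), qp, dtype=np.int64))
            spos_list.append(hits)
    if not qpos_list:
        return []
    qpos = np.concatenate(qpos_list)
    spos = np.concatenate(spos_list)
    clusters = _two_hit_clusters(qpos, spos, params.max_seed_gap)

    raw: list[_RawHit] = []
    seen: set[tuple[int, int, int]] = set()
    for diag, qf, ql in clusters:
        q0, q1, score = _xdrop_extend(qarr, sarr, mat, qf, ql + word_span,
                                      diag, params.xdrop)
        key = (diag, q0, q1)
        if key in seen:
            continue
        seen.add(key)
        score, n_ident = _span_stats(qarr, sarr, mat, ident_ok, q0, q1, diag)
        raw.append(_RawHit(diag, q0, q1, score, n_ident, q1 - q0))

    raw = _merge_same_diagonal(raw, qarr, sarr, mat, ident_ok, params.merge_gap)
    raw = _join_gapped(raw, qarr, sarr, mat, ident_ok, params)
    return raw


def _merge_same_diagonal(raw: list[_RawHit], qarr, sarr, mat, ident_ok,
                         merge_gap: int) -> list[_RawHit]:
    by_diag: dict[int, list[_RawHit]] = {}
    for h in raw:
        by_diag.setdefault(h.diag, []).append(h)
    merged: list[_RawHit] = []
    for diag, hits in by_diag.items():
        hits.sort(key=lambda h: h.q0)
        cur = hits[0]
        for h in hits[1:]:
            if h.q0 - cur.q1 < merge_gap:
                q0, q1 = cur.q0, max(cur.q1, h.q1)
                score, n_ident = _span_stats(qarr, sarr, mat, ident_ok,
                                             q0, q1, diag)
                cur = _RawHit(diag, q0, q1, score, n_ident, q1 - q0)
            else:
                merged.append(cur)
                cur = h
        merged.append(cur)
    return merged


def _join_gapped(raw: list[_RawHit], qarr, sarr, mat, ident_ok,
                 params: SearchParams) -> list[_RawHit]:
    """Join chains on nearby diagonals across short gaps (gapped extension)."""
    if len(raw) < 2:
        return raw
    scoring = params.resolved_scoring()
    raw.sort(key=lambda h: (h.q0, h.q0 + h.diag))
    out: list[_RawHit] = []
    cur = raw[0]
    for h in raw[1:]:
        qgap = h.q0 - cur.q1
        s_cur_end = cur.q1 + cur.diag
        sgap = (h.q0 + h.diag) - s_cur_end
        dshift = abs(h.diag - cur.diag)
        if (h.diag != cur.diag and 0 <= qgap <= params.join_gap
                and 0 <= sgap <= params.join_gap and dshift <= params.join_band):
            gap_score = -(scoring.gap_open + scoring.gap_extend * dshift)
            bridge_ident = 0
            bridge_cols = min(qgap, sgap)
            if qgap and sgap:
                qa = qarr[cur.q1:h.q0]
                sa = sarr[s_cur_end:h.q0 + h.diag]
                m = min(len(qa), len(sa))
                gap_score += float(mat[qa[:m], sa[:m]].sum())
                bridge_ident = int(np.sum((qa[:m] == sa[:m]) & ident_ok[qa[:m]]))
            joined_score = cur.score + h.score + gap_score
            if joined_score > max(cur.score, h.score):
                cur = _RawHit(
                    diag=h.diag, q0=cur.q0, q1=h.q1,
                    score=joined_score,
                    n_ident=cur.n_ident + h.n_ident + bridge_ident,
                    aln_cols=cur.aln_cols + h.aln_cols + bridge_cols,
                    gap_opens=cur.gap_opens + h.gap_opens + 1,
                    s0=cur.q0 + cur.diag,
                )
                cur.aln_cols_sub = (h.q1 + h.diag) - (cur.s0)
                continue
        out.append(cur)
        cur = h
    out.append(cur)
    return out


def _rescore_with_local(query: str, subject: str, hit: AlignmentHit,
                        scoring: Scoring, q_orig_len: int,
                        db_len: int) -> AlignmentHit | None:
    qsub = query[hit.query_start:hit.query_end]
    ssub = subject[hit.subject_locus.start:hit.subject_locus.end]
    if not qsub or not ssub:
        return None
    aln = local_align(qsub, ssub, scoring=scoring)
    if aln.is_empty:
        return None
    new = replace(
        hit,
        query_start=hit.query_start + aln.a_start,
        query_end=hit.query_start + aln.a_end,
        subject_locus=Locus(hit.subject_locus.contig,
                            hit.subject_locus.start + aln.b_start,
                            hit.subject_locus.start + aln.b_end,
                            hit.subject_locus.strand),
        identity=aln.identity,
        score=aln.score,
        n_ident=aln.n_ident,
        aln_cols=aln.aln_cols,
        mismatches=aln.aln_cols - aln.n_ident,
        gap_opens=max(0, len(aln.blocks) - 1),
    )
    new.coverage = new.query_span / q_orig_len
    new.evalue = estimate_evalue(new.score, q_orig_len, db_len, scoring)
    return new


def _query_words(qarr: np.ndarray, params: SearchParams) -> tuple[np.ndarray, int]:
    if params.mode == "dc":
        pattern = params.spaced_pattern or DC_SEED_PATTERN
        return _spaced_words(qarr, pattern), len(pattern)
    return _contiguous_words(qarr, params.seed_len, 4), params.seed_len


def seeded_search(query: str, genome: ContigSet, params: SearchParams,
                  query_id: str = "query") -> list[AlignmentHit]:
    """Heuristic BLAST-style search of one query against a genome.

    Nucleotide and dc (discontiguous spaced-seed) modes search both strands;
    protein mode searches the query peptide against all six translated frames
    of every contig. Hits are filtered at ``params.evalue_cutoff`` and sorted
    by (evalue, contig, subject start).
    """
    if not query:
        raise ParameterError("empty query")
    if params.mode in ("nucleotide", "dc"):
        span = len(params.spaced_pattern or "") if params.mode == "dc" \
            else params.seed_len
        if span > len(query):
            raise ParameterError(
                f"seed span {span} exceeds query length {len(query)}")
        return _seeded_search_nt(query, genome, params, query_id)
    if params.mode == "protein":
        if params.seed_len > len(query):
            raise ParameterError("seed length exceeds query length")
        return _seeded_search_protein(query, genome, params, query_id)
    raise ParameterError(f"unknown search mode {params.mode!r}")


def _seeded_search_nt(query: str, genome: ContigSet, params: SearchParams,
                      query_id: str) -> list[AlignmentHit]:
    scoring = params.resolved_scoring()
    mat = scoring.matrix
    ident_ok = np.array([True, True, True, True, False])
    db_len = genome.total_length
    qlen = len(query)

    queries = {"+": query, "-": revcomp(query)}
    hits: list[AlignmentHit] = []
    for contig in genome:
        subject = genome[contig]
        sarr = encode_nt(subject)
        if params.mode == "dc":
            swords = _spaced_words(sarr, params.spaced_pattern or DC_SEED_PATTERN)
        else:
            swords = _contiguous_words(sarr, params.seed_len, 4)
        sindex = _index_words(swords)
        for strand, q in queries.items():
            qarr = encode_nt(q)
            qwords, span = _query_words(qarr, params)
            raw = _search_one_strand(qarr, sarr, sindex, params, mat,
                                     ident_ok, qwords, span)
            for rh in raw:
                if rh.score < params.min_score or rh.aln_cols == 0:
                    continue
                s0 = rh.s0 if rh.s0 >= 0 else rh.q0 + rh.diag
                s1 = (s0 + rh.aln_cols_sub) if rh.aln_cols_sub else rh.q1 + rh.diag
                if strand == "+":
                    q0, q1 = rh.q0, rh.q1
                else:
                    q0, q1 = qlen - rh.q1, qlen - rh.q0
                ev = estimate_evalue(rh.score, qlen, db_len, scoring)
                if ev > params.evalue_cutoff:
                    # ungapped significance gate; optimal re-scoring can only
                    # raise the score of hits worth keeping
                    continue
                hit = AlignmentHit(
                    query_id=query_id, query_start=q0, query_end=q1,
                    subject_locus=Locus(contig, s0, s1, strand), frame=0,
                    identity=rh.n_ident / rh.aln_cols,
                    coverage=(rh.q1 - rh.q0) / qlen,
                    score=rh.score, evalue=ev,
                    n_ident=rh.n_ident, aln_cols=rh.aln_cols,
                    mismatches=rh.aln_cols - rh.n_ident,
                    gap_opens=rh.gap_opens,
                )
                if hit.query_span <= params.rescore_cap and strand == "+":
                    rescored = _rescore_with_local(query, subject, hit,
                                                   scoring, qlen, db_len)
                    if rescored is None:
                        continue
                    hit = rescored
                elif hit.query_span <= params.rescore_cap:
                    rescored = _rescore_with_local(
                        queries["-"], subject,
                        replace(hit, query_start=rh.q0, query_end=rh.q1),
                        scoring, qlen, db_len)
                    if rescored is None:
                        continue
                    hit = replace(rescored,
                                  query_start=qlen - rescored.query_end,
                                  query_end=qlen - rescored.query_start)
                if hit.evalue <= params.evalue_cutoff:
                    hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, h.subject_locus.contig,
                             h.subject_locus.start, h.query_start))
    return hits


def _seeded_search_protein(query: str, genome: ContigSet, params: SearchParams,
                           query_id: str) -> list[AlignmentHit]:
    scoring = params.resolved_scoring()
    mat = scoring.matrix
    ident_ok = np.array([c not in ("X", "*") for c in PROT_ALPHABET])
    k = params.seed_len
    qarr = encode_prot(query)
    qlen = len(query)
    alpha = len(PROT_ALPHABET)

    # translate everything once and build one word index over all frames
    frames: list[tuple[str, FrameTranslation, np.ndarray]] = []
    db_len = 0
    for contig in genome:
        for ft in translate_six_frames(genome[contig]):
            parr = encode_prot(ft.protein)
            frames.append((contig, ft, parr))
            db_len += len(ft.protein)

    # neighborhood seeding: query word w_q seeds subject word w_s whenever
    # blosum62(w_q, w_s) >= neighbor_threshold
    qwords = _contiguous_words(qarr, k, alpha)
    distinct_q = np.unique(qwords[qwords >= 0])
    if len(distinct_q) == 0:
        return []
    q_res = np.stack([(distinct_q // alpha ** (k - 1 - j)) % alpha
                      for j in range(k)])

    hits: list[AlignmentHit] = []
    for contig, ft, parr in frames:
        swords = _contiguous_words(parr, k, alpha)
        distinct_s = np.unique(swords[swords >= 0])
        if len(distinct_s) == 0:
            continue
        s_res = np.stack([(distinct_s // alpha ** (k - 1 - j)) % alpha
                          for j in range(k)])
        # pairwise word scores, vectorized over the distinct-word grid
        pair = np.zeros((len(distinct_q), len(distinct_s)))
        for j in range(k):
            pair += mat[np.ix_(q_res[j], s_res[j])]
        qi, si = np.nonzero(pair >= params.neighbor_threshold)
        if len(qi) == 0:
            continue
        sindex = _index_words(swords)
        qindex = _index_words(qwords)
        qpos_list, spos_list = [], []
        for a, b in zip(qi, si):
            qp = qindex[int(distinct_q[a])]
            sp = sindex[int(distinct_s[b])]
            if len(qp) * len(sp) == 0:
                continue
            qq, ss = np.meshgrid(qp, sp, indexing="ij")
            qpos_list.append(qq.ravel())
            spos_list.append(ss.ravel())
        if not qpos_list:
            continue
        qpos = np.concatenate(qpos_list)
        spos = np.concatenate(spos_list)
        clusters = _two_hit_clusters(qpos, spos, params.max_seed_gap)
        seen: set[tuple[int, int, int]] = set()
        for diag, qf, ql in clusters:
            q0, q1, _ = _xdrop_extend(qarr, parr, mat, qf, ql + k, diag,
                                      params.xdrop)
            key = (diag, q0, q1)
            if key in seen:
                continue
            seen.add(key)
            score, n_ident = _span_stats(qarr, parr, mat, ident_ok, q0, q1, diag)
            if score < params.min_score:
                continue
            # cheap ungapped significance gate before the optimal re-score
            if score <= 0 or estimate_evalue(score, qlen, db_len,
                                             scoring) > params.evalue_cutoff:
                continue
            p0, p1 = q0 + diag, q1 + diag
            # optimal re-score of the reported protein ranges
            aln = local_align(query[q0:q1], ft.protein[p0:p1], scoring=scoring)
            if aln.is_empty:
                continue
            q0r, q1r = q0 + aln.a_start, q0 + aln.a_end
            p0r, p1r = p0 + aln.b_start, p0 + aln.b_end
            nt0, nt1, strand = ft.nt_span(p0r, p1r)
            ev = estimate_evalue(aln.score, qlen, db_len, scoring)
            if ev > params.evalue_cutoff:
                continue
            hits.append(AlignmentHit(
                query_id=query_id, query_start=q0r, query_end=q1r,
                subject_locus=Locus(contig, nt0, nt1, strand),
                frame=ft.frame,
                identity=aln.identity, coverage=(q1r - q0r) / qlen,
                score=aln.score, evalue=ev,
                n_ident=aln.n_ident, aln_cols=aln.aln_cols,
                mismatches=aln.aln_cols - aln.n_ident,
                gap_opens=max(0, len(aln.blocks) - 1),
            ))
    # dedupe identical subject ranges (different clusters may converge)
    uniq: dict[tuple, AlignmentHit] = {}
    for h in hits:
        key = (h.subject_locus.contig, h.subject_locus.start,
               h.subject_locus.end, h.subject_locus.strand, h.frame)
        if key not in uniq or h.score > uniq[key].score:
            uniq[key] = h
    out = list(uniq.values())
    out.sort(key=lambda h: (h.evalue, h.subject_locus.contig,
                            h.subject_locus.start, h.query_start))
    return out


# ---------------------------------------------------------------------------
# BLAST outfmt-6 style table

OUTFMT6_COLUMNS = ["query", "subject", "pident", "length", "mismatches",
                   "gapopens", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def hits_to_records(hits: Iterable[AlignmentHit]) -> list[dict[str, object]]:
    """BLAST outfmt-6 column order; coordinates 1-based inclusive."""
    rows = []
    for h in hits:
        loc = h.subject_locus
        if loc.strand == "+":
            s_start, s_end = loc.start + 1, loc.end
        else:
            s_start, s_end = loc.end, loc.start + 1
        rows.append({
            "query": h.query_id,
            "subject": loc.contig,
            "pident": f"{100.0 * h.identity:.2f}",
            "length": h.aln_cols,
            "mismatches": h.mismatches,
            "gapopens": h.gap_opens,
            "qstart": h.query_start + 1,
            "qend": h.query_end,
            "sstart": s_start,
            "send": s_end,
            "evalue": f"{h.evalue:.2e}",
            "bitscore": f"{h.score:.1f}",
        })
    return rows
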