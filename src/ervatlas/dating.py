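"""Paired-LTR molecular dating under the Kimura two-parameter model.

At integration the two LTRs of a provirus are identical; afterwards each
accumulates neutral substitutions independently, so their divergence D clocks
the insertion: T = (D / R) / 2, with R the neutral substitution rate per site
per year (default 2.2e-9, the average mammalian rate) and the factor of two
reflecting the two independently evolving copies. D is the K2P distance

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the proportions of compared sites differing by a transition
and a transversion respectively. Columns containing a gap or an N are removed
before counting (complete deletion on the pairwise alignment). Saturated
pairs (either log argument non-positive) have no defined distance; they are
flagged and excluded from dating rather than truncated.

No correction is attempted for gene conversion between LTRs or CpG
hypermutation; with a borrowed average rate the resulting ages are estimates
of order, not precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import alignment as al
from .genome_io import ContigSet, extract

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

DEFAULT_RATE = 2.2e-9


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence beyond the model's range."""


class DatingInputError(ValueError):
    """Element not eligible for paired-LTR dating."""


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or \
        (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class K2PEstimate:
    """Transition/transversion proportions and the K2P distance they imply."""

    P: float
    Q: float
    D: float
    sites: int


def k2p_from_counts(transitions: int, transversions: int, sites: int,
                    ) -> K2PEstimate:
    """K2P distance from site counts; raises :class:`SaturationError` when
    the closed form is undefined."""
    if sites <= 0:
        raise DatingInputError("no comparable sites")
    p = transitions / sites
    q = transversions / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated divergence (P={p:.4f}, Q={q:.4f})")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    d += 0.0    # normalize IEEE negative zero for identical sequences
    return K2PEstimate(P=p, Q=q, D=d, sites=sites)


def k2p_distance(a: str, b: str) -> K2PEstimate:
    """K2P distance between two aligned, equal-length sequences.

    Columns where either sequence has a gap ('-') or N are excluded from the
    site count (complete deletion).
    """
    if len(a) != len(b):
        raise DatingInputError("aligned sequences must have equal length")
    ts = tv = sites = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if _is_transition(x, y):
            ts += 1
        else:
            tv += 1
    return k2p_from_counts(ts, tv, sites)


def insertion_time(D: float, R: float = DEFAULT_RATE) -> float:
    """Insertion age in Myr from paired-LTR divergence: T = (D/R)/2."""
    if D < 0:
        raise DatingInputError("distance must be non-negative")
    if R <= 0:
        raise al.ParameterError("substitution rate must be positive")
    return D / (2.0 * R) / 1e6


@dataclass(frozen=True)
class DatingResult:
    element_id: str
    estimate: K2PEstimate | None
    R: float
    T_mya: float | None
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.T_mya is not None

    def to_record(self) -> dict[str, object]:
        est = self.estimate
        return {
            "element_id": self.element_id,
            "sites": est.sites if est else "",
            "P": f"{est.P:.6f}" if est else "",
            "Q": f"{est.Q:.6f}" if est else "",
            "D": f"{est.D:.6f}" if est else "",
            "R": f"{self.R:.3e}",
            "T_mya": f"{self.T_mya:.2f}" if self.T_mya is not None else "NA",
            "flags": ",".join(self.flags),
        }


def date_ltr_pair(ltr5_seq: str, ltr3_seq: str, R: float = DEFAULT_RATE,
                  element_id: str = "element") -> DatingResult:
    """Globally align the two LTRs of one element and date their divergence.

    A global (end-to-end) alignment is appropriate because both LTR
    boundaries are structurally defined; gap and N columns are then dropped.
    """
    aln = al.global_align(ltr5_seq, ltr3_seq)
    cols_a: list[str] = []
    cols_b: list[str] = []
    for a0, a1, b0, b1 in aln.blocks:
        cols_a.append(ltr5_seq[a0:a1])
        cols_b.append(ltr3_seq[b0:b1])
    try:
        est = k2p_distance("".join(cols_a), "".join(cols_b))
    except SaturationError:
        return DatingResult(element_id, None, R, None, flags=("saturated",))
    return DatingResult(element_id, est, R, insertion_time(est.D, R))


def date_provirus(provirus, genome: ContigSet, R: float = DEFAULT_RATE,
                  ) -> DatingResult:
    """Date a full-length provirus from its two annotated LTR loci.

    Only elements with intact paired-LTR structure are eligible; solo LTRs
    and assemblies lacking a pair are rejected.
    """
    if not getattr(provirus, "full_length", False) or provirus.ltr3 is None:
        raise DatingInputError(
            f"{provirus.element_id}: dating requires a full-length element "
            "with both LTRs")
    ltr5, _, _ = extract(genome, provirus.ltr5)
    ltr3, _, _ = extract(genome, provirus.ltr3)
    return date_ltr_pair(ltr5, ltr3, R=R, element_id=provirus.element_id)
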