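"""ORF calling on consensus elements and retroviral motif scanning.

The motif set characterizes the three retroviral genes: in GAG the Cys-His
box (CX2CX4HX4C, nucleocapsid zinc knuckle required for packaging), the
PPPY late domain driving particle release, and the major homology region
(QGxxExxxxFxx) of capsid; in ENV the furin cleavage site (K/R-X-K/R-R)
separating SU from TM, the CX6CC motif whose presence (instead of CX6C)
marks a gamma-type envelope, the YXXL cytoplasmic-tail motif needed for Env
incorporation, and the SDGGGXXDXXR receptor-binding motif diagnostic of the
RDR interference group. Patterns are degenerate: X is any residue,
bracketed sets are alternatives; matching never crosses a stop codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import alignment as al


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on an element (element-relative forward coords).

    ``start``/``end`` cover start codon through stop codon (when present);
    the protein excludes the stop.
    """

    start: int
    end: int
    frame: int
    protein: str
    gene_guess: str = "other"

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    position: int           # 0-based within the scanned protein
    match: str


# motif_id -> compiled degenerate pattern
MOTIF_PATTERNS: dict[str, re.Pattern] = {
    "CysHis": re.compile(r"C.{2}C.{4}H.{4}C"),
    "PPPY": re.compile(r"PPPY"),
    "MHR": re.compile(r"QG..E....F.."),
    "Furin": re.compile(r"[KR].[KR]R"),
    "CX6CC": re.compile(r"C.{6}CC"),
    "CX6C": re.compile(r"C.{6}C"),
    "YXXL": re.compile(r"Y..L"),
    "RBM": re.compile(r"SDGGG..D..R"),
}


def find_orfs(element: str, min_nt: int = 180, require_atg: bool = True,
              ) -> list[OrfAnnotation]:
    """All six-frame ORFs longer than ``min_nt`` nucleotides.

    An ORF runs from a start codon (first AUG of a stop-delimited segment
    when ``require_atg``, else the segment start) through its stop codon, or
    to the element end when no stop follows. The length gate is strict
    (longer than ``min_nt``) and counts the stop codon.
    """
    if len(element) < 3:
        raise al.ParameterError("element too short to translate")
    orfs: list[OrfAnnotation] = []
    for ft in al.translate_six_frames(element):
        protein = ft.protein
        seg_start = 0
        n = len(protein)
        for i in range(n + 1):
            at_stop = i < n and protein[i] == "*"
            at_end = i == n
            if not (at_stop or at_end):
                continue
            seg = protein[seg_start:i]
            if require_atg:
                m = seg.find("M")
                orf_start = seg_start + m if m >= 0 else -1
            else:
                orf_start = seg_start if seg else -1
            if orf_start >= 0:
                prot = protein[orf_start:i]
                # span includes the stop codon when present
                prot_end = i + 1 if at_stop else i
                nt0, nt1, strand = ft.nt_span(orf_start, prot_end)
                if (nt1 - nt0) > min_nt and prot:
                    orfs.append(OrfAnnotation(
                        start=nt0, end=nt1, frame=ft.frame, protein=prot))
            seg_start = i + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


def assign_genes(orfs: list[OrfAnnotation],
                 probes: dict[str, str] | None = None,
                 min_probe_score: float = 100.0) -> list[OrfAnnotation]:
    """Guess GAG/POL/ENV for each ORF.

    With probe proteins supplied (keys GAG/POL/ENV), homology decides; else
    the three longest ORFs are labeled GAG, POL, ENV in positional order —
    the canonical retroviral gene order.
    """
    from dataclasses import replace

    if probes:
        out = []
        for orf in orfs:
            best_gene, best_score = "other", min_probe_score
            for gene, probe in sorted(probes.items()):
                score = al.local_align(orf.protein, probe,
                                       mode="protein").score
                if score > best_score:
                    best_gene, best_score = gene, score
            out.append(replace(orf, gene_guess=best_gene))
        return out
    ranked = sorted(orfs, key=lambda o: -o.length_aa)[:3]
    chosen = sorted(ranked, key=lambda o: o.start)
    labels = ["GAG", "POL", "ENV"][:len(chosen)]
    mapping = {id(o): lab for o, lab in zip(chosen, labels)}
    from dataclasses import replace as _r
    return [_r(o, gene_guess=mapping.get(id(o), "other")) for o in orfs]


def scan_motifs(protein: str) -> list[MotifHit]:
    """All occurrences of every motif pattern, overlapping matches included.

    CX6C is suppressed at anchors where CX6CC matches (the longer motif
    subsumes it). Matching is restricted to stop-free segments: motifs never
    span a '*'.
    """
    hits: list[MotifHit] = []
    offset = 0
    for segment in protein.split("*"):
        for motif_id, pattern in MOTIF_PATTERNS.items():
            for m in re.finditer(f"(?=({pattern.pattern}))", segment):
                pos = m.start()
                if motif_id == "CX6C" and \
                        MOTIF_PATTERNS["CX6CC"].match(segment, pos):
                    continue
                hits.append(MotifHit(motif_id=motif_id, position=offset + pos,
                                     match=m.group(1)))
        offset += len(segment) + 1
    hits.sort(key=lambda h: (h.position, h.motif_id))
    return hits


def classify_env_type(env_motifs: list[MotifHit]) -> str:
    """Envelope class from the TM cysteine motif: CX6CC marks a gamma-type
    envelope, CX6C without CX6CC a beta-type, neither is indeterminate."""
    ids = {h.motif_id for h in env_motifs}
    if "CX6CC" in ids:
        return "gamma_type"
    if "CX6C" in ids:
        return "beta_type"
    return "indeterminate"


PHYLO_MIN_AA = {"GAG": 500, "POL": 600, "ENV": 400}


def select_phylo_candidates(proteins: dict[tuple[str, str], str],
                            ) -> dict[tuple[str, str], str]:
    """Keep proteins long enough for tree building: GAG > 500 aa,
    POL > 600 aa, ENV > 400 aa (strict)."""
    out = {}
    for (lineage, gene), prot in proteins.items():
        floor = PHYLO_MIN_AA.get(gene)
        if floor is not None and len(prot) > floor:
            out[(lineage, gene)] = prot
    return out
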