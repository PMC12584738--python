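"""Ground-truth genome simulator: planted proviruses under a K2P clock.

The simulator is the forward process of the dating model the pipeline
inverts. A provirus template is LTR + PBS + gag/pol/env ORF cassettes + PPT +
LTR; on planting, a target-site duplication (TSD) is created, the two LTRs
are mutated *independently* for the element's age (so their expected
divergence is 2·R·t) and the internal region is mutated once. Degraded
copies additionally carry a premature stop per ORF; solo LTRs model the
product of LTR–LTR recombination (one aged LTR between the TSD copies);
nested elements carry a LINE-1-like cassette between ENV and the 3' LTR.

Substitutions follow the Kimura two-parameter process: per-site event counts
are Poisson(R·t) — equivalent to summing per-site exponential waiting times —
and each event is a transition with probability kappa/(kappa+1) or one of the
two transversions with probability 1/(2(kappa+1)) each, applied sequentially
so multiple hits (including back-mutations) occur naturally.

Host-side sequence (background, TSD copies) is not aged within one genome:
the clock of interest is the element's. Host divergence enters only in
:func:`simulate_species_pair`, where the whole descendant genomes are mutated
independently after the split. Indels, gene conversion and insertion-site
preference are out of scope.

Every random draw descends from one master seed through labeled streams, so
fixtures are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genome_io import ContigSet, Locus, write_tsv
from .trna_library import SYNTHETIC_TRNA_3P_18MERS, pbs_for

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate("ACGTN")}

# K2P event maps on codes A=0,C=1,G=2,T=3
_TRANSITION = np.array([2, 3, 0, 1, 4])
_TRANSVERSION_1 = np.array([1, 0, 1, 0, 4])   # A->C, C->A, G->C, T->A
_TRANSVERSION_2 = np.array([3, 2, 3, 2, 4])   # A->T, C->G, G->T, T->G

VALID_STATES = ("intact", "degraded", "solo", "nested")

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# deterministic codon choice per amino acid (first codon of the standard
# table, alphabetical); reverse translation randomizes over all synonyms
_CODONS: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            pass
_STANDARD = {
    "A": ["GCA", "GCC", "GCG", "GCT"], "C": ["TGC", "TGT"],
    "D": ["GAC", "GAT"], "E": ["GAA", "GAG"], "F": ["TTC", "TTT"],
    "G": ["GGA", "GGC", "GGG", "GGT"], "H": ["CAC", "CAT"],
    "I": ["ATA", "ATC", "ATT"], "K": ["AAA", "AAG"],
    "L": ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"],
    "M": ["ATG"], "N": ["AAC", "AAT"],
    "P": ["CCA", "CCC", "CCG", "CCT"], "Q": ["CAA", "CAG"],
    "R": ["AGA", "AGG", "CGA", "CGC", "CGG", "CGT"],
    "S": ["AGC", "AGT", "TCA", "TCC", "TCG", "TCT"],
    "T": ["ACA", "ACC", "ACG", "ACT"], "V": ["GTA", "GTC", "GTG", "GTT"],
    "W": ["TGG"], "Y": ["TAC", "TAT"],
}
_STOPS = ["TAA", "TAG", "TGA"]


class PlacementError(ValueError):
    """Insertion point collides with an already planted element."""


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """A labeled, reproducible RNG stream derived from one master seed."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF,
                                  zlib.crc32(label.encode())])


@dataclass(frozen=True)
class SubstitutionParams:
    """Neutral substitution process: rate R (subs/site/year) and kappa."""

    rate: float = 2.2e-9
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.kappa <= 0:
            raise ValueError("rate and kappa must be positive")


def encode(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, 4, dtype=np.int8)
    for c, i in _NT_INDEX.items():
        lut[ord(c)] = i
    return lut[out].astype(np.int64)


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def make_background(length: int, gc: float, rng: np.random.Generator | int,
                    ) -> str:
    """I.i.d. background DNA with expected GC content ``gc``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p)
    return decode(arr)


def mutate_k2p(seq: str, params: SubstitutionParams, time_myr: float,
               rng: np.random.Generator) -> str:
    """Evolve ``seq`` for ``time_myr`` under the K2P process. N sites are inert."""
    if time_myr < 0:
        raise ValueError("time_myr must be non-negative")
    if time_myr == 0 or not seq:
        return seq
    arr = encode(seq)
    mu = params.rate * time_myr * 1e6
    counts = rng.poisson(mu, size=len(arr))
    counts[arr == 4] = 0
    max_events = int(counts.max(initial=0))
    p_ts = params.kappa / (params.kappa + 1.0)
    for round_idx in range(max_events):
        active = np.flatnonzero(counts > round_idx)
        if len(active) == 0:
            break
        u = rng.random(len(active))
        ts = active[u < p_ts]
        tv = active[u >= p_ts]
        half = p_ts + (1 - p_ts) / 2
        tv1 = active[(u >= p_ts) & (u < half)]
        tv2 = active[u >= half]
        arr[ts] = _TRANSITION[arr[ts]]
        arr[tv1] = _TRANSVERSION_1[arr[tv1]]
        arr[tv2] = _TRANSVERSION_2[arr[tv2]]
        del tv
    return decode(arr)


# ---------------------------------------------------------------------------
# provirus templates

@dataclass(frozen=True)
class MotifTruth:
    gene: str        # GAG | POL | ENV
    motif_id: str
    aa_pos: int      # 0-based position within the gene's protein


@dataclass(frozen=True)
class ProvirusTemplate:
    """Blueprint of an un-aged provirus: LTR + PBS + ORFs + PPT + LTR."""

    lineage_id: str
    genus: str                  # Alpha | Beta | Gamma
    ltr: str
    pbs: str
    pbs_trna: str
    gag_nt: str
    pol_nt: str
    env_nt: str
    spacers: tuple[str, str, str, str]
    ppt: str
    tsd_len: int
    gag_aa: str
    pol_aa: str
    env_aa: str
    motif_truth: tuple[MotifTruth, ...]

    def __post_init__(self) -> None:
        if not (100 <= len(self.ltr) <= 7000):
            raise ValueError("LTR length must lie in [100, 7000]")
        if len(self.pbs) != 18:
            raise ValueError("PBS must be an 18-mer")
        if len(self.ppt) < 10:
            raise ValueError("PPT must be >= 10 nt")
        if not (4 <= self.tsd_len <= 6):
            raise ValueError("tsd_len must lie in [4, 6]")
        total = len(self.element)
        if not (2 * len(self.ltr) + 1000 <= total <= 15000 + len(self.ltr)):
            raise ValueError(
                f"element length {total} outside the detectable window")

    @property
    def internal(self) -> str:
        s1, s2, s3, s4 = self.spacers
        return (self.pbs + s1 + self.gag_nt + s2 + self.pol_nt + s3
                + self.env_nt + s4 + self.ppt)

    @property
    def element(self) -> str:
        return self.ltr + self.internal + self.ltr

    @property
    def internal_orf_offsets(self) -> dict[str, int]:
        """Offset of each gene's ORF start within the internal region."""
        s1, s2, s3, _ = self.spacers
        gag = len(self.pbs) + len(s1)
        pol = gag + len(self.gag_nt) + len(s2)
        env = pol + len(self.pol_nt) + len(s3)
        return {"GAG": gag, "POL": pol, "ENV": env}


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    idx = rng.integers(0, len(AA20), size=length)
    return [AA20[i] for i in idx]


def _place(protein: list[str], pos: int, instance: str) -> None:
    protein[pos:pos + len(instance)] = list(instance)


def _reverse_translate(protein: Sequence[str], rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        choices = _STANDARD[aa]
        codons.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(codons)


def make_template(rng: np.random.Generator, lineage_id: str = "Gamma.a",
                  genus: str = "Gamma", ltr_len: int = 600, tsd_len: int = 5,
                  pbs_trna: str = "Lys", gag_aa: int = 520, pol_aa: int = 650,
                  env_aa: int = 430) -> ProvirusTemplate:
    """Build a provirus template whose ORFs carry the full motif set at
    recorded positions, so motif recall is measurable against truth."""
    ltr = make_background(ltr_len, 0.45, rng)
    pbs = pbs_for(pbs_trna)
    ppt = "AGGGAGGGAAGGGGA"  # 15 nt, all purine

    gag = _random_protein(rng, gag_aa)
    gag[0] = "M"
    truth: list[MotifTruth] = []
    mhr_pos = gag_aa // 2
    _place(gag, mhr_pos, "QGTAEWKRLFDA")          # QGxxExxxxFxx
    truth.append(MotifTruth("GAG", "MHR", mhr_pos))
    ch_pos = gag_aa - 80
    _place(gag, ch_pos, "CLWCEKTNHSRDWC")          # CX2CX4HX4C
    truth.append(MotifTruth("GAG", "CysHis", ch_pos))
    pppy_pos = gag_aa - 30
    _place(gag, pppy_pos, "PPPY")
    truth.append(MotifTruth("GAG", "PPPY", pppy_pos))

    pol = _random_protein(rng, pol_aa)
    pol[0] = "M"

    env = _random_protein(rng, env_aa)
    env[0] = "M"
    rbm_pos = 100
    _place(env, rbm_pos, "SDGGGWTDSLR")            # SDGGGxxDxxR
    truth.append(MotifTruth("ENV", "RBM", rbm_pos))
    furin_pos = 200
    _place(env, furin_pos, "RQKR")                 # [KR]x[KR]R
    truth.append(MotifTruth("ENV", "Furin", furin_pos))
    cx_pos = 300
    _place(env, cx_pos, "CWNELGACC")               # CX6CC
    truth.append(MotifTruth("ENV", "CX6CC", cx_pos))
    yxxl_pos = env_aa - 20
    _place(env, yxxl_pos, "YTSL")                  # YxxL
    truth.append(MotifTruth("ENV", "YXXL", yxxl_pos))

    def orf(protein: list[str]) -> str:
        return _reverse_translate(protein, rng) + "TAA"

    # the spacer ahead of the PPT is pyrimidine-only so the planted tract is
    # the unique maximal purine run at the 3' junction
    spacers = tuple(make_background(12, 0.4, rng) for _ in range(3)) + \
        ("CTTCCTCTTTCC",)
    return ProvirusTemplate(
        lineage_id=lineage_id, genus=genus, ltr=ltr, pbs=pbs,
        pbs_trna=pbs_trna, gag_nt=orf(gag), pol_nt=orf(pol), env_nt=orf(env),
        spacers=spacers, ppt=ppt, tsd_len=tsd_len,
        gag_aa="".join(gag), pol_aa="".join(pol), env_aa="".join(env),
        motif_truth=tuple(truth),
    )


# ---------------------------------------------------------------------------
# truth table

@dataclass
class TruthRow:
    """One planted element: where it is, what it is, and how old it is."""

    element_id: str
    species_tag: str
    locus: Locus                    # element span (excludes the TSD copies)
    state: str
    true_age_myr: float
    tsd: str
    lineage_id: str
    ortholog_group: str = ""
    ltr5: Locus | None = None
    ltr3: Locus | None = None

    def to_record(self) -> dict[str, object]:
        return {
            "element_id": self.element_id,
            "species_tag": self.species_tag,
            "contig": self.locus.contig,
            "start": self.locus.start,
            "end": self.locus.end,
            "strand": self.locus.strand,
            "state": self.state,
            "true_age_myr": self.true_age_myr,
            "tsd": self.tsd,
            "lineage_id": self.lineage_id,
            "ortholog_group": self.ortholog_group,
            "ltr5_start": self.ltr5.start if self.ltr5 else "",
            "ltr5_end": self.ltr5.end if self.ltr5 else "",
            "ltr3_start": self.ltr3.start if self.ltr3 else "",
            "ltr3_end": self.ltr3.end if self.ltr3 else "",
        }


class TruthTable:
    """The simulator's planted elements with true states/ages — the
    acceptance surface every pipeline stage is scored against."""

    def __init__(self, rows: Iterable[TruthRow] = ()) -> None:
        self.rows: list[TruthRow] = list(rows)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def for_species(self, tag: str) -> list[TruthRow]:
        return [r for r in self.rows if r.species_tag == tag]

    def write_tsv(self, path) -> None:
        write_tsv([r.to_record() for r in self.rows], path)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in sorted(self.rows, key=lambda r: (r.species_tag,
                                                      r.locus.contig,
                                                      r.locus.start)):
                fh.write(f"{r.locus.contig}\t{r.locus.start}\t{r.locus.end}"
                         f"\t{r.element_id}\t{r.true_age_myr}"
                         f"\t{r.locus.strand}\n")


# ---------------------------------------------------------------------------
# planting

def _tsd_site_unambiguous(seq: str, point: int, tsd_len: int,
                          element: str, reach: int = 7) -> bool:
    """True when the planted TSD is the unique flanking duplication.

    Rejects sites where, after insertion, some boundary shift within
    ``reach`` bp would be flanked by an exact duplication *longer* than the
    planted TSD — such a site has no single well-defined integration
    boundary, so it cannot serve as ground truth.
    """
    tsd = seq[point:point + tsd_len]
    if "N" in tsd:
        return False
    ctx = 16
    left_ctx = seq[max(0, point - ctx):point]
    right_ctx = seq[point:point + ctx]
    post = left_ctx + tsd + element + right_ctx
    es = len(left_ctx) + tsd_len
    ee = es + len(element)
    for s in range(-reach, reach + 1):
        for e in range(-reach, reach + 1):
            for L in range(tsd_len + 1, 7):
                a = post[max(0, es + s - L):es + s]
                b = post[ee - e:ee - e + L]
                if len(a) == L and len(b) == L and a == b and "N" not in a:
                    return False
    return True


class GenomeSimulator:
    """Mutable genome being populated with planted elements.

    Insertion points are given in *current* coordinates; previously planted
    rows downstream of an insertion are shifted, so plants may arrive in any
    order. Overlapping a previously planted element raises
    :class:`PlacementError` rather than shifting the request (unambiguous
    truth).
    """

    def __init__(self, genome: ContigSet, params: SubstitutionParams,
                 master_seed: int, species_tag: str = "simA") -> None:
        self.contigs = dict(genome.contigs)
        self.params = params
        self.master_seed = int(master_seed)
        self.species_tag = species_tag
        self.truth = TruthTable()
        self._counter = 0
        self._line1_cache: str | None = None

    def as_contigset(self) -> ContigSet:
        return ContigSet(dict(self.contigs), species_tag=self.species_tag)

    def _rng(self, label: str) -> np.random.Generator:
        return derive_rng(self.master_seed, label)

    def _line1_cassette(self) -> str:
        # one shared LINE-1-like cassette per simulation: a long interspersed
        # non-LTR element body (no terminal repeats), ~3 kb
        if self._line1_cache is None:
            rng = self._rng("line1")
            body = _random_protein(rng, 950)
            body[0] = "M"
            orf2 = _reverse_translate(body, rng) + "TAA"
            self._line1_cache = make_background(120, 0.4, rng) + orf2 + \
                "A" * 30  # poly-A tail
        return self._line1_cache

    def _build_element(self, template: ProvirusTemplate, age_myr: float,
                       state: str, rng: np.random.Generator,
                       ) -> tuple[str, int, int]:
        """Return (element sequence, ltr5 length, ltr3 length)."""
        ltr5 = mutate_k2p(template.ltr, self.params, age_myr, rng)
        if state == "solo":
            return ltr5, len(ltr5), 0
        ltr3 = mutate_k2p(template.ltr, self.params, age_myr, rng)
        internal = template.internal
        if state == "degraded":
            internal = self._degrade(template)
        internal = mutate_k2p(internal, self.params, age_myr, rng)
        if state == "nested":
            # LINE-1-like interruption between ENV and the 3' LTR; the
            # element's own spacer/PPT junction stays intact downstream
            cut = len(internal) - len(template.ppt) - len(template.spacers[3])
            internal = internal[:cut] + self._line1_cassette() + internal[cut:]
        return ltr5 + internal + ltr3, len(ltr5), len(ltr3)

    @staticmethod
    def _degrade(template: ProvirusTemplate) -> str:
        """Inject one premature stop codon mid-ORF in each of GAG/POL/ENV."""
        internal = template.internal
        out = internal
        for gene, off in template.internal_orf_offsets.items():
            orf_len = {"GAG": len(template.gag_nt), "POL": len(template.pol_nt),
                       "ENV": len(template.env_nt)}[gene]
            stop_at = off + 3 * ((orf_len // 3) // 2)
            out = out[:stop_at] + "TAA" + out[stop_at + 3:]
        return out

    def plant(self, template: ProvirusTemplate, contig: str, point: int,
              age_myr: float, state: str) -> TruthRow:
        if state not in VALID_STATES:
            raise ValueError(f"unknown state {state!r}")
        seq = self.contigs[contig]
        if not (template.tsd_len <= point <= len(seq) - template.tsd_len):
            raise PlacementError("insertion point too close to a contig end")
        for row in self.truth.for_species(self.species_tag):
            if row.locus.contig == contig and \
                    row.locus.start - template.tsd_len <= point < \
                    row.locus.end + template.tsd_len:
                raise PlacementError(
                    f"insertion point {point} overlaps {row.element_id}")

        self._counter += 1
        eid = f"{self.species_tag}_e{self._counter:03d}"
        rng = self._rng(f"plant/{eid}")
        element, ltr5_len, ltr3_len = self._build_element(
            template, age_myr, state, rng)
        # An integration site is ambiguous when chance context matches create
        # a flanking duplication longer than the planted TSD at a nearby
        # boundary shift (the TSD is then not unique, as happens in real
        # genomes). Slide to the nearest unambiguous site so the planted TSD
        # is a well-defined ground truth.
        for _ in range(200):
            if _tsd_site_unambiguous(seq, point, template.tsd_len, element):
                break
            point += 1
            if point > len(seq) - template.tsd_len:
                raise PlacementError("no unambiguous insertion site found")
        else:
            raise PlacementError("no unambiguous insertion site found")
        tsd = seq[point:point + template.tsd_len]
        inserted = tsd + element
        self.contigs[contig] = seq[:point] + inserted + seq[point:]

        shift = len(inserted)
        for row in self.truth.rows:
            if row.species_tag == self.species_tag and \
                    row.locus.contig == contig and row.locus.start >= point:
                row.locus = Locus(contig, row.locus.start + shift,
                                  row.locus.end + shift, row.locus.strand)
                if row.ltr5:
                    row.ltr5 = Locus(contig, row.ltr5.start + shift,
                                     row.ltr5.end + shift, row.ltr5.strand)
                if row.ltr3:
                    row.ltr3 = Locus(contig, row.ltr3.start + shift,
                                     row.ltr3.end + shift, row.ltr3.strand)

        el_start = point + template.tsd_len
        el_end = el_start + len(element)
        ltr5_loc = Locus(contig, el_start, el_start + ltr5_len)
        ltr3_loc = (Locus(contig, el_end - ltr3_len, el_end)
                    if ltr3_len else None)
        row = TruthRow(
            element_id=eid, species_tag=self.species_tag,
            locus=Locus(contig, el_start, el_end), state=state,
            true_age_myr=age_myr, tsd=tsd, lineage_id=template.lineage_id,
            ltr5=ltr5_loc, ltr3=ltr3_loc,
        )
        self.truth.rows.append(row)
        return row


def plant(genome: ContigSet, template: ProvirusTemplate, contig: str,
          point: int, age_myr: float, state: str, params: SubstitutionParams,
          seed: int) -> tuple[ContigSet, TruthRow]:
    """One-shot planting convenience over :class:`GenomeSimulator`."""
    sim = GenomeSimulator(genome, params, seed, species_tag=genome.species_tag
                          or "sim")
    row = sim.plant(template, contig, point, age_myr, state)
    return sim.as_contigset(), row


# ---------------------------------------------------------------------------
# species pair

def simulate_species_pair(ancestor: GenomeSimulator, speciation_myr: float,
                          private: Sequence[tuple[ProvirusTemplate, str, int,
                                                  float, str, str]] = (),
                          tags: tuple[str, str] = ("Mpen", "Mjav"),
                          ) -> tuple[ContigSet, ContigSet, TruthTable]:
    """Evolve two descendant genomes from a populated ancestor.

    Every ancestral element becomes an orthologous insertion present in both
    descendants (shared ``ortholog_group``); ``private`` requests
    ``(template, species_tag, contig, point, age, state)`` are planted
    post-split in exactly one descendant. Because the substitution process is
    indel-free, ancestral coordinates remain valid in both descendants until
    private insertions shift them (handled by the per-species simulators).
    """
    if speciation_myr < 0:
        raise ValueError("speciation_myr must be non-negative")
    tag_a, tag_b = tags
    params = ancestor.params
    out: dict[str, GenomeSimulator] = {}
    truth = TruthTable()
    for tag in (tag_a, tag_b):
        rng = derive_rng(ancestor.master_seed, f"speciation/{tag}")
        contigs = {
            cid: mutate_k2p(seq, params, speciation_myr, rng)
            for cid, seq in ancestor.contigs.items()
        }
        sim = GenomeSimulator(ContigSet(contigs, species_tag=tag), params,
                              ancestor.master_seed + (1 if tag == tag_b else 0),
                              species_tag=tag)
        for row in ancestor.truth.rows:
            sim.truth.rows.append(TruthRow(
                element_id=f"{tag}_{row.element_id}", species_tag=tag,
                locus=Locus(row.locus.contig, row.locus.start, row.locus.end,
                            row.locus.strand),
                state=row.state,
                true_age_myr=row.true_age_myr + speciation_myr,
                tsd=row.tsd, lineage_id=row.lineage_id,
                ortholog_group=row.element_id,
                ltr5=row.ltr5, ltr3=row.ltr3,
            ))
        out[tag] = sim
    for template, tag, contig, point, age, state in private:
        out[tag].plant(template, contig, point, age, state)
    for tag in (tag_a, tag_b):
        truth.rows.extend(out[tag].truth.rows)
    return out[tag_a].as_contigset(), out[tag_b].as_contigset(), truth


# ---------------------------------------------------------------------------
# species-pair demo

@dataclass
class PairDemoSpec:
    """Conditions of the bundled two-species demo simulation.

    Five orthologous insertions planted in a common ancestor (one per
    contig), evolved through a speciation event, plus post-split private
    insertions in each descendant. Descendant element ages stay at or below
    ~10 Myr so every structural feature remains recoverable.
    """

    n_contigs: int = 7
    contig_length: int = 70_000
    gc: float = 0.42
    shared_ages: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 1.0)
    shared_states: tuple[str, ...] = ("intact", "intact", "intact",
                                      "intact", "degraded")
    speciation_myr: float = 8.0
    rate: float = 2.2e-9
    kappa: float = 2.0
    tags: tuple[str, str] = ("Mpen", "Mjav")


def build_pair_demo(seed: int, spec: PairDemoSpec | None = None,
                    ) -> tuple[ContigSet, ContigSet, TruthTable,
                               list[ProvirusTemplate]]:
    """Simulate the bundled orthology demo: two descendant genomes sharing
    five ancestral insertions, each also carrying private ones."""
    spec = spec or PairDemoSpec()
    params = SubstitutionParams(rate=spec.rate, kappa=spec.kappa)
    rng_bg = derive_rng(seed, "pair/background")
    contigs = {
        f"anc{i + 1}": make_background(spec.contig_length, spec.gc, rng_bg)
        for i in range(spec.n_contigs)
    }
    anc = GenomeSimulator(ContigSet(contigs, species_tag="ancestor"), params,
                          seed, species_tag="ancestor")
    rng_t = derive_rng(seed, "pair/templates")
    templates = [
        make_template(rng_t, lineage_id="Gamma.a", genus="Gamma",
                      pbs_trna="Pro", tsd_len=5),
        make_template(rng_t, lineage_id="Beta.a", genus="Beta",
                      pbs_trna="Lys", tsd_len=4, ltr_len=387),
    ]
    for i, (age, state) in enumerate(zip(spec.shared_ages,
                                         spec.shared_states)):
        template = templates[0] if i % 3 != 2 else templates[1]
        anc.plant(template, f"anc{i + 1}", spec.contig_length // 2, age,
                  state)
    tag_a, tag_b = spec.tags
    nA, nB = spec.n_contigs - 1, spec.n_contigs
    private = [
        (templates[0], tag_a, f"anc{nA}", spec.contig_length // 2, 3.0,
         "intact"),
        (templates[0], tag_a, f"anc{nA}", 8_000, 2.0, "solo"),
        (templates[1], tag_b, f"anc{nB}", spec.contig_length // 2, 4.0,
         "intact"),
        (templates[0], tag_b, f"anc{nB}", 8_000, 1.0, "solo"),
    ]
    genomeA, genomeB, truth = simulate_species_pair(
        anc, spec.speciation_myr, private=private, tags=spec.tags)
    return genomeA, genomeB, truth, templates


# ---------------------------------------------------------------------------
# demo genome

@dataclass
class DemoSpec:
    """Conditions of the bundled single-genome demo simulation."""

    genome_length: int = 620_000
    gc: float = 0.42
    n_contigs: int = 2
    species_tag: str = "Msyn"
    ages_myr: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 10.0)
    n_intact: int = 12
    n_degraded: int = 4
    n_solo: int = 5
    n_nested: int = 1
    min_spacing: int = 16_000
    rate: float = 2.2e-9
    kappa: float = 2.0


def build_demo(seed: int, spec: DemoSpec | None = None,
               ) -> tuple[GenomeSimulator, list[ProvirusTemplate]]:
    """Simulate the bundled demo genome: two lineages, >=20 planted elements
    spaced >15 kb apart, ages <= 10 Myr, with every state represented."""
    spec = spec or DemoSpec()
    params = SubstitutionParams(rate=spec.rate, kappa=spec.kappa)
    rng_bg = derive_rng(seed, "background")
    per_contig = spec.genome_length // spec.n_contigs
    contigs = {
        f"chr{i + 1}": make_background(per_contig, spec.gc, rng_bg)
        for i in range(spec.n_contigs)
    }
    genome = ContigSet(contigs, species_tag=spec.species_tag)
    sim = GenomeSimulator(genome, params, seed, species_tag=spec.species_tag)

    rng_t = derive_rng(seed, "templates")
    templates = [
        make_template(rng_t, lineage_id="Gamma.a", genus="Gamma",
                      pbs_trna="Pro", tsd_len=5),
        make_template(rng_t, lineage_id="Beta.a", genus="Beta",
                      pbs_trna="Lys", tsd_len=4, ltr_len=387),
    ]

    states = (["intact"] * spec.n_intact + ["degraded"] * spec.n_degraded
              + ["solo"] * spec.n_solo + ["nested"] * spec.n_nested)
    n = len(states)
    rng_place = derive_rng(seed, "placement")
    # deterministic round-robin over contigs with fixed spacing + jitter
    slots_per_contig = -(-n // spec.n_contigs)
    idx = 0
    for ci in range(spec.n_contigs):
        cid = f"chr{ci + 1}"
        pos = 8_000
        for _ in range(slots_per_contig):
            if idx >= n:
                break
            state = states[idx]
            template = templates[0] if idx % 3 != 2 else templates[1]
            age = spec.ages_myr[idx % len(spec.ages_myr)]
            jitter = int(rng_place.integers(0, 2_000))
            row = sim.plant(template, cid, pos + jitter, age, state)
            # next insertion point in *current* coordinates, > min_spacing
            # downstream of the element just planted
            pos = row.locus.end + spec.min_spacing + template.tsd_len
            idx += 1
    return sim, templates
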