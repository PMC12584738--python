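"""End-to-end orchestration: simulate -> scan -> annotate -> lineages ->
solos -> motifs -> date -> orthologs -> report.

The desk-mode pipeline runs on the bundled two-species simulation: every
stage writes its outputs (FASTA/GFF3/TSV) into the run directory before the
next stage starts, the effective configuration is echoed alongside, and a
rerun with the same config and seed is byte-identical. Stage logging
(attrition counts: hits before/after each filter) goes to stderr, never
into the output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment as al
from . import dating as dat
from . import discovery as disc
from . import lineages as lin
from . import motifs as mot
from . import orthology as orth
from .config import RunConfig
from .genome_io import ContigSet, Feature, Locus, extract, write_fasta, \
    write_gff3, write_tsv
from .ltr_structure import ProvirusCandidate, annotate_candidate
from .synthetic_genome import PairDemoSpec, ProvirusTemplate, TruthTable, \
    build_pair_demo

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    genome_a: ContigSet
    genome_b: ContigSet
    truth: TruthTable
    templates: list[ProvirusTemplate]
    candidates: list[disc.CandidateLocus] = field(default_factory=list)
    catalog: list[ProvirusCandidate] = field(default_factory=list)
    lineages: list[lin.Lineage] = field(default_factory=list)
    lineage_of_element: dict[str, str] = field(default_factory=dict)
    solos: list[lin.SoloLtr] = field(default_factory=list)
    motif_records: list[dict] = field(default_factory=list)
    env_types: dict[str, str] = field(default_factory=dict)
    datings: list[tuple[str, dat.DatingResult]] = field(default_factory=list)
    ortholog_calls: list[tuple[str, orth.OrthologCall]] = \
        field(default_factory=list)
    summary_rows: list[dict] = field(default_factory=list)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return inner
    return wrap


# ---------------------------------------------------------------------------
# stages

@_stage("simulate")
def _simulate(config: RunConfig):
    spec = PairDemoSpec(
        n_contigs=config.sim_n_contigs,
        contig_length=config.sim_contig_length,
        gc=config.sim_gc,
        speciation_myr=config.sim_speciation_myr,
        rate=config.sim_rate, kappa=config.sim_kappa,
        tags=(config.host_suffix_a, config.host_suffix_b),
    )
    return build_pair_demo(config.seed, spec)


@_stage("scan")
def _scan(config: RunConfig, genome_a: ContigSet,
          templates: list[ProvirusTemplate]) -> list[disc.CandidateLocus]:
    probes = {f"POL_{t.lineage_id}": t.pol_aa for t in templates}
    candidates = disc.screen_genome(probes, genome_a,
                                    config.screen_params())
    logger.info("scan: %d candidate loci", len(candidates))
    return candidates


@_stage("annotate")
def _annotate(config: RunConfig, genome_a: ContigSet,
              candidates: list[disc.CandidateLocus],
              ) -> list[ProvirusCandidate]:
    catalog = []
    params = config.ltr_params()
    for i, cand in enumerate(candidates):
        pv = annotate_candidate(genome_a, cand, params,
                                element_id=f"ERV{i + 1:03d}")
        if pv is None:
            logger.info("annotate: candidate %d at %s has no LTR pair",
                        i + 1, cand.locus)
            continue
        pv.stage = cand.stage
        catalog.append(pv)
    logger.info("annotate: %d/%d candidates assembled, %d full length",
                len(catalog), len(candidates),
                sum(p.full_length for p in catalog))
    return catalog


@_stage("lineages")
def _lineages(config: RunConfig, genome_a: ContigSet,
              candidates: list[disc.CandidateLocus],
              catalog: list[ProvirusCandidate],
              templates: list[ProvirusTemplate]):
    params = config.lineage_params()
    genus_of_probe = {f"POL_{t.lineage_id}": t.genus for t in templates}

    copies: list[lin.CopyHit] = []
    for pv in catalog:
        if not pv.full_length:
            continue
        if any(c.locus.overlaps(pv.span) for c in copies):
            continue   # this element is already retrieved as a copy
        query, _, _ = extract(genome_a, pv.span)
        for hit in lin.find_copies(query, genome_a, params):
            if not any(c.locus.overlaps(hit.locus) for c in copies):
                copies.append(hit)
    copies.sort(key=lambda c: (c.locus.contig, c.locus.start))
    seqs = [extract(genome_a, c.locus)[0] for c in copies]
    if not copies:
        return [], {}
    clusters = lin.cluster_lineages(seqs, params)
    consensuses = [lin.build_consensus([seqs[i] for i in idx], params)
                   for idx in clusters]

    # genus from probe provenance of the candidate overlapping each cluster
    cand_genus: list[str] = []
    for idx in clusters:
        label = "unassigned"
        for i in idx:
            for cand in candidates:
                if cand.locus.overlaps(copies[i].locus):
                    label = genus_of_probe.get(cand.best_query_id,
                                               "unassigned")
                    break
            if label != "unassigned":
                break
        cand_genus.append(label)
    named = lin.assign_names([[copies[i] for i in idx] for idx in clusters],
                             consensuses, cand_genus, config.host_suffix_a)

    lineage_of_element: dict[str, str] = {}
    for pv in catalog:
        for lineage in named:
            for copy, cname in zip(lineage.copies, lineage.copy_names):
                if copy.locus.overlaps(pv.span):
                    lineage_of_element[pv.element_id] = lineage.name
                    pv.lineage_name = cname
    logger.info("lineages: %d copies in %d lineages", len(copies),
                len(named))
    return named, lineage_of_element


def _lineage_parts(genome_a: ContigSet, catalog: list[ProvirusCandidate],
                   lineage_of_element: dict[str, str],
                   ) -> dict[str, tuple[str, str]]:
    """Per lineage: (5' LTR sequence, internal sequence) of its best member."""
    parts: dict[str, tuple[str, str]] = {}
    for pv in catalog:
        if not pv.full_length or pv.internal is None:
            continue
        name = lineage_of_element.get(pv.element_id)
        if name is None or name in parts:
            continue
        ltr, _, _ = extract(genome_a, pv.ltr5)
        internal, _, _ = extract(genome_a, pv.internal)
        parts[name] = (ltr, internal)
    return parts


@_stage("solos")
def _solos(config: RunConfig, genome_a: ContigSet,
           lineage_parts: dict[str, tuple[str, str]],
           lineages: list[lin.Lineage]) -> list[lin.SoloLtr]:
    params = config.lineage_params()
    genus_of = {}
    ltr_queries = {}
    internal_queries = {}
    genus_by_name = {l.name: l.genus_label for l in lineages}
    for name, (ltr, internal) in sorted(lineage_parts.items()):
        qid = f"LTR_{name}"
        ltr_queries[qid] = ltr
        internal_queries[f"INT_{name}"] = internal
        genus_of[qid] = genus_by_name.get(name, "unassigned")
    if not ltr_queries:
        return []
    solos = lin.classify_solo_ltrs(ltr_queries, genome_a, internal_queries,
                                   params, host_suffix=config.host_suffix_a,
                                   genus_of=genus_of)
    logger.info("solos: %d solo LTRs", len(solos))
    return solos


@_stage("motifs")
def _motifs(config: RunConfig, lineages: list[lin.Lineage]):
    records: list[dict] = []
    env_types: dict[str, str] = {}
    for lineage in lineages:
        orfs = mot.find_orfs(lineage.consensus, min_nt=config.orf_min_nt,
                             require_atg=config.require_atg)
        orfs = mot.assign_genes(orfs)
        env_hits: list[mot.MotifHit] = []
        for orf in orfs:
            if orf.gene_guess == "other":
                continue
            for hit in mot.scan_motifs(orf.protein):
                records.append({
                    "lineage": lineage.name, "gene": orf.gene_guess,
                    "motif": hit.motif_id, "position": hit.position,
                    "match": hit.match,
                })
                if orf.gene_guess == "ENV":
                    env_hits.append(hit)
        env_types[lineage.name] = mot.classify_env_type(env_hits)
    return records, env_types


@_stage("date")
def _date(config: RunConfig, genome_a: ContigSet,
          catalog: list[ProvirusCandidate],
          lineage_of_element: dict[str, str],
          ) -> list[tuple[str, dat.DatingResult]]:
    out = []
    for pv in catalog:
        if not pv.full_length:
            logger.info("date: %s skipped (not full length)", pv.element_id)
            continue
        res = dat.date_provirus(pv, genome_a, R=config.dating_rate)
        out.append((lineage_of_element.get(pv.element_id, ""), res))
    return out


@_stage("orthologs")
def _orthologs(config: RunConfig, genome_a: ContigSet, genome_b: ContigSet,
               catalog: list[ProvirusCandidate],
               lineage_parts: dict[str, tuple[str, str]],
               ) -> list[tuple[str, orth.OrthologCall]]:
    screen = config.screen_params()
    ltrp = config.ltr_params()
    cand_b: list[Locus] = []
    for name, (_, internal) in sorted(lineage_parts.items()):
        for cand in disc.rt_cross_species_search(internal, genome_b, screen,
                                                 query_id=f"RT_{name}"):
            pv = annotate_candidate(genome_b, cand, ltrp,
                                    element_id=f"B_{name}")
            span = pv.span if pv is not None else cand.locus
            if not any(span.overlaps(s) for s in cand_b):
                cand_b.append(span)
    cand_b.sort()
    loci_a = [(pv.element_id, pv.span) for pv in catalog if pv.full_length]
    calls = orth.survey_orthologs(loci_a, genome_a, genome_b, cand_b,
                                  config.orthology_params())
    logger.info("orthologs: %d/%d elements called ortholog",
                sum(c.is_ortholog for _, c in calls), len(loci_a))
    return calls


@_stage("report")
def _report(result: PipelineResult) -> list[dict]:
    rows = []
    per_lineage_T: dict[str, list[float]] = {}
    per_lineage_sat: dict[str, int] = {}
    for name, res in result.datings:
        if res.ok:
            per_lineage_T.setdefault(name, []).append(res.T_mya)
        else:
            per_lineage_sat[name] = per_lineage_sat.get(name, 0) + 1
    ortho_by_lineage: dict[str, int] = {}
    for eid, call in result.ortholog_calls:
        if call.is_ortholog:
            name = result.lineage_of_element.get(eid, "")
            ortho_by_lineage[name] = ortho_by_lineage.get(name, 0) + 1
    motif_ids = sorted({r["motif"] for r in result.motif_records})
    for lineage in result.lineages:
        Ts = per_lineage_T.get(lineage.name, [])
        if Ts:
            age_range = f"{min(Ts):.2f}-{max(Ts):.2f}"
        elif per_lineage_sat.get(lineage.name):
            age_range = "NA"
        else:
            age_range = ""
        full = sum(1 for pv in result.catalog
                   if result.lineage_of_element.get(pv.element_id)
                   == lineage.name and pv.full_length)
        present = {r["motif"] for r in result.motif_records
                   if r["lineage"] == lineage.name}
        n_solo = sum(1 for s in result.solos
                     if lin.parse_name(s.lineage_name)["genus"]
                     == lineage.genus_label)
        row = {
            "lineage": lineage.name,
            "genus": lineage.genus_label,
            "n_copies": len(lineage.copies),
            "n_full_length": full,
            "n_solo": n_solo,
            "age_min_mya": f"{min(Ts):.2f}" if Ts else "NA",
            "age_max_mya": f"{max(Ts):.2f}" if Ts else "NA",
            "age_range": age_range,
            "n_saturated": per_lineage_sat.get(lineage.name, 0),
            "n_orthologs": ortho_by_lineage.get(lineage.name, 0),
            "env_type": result.env_types.get(lineage.name, ""),
        }
        for mid in motif_ids:
            row[f"motif_{mid}"] = int(mid in present)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# driver

SUMMARY_BASE_COLUMNS = ["lineage", "genus", "n_copies", "n_full_length",
                        "n_solo", "age_min_mya", "age_max_mya", "age_range",
                        "n_saturated", "n_orthologs", "env_type"]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 ) -> PipelineResult:
    """Run every stage in dependency order, writing outputs as each stage
    completes; returns the in-memory result bundle."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    genome_a, genome_b, truth, templates = _simulate(config)
    result = PipelineResult(genome_a=genome_a, genome_b=genome_b,
                            truth=truth, templates=templates)
    write_fasta(genome_a.contigs, out / "genome_a.fasta")
    write_fasta(genome_b.contigs, out / "genome_b.fasta")
    truth.write_tsv(out / "truth.tsv")
    truth.write_bed(out / "truth.bed")
    write_fasta({f"POL_{t.lineage_id}": t.pol_aa for t in templates},
                out / "probes.faa")

    result.candidates = _scan(config, genome_a, templates)
    write_gff3([Feature(c.locus, "candidate_ERV",
                        attributes={"ID": f"cand{i + 1}",
                                    "stage": c.stage,
                                    "best_query": c.best_query_id})
                for i, c in enumerate(result.candidates)],
               out / "candidates.gff3")
    write_tsv(al.hits_to_records(
        [h for c in result.candidates for h in c.supporting_hits]),
        out / "screen_hits.tsv", columns=al.OUTFMT6_COLUMNS)

    result.catalog = _annotate(config, genome_a, result.candidates)
    result.lineages, result.lineage_of_element = _lineages(
        config, genome_a, result.candidates, result.catalog, templates)
    write_tsv([pv.to_record() for pv in result.catalog],
              out / "catalog.tsv")
    feats = []
    for pv in result.catalog:
        feats.append(Feature(pv.span, "LTR_retrotransposon",
                             attributes={"ID": pv.element_id,
                                         "full_length":
                                         str(pv.full_length).lower()}))
        feats.append(Feature(pv.ltr5, "long_terminal_repeat",
                             attributes={"Parent": pv.element_id}))
        if pv.ltr3:
            feats.append(Feature(pv.ltr3, "long_terminal_repeat",
                                 attributes={"Parent": pv.element_id}))
        if pv.pbs:
            feats.append(Feature(pv.pbs.locus, "primer_binding_site",
                                 attributes={"Parent": pv.element_id,
                                             "trna": pv.pbs.trna_label}))
        if pv.ppt:
            feats.append(Feature(pv.ppt.locus, "RR_tract",
                                 attributes={"Parent": pv.element_id}))
    write_gff3(feats, out / "proviruses.gff3")
    write_tsv([{"lineage": l.name, "genus": l.genus_label,
                "n_copies": len(l.copies),
                "copies": ";".join(f"{c.locus.contig}:{c.locus.start}-"
                                   f"{c.locus.end}" for c in l.copies)}
               for l in result.lineages], out / "lineages.tsv")
    write_fasta({l.name: l.consensus for l in result.lineages},
                out / "consensus.fasta")

    parts = _lineage_parts(genome_a, result.catalog,
                           result.lineage_of_element)
    result.solos = _solos(config, genome_a, parts, result.lineages)
    write_tsv([{"name": s.lineage_name, "contig": s.locus.contig,
                "start": s.locus.start, "end": s.locus.end,
                "identity_to_consensus":
                f"{s.identity_to_consensus:.4f}"}
               for s in result.solos], out / "solos.tsv")

    result.motif_records, result.env_types = _motifs(config,
                                                     result.lineages)
    write_tsv(result.motif_records, out / "motifs.tsv",
              columns=["lineage", "gene", "motif", "position", "match"])

    result.datings = _date(config, genome_a, result.catalog,
                           result.lineage_of_element)
    write_tsv([dict(res.to_record(), lineage=name)
               for name, res in result.datings], out / "dating.tsv")

    result.ortholog_calls = _orthologs(config, genome_a, genome_b,
                                       result.catalog, parts)
    write_tsv([dict(call.to_record(), element_id=eid)
               for eid, call in result.ortholog_calls],
              out / "orthologs.tsv")

    result.summary_rows = _report(result)
    motif_cols = sorted({k for row in result.summary_rows for k in row
                         if k.startswith("motif_")})
    write_tsv(result.summary_rows, out / "summary.tsv",
              columns=SUMMARY_BASE_COLUMNS + motif_cols)
    _write_summary_text(result, out / "summary.txt")
    return result


def _write_summary_text(result: PipelineResult, path: Path) -> None:
    lines = ["ervatlas run summary", "====================", ""]
    for row in result.summary_rows:
        lines.append(
            f"{row['lineage']}: {row['n_copies']} copies "
            f"({row['n_full_length']} full length, {row['n_solo']} solo), "
            f"insertion times {row['age_range'] or 'NA'} Mya, "
            f"{row['n_orthologs']} orthologous insertions, "
            f"env {row['env_type'] or 'NA'}")
    n_solo = len(result.solos)
    n_ortho = sum(c.is_ortholog for _, c in result.ortholog_calls)
    lines += ["", f"total solo LTRs: {n_solo}",
              f"total orthologous insertions: {n_ortho}", ""]
    path.write_text("\n".join(lines))
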