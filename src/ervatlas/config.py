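"""One flat registry of every threshold the pipeline uses.

Defaults are the published operating points of each stage (screen filters,
LTR geometry, copy/cluster/solo gates, dating rate, orthology rule). A
config file is flat key: value YAML; unknown keys are rejected so drift
between documentation and behaviour cannot hide, and the effective
configuration is echoed into every run directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .discovery import ScreenParams
from .lineages import LineageParams
from .ltr_structure import LtrParams
from .orthology import OrthologyParams


@dataclass
class RunConfig:
    # run
    seed: int = 1
    out_dir: str = "ervatlas_run"
    host_suffix_a: str = "Mpen"
    host_suffix_b: str = "Mjav"
    # simulation (desk mode)
    sim_contig_length: int = 70000
    sim_n_contigs: int = 7
    sim_gc: float = 0.42
    sim_speciation_myr: float = 8.0
    sim_rate: float = 2.2e-9
    sim_kappa: float = 2.0
    # protein screen
    screen_min_identity: float = 0.30
    screen_min_coverage: float = 0.40
    screen_evalue: float = 1e-5
    screen_merge_gap: int = 1000
    # LTR structure
    ltr_min_len: int = 100
    ltr_max_len: int = 7000
    ltr_min_dist: int = 1000
    ltr_max_dist: int = 15000
    ltr_min_similarity: float = 0.85
    tsd_min: int = 4
    tsd_max: int = 6
    pbs_offset_max: int = 20
    pbs_mismatch_max: int = 2
    ppt_offset_max: int = 20
    ppt_min_len: int = 10
    ppt_purine_fraction: float = 0.9
    # lineages / solos
    copy_min_len: int = 4000
    copy_min_identity: float = 0.80
    cluster_identity: float = 0.90
    solo_min_coverage: float = 0.10
    solo_min_identity: float = 0.80
    solo_window: int = 15000
    # ORFs / motifs
    orf_min_nt: int = 180
    require_atg: bool = True
    # dating
    dating_rate: float = 2.2e-9
    # cross-species RT search
    rt_min_identity: float = 0.80
    rt_min_coverage: float = 0.80
    # orthology
    ortho_flank: int = 30000
    ortho_min_insertion_identity: float = 0.85
    ortho_min_flank_coverage: float = 0.50
    ortho_min_aln_len: int = 500
    ortho_evalue: float = 1e-5

    # ----- derived per-stage parameter objects -----

    def screen_params(self) -> ScreenParams:
        return ScreenParams(
            min_identity=self.screen_min_identity,
            min_coverage=self.screen_min_coverage,
            evalue_cutoff=self.screen_evalue,
            merge_gap=self.screen_merge_gap,
            rt_min_identity=self.rt_min_identity,
            rt_min_coverage=self.rt_min_coverage,
        )

    def ltr_params(self) -> LtrParams:
        return LtrParams(
            min_ltr_len=self.ltr_min_len, max_ltr_len=self.ltr_max_len,
            min_dist=self.ltr_min_dist, max_dist=self.ltr_max_dist,
            min_similarity=self.ltr_min_similarity,
            tsd_min=self.tsd_min, tsd_max=self.tsd_max,
            pbs_offset_max=self.pbs_offset_max,
            pbs_mismatch_max=self.pbs_mismatch_max,
            ppt_offset_max=self.ppt_offset_max,
            ppt_min_len=self.ppt_min_len,
            ppt_purine_fraction=self.ppt_purine_fraction,
        )

    def lineage_params(self) -> LineageParams:
        return LineageParams(
            min_copy_len=self.copy_min_len,
            min_copy_identity=self.copy_min_identity,
            cluster_identity=self.cluster_identity,
            solo_min_coverage=self.solo_min_coverage,
            solo_min_identity=self.solo_min_identity,
            solo_window=self.solo_window,
            pair_min_dist=self.ltr_min_dist,
            pair_max_dist=self.ltr_max_dist,
        )

    def orthology_params(self) -> OrthologyParams:
        return OrthologyParams(
            flank=self.ortho_flank,
            min_insertion_identity=self.ortho_min_insertion_identity,
            min_flank_coverage=self.ortho_min_flank_coverage,
            min_aln_len=self.ortho_min_aln_len,
            evalue_cutoff=self.ortho_evalue,
        )

    # ----- I/O -----

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
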