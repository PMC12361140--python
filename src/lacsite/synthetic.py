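"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study's measurement layers with known ground
truth, so parameter recovery can be tested end to end without the original
raw data:

* qRT-PCR CT tables whose ddCT-recovered fold changes equal configured
  truths.  Reference-gene CT is a base value plus a biological replicate
  effect plus technical noise; target CT subtracts log2(fold change) and
  shares the same biological effect (sample-loading covariance that dCT
  cancels), making ddCT unbiased by construction.
* Plate-reader ONPG curves sampled from the smoothed-Monod model plus
  Gaussian OD noise on the 0-240 min, 5-min grid (49 points).
* A toy circular genome whose target-site neighborhoods realize the study's
  six topology archetypes (divergent promoters, downstream ORF,
  inter-operonic, pre-terminator, convergent 3', intra-gene), with
  compartment intervals, replication origins and per-site coordinates laid
  out to reproduce the published site table's nearest-origin geometry.
* Binomial pop-in CFU screening counts.

One global seed is expanded into independent substreams (ct, kinetics, cfu)
so adding draws to one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_context import (
    CircularGenome,
    CompartmentInterval,
    GeneFeature,
    ReplicationOrigin,
    TargetSite,
    TerminatorFeature,
)
from .kinetics import KineticCurve, MonodFitParams, eval_model

__all__ = [
    "StrainSpec",
    "SynthConfig",
    "study_mimic_config",
    "gen_ct_table",
    "gen_kinetic_plate",
    "build_genome_objects",
    "gen_genome_fixture",
    "gen_cfu_counts",
    "generate_all",
]

TOPOLOGIES = {
    "divergent_promoters",
    "downstream_orf",
    "inter_operonic",
    "pre_terminator",
    "convergent_3prime",
    "intra_gene",
}

_STREAMS = {"ct": 0, "kinetics": 1, "cfu": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass(frozen=True)
class StrainSpec:
    """Ground truth for one knock-in strain."""

    strain_id: str
    compartment: str
    site_position: int
    topology: str
    true_fold_change: float  # lacS transcription rel. to the lowest strain
    true_slope: float  # OD410/min
    popin_fraction: float  # percent lacS+ of screened CFUs
    neighbor_locus: str
    neighbor_cpm: float
    neighbor_essentiality: Optional[int] = None
    condition_regulation: dict = field(default_factory=dict)  # condition -> fold multiplier
    cfu_total: int = 20000

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.true_fold_change <= 0 or self.true_slope <= 0:
            raise ValueError("fold change and slope must be positive")


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    strains: tuple
    # qPCR noise model (cycles)
    ct_base_reference: float = 18.0
    ct_base_target: float = 14.0  # keeps CT > 8 for fold changes up to ~60
    sigma_tech_ct: float = 0.15
    sigma_bio_ct: float = 0.2
    n_bio: int = 3
    n_tech: int = 3
    conditions: tuple = ("reference",)
    n_bio_per_condition: dict = field(default_factory=dict)
    # kinetics
    kin_m: float = 1.0
    kin_t_off: float = 10.0
    kin_d: float = 5.0
    sigma_od: float = 0.002
    t_max: float = 240.0
    t_step: float = 5.0
    kin_n_tech: int = 3
    # genome
    genome_length: int = 2_225_959
    ori_positions: tuple = (("oriC1", 556_450), ("oriC2", 24), ("oriC3", 1_225_600))
    compartment_intervals: tuple = (
        (1, 250_000, "A"),
        (250_001, 320_000, "B"),
        (320_001, 850_000, "A"),
        (850_001, 2_100_000, "B"),
        (2_100_001, 2_225_959, "A"),
    )


def study_mimic_config(seed: int = 1) -> SynthConfig:
    """The default study conditions: nine knock-in strains on a toy genome.

    Fold changes of the five strains the study discusses individually are set
    to the printed values (slaA 55, vapC 6.2, ccc1 5.2, clsN 1.88, acad 1.86,
    all relative to arlJ = 1); per-strain slopes average to the printed
    compartment means (A 2.412e-4, B 1.419e-4 OD410/min) and pop-in fractions
    to the printed compartment means (A 0.56%, B 0.22%).  Site coordinates,
    neighbor loci, CPM and essentiality follow the published site table.
    """
    mk = StrainSpec
    strains = (
        mk("clsN", "A", 32_281, "divergent_promoters", 1.88, 3.00e-4, 0.30,
           "Saci_0046", 1.955, 3),
        mk("ccc1", "A", 235_243, "inter_operonic", 5.2, 1.70e-4, 0.80,
           "Saci_0278", 55.012, 13),
        mk("sdhC", "B", 278_353, "downstream_orf", 3.0, 1.60e-4, 0.30,
           "Saci_0325", 129.5, 20,
           {"starvation": 2.2, "stationary": 2.0}),
        mk("vapC", "A", 394_047, "pre_terminator", 6.2, 2.80e-4, 0.25,
           "Saci_0467", 1.47, 23,
           {"starvation": 0.5, "stationary": 0.6}),
        mk("l2p", "A", 473_288, "downstream_orf", 2.5, 1.66e-4, 0.25,
           "Saci_0594", 53.09, 2),
        mk("acad", "B", 928_402, "divergent_promoters", 1.86, 1.50e-4, 0.15,
           "Saci_1123", 56.12, 43,
           {"starvation": 1.7}),
        mk("arlJ", "B", 987_911, "convergent_3prime", 1.0, 1.20e-4, 0.13,
           "Saci_1172", 18.05, None),
        mk("arlB", "B", 993_346, "downstream_orf", 2.0, 1.376e-4, 0.30,
           "Saci_1178", 35.18, 11,
           {"starvation": 2.5, "stationary": 2.2}),
        mk("slaA", "A", 2_199_897, "downstream_orf", 55.0, 2.90e-4, 1.20,
           "Saci_2355", 11.554, 7,
           {"starvation": 0.4, "stationary": 0.5}),
    )
    return SynthConfig(
        seed=seed,
        strains=strains,
        conditions=("reference", "starvation", "stationary"),
        n_bio_per_condition={"starvation": 1},
    )


def gen_ct_table(config: SynthConfig) -> pd.DataFrame:
    """Simulated CT records for target and reference genes, long format."""
    rng = _rng(config.seed, "ct")
    rows = []
    for strain in config.strains:
        for cond in config.conditions:
            n_bio = config.n_bio_per_condition.get(cond, config.n_bio)
            fold = strain.true_fold_change * strain.condition_regulation.get(cond, 1.0)
            target_mu = config.ct_base_target - np.log2(fold)
            for b in range(1, n_bio + 1):
                bio_eff = rng.normal(0.0, config.sigma_bio_ct)
                for role, mu in (("target", target_mu), ("reference", config.ct_base_reference)):
                    for r in range(1, config.n_tech + 1):
                        ct = mu + bio_eff + rng.normal(0.0, config.sigma_tech_ct)
                        rows.append((strain.strain_id, cond, role, b, r, ct))
    return pd.DataFrame(rows, columns=["strain", "condition", "gene_role", "bio_rep", "tech_rep", "ct"])


def _time_grid(config: SynthConfig) -> np.ndarray:
    return np.arange(0.0, config.t_max + config.t_step / 2, config.t_step)


def gen_kinetic_curve(
    true_slope: float,
    config: SynthConfig,
    rng: np.random.Generator,
    strain_id: str = "synthetic",
    condition: str = "reference",
    bio_rep: int = 1,
    tech_rep: int = 1,
) -> KineticCurve:
    """One ONPG curve from the smoothed-Monod model plus Gaussian noise."""
    t = _time_grid(config)
    params = MonodFitParams(sl=true_slope, m=config.kin_m, t_off=config.kin_t_off, d=config.kin_d)
    od = eval_model(params, t)
    if config.sigma_od > 0:
        od = od + rng.normal(0.0, config.sigma_od, size=t.shape)
    return KineticCurve(strain_id, condition, bio_rep, tech_rep, t, od)


def gen_kinetic_plate(config: SynthConfig) -> list:
    """Technical-replicate ONPG curves for every strain at its true slope."""
    rng = _rng(config.seed, "kinetics")
    curves = []
    for strain in config.strains:
        for r in range(1, config.kin_n_tech + 1):
            curves.append(
                gen_kinetic_curve(strain.true_slope, config, rng,
                                  strain_id=strain.strain_id, tech_rep=r)
            )
    return curves


def _next_locus(tag: str, offset: int) -> str:
    prefix, num = tag.rsplit("_", 1)
    return f"{prefix}_{int(num) + offset:0{len(num)}d}"


def _neighborhood(strain: StrainSpec) -> tuple[list, list]:
    """Genes and terminators realizing one site's topology archetype.

    The named neighbor from the site table is placed as the gene relevant to
    the call (donor, or nearest divergent gene); a second flanking gene with
    the successive locus tag completes the context.
    """
    p = strain.site_position
    tag = strain.neighbor_locus
    cpm = strain.neighbor_cpm
    ess = strain.neighbor_essentiality
    other = _next_locus(tag, 1)
    topo = strain.topology
    genes, terms = [], []

    if topo == "divergent_promoters":
        genes = [
            GeneFeature(tag, p - 1200, p - 150, "-", cpm, ess),
            GeneFeature(other, p + 150, p + 1200, "+", 5.0, None),
        ]
    elif topo == "downstream_orf":
        genes = [
            GeneFeature(tag, p - 1200, p - 150, "+", cpm, ess),
            GeneFeature(other, p + 300, p + 1300, "+", 5.0, None),
        ]
    elif topo == "inter_operonic":
        op = f"op_{strain.strain_id}"
        genes = [
            GeneFeature(tag, p - 1200, p - 150, "+", cpm, ess, operon_id=op),
            GeneFeature(other, p + 300, p + 1300, "+", 5.0, None, operon_id=op),
        ]
    elif topo == "pre_terminator":
        genes = [
            GeneFeature(tag, p - 1200, p - 150, "+", cpm, ess),
            GeneFeature(other, p + 400, p + 1400, "+", 5.0, None),
        ]
        terms = [TerminatorFeature(p + 150, "+")]  # beyond the site: no shield
    elif topo == "convergent_3prime":
        prev = _next_locus(tag, -1)
        genes = [
            GeneFeature(tag, p - 1100, p - 100, "+", cpm, ess),
            GeneFeature(prev, p + 150, p + 1150, "-", 5.0, None),
        ]
    elif topo == "intra_gene":
        genes = [GeneFeature(tag, p - 500, p + 500, "+", cpm, ess)]
    return genes, terms


def build_genome_objects(config: SynthConfig):
    """In-memory toy genome: (genome, origins, intervals, genes, terminators, sites)."""
    genome = CircularGenome("toy_chromosome", config.genome_length)
    origins = [ReplicationOrigin(n, p) for n, p in config.ori_positions]
    intervals = [CompartmentInterval(s, e, lab) for s, e, lab in config.compartment_intervals]
    genes, terms, sites = [], [], []
    for strain in config.strains:
        if not 1 <= strain.site_position <= config.genome_length:
            raise ValueError(f"site {strain.strain_id} outside the genome")
        g, t = _neighborhood(strain)
        genes.extend(g)
        terms.extend(t)
        sites.append(TargetSite(strain.strain_id, strain.site_position, "+"))
    return genome, origins, intervals, genes, terms, sites


def gen_genome_fixture(config: SynthConfig, out_dir) -> dict:
    """Write the toy genome as GFF3/BED/TSV files; returns {kind: path}."""
    from . import io as lio

    genome, origins, intervals, genes, terms, sites = build_genome_objects(config)
    out = {}
    out["gff"] = lio.write_gff3(genes, terms, genome, f"{out_dir}/genes.gff3")
    out["bed"] = lio.write_bed(intervals, genome, f"{out_dir}/compartments.bed")
    out["origins"] = lio.write_origins_tsv(origins, f"{out_dir}/origins.tsv")
    out["sites"] = lio.write_sites_tsv(sites, f"{out_dir}/sites.tsv")
    return out


def gen_cfu_counts(config: SynthConfig) -> pd.DataFrame:
    """Binomial pop-in screening counts per strain."""
    rng = _rng(config.seed, "cfu")
    rows = []
    for strain in config.strains:
        blue = int(rng.binomial(strain.cfu_total, strain.popin_fraction / 100.0))
        rows.append((strain.strain_id, blue, strain.cfu_total))
    return pd.DataFrame(rows, columns=["strain", "blue_cfu", "total_cfu"])


def generate_all(config: SynthConfig, out_dir) -> dict:
    """Write every synthetic input file to out_dir; returns {kind: path}."""
    from . import io as lio

    paths = gen_genome_fixture(config, out_dir)
    paths["ct"] = lio.write_ct_csv(gen_ct_table(config), f"{out_dir}/ct.csv")
    paths["plate"] = lio.write_plate_csv(gen_kinetic_plate(config), f"{out_dir}/plate.csv")
    paths["cfu"] = lio.write_cfu_tsv(gen_cfu_counts(config), f"{out_dir}/cfu.tsv")
    return paths
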