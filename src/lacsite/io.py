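"""Format readers and writers for the pipeline's tabular and annotation files.

Conventions: CSV/TSV are UTF-8 with decimal points and a mandatory header;
genes and sites use 1-based inclusive coordinates (GFF3 convention); BED
compartment intervals are converted from 0-based half-open to 1-based
inclusive at the reader boundary and back on write.  GFF3 parsing goes
through gffutils' line parser so malformed rows can be reported with their
line numbers.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .correlate import RegressionResult
from .genome_context import (
    CircularGenome,
    CompartmentInterval,
    GeneFeature,
    ReplicationOrigin,
    SiteContext,
    TargetSite,
    TerminatorFeature,
)
from .kinetics import ActivitySummary, KineticCurve, SlopeEstimate
from .qpcr import CT_COLUMNS, ConditionRatio, ExpressionRatio

PLATE_COLUMNS = ["strain", "condition", "bio_rep", "tech_rep", "time_min", "od410"]


def _read_table(path, sep, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected header {list(required)}")
    return df


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------- plate reader

def read_plate_csv(path) -> list:
    """Long-format plate-reader CSV -> list of KineticCurve."""
    df = _read_table(path, ",", PLATE_COLUMNS)
    curves = []
    for key, grp in df.groupby(["strain", "condition", "bio_rep", "tech_rep"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            KineticCurve(str(key[0]), str(key[1]), int(key[2]), int(key[3]),
                         grp["time_min"].to_numpy(float), grp["od410"].to_numpy(float))
        )
    return curves


def write_plate_csv(curves: Sequence[KineticCurve], path):
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od410):
            rows.append((c.strain_id, c.condition, c.bio_rep, c.tech_rep, t, od))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)
    return path


def write_slopes_tsv(estimates: Sequence[SlopeEstimate], path):
    df = pd.DataFrame(
        [
            (e.strain_id, e.condition, e.bio_rep, e.tech_rep, e.slope, e.slope_se,
             e.fit_error, e.end_index, e.provenance)
            for e in estimates
        ],
        columns=["strain", "condition", "bio_rep", "tech_rep", "slope", "slope_se",
                 "fit_error", "end_index", "provenance"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_summary_tsv(summaries: Sequence[ActivitySummary], path):
    df = pd.DataFrame(
        [
            (s.strain_id, s.condition, s.geo_mean_slope, s.geo_se, s.reported_error,
             s.n_replicates)
            for s in summaries
        ],
        columns=["strain", "condition", "geo_mean_slope", "geo_se", "reported_error",
                 "n_replicates"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_summary_tsv(path) -> pd.DataFrame:
    return _read_table(path, "\t", ["strain", "condition", "geo_mean_slope"])


# ------------------------------------------------------------------------ qPCR

def read_ct_csv(path) -> pd.DataFrame:
    return _read_table(path, ",", CT_COLUMNS)


def write_ct_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False)
    return path


def write_ratios_tsv(ratios: Sequence[ExpressionRatio], path):
    df = pd.DataFrame(
        [
            (r.strain_id, r.condition, r.fold_change, r.sd_log2,
             "" if r.p_two_tailed is None else r.p_two_tailed,
             r.zero_variance, r.n_bio)
            for r in ratios
        ],
        columns=["strain", "condition", "fold_change", "sd_log2", "p_two_tailed",
                 "zero_variance", "n_bio"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_ratios_tsv(path) -> pd.DataFrame:
    return _read_table(path, "\t", ["strain", "condition", "fold_change"])


def write_condition_ratios_tsv(ratios: Sequence[ConditionRatio], path):
    df = pd.DataFrame(
        [(r.strain_id, r.numerator_condition, r.denominator_condition, r.ratio) for r in ratios],
        columns=["strain", "numerator_condition", "denominator_condition", "ratio"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ------------------------------------------------------------------ annotation

_FLOAT_ATTRS = {"expression_cpm": float}


def read_gff3(path) -> tuple[list, list]:
    """GFF3 -> (genes, terminators); gene rows must carry a locus_tag.

    Rows of type ``gene`` become GeneFeature (attributes expression_cpm,
    essentiality_rank, operon_id are optional); rows of type ``terminator``
    become TerminatorFeature at the feature midpoint.
    """
    genes, terms = [], []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:
            raise ValueError(f"{path}:{lineno}: unparseable GFF3 line ({exc})") from exc
        if feat.featuretype == "gene":
            attrs = feat.attributes
            if "locus_tag" not in attrs:
                raise ValueError(f"{path}:{lineno}: gene feature lacks a locus_tag attribute")
            cpm = attrs.get("expression_cpm", [None])[0]
            ess = attrs.get("essentiality_rank", [None])[0]
            op = attrs.get("operon_id", [None])[0]
            genes.append(
                GeneFeature(
                    locus_tag=attrs["locus_tag"][0],
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    expression_cpm=None if cpm in (None, "") else float(cpm),
                    essentiality_rank=None if ess in (None, "") else int(ess),
                    operon_id=op or None,
                )
            )
        elif feat.featuretype == "terminator":
            terms.append(TerminatorFeature((feat.start + feat.end) // 2, feat.strand))
    if not genes:
        raise ValueError(f"{path}: no gene features found")
    return genes, terms


def write_gff3(genes: Sequence[GeneFeature], terminators: Sequence[TerminatorFeature],
               genome: CircularGenome, path):
    lines = ["##gff-version 3", f"##sequence-region {genome.name} 1 {genome.length}"]
    for g in sorted(genes, key=lambda g: g.start):
        attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
        if g.expression_cpm is not None:
            attrs.append(f"expression_cpm={g.expression_cpm}")
        if g.essentiality_rank is not None:
            attrs.append(f"essentiality_rank={g.essentiality_rank}")
        if g.operon_id is not None:
            attrs.append(f"operon_id={g.operon_id}")
        lines.append(
            "\t".join([genome.name, "lacsite", "gene", str(g.start), str(g.end), ".",
                       g.strand, ".", ";".join(attrs)])
        )
    for i, t in enumerate(sorted(terminators, key=lambda t: t.position), 1):
        lines.append(
            "\t".join([genome.name, "lacsite", "terminator", str(t.position),
                       str(t.position), ".", t.strand, ".", f"ID=ter{i}"])
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_bed(path) -> list:
    """BED (0-based half-open) -> CompartmentInterval (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: compartment BED needs chrom,start,end,label columns")
    out = []
    for _, row in df.iterrows():
        out.append(CompartmentInterval(int(row[1]) + 1, int(row[2]), str(row[3])))
    if not out:
        raise ValueError(f"{path}: empty BED")
    return out


def write_bed(intervals: Sequence[CompartmentInterval], genome: CircularGenome, path):
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: iv.start):
            fh.write(f"{genome.name}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")
    return path


def read_origins_tsv(path) -> list:
    df = _read_table(path, "\t", ["name", "position"])
    return [ReplicationOrigin(str(r["name"]), int(r["position"])) for _, r in df.iterrows()]


def write_origins_tsv(origins: Sequence[ReplicationOrigin], path):
    pd.DataFrame([(o.name, o.position) for o in origins],
                 columns=["name", "position"]).to_csv(path, sep="\t", index=False)
    return path


def read_sites_tsv(path) -> list:
    df = _read_table(path, "\t", ["name", "position", "strand"])
    return [TargetSite(str(r["name"]), int(r["position"]), str(r["strand"]))
            for _, r in df.iterrows()]


def write_sites_tsv(sites: Sequence[TargetSite], path):
    pd.DataFrame([(s.name, s.position, s.cassette_strand) for s in sites],
                 columns=["name", "position", "strand"]).to_csv(path, sep="\t", index=False)
    return path


def read_cfu_tsv(path) -> pd.DataFrame:
    return _read_table(path, "\t", ["strain", "blue_cfu", "total_cfu"])


def write_cfu_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)
    return path


def write_context_tsv(contexts: Sequence[SiteContext], path):
    df = pd.DataFrame(
        [
            (c.site, c.position, c.nearest_ori, c.ori_distance, c.compartment,
             c.insulated, c.readthrough_donor or "",
             "" if c.donor_expression_cpm is None else c.donor_expression_cpm,
             c.ambiguous)
            for c in contexts
        ],
        columns=["site", "position", "nearest_ori", "ori_distance", "compartment",
                 "insulated", "readthrough_donor", "donor_expression_cpm", "ambiguous"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_context_tsv(path) -> pd.DataFrame:
    return _read_table(path, "\t", ["site", "ori_distance", "compartment", "insulated"])


def write_regressions_tsv(results: dict, path):
    df = pd.DataFrame(
        [(name, r.slope, r.intercept, r.r_squared, r.p_two_tailed, r.n)
         for name, r in results.items()],
        columns=["regression", "slope", "intercept", "r_squared", "p_two_tailed", "n"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path
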