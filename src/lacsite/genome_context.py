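"""Genome-context annotation of reporter-cassette integration sites.

Each integration site on the circular S. acidocaldarius chromosome is
annotated with its distance to the nearest replication origin (gene dosage
proxy), its A/B chromatin compartment, and a transcriptional-insulation call:
a site is insulated only when its two flanking genes are divergently oriented
(both 5' ends facing the site) so that no neighboring transcription unit can
read through the cassette.  Otherwise the classifier names the read-through
donor — the nearest flanking gene (or operon) transcribing toward the site
with no terminator in between.  Convergent 3'/3' contexts without a
terminator are flagged ambiguous: which neighbor, if either, reads through is
genuinely unclear.  Pop-in screening fractions (blue CFUs over total) are
summarized per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "CircularGenome",
    "ReplicationOrigin",
    "GeneFeature",
    "CompartmentInterval",
    "TerminatorFeature",
    "TargetSite",
    "SiteContext",
    "circular_distance",
    "nearest_origin",
    "assign_compartment",
    "classify_site_context",
    "build_site_table",
    "popin_fraction",
    "compartment_mean_fraction",
]


@dataclass(frozen=True)
class CircularGenome:
    name: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")


@dataclass(frozen=True)
class ReplicationOrigin:
    name: str
    position: int  # 1-based bp


@dataclass(frozen=True)
class GeneFeature:
    locus_tag: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    expression_cpm: Optional[float] = None
    essentiality_rank: Optional[int] = None
    operon_id: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be + or -")


@dataclass(frozen=True)
class CompartmentInterval:
    start: int  # 1-based inclusive
    end: int
    label: str  # 'A' or 'B'


@dataclass(frozen=True)
class TerminatorFeature:
    position: int
    strand: str


@dataclass(frozen=True)
class TargetSite:
    name: str
    position: int
    cassette_strand: str = "+"


@dataclass
class SiteContext:
    site: str
    position: int
    nearest_ori: str
    ori_distance: int
    compartment: str
    insulated: bool
    readthrough_donor: Optional[str]
    donor_expression_cpm: Optional[float]
    ambiguous: bool = False


def circular_distance(a: int, b: int, genome: CircularGenome) -> int:
    """Shortest-arc distance between two positions on the circular chromosome."""
    for x in (a, b):
        if not 1 <= x <= genome.length:
            raise ValueError(f"position {x} outside genome of length {genome.length}")
    d = abs(a - b)
    return min(d, genome.length - d)


def nearest_origin(
    site: TargetSite, origins: Sequence[ReplicationOrigin], genome: CircularGenome
) -> tuple[str, int]:
    """Closest replication origin by circular distance; ties by origin name."""
    if not origins:
        raise ValueError("no replication origins supplied")
    best = min(origins, key=lambda o: (circular_distance(site.position, o.position, genome), o.name))
    return best.name, circular_distance(site.position, best.position, genome)


def assign_compartment(site: TargetSite, intervals: Sequence[CompartmentInterval]) -> str:
    """Compartment label of the covering interval, or of the nearest boundary.

    Gap handling mirrors a gene-by-gene lift-over: a site falling between
    annotated intervals takes the label of the closest interval edge.
    """
    if not intervals:
        raise ValueError("no compartment intervals supplied")
    for iv in intervals:
        if iv.start <= site.position <= iv.end:
            return iv.label
    def edge_dist(iv):
        return min(abs(site.position - iv.start), abs(site.position - iv.end))
    return min(intervals, key=edge_dist).label


def _terminator_between(lo: int, hi: int, strand: str,
                        terminators: Sequence[TerminatorFeature]) -> bool:
    return any(lo < t.position < hi and t.strand == strand for t in terminators)


def classify_site_context(
    site: TargetSite,
    genes: Sequence[GeneFeature],
    terminators: Sequence[TerminatorFeature] = (),
) -> tuple[bool, Optional[GeneFeature], bool]:
    """Insulation call for one site: (insulated, donor gene, ambiguous).

    Rules, evaluated on the immediate flanking genes only:

    * the site overlaps a gene -> never insulated, donor is that gene;
    * the site lies inside an operon (flanks share an operon_id) -> donor is
      the upstream operonic gene;
    * flanks divergent (left '-', right '+'; both 5' ends facing the site)
      -> insulated, no donor;
    * otherwise the donor is the nearest flanking gene transcribing toward
      the site with no same-strand terminator between its 3' end and the
      site; a convergent 3'/3' context offering two such donors takes the
      nearer one and is flagged ambiguous.
    """
    pos = site.position
    overlapping = [g for g in genes if g.start <= pos <= g.end]
    if overlapping:
        return False, overlapping[0], False

    lefts = [g for g in genes if g.end < pos]
    rights = [g for g in genes if g.start > pos]
    if not lefts or not rights:
        raise ValueError(f"site {site.name}: no flanking genes on both sides")
    left = max(lefts, key=lambda g: g.end)
    right = min(rights, key=lambda g: g.start)

    if left.operon_id is not None and left.operon_id == right.operon_id:
        donor = left if left.strand == "+" else right
        return False, donor, False

    if left.strand == "-" and right.strand == "+":
        return True, None, False

    candidates = []  # (distance to site, gene)
    if left.strand == "+":
        if not _terminator_between(left.end, pos, "+", terminators):
            candidates.append((pos - left.end, left))
    if right.strand == "-":
        if not _terminator_between(pos, right.start, "-", terminators):
            candidates.append((right.start - pos, right))

    if not candidates:
        return False, None, False
    ambiguous = len(candidates) == 2 and left.strand == "+" and right.strand == "-"
    candidates.sort(key=lambda c: c[0])
    return False, candidates[0][1], ambiguous


def build_site_table(
    sites: Sequence[TargetSite],
    genes: Sequence[GeneFeature],
    origins: Sequence[ReplicationOrigin],
    intervals: Sequence[CompartmentInterval],
    terminators: Sequence[TerminatorFeature],
    genome: CircularGenome,
) -> list[SiteContext]:
    """One fully annotated SiteContext row per target site."""
    rows = []
    for site in sites:
        ori_name, ori_dist = nearest_origin(site, origins, genome)
        comp = assign_compartment(site, intervals)
        insulated, donor, ambiguous = classify_site_context(site, genes, terminators)
        rows.append(
            SiteContext(
                site=site.name,
                position=site.position,
                nearest_ori=ori_name,
                ori_distance=ori_dist,
                compartment=comp,
                insulated=insulated,
                readthrough_donor=donor.locus_tag if donor else None,
                donor_expression_cpm=donor.expression_cpm if donor else None,
                ambiguous=ambiguous,
            )
        )
    return rows


def popin_fraction(blue_cfu: int, total_cfu: int) -> float:
    """Percentage of lacS+ integrant ('blue') CFUs among all screened CFUs."""
    if total_cfu <= 0:
        raise ValueError("total CFU count must be positive")
    if not 0 <= blue_cfu <= total_cfu:
        raise ValueError("blue CFU count must lie in [0, total]")
    return 100.0 * blue_cfu / total_cfu


def compartment_mean_fraction(
    fractions: dict, contexts: Sequence[SiteContext]
) -> dict:
    """Arithmetic mean pop-in percentage per compartment label."""
    comp_of = {c.site: c.compartment for c in contexts}
    sums: dict = {}
    for site, frac in fractions.items():
        if site not in comp_of:
            raise ValueError(f"site {site!r} has no compartment annotation")
        sums.setdefault(comp_of[site], []).append(frac)
    return {label: sum(v) / len(v) for label, v in sorted(sums.items())}
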