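"""Relative transcription quantification by the ddCT method.

qRT-PCR quantification cycles (CT) for a target gene (the lacS reporter) and a
reference gene (tbp) are reduced to fold changes in four steps: technical
replicates are averaged per biological replicate; dCT = CT(target) -
CT(reference) normalizes template input; a baseline strain — by default the
one with the lowest expression, i.e. the largest mean dCT — anchors the scale;
and fold change = E^-(ddCT) with amplification efficiency E = 2 (perfect
doubling) by default.  Per-strain significance is a two-tailed one-sample t
test of the log2 per-replicate ratios against 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRatio",
    "ConditionRatio",
    "average_technical",
    "delta_ct",
    "select_baseline",
    "fold_change_ddct",
    "one_sample_log_test",
    "condition_fold_change",
    "regulation_concordance",
    "run_ddct",
]

CT_COLUMNS = ["strain", "condition", "gene_role", "bio_rep", "tech_rep", "ct"]
GENE_ROLES = {"target", "reference"}


@dataclass
class ExpressionRatio:
    strain_id: str
    condition: str
    fold_change: float
    per_bio_rep_ratios: list
    sd_log2: float
    p_two_tailed: Optional[float]
    zero_variance: bool
    n_bio: int


@dataclass
class ConditionRatio:
    strain_id: str
    numerator_condition: str
    denominator_condition: str
    ratio: float


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"CT table is missing columns {missing}; expected {CT_COLUMNS}")
    bad = set(records["gene_role"]) - GENE_ROLES
    if bad:
        raise ValueError(f"unknown gene_role values {sorted(bad)}")
    if (records["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return records


def average_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Mean CT over technical replicates per (strain, condition, gene_role, bio_rep).

    Biological replicates that have target but no reference measurements are
    dropped with a warning column rather than poisoning downstream joins.
    """
    records = _validate(records)
    if records.empty:
        raise ValueError("empty CT table")
    out = (
        records.groupby(["strain", "condition", "gene_role", "bio_rep"], as_index=False)
        .agg(mean_ct=("ct", "mean"), n_tech=("ct", "size"))
    )
    return out


def delta_ct(mean_ct: pd.DataFrame) -> pd.DataFrame:
    """dCT = mean CT(target) - mean CT(reference) per (strain, condition, bio_rep)."""
    wide = mean_ct.pivot_table(
        index=["strain", "condition", "bio_rep"], columns="gene_role",
        values="mean_ct", aggfunc="mean",
    )
    for role in ("target", "reference"):
        if role not in wide.columns:
            wide[role] = np.nan
    incomplete = wide[wide[["target", "reference"]].isna().any(axis=1)]
    wide = wide.dropna(subset=["target", "reference"])
    out = wide.reset_index()
    out["delta_ct"] = out["target"] - out["reference"]
    out.attrs["n_dropped_incomplete"] = len(incomplete)
    return out[["strain", "condition", "bio_rep", "delta_ct"]]


def select_baseline(dct: pd.DataFrame, condition: str) -> str:
    """Strain with the lowest expression (largest mean dCT); ties lexicographic."""
    sub = dct[dct["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no dCT rows for condition {condition!r}")
    means = sub.groupby("strain")["delta_ct"].mean()
    if len(means) < 2:
        raise ValueError("baseline selection needs at least 2 strains")
    best = means.max()
    return sorted(means.index[means == best])[0]


def one_sample_log_test(per_bio_rep_ratios) -> tuple[Optional[float], bool]:
    """Two-tailed one-sample t test of log2 ratios against 0.

    Returns (p, zero_variance_flag); p is None for n < 2 or degenerate
    zero-variance samples.
    """
    logs = np.log2(np.asarray(per_bio_rep_ratios, dtype=float))
    n = len(logs)
    if n < 2:
        return None, False
    sd = logs.std(ddof=1)
    if sd == 0:
        return None, True
    t = logs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(p), False


def fold_change_ddct(
    dct: pd.DataFrame, baseline: str, condition: str, efficiency: float = 2.0
) -> list[ExpressionRatio]:
    """ddCT fold changes of every strain relative to the baseline strain.

    The baseline dCT* is the mean over the baseline's biological replicates
    (replicates are not paired across strains); each biological replicate b of
    strain s contributes ratio = E^-(dCT_{s,b} - dCT*), and the strain's fold
    change is the geometric mean of those ratios.
    """
    sub = dct[dct["condition"] == condition]
    base = sub[sub["strain"] == baseline]
    if base.empty:
        raise ValueError(f"baseline strain {baseline!r} absent in condition {condition!r}")
    base_dct = base["delta_ct"].mean()
    out = []
    for strain, grp in sub.groupby("strain"):
        ratios = (efficiency ** -(grp["delta_ct"] - base_dct)).to_numpy()
        logs = np.log2(ratios)
        p, zero_var = one_sample_log_test(ratios)
        out.append(
            ExpressionRatio(
                strain_id=str(strain),
                condition=condition,
                fold_change=float(np.exp(np.log(ratios).mean())),
                per_bio_rep_ratios=ratios.tolist(),
                sd_log2=float(logs.std(ddof=1)) if len(logs) > 1 else 0.0,
                p_two_tailed=p,
                zero_variance=zero_var,
                n_bio=len(ratios),
            )
        )
    return out


def condition_fold_change(
    dct: pd.DataFrame, strain: str, cond_num: str, cond_den: str,
    efficiency: float = 2.0,
) -> ConditionRatio:
    """Within-strain fold change between two growth conditions.

    ratio = E^-(mean dCT in cond_num - mean dCT in cond_den); each condition
    is normalized by its own reference-gene CT, so condition effects on the
    reference gene cancel only if it is stable — the usual ddCT caveat.
    """
    sub = dct[dct["strain"] == strain]
    means = {}
    for cond in (cond_num, cond_den):
        rows = sub[sub["condition"] == cond]
        if rows.empty:
            raise ValueError(f"strain {strain!r} has no dCT rows for condition {cond!r}")
        means[cond] = rows["delta_ct"].mean()
    ratio = float(efficiency ** -(means[cond_num] - means[cond_den]))
    return ConditionRatio(strain, cond_num, cond_den, ratio)


def regulation_concordance(lacs_log2fc: float, neighbor_log2fc: float,
                           threshold: float = 0.58) -> str:
    """Classify reporter-vs-neighbor regulation agreement.

    With |log2 fc| < threshold counting as unregulated (default 0.58, about
    1.5-fold): 'neither_regulated' if both are below threshold, 'concordant'
    if both exceed it with the same sign, 'discordant' otherwise.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = abs(lacs_log2fc) >= threshold
    b = abs(neighbor_log2fc) >= threshold
    if not a and not b:
        return "neither_regulated"
    if a and b and (lacs_log2fc > 0) == (neighbor_log2fc > 0):
        return "concordant"
    return "discordant"


def run_ddct(records: pd.DataFrame, condition: str, baseline: str = "auto",
             efficiency: float = 2.0) -> tuple[str, list[ExpressionRatio]]:
    """End-to-end ddCT for one condition; returns (baseline strain, ratios)."""
    dct = delta_ct(average_technical(records))
    if baseline == "auto":
        baseline = select_baseline(dct, condition)
    return baseline, fold_change_ddct(dct, baseline, condition, efficiency=efficiency)
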