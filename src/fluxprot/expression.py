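"""FPKM expression analysis: fold changes, volcano classification,
ontology-cluster direction summaries, and flux-vs-expression pairing.

Expression tables are long-format DataFrames with columns
``gene_id, stage, replicate, fpkm``; the ontology map carries
``accession, gene_id, cluster`` with at most one gene and one cluster per
protein accession.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ClusterSummary, binomial_direction_test

__all__ = [
    "PSEUDOCOUNT_DEFAULT",
    "VolcanoSummary",
    "log2_fold_change",
    "fold_change_table",
    "round_half_away",
    "class_percentages",
    "volcano_classify",
    "validate_ontology_map",
    "match_genes_to_proteins",
    "cluster_direction_summary",
]

PSEUDOCOUNT_DEFAULT = 0.1  # FPKM units


def log2_fold_change(case_fpkms, control_fpkms, pseudocount: float = PSEUDOCOUNT_DEFAULT) -> float:
    """log2((mean_case + eps) / (mean_control + eps)).

    The pseudocount (default 0.1 FPKM) keeps zero-expression genes finite and
    maps 0-vs-0 to a fold change of exactly 0.
    """
    case = np.asarray(case_fpkms, float)
    control = np.asarray(control_fpkms, float)
    if case.size < 1 or control.size < 1:
        raise ValueError("need at least one replicate per side")
    return float(np.log2((case.mean() + pseudocount) / (control.mean() + pseudocount)))


def fold_change_table(
    expression: pd.DataFrame,
    case_stage: str,
    control_stage: str = "Control",
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2FC and t-test p for one stage versus control.

    The per-gene p-value is a two-sided equal-variance t-test on the
    per-replicate FPKMs.  Genes need >= 2 replicates on both sides to get a
    p-value; others are classed ``ns`` and flagged.  Classification:
    significant iff p <= alpha (the -log10 p >= 1.301 boundary is inclusive),
    direction by the sign of log2FC.
    """
    present = set(expression["stage"].unique())
    for stage in (case_stage, control_stage):
        if stage not in present:
            raise ValueError(f"stage {stage!r} absent from expression table")

    def _stage_matrix(stage: str) -> pd.DataFrame:
        sub = expression[expression["stage"] == stage]
        return sub.pivot_table(
            index="gene_id", columns="replicate", values="fpkm", aggfunc="mean"
        )

    case_m = _stage_matrix(case_stage)
    ctrl_m = _stage_matrix(control_stage)
    genes = case_m.index.intersection(ctrl_m.index)  # genes measured in both
    case_a = case_m.loc[genes].to_numpy(float)
    ctrl_a = ctrl_m.loc[genes].to_numpy(float)

    case_n = np.sum(~np.isnan(case_a), axis=1)
    ctrl_n = np.sum(~np.isnan(ctrl_a), axis=1)
    case_mean = np.nanmean(np.where(np.isnan(case_a), np.nan, case_a), axis=1)
    ctrl_mean = np.nanmean(np.where(np.isnan(ctrl_a), np.nan, ctrl_a), axis=1)
    l2fc = np.log2((case_mean + pseudocount) / (ctrl_mean + pseudocount))

    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = sps.ttest_ind(case_a, ctrl_a, axis=1, equal_var=True, nan_policy="omit").pvalue
    pvals = np.asarray(pvals, float)
    # degenerate rows: no spread on either side -> p by the equality convention
    zero_var = (np.nanvar(case_a, axis=1) == 0.0) & (np.nanvar(ctrl_a, axis=1) == 0.0)
    pvals[zero_var & (case_mean == ctrl_mean)] = 1.0
    pvals[zero_var & (case_mean != ctrl_mean)] = 0.0
    flagged = (case_n < 2) | (ctrl_n < 2) | np.isnan(pvals)
    pvals[flagged] = np.nan

    out = pd.DataFrame(
        {
            "gene_id": genes,
            "stage": case_stage,
            "log2_fc": l2fc,
            "p_value": pvals,
            "p_missing": flagged,
        }
    )
    sig = out["p_value"].le(alpha) & ~out["p_missing"]
    out["class"] = np.select(
        [sig & (out["log2_fc"] > 0), sig & (out["log2_fc"] < 0)], ["up", "down"], "ns"
    )
    return out.sort_values("gene_id", ignore_index=True)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def class_percentages(n_up: int, n_down: int, n_ns: int) -> tuple[float, float, float]:
    """Percentages of up/down/ns classes to one decimal, half away from zero."""
    total = n_up + n_down + n_ns
    if total == 0:
        return 0.0, 0.0, 0.0
    return tuple(round_half_away(100.0 * n / total, 1) for n in (n_up, n_down, n_ns))


@dataclass(frozen=True)
class VolcanoSummary:
    stage: str
    n_up: int
    n_down: int
    n_ns: int
    pct_up: float
    pct_down: float
    pct_ns: float

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down + self.n_ns


def volcano_classify(fold_changes: pd.DataFrame, alpha: float = 0.05) -> VolcanoSummary:
    """Counts and percentages of up/down/ns genes at the -log10 p threshold.

    A record is significant iff p <= alpha (so p = 0.05 exactly is
    significant); records with a missing p-value count as ns.
    """
    stage = fold_changes["stage"].iloc[0] if len(fold_changes) else ""
    if "class" in fold_changes.columns:
        cls = fold_changes["class"]
    else:
        sig = fold_changes["p_value"].le(alpha) & fold_changes["p_value"].notna()
        cls = np.select(
            [sig & (fold_changes["log2_fc"] > 0), sig & (fold_changes["log2_fc"] < 0)],
            ["up", "down"],
            "ns",
        )
        cls = pd.Series(cls)
    n_up = int((cls == "up").sum())
    n_down = int((cls == "down").sum())
    n_ns = int((cls == "ns").sum())
    pct_up, pct_down, pct_ns = class_percentages(n_up, n_down, n_ns)
    return VolcanoSummary(str(stage), n_up, n_down, n_ns, pct_up, pct_down, pct_ns)


def validate_ontology_map(ontology: pd.DataFrame) -> pd.DataFrame:
    """Check the accession -> (gene, cluster) map is single-valued."""
    required = {"accession", "gene_id", "cluster"}
    missing = required - set(ontology.columns)
    if missing:
        raise ValueError(f"ontology map missing columns: {sorted(missing)}")
    dup = ontology.groupby("accession").agg(
        genes=("gene_id", "nunique"), clusters=("cluster", "nunique")
    )
    bad = dup[(dup["genes"] > 1) | (dup["clusters"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"accessions mapping to multiple genes or clusters: {list(bad.index[:5])}"
        )
    return ontology.drop_duplicates("accession")


def match_genes_to_proteins(
    protein_fold_changes: pd.DataFrame,
    ontology: pd.DataFrame,
    gene_fold_changes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair protein-FSR fold changes with gene-FPKM fold changes via accession.

    ``protein_fold_changes`` needs columns ``protein_accession, log2_fc_fsr``;
    ``gene_fold_changes`` needs ``gene_id, log2_fc``.  Returns
    ``(paired, unmatched)`` where ``paired`` carries accession, gene, cluster
    and both fold changes; the inner join is deterministic and
    order-independent (sorted by accession).
    """
    onto = validate_ontology_map(ontology)
    merged = protein_fold_changes.merge(
        onto, left_on="protein_accession", right_on="accession", how="left"
    ).merge(
        gene_fold_changes.rename(columns={"log2_fc": "log2_fc_fpkm"})[
            ["gene_id", "log2_fc_fpkm"]
        ],
        on="gene_id",
        how="left",
    )
    matched = merged["log2_fc_fpkm"].notna() & merged["gene_id"].notna()
    paired = (
        merged.loc[matched, ["protein_accession", "gene_id", "cluster", "log2_fc_fsr", "log2_fc_fpkm"]]
        .sort_values("protein_accession", ignore_index=True)
    )
    unmatched = (
        merged.loc[~matched, ["protein_accession"]]
        .assign(reason=np.where(merged.loc[~matched, "gene_id"].isna(), "no gene mapping", "gene not measured"))
        .sort_values("protein_accession", ignore_index=True)
    )
    return paired, unmatched


def cluster_direction_summary(
    members: pd.DataFrame,
    value_column: str,
    cluster_column: str = "cluster",
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-cluster direction-of-change counts with an exact binomial p.

    ``members`` holds one row per cluster member with a signed change in
    ``value_column`` (e.g. a log2 fold change or an injured-minus-control FSR
    difference).  Exact zeros are ties: recorded separately and excluded from
    the test denominator.  Empty clusters are simply absent from the output.
    """
    rows = []
    for cluster, grp in members.groupby(cluster_column, sort=True):
        vals = grp[value_column].to_numpy(float)
        n_inc = int((vals > 0).sum())
        n_dec = int((vals < 0).sum())
        n_tie = int((vals == 0).sum())
        n_test = n_inc + n_dec
        majority = "increased" if n_inc >= n_dec else "decreased"
        p = (
            binomial_direction_test(max(n_inc, n_dec), n_test, two_sided=two_sided)
            if n_test
            else 1.0
        )
        rows.append(
            ClusterSummary(
                cluster=str(cluster),
                n_members=len(grp),
                n_increased=n_inc,
                n_decreased=n_dec,
                n_ties=n_tie,
                majority_direction=majority,
                p_value=p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
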