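"""Study orchestration: isotope chemistry -> kinetics -> statistics ->
expression -> flux/expression correlation, with deterministic report tables.

The entry point is :func:`run_study`, which consumes a :class:`StudyConfig`
pointing at the study's input tables (typically a directory written by
:mod:`fluxprot.synthetic`, or equivalently formatted real extractions) and
returns a :class:`ReportBundle`.  :func:`write_report` serializes every table
with stable ordering and fixed float formatting, so re-running on the same
inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr_mod
from . import stats as stats_mod
from .kinetics import (
    DEFAULT_STAGES,
    PeptideSpec,
    RollupResult,
    StageDesign,
    compute_peptide_kinetics,
    dna_fraction_new,
    labeling_site_table,
    protein_rollup,
)

log = logging.getLogger("fluxprot")

INJURED_STAGES = ("Proliferation", "Differentiation", "Maturation")


class InputError(ValueError):
    """Malformed or missing study inputs (CLI exit code 1)."""


@dataclass
class StudyConfig:
    """Paths and analysis options for one study run.

    ``comparator`` selects the control arm for every injured-limb
    comparison: ``"uninjured_group"`` (separate unlabeled-control animals,
    the default) or ``"contralateral_limb"`` (the uninjected limb of the
    same animals).
    """

    isotopomers: Path
    body_water: Path
    peptide_map: Path
    ontology_map: Path
    fpkm: Path
    dna: Path | None = None
    stages: dict[str, StageDesign] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    comparator: str = "uninjured_group"
    alpha: float = 0.05
    pseudocount: float = expr_mod.PSEUDOCOUNT_DEFAULT
    fixed_mods: tuple[str, ...] = ("carbamidomethyl",)
    equal_variance: bool = True
    binomial_two_sided: bool = False
    f_cap: float = 0.99
    k_window: int = 4
    min_peptides: int = 2
    min_animals: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha={self.alpha} outside (0, 1)")
        if self.comparator not in ("uninjured_group", "contralateral_limb"):
            raise InputError(f"unknown comparator mode {self.comparator!r}")

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, **overrides) -> "StudyConfig":
        """Configure from a bundle directory with the standard file names."""
        d = Path(bundle_dir)
        stages = dict(DEFAULT_STAGES)
        stages_file = d / "stages.yaml"
        if stages_file.exists():
            with open(stages_file) as fh:
                raw = yaml.safe_load(fh)
            stages = {
                name: StageDesign(name, spec["label_start"], spec["label_end"])
                for name, spec in raw.items()
            }
        dna = d / "dna.tsv"
        return cls(
            isotopomers=d / "isotopomers.tsv",
            body_water=d / "body_water.tsv",
            peptide_map=d / "peptide_map.tsv",
            ontology_map=d / "ontology_map.tsv",
            fpkm=d / "fpkm.tsv",
            dna=dna if dna.exists() else None,
            stages=stages,
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs: dict = {}
        for key in ("isotopomers", "body_water", "peptide_map", "ontology_map", "fpkm", "dna"):
            if key in raw.get("paths", {}):
                kwargs[key] = base / raw["paths"][key]
        if "stages" in raw:
            kwargs["stages"] = {
                name: StageDesign(name, spec["label_start"], spec["label_end"])
                for name, spec in raw["stages"].items()
            }
        for key in ("comparator", "alpha", "pseudocount", "equal_variance",
                    "binomial_two_sided", "f_cap", "k_window", "min_peptides", "min_animals"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """Every report table the pipeline emits; see :func:`write_report`."""

    peptide_kinetics: pd.DataFrame
    protein_kinetics: pd.DataFrame
    rejects: pd.DataFrame
    filter_ledger: dict[str, int]
    global_tests: pd.DataFrame
    per_protein_tests: pd.DataFrame
    flux_cluster_summary: pd.DataFrame
    fold_changes: pd.DataFrame
    volcano_summary: pd.DataFrame
    expression_cluster_summary: pd.DataFrame
    paired_flux_expression: pd.DataFrame
    unmatched_proteins: pd.DataFrame
    correlations: pd.DataFrame
    dna_summary: pd.DataFrame


def _read_tsv(path: Path, required: set[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file
        raise InputError(f"cannot parse {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


def _build_peptide_specs(
    peptide_map: pd.DataFrame, config: StudyConfig
) -> dict[str, PeptideSpec]:
    site_table = labeling_site_table()
    specs: dict[str, PeptideSpec] = {}
    multi = peptide_map.groupby("peptide")["protein_accession"].nunique()
    shared = multi[multi > 1]
    if not shared.empty:
        raise InputError(
            f"peptides mapping to multiple proteins: {list(shared.index[:5])}"
        )
    for seq in peptide_map["peptide"].unique():
        try:
            specs[seq] = PeptideSpec.from_sequence(
                seq, mods=config.fixed_mods, site_table=site_table
            )
        except ValueError as exc:
            raise InputError(f"bad peptide {seq!r}: {exc}") from exc
    return specs


def _comparator_frame(
    samples: pd.DataFrame, stage: str, comparator: str
) -> pd.DataFrame:
    ok = samples[samples["passes_peptide_filter"]]
    if comparator == "uninjured_group":
        return ok[(ok["stage"] == "Control") & (ok["limb"] == "control")]
    return ok[(ok["stage"] == stage) & (ok["limb"] == "control")]


def run_study(config: StudyConfig) -> ReportBundle:
    """Execute the full analysis and return every report table.

    Raises :class:`InputError` on schema problems (missing files or columns,
    an animal without a body-water record, a peptide mapped to two proteins).
    """
    iso = _read_tsv(
        config.isotopomers,
        {"peptide", "protein_accession", "animal_id", "limb", "stage"}
        | {f"M{i}" for i in range(config.k_window)},
    )
    body_water_df = _read_tsv(config.body_water, {"animal_id", "p"})
    peptide_map = _read_tsv(config.peptide_map, {"peptide", "protein_accession"})
    ontology = _read_tsv(config.ontology_map, {"accession", "gene_id", "cluster"})
    fpkm = _read_tsv(config.fpkm, {"gene_id", "stage", "replicate", "fpkm"})
    try:
        ontology = expr_mod.validate_ontology_map(ontology)
    except ValueError as exc:
        raise InputError(str(exc)) from exc

    body_water = dict(zip(body_water_df["animal_id"], body_water_df["p"]))
    specs = _build_peptide_specs(peptide_map, config)

    try:
        pep_kin = compute_peptide_kinetics(
            iso, specs, body_water, config.stages, config.k_window, config.f_cap
        )
    except ValueError as exc:
        raise InputError(str(exc)) from exc
    rollup: RollupResult = protein_rollup(
        pep_kin, min_peptides=config.min_peptides, min_animals=config.min_animals
    )
    log.info(
        "roll-up: %(proteins_in)d protein-groups in, %(compared)d compared, "
        "%(excluded_peptide_filter)d failed the peptide filter, "
        "%(excluded_animal_filter)d failed the animal filter",
        rollup.ledger,
    )

    cluster_by_acc = dict(zip(ontology["accession"], ontology["cluster"]))

    global_rows, per_protein_rows, flux_cluster_frames = [], [], []
    protein_fc_frames = []
    for stage in INJURED_STAGES:
        injured = rollup.proteins[
            (rollup.proteins["stage"] == stage) & (rollup.proteins["limb"] == "injured")
        ]
        comp_samples = _comparator_frame(rollup.samples, stage, config.comparator)
        comp_proteins = (
            comp_samples.groupby("protein_accession")
            .filter(lambda g: g["animal_id"].nunique() >= config.min_animals)
            .groupby("protein_accession")["fsr_pct_per_day"]
            .mean()
        )
        common = sorted(set(injured["protein_accession"]) & set(comp_proteins.index))
        if len(common) >= 2:
            inj_means = injured.set_index("protein_accession").loc[
                common, "mean_fsr_pct_per_day"
            ]
            res = stats_mod.unpaired_t(
                inj_means, comp_proteins.loc[common], config.equal_variance
            )
            global_rows.append(
                {
                    "stage": stage,
                    "n_proteins": len(common),
                    "mean_fsr_injured": float(inj_means.mean()),
                    "mean_fsr_comparator": float(comp_proteins.loc[common].mean()),
                    "t_statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )

        # per-protein comparisons on animal-level values, BH within the stage
        inj_samples = rollup.samples[
            (rollup.samples["stage"] == stage)
            & (rollup.samples["limb"] == "injured")
            & rollup.samples["passes_peptide_filter"]
        ]
        stage_tests = []
        for acc in common:
            x = inj_samples[inj_samples["protein_accession"] == acc][
                "fsr_pct_per_day"
            ].to_numpy()
            y = comp_samples[comp_samples["protein_accession"] == acc][
                "fsr_pct_per_day"
            ].to_numpy()
            if x.size < 2 or y.size < 2:
                continue
            res = stats_mod.unpaired_t(x, y, config.equal_variance)
            stage_tests.append(
                {
                    "stage": stage,
                    "protein_accession": acc,
                    "cluster": cluster_by_acc.get(acc, "Unassigned"),
                    "mean_fsr_injured": float(x.mean()),
                    "mean_fsr_comparator": float(y.mean()),
                    "delta_fsr": float(x.mean() - y.mean()),
                    "t_statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        if stage_tests:
            stage_df = pd.DataFrame(stage_tests)
            stage_df["adjusted_p"] = stats_mod.bh_adjust(stage_df["p_value"])
            stage_df["significant"] = stage_df["adjusted_p"] <= config.alpha
            per_protein_rows.append(stage_df)

            members = stage_df[stage_df["cluster"] != "Unassigned"][
                ["protein_accession", "cluster", "delta_fsr"]
            ]
            if not members.empty:
                summary = expr_mod.cluster_direction_summary(
                    members, "delta_fsr", two_sided=config.binomial_two_sided
                )
                summary.insert(0, "stage", stage)
                flux_cluster_frames.append(summary)

            fc = stage_df[["protein_accession", "mean_fsr_injured", "mean_fsr_comparator"]]
            protein_fc_frames.append(
                pd.DataFrame(
                    {
                        "stage": stage,
                        "protein_accession": fc["protein_accession"],
                        "log2_fc_fsr": np.log2(
                            fc["mean_fsr_injured"] / fc["mean_fsr_comparator"]
                        ),
                    }
                )
            )

    # expression layer: per-stage fold changes vs the uninjured control stage
    fc_frames, volcano_rows, expr_cluster_frames = [], [], []
    paired_frames, unmatched_frames, corr_rows = [], [], []
    for stage in INJURED_STAGES:
        fc = expr_mod.fold_change_table(
            fpkm, stage, "Control", config.pseudocount, config.alpha
        )
        fc_frames.append(fc)
        v = expr_mod.volcano_classify(fc, config.alpha)
        volcano_rows.append(v.__dict__ | {"n_total": v.n_total})
        log.info(
            "volcano %s: %d up (%.1f%%), %d down (%.1f%%), %d ns (%.1f%%)",
            stage, v.n_up, v.pct_up, v.n_down, v.pct_down, v.n_ns, v.pct_ns,
        )

        # cluster direction of expression for genes matched to measured proteins
        matched_genes = ontology.merge(
            fc[["gene_id", "log2_fc"]], on="gene_id", how="inner"
        )
        if not matched_genes.empty:
            summary = expr_mod.cluster_direction_summary(
                matched_genes, "log2_fc", two_sided=config.binomial_two_sided
            )
            summary.insert(0, "stage", stage)
            expr_cluster_frames.append(summary)

        # pair protein flux fold changes with gene expression fold changes
        stage_fc = [f for f in protein_fc_frames if (f["stage"] == stage).any()]
        if stage_fc:
            paired, unmatched = expr_mod.match_genes_to_proteins(
                stage_fc[0], ontology, fc
            )
            paired.insert(0, "stage", stage)
            unmatched.insert(0, "stage", stage)
            paired_frames.append(paired)
            unmatched_frames.append(unmatched)
            if len(paired) >= 3 and paired["log2_fc_fsr"].nunique() > 1:
                reg = stats_mod.linear_regression_r2(
                    paired["log2_fc_fsr"], paired["log2_fc_fpkm"]
                )
                corr_rows.append(
                    {
                        "stage": stage,
                        "n_pairs": reg.n,
                        "slope": reg.slope,
                        "intercept": reg.intercept,
                        "r_squared": reg.r_squared,
                        "p_value": reg.p_value,
                    }
                )
            else:
                log.warning("stage %s: <3 usable pairs, regression skipped", stage)

    dna_rows = []
    if config.dna is not None:
        dna = _read_tsv(
            config.dna, {"animal_id", "stage", "measured_enrichment", "asymptote_enrichment"}
        )
        dna["f_dna_pct"] = [
            dna_fraction_new(m, a)
            for m, a in zip(dna["measured_enrichment"], dna["asymptote_enrichment"])
        ]
        for stage, grp in dna.groupby("stage", sort=True):
            dna_rows.append(
                {
                    "stage": stage,
                    "n_animals": len(grp),
                    "mean_f_dna_pct": float(grp["f_dna_pct"].mean()),
                    "sd_f_dna_pct": float(grp["f_dna_pct"].std(ddof=1)),
                }
            )

    def _concat(frames: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
        if frames:
            return pd.concat(frames, ignore_index=True)
        return pd.DataFrame(columns=columns)

    table1 = rollup.proteins.merge(
        ontology[["accession", "cluster"]],
        left_on="protein_accession",
        right_on="accession",
        how="left",
    ).drop(columns=["accession"])
    table1["cluster"] = table1["cluster"].fillna("Unassigned")

    return ReportBundle(
        peptide_kinetics=pep_kin,
        protein_kinetics=table1,
        rejects=rollup.rejects,
        filter_ledger=rollup.ledger,
        global_tests=pd.DataFrame(global_rows),
        per_protein_tests=_concat(per_protein_rows, ["stage", "protein_accession"]),
        flux_cluster_summary=_concat(flux_cluster_frames, ["stage", "cluster"]),
        fold_changes=_concat(fc_frames, ["gene_id", "stage", "log2_fc", "p_value"]),
        volcano_summary=pd.DataFrame(volcano_rows),
        expression_cluster_summary=_concat(expr_cluster_frames, ["stage", "cluster"]),
        paired_flux_expression=_concat(
            paired_frames,
            ["stage", "protein_accession", "gene_id", "cluster", "log2_fc_fsr", "log2_fc_fpkm"],
        ),
        unmatched_proteins=_concat(unmatched_frames, ["stage", "protein_accession", "reason"]),
        correlations=pd.DataFrame(corr_rows),
        dna_summary=pd.DataFrame(dna_rows),
    )


def correlate_flux_expression(paired: pd.DataFrame) -> pd.DataFrame:
    """Per-stage OLS of gene log2FC (response) on protein-FSR log2FC.

    Stages with fewer than 3 pairs (or constant predictor) are skipped with
    a warning; R^2 is symmetric in the axis choice, the slope p nearly so.
    """
    rows = []
    for stage, grp in paired.groupby("stage", sort=True):
        if len(grp) < 3 or grp["log2_fc_fsr"].nunique() < 2:
            log.warning("stage %s: insufficient pairs for regression", stage)
            continue
        reg = stats_mod.linear_regression_r2(grp["log2_fc_fsr"], grp["log2_fc_fpkm"])
        rows.append(
            {
                "stage": stage,
                "n_pairs": reg.n,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "p_value": reg.p_value,
            }
        )
    return pd.DataFrame(rows)


_REPORT_SORT_KEYS: dict[str, list[str]] = {
    "peptide_kinetics": ["stage", "limb", "animal_id", "protein_accession", "peptide"],
    "protein_kinetics": ["stage", "limb", "protein_accession"],
    "rejects": ["stage", "limb", "protein_accession"],
    "global_tests": ["stage"],
    "per_protein_tests": ["stage", "protein_accession"],
    "flux_cluster_summary": ["stage", "cluster"],
    "fold_changes": ["stage", "gene_id"],
    "volcano_summary": ["stage"],
    "expression_cluster_summary": ["stage", "cluster"],
    "paired_flux_expression": ["stage", "protein_accession"],
    "unmatched_proteins": ["stage", "protein_accession"],
    "correlations": ["stage"],
    "dna_summary": ["stage"],
}


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every report table as TSV with stable order and float format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, keys in _REPORT_SORT_KEYS.items():
        df: pd.DataFrame = getattr(bundle, name)
        if not df.empty:
            usable = [k for k in keys if k in df.columns]
            df = df.sort_values(usable, ignore_index=True) if usable else df
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    ledger = pd.DataFrame(
        sorted(bundle.filter_ledger.items()), columns=["counter", "count"]
    )
    ledger.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
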