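"""Synthetic heavy-water study generator.

Emits a complete study bundle — peptide isotopomer tables, body-water
enrichments, FPKM tables, an ontology map, stage designs, and a ground-truth
file — with the statistical structure the analysis pipeline assumes: five
animals per group across four groups (three post-injury regeneration windows
plus an uninjured 3-day-labeled control), ~100 proteins per group in five
functional clusters with 2-5 tryptic-like peptides each, Gaussian envelope
measurement noise, and per-stage expression tables with planted fold changes.

The forward model inverts the analysis exactly: for a protein with true
replacement rate k measured over t days, f = 1 - exp(-k t) and the noiseless
peptide envelope is f * labeled(p, n) + (1 - f) * natural, both on the
renormalized M0-M3 window.  Everything is deterministic per seed
(numpy PCG64).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .isotopes import natural_distribution
from .kinetics import (
    DEFAULT_STAGES,
    PeptideSpec,
    StageDesign,
    labeled_distribution,
    labeling_site_table,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_peptides",
           "simulate_isotopomer_measurements", "simulate_expression",
           "simulate_dna", "simulate_study_bundle"]

CLUSTERS = ("Cytoplasm", "Glycolysis", "Mitochondria", "Myofibril", "OxPhos")
INJURED_STAGES = ("Proliferation", "Differentiation", "Maturation")

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the modeled study: n = 5 animals per group, four labeling
    windows, five ontology clusters of 20 proteins (inside the study's
    73-127 proteins-per-group band), body water near 5% enrichment, and
    true FSR regimes matching the reported per-stage magnitudes (control
    2-4 %/day; injured Differentiation 12-20; Maturation 6-13).  These are
    simulation defaults, not claimed reproductions of the deposited data.
    """

    animals_per_group: int = 5
    proteins_per_cluster: int = 20
    peptides_per_protein: tuple[int, int] = (2, 5)
    peptide_length: tuple[int, int] = (7, 25)
    fixed_mods: tuple[str, ...] = ("carbamidomethyl",)
    body_water_mean: float = 0.05
    body_water_sd: float = 0.003
    envelope_noise_sd: float = 0.003
    k_window: int = 4
    #: true FSR (%/day) uniform ranges; "control" covers every control limb
    #: and the uninjured control group.
    fsr_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (2.0, 4.0),
            "Proliferation": (2.0, 4.0),  # no global shift in this window
            "Differentiation": (12.0, 20.0),
            "Maturation": (6.0, 13.0),
        }
    )
    # expression model
    n_genes: int = 17000
    fpkm_log_mean: float = 2.0
    fpkm_log_sd: float = 1.5
    replicate_log_sd: float = 0.25
    de_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "Proliferation": 0.29,
            "Differentiation": 0.28,
            "Maturation": 0.09,
        }
    )
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.5
    #: planted mean log2FC of protein-matched genes per stage x cluster
    #: (directional expression shifts; near-zero entries are null clusters).
    cluster_expression_log2fc: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Proliferation": {
                "Cytoplasm": -0.15,
                "Glycolysis": -1.2,
                "Mitochondria": -1.2,
                "Myofibril": -1.2,
                "OxPhos": -1.2,
            },
            "Differentiation": {
                "Cytoplasm": -1.0,
                "Glycolysis": -1.0,
                "Mitochondria": -1.2,
                "Myofibril": 0.0,
                "OxPhos": -1.0,
            },
            "Maturation": {
                "Cytoplasm": 0.1,
                "Glycolysis": 1.2,
                "Mitochondria": -0.1,
                "Myofibril": 1.0,
                "OxPhos": 1.0,
            },
        }
    )
    cluster_gene_log2fc_sd: float = 0.4
    # DNA replication readout (fraction of newly divided cells, %)
    dna_fraction_pct: dict[str, float] = field(
        default_factory=lambda: {
            "Proliferation": 44.0,
            "Differentiation": 10.0,
            "Maturation": 3.0,
            "Control": 2.0,
        }
    )
    dna_noise_pct_sd: float = 3.0
    stages: dict[str, StageDesign] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    rng_algorithm: str = "numpy PCG64"

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "stages"
        }
        out["stages"] = {
            name: {"label_start": s.label_start, "label_end": s.label_end}
            for name, s in self.stages.items()
        }
        return out


@dataclass
class GroundTruth:
    """Planted parameters, sufficient to score pipeline recovery."""

    proteins: pd.DataFrame  # accession, cluster, gene_id, stage, limb, true_k_per_day, true_fsr_pct
    genes: pd.DataFrame  # gene_id, stage, true_log2fc, is_de
    animals: pd.DataFrame  # animal_id, stage, p
    dna: pd.DataFrame  # stage, true_fraction_pct


def _random_tryptic_peptide(rng: np.random.Generator, length: tuple[int, int]) -> str:
    n = int(rng.integers(length[0], length[1] + 1))
    body = "".join(rng.choice(list(_AA), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_peptides(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, PeptideSpec], pd.DataFrame]:
    """Random tryptic-like peptides (7-25 residues ending K/R) per protein.

    Returns the PeptideSpec dictionary and a peptide -> protein map with the
    protein's cluster and matched gene id.  Deterministic per rng state.
    """
    site_table = labeling_site_table()
    peptides: dict[str, PeptideSpec] = {}
    rows = []
    idx = 0
    for cluster in CLUSTERS:
        for _ in range(config.proteins_per_cluster):
            acc = f"SYN{idx:04d}"
            gene = f"GENE{idx:04d}"
            idx += 1
            n_pep = int(
                rng.integers(config.peptides_per_protein[0], config.peptides_per_protein[1] + 1)
            )
            for _ in range(n_pep):
                seq = _random_tryptic_peptide(rng, config.peptide_length)
                while seq in peptides:
                    seq = _random_tryptic_peptide(rng, config.peptide_length)
                peptides[seq] = PeptideSpec.from_sequence(
                    seq, mods=config.fixed_mods, site_table=site_table
                )
                rows.append(
                    {
                        "peptide": seq,
                        "protein_accession": acc,
                        "cluster": cluster,
                        "gene_id": gene,
                        "charge": int(rng.integers(2, 4)),
                    }
                )
    return peptides, pd.DataFrame(rows)


def _true_kinetics(
    config: SimulationConfig, peptide_map: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    proteins = peptide_map[["protein_accession", "cluster", "gene_id"]].drop_duplicates()
    rows = []
    for rec in proteins.itertuples(index=False):
        for stage in INJURED_STAGES + ("Control",):
            limbs = ("injured", "control") if stage != "Control" else ("control",)
            for limb in limbs:
                regime = stage if (limb == "injured") else "control"
                lo, hi = config.fsr_ranges[regime]
                fsr = float(rng.uniform(lo, hi))
                rows.append(
                    {
                        "protein_accession": rec.protein_accession,
                        "cluster": rec.cluster,
                        "gene_id": rec.gene_id,
                        "stage": stage,
                        "limb": limb,
                        "true_k_per_day": fsr / 100.0,
                        "true_fsr_pct": fsr,
                    }
                )
    return pd.DataFrame(rows)


def simulate_isotopomer_measurements(
    config: SimulationConfig,
    peptides: Mapping[str, PeptideSpec],
    peptide_map: pd.DataFrame,
    truth_proteins: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy M0-M3 tables plus per-animal body-water records.

    Per animal, p ~ Normal(mean, sd) truncated at 0; per measurement the
    noiseless mixture envelope gets additive Gaussian noise on each fraction,
    is clamped at 0, and renormalized over the window.
    """
    k = config.k_window
    animal_rows = []
    animals: dict[str, list[str]] = {}
    for stage in INJURED_STAGES + ("Control",):
        ids = []
        for j in range(config.animals_per_group):
            animal_id = f"{stage[:4].lower()}_{j + 1}"
            p = -1.0
            while not 0.0 <= p < 0.5:
                p = float(rng.normal(config.body_water_mean, config.body_water_sd))
            animal_rows.append({"animal_id": animal_id, "stage": stage, "p": p})
            ids.append(animal_id)
        animals[stage] = ids
    animal_df = pd.DataFrame(animal_rows)
    p_by_animal = dict(zip(animal_df["animal_id"], animal_df["p"]))

    truth_idx = truth_proteins.set_index(["protein_accession", "stage", "limb"])[
        "true_k_per_day"
    ]
    nat_cache = {
        seq: natural_distribution(spec.formula, k) for seq, spec in peptides.items()
    }
    lab_cache: dict[tuple[str, str], np.ndarray] = {}

    rows = []
    pep_records = list(peptide_map.itertuples(index=False))
    for stage in INJURED_STAGES + ("Control",):
        t = config.stages[stage].t
        limbs = ("injured", "control") if stage != "Control" else ("control",)
        for animal_id in animals[stage]:
            p = p_by_animal[animal_id]
            for limb in limbs:
                for rec in pep_records:
                    key = (rec.peptide, animal_id)
                    if key not in lab_cache:
                        spec = peptides[rec.peptide]
                        lab_cache[key] = labeled_distribution(spec.formula, spec.n_sites, p, k)
                    true_k = float(truth_idx[(rec.protein_accession, stage, limb)])
                    f = 1.0 - np.exp(-true_k * t)
                    env = f * lab_cache[key] + (1.0 - f) * nat_cache[rec.peptide]
                    if config.envelope_noise_sd > 0:
                        env = env + rng.normal(0.0, config.envelope_noise_sd, size=k)
                        env = np.clip(env, 0.0, None)
                    env = env / env.sum()
                    row = {
                        "peptide": rec.peptide,
                        "protein_accession": rec.protein_accession,
                        "animal_id": animal_id,
                        "limb": limb,
                        "stage": stage,
                    }
                    row.update({f"M{i}": env[i] for i in range(k)})
                    rows.append(row)
    iso = pd.DataFrame(rows)
    body_water = animal_df[["animal_id", "p"]].copy()
    return iso, body_water


def simulate_expression(
    config: SimulationConfig,
    peptide_map: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format FPKM tables per stage plus the per-gene ground truth.

    Protein-matched genes receive the configured per-cluster directional
    shifts; background genes are differentially expressed with the per-stage
    planted fraction and symmetric random sign.
    """
    matched = peptide_map[["gene_id", "cluster"]].drop_duplicates().reset_index(drop=True)
    n_matched = len(matched)
    n_background = max(config.n_genes - n_matched, 0)
    gene_ids = list(matched["gene_id"]) + [f"BG{i:05d}" for i in range(n_background)]
    clusters = list(matched["cluster"]) + [None] * n_background
    base = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, size=len(gene_ids))

    truth_rows = []
    expr_rows: dict[str, np.ndarray] = {}
    n_rep = config.animals_per_group
    stages = list(INJURED_STAGES) + ["Control"]
    # planted log2 fold changes per stage (Control row is all zeros)
    planted = np.zeros((len(stages), len(gene_ids)))
    for si, stage in enumerate(INJURED_STAGES):
        shifts = np.zeros(len(gene_ids))
        for gi, cluster in enumerate(clusters):
            if cluster is not None:
                mean = config.cluster_expression_log2fc[stage][cluster]
                shifts[gi] = rng.normal(mean, config.cluster_gene_log2fc_sd)
            else:
                if rng.random() < config.de_fraction[stage]:
                    mag = abs(rng.normal(config.de_log2fc_mean, config.de_log2fc_sd))
                    shifts[gi] = mag if rng.random() < 0.5 else -mag
        planted[si] = shifts
        for gi, gene in enumerate(gene_ids):
            truth_rows.append(
                {
                    "gene_id": gene,
                    "stage": stage,
                    "true_log2fc": shifts[gi],
                    "is_de": bool(abs(shifts[gi]) > 0.0) if clusters[gi] is None
                    else bool(abs(config.cluster_expression_log2fc[stage][clusters[gi]]) >= 0.5),
                }
            )

    records = []
    for si, stage in enumerate(stages):
        stage_mean = base * np.power(2.0, planted[si])
        noise = rng.lognormal(0.0, config.replicate_log_sd, size=(n_rep, len(gene_ids)))
        fpkm = stage_mean[None, :] * noise
        for rep in range(n_rep):
            records.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "stage": stage,
                        "replicate": rep + 1,
                        "fpkm": fpkm[rep],
                    }
                )
            )
    expr = pd.concat(records, ignore_index=True)
    return expr, pd.DataFrame(truth_rows)


def simulate_dna(
    config: SimulationConfig,
    animals: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deoxyribose 2H enrichment per animal with a supplied asymptote.

    The asymptote (fully-turned-over reference enrichment) scales with the
    animal's body-water p; the measured enrichment is the planted division
    fraction of it plus Gaussian noise, floored at zero.
    """
    rows = []
    for rec in animals.itertuples(index=False):
        asym = 0.65 * rec.p  # reference amplification factor for deoxyribose
        true_pct = config.dna_fraction_pct[rec.stage]
        noisy_pct = max(float(rng.normal(true_pct, config.dna_noise_pct_sd)), 0.0)
        rows.append(
            {
                "animal_id": rec.animal_id,
                "stage": rec.stage,
                "measured_enrichment": noisy_pct / 100.0 * asym,
                "asymptote_enrichment": asym,
            }
        )
    truth = pd.DataFrame(
        [{"stage": s, "true_fraction_pct": v} for s, v in config.dna_fraction_pct.items()]
    )
    return pd.DataFrame(rows), truth


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # 12 significant digits: enough for exact noise-free kinetic round trips
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def simulate_study_bundle(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int,
) -> GroundTruth:
    """Generate every input file the pipeline consumes, plus ground truth.

    Layout under ``out_dir``: isotopomers.tsv, body_water.tsv,
    peptide_map.tsv, proteins.fasta, ontology_map.tsv, fpkm.tsv, dna.tsv,
    stages.yaml, config.yaml, manifest.tsv and a ground_truth/ directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    rng = np.random.default_rng(seed)
    peptides, peptide_map = simulate_peptides(config, rng)
    truth_proteins = _true_kinetics(config, peptide_map, rng)
    iso, body_water = simulate_isotopomer_measurements(
        config, peptides, peptide_map, truth_proteins, rng
    )
    animals = (
        iso[["animal_id", "stage"]].drop_duplicates().merge(body_water, on="animal_id")
    )
    expr, truth_genes = simulate_expression(config, peptide_map, rng)
    dna, truth_dna = simulate_dna(config, animals, rng)

    _write_tsv(iso, out / "isotopomers.tsv")
    _write_tsv(body_water, out / "body_water.tsv")
    _write_tsv(
        peptide_map[["peptide", "protein_accession", "charge"]], out / "peptide_map.tsv"
    )
    _write_tsv(
        peptide_map[["protein_accession", "gene_id", "cluster"]].drop_duplicates().rename(
            columns={"protein_accession": "accession"}
        ),
        out / "ontology_map.tsv",
    )
    _write_tsv(expr, out / "fpkm.tsv")
    _write_tsv(dna, out / "dna.tsv")

    with open(out / "proteins.fasta", "w") as fh:
        for acc, grp in peptide_map.groupby("protein_accession", sort=True):
            fh.write(f">{acc} synthetic\n")
            fh.write("".join(grp["peptide"]) + "\n")

    with open(out / "stages.yaml", "w") as fh:
        yaml.safe_dump(
            {
                name: {"label_start": s.label_start, "label_end": s.label_end}
                for name, s in config.stages.items()
            },
            fh,
            sort_keys=True,
        )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, **config.to_dict()}, fh, sort_keys=True)

    _write_tsv(truth_proteins, truth_dir / "proteins.tsv")
    _write_tsv(truth_genes, truth_dir / "genes.tsv")
    _write_tsv(animals, truth_dir / "animals.tsv")
    _write_tsv(truth_dna, truth_dir / "dna.tsv")

    manifest_rows = []
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest_rows.append({"file": str(path.relative_to(out)), "sha256": digest})
    _write_tsv(pd.DataFrame(manifest_rows), out / "manifest.tsv")

    return GroundTruth(
        proteins=truth_proteins, genes=truth_genes, animals=animals, dna=truth_dna
    )
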