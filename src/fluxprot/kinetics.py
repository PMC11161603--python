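"""MIDA label-incorporation model and protein turnover kinetics.

During continuous heavy-water labeling at body-water enrichment ``p``, a
newly synthesized peptide incorporates deuterium at ``n`` of its C-H
positions.  The measured envelope of a partially turned-over pool is the
mixture

    measured = f * labeled(p, n) + (1 - f) * natural,

so the fraction newly synthesized follows from the depletion of the
monoisotopic peak:

    f = (M0_measured - M0_natural) / (M0_asymptote - M0_natural),

where the denominator (``EM0*``) is the M0 change at complete turnover.
First-order replacement converts f over a labeling window of t days into a
rate constant k = -ln(1 - f) / t and a fractional synthesis rate
FSR = 100 * k (% of the pool replaced per day).

All envelopes here are computed on the same truncated, renormalized M0..M3
window as :mod:`fluxprot.isotopes` (K configurable), because the upstream
extraction only reports those four isotopomers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotopes import (
    ElementalFormula,
    _convolve_trunc,
    _poly_power_trunc,
    element_shift_poly,
    isotope_table,
    natural_distribution,
    peptide_formula,
)

__all__ = [
    "BodyWaterRecord",
    "PeptideSpec",
    "StageDesign",
    "DEFAULT_STAGES",
    "F_CAP_DEFAULT",
    "labeling_site_table",
    "n_labeling_sites",
    "labeled_distribution",
    "em0_asymptote",
    "em0_polynomial_fit",
    "fraction_new",
    "rate_constant",
    "compute_peptide_kinetics",
    "protein_rollup",
    "dna_fraction_new",
]

F_CAP_DEFAULT = 0.99


@dataclass(frozen=True)
class BodyWaterRecord:
    """Per-animal body-water 2H mole-fraction enrichment (the precursor pool)."""

    animal_id: str
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 0.5:
            raise ValueError(f"body-water enrichment p={self.p} outside [0, 0.5)")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide as a kinetic measurement unit: sequence, formula, site count n."""

    sequence: str
    formula: ElementalFormula
    n_sites: float

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_sites > self.formula.get("H", 0):
            raise ValueError(
                f"n_sites={self.n_sites} exceeds hydrogen count "
                f"{self.formula.get('H', 0)} for {self.sequence!r}"
            )

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        mods: Sequence[str] = (),
        site_table: Mapping[str, float] | None = None,
    ) -> "PeptideSpec":
        return cls(
            sequence=sequence,
            formula=peptide_formula(sequence, mods),
            n_sites=n_labeling_sites(sequence, site_table),
        )


@dataclass(frozen=True)
class StageDesign:
    """A labeling window: stage name, label start/end (days), duration t."""

    name: str
    label_start: float
    label_end: float

    def __post_init__(self) -> None:
        if self.label_end <= self.label_start:
            raise ValueError("label_end must exceed label_start")

    @property
    def t(self) -> float:
        return self.label_end - self.label_start


#: The study design: three regeneration windows after injury plus an
#: uninjured control labeled for 3 days.
DEFAULT_STAGES: dict[str, StageDesign] = {
    "Proliferation": StageDesign("Proliferation", 0.0, 4.0),
    "Differentiation": StageDesign("Differentiation", 4.0, 7.0),
    "Maturation": StageDesign("Maturation", 10.0, 14.0),
    "Control": StageDesign("Control", 0.0, 3.0),
}


@lru_cache(maxsize=1)
def labeling_site_table() -> dict[str, float]:
    """Default per-residue deuterium-accessible C-H site counts."""
    with resources.files("fluxprot.data").joinpath("labeling_sites.json").open("r") as fh:
        return {aa: float(v) for aa, v in json.load(fh)["sites"].items()}


def n_labeling_sites(sequence: str, site_table: Mapping[str, float] | None = None) -> float:
    """Sum of per-residue site counts; additive and order-independent."""
    table = labeling_site_table() if site_table is None else site_table
    total = 0.0
    for ch in sequence:
        try:
            total += table[ch]
        except KeyError:
            raise ValueError(f"residue {ch!r} missing from labeling-site table") from None
    return total


def _labeled_envelope_int(
    formula: ElementalFormula,
    m: int,
    p: float,
    k: int,
) -> np.ndarray:
    """Raw envelope with exactly ``m`` H sites at enrichment p, rest natural."""
    env = np.zeros(k)
    env[0] = 1.0
    for el, count in formula.items():
        if el == "H":
            count -= m
        if count:
            env = _convolve_trunc(env, _poly_power_trunc(element_shift_poly(el, k), count, k), k)
    if m:
        site = np.zeros(k)
        site[0] = 1.0 - p
        site[1] = p
        env = _convolve_trunc(env, _poly_power_trunc(site, m, k), k)
    return env


def labeled_distribution(
    formula: ElementalFormula | Mapping[str, int],
    n: float,
    p: float,
    k: int = 4,
    renormalize: bool = True,
) -> np.ndarray:
    """Envelope with ``n`` H positions at 2H probability ``p``.

    Fractional ``n`` is handled by linear interpolation between the
    floor(n)- and ceil(n)-site envelopes.  The effective site enrichment is
    ``max(p, natural 2H abundance)`` — body water never drops below natural
    abundance — so ``p=0`` reproduces the natural distribution exactly, as
    does ``p`` equal to the natural abundance itself.
    """
    if not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    if not 0.0 <= p < 0.5:
        raise ValueError(f"enrichment p={p} outside [0, 0.5)")
    p = max(p, dict(isotope_table()["H"]).get(1, 0.0))
    n_h = formula.get("H", 0)
    if not 0.0 <= n <= n_h:
        raise ValueError(f"n={n} outside [0, {n_h}] for formula {formula!r}")
    lo = math.floor(n)
    hi = math.ceil(n)
    env = _labeled_envelope_int(formula, lo, p, k)
    if hi != lo:
        frac = n - lo
        env = (1.0 - frac) * env + frac * _labeled_envelope_int(formula, hi, p, k)
    if renormalize:
        env = env / env.sum()
    return env


def em0_asymptote(
    formula: ElementalFormula | Mapping[str, int],
    n: float,
    p: float,
    k: int = 4,
) -> float:
    """EM0*: change in the M0 fraction at complete turnover (<= 0).

    Zero iff ``p == 0`` or ``n == 0``.
    """
    labeled = labeled_distribution(formula, n, p, k)
    natural = natural_distribution(formula, k)
    return float(labeled[0] - natural[0])


def em0_polynomial_fit(
    formula: ElementalFormula | Mapping[str, int],
    n: float,
    k: int = 4,
    degree: int = 4,
    p_max: float = 0.12,
    n_points: int = 41,
) -> np.ndarray:
    """Polynomial coefficients (ascending powers, zero intercept) of EM0*(p).

    Provided for parity with instrument workflows that precompute curve-fit
    parameters of enrichment versus precursor enrichment; the main analysis
    path computes EM0* exactly per (p, n) instead.
    """
    ps = np.linspace(0.0, p_max, n_points)
    em0 = np.array([em0_asymptote(formula, n, p, k) for p in ps])
    # force a zero intercept: EM0*(0) = 0 by construction
    design = np.vander(ps, degree + 1, increasing=True)[:, 1:]
    coef, *_ = np.linalg.lstsq(design, em0, rcond=None)
    return np.concatenate([[0.0], coef])


def fraction_new(
    m0_measured: float,
    m0_baseline: float,
    m0_asymptote: float,
    f_cap: float = 1.0,
) -> tuple[float, bool]:
    """Fraction newly synthesized from the M0 mixture identity.

    Returns ``(f, clamped)`` where ``f`` is clamped to ``[0, f_cap]`` and
    ``clamped`` flags whether noise pushed the raw value outside that range.
    The default cap is 1 (a fully turned-over pool); the first-order rate
    cap lives in :func:`rate_constant`.
    """
    denom = m0_asymptote - m0_baseline
    if denom == 0.0:
        raise ValueError("M0 asymptote equals baseline (p or n is zero); f undefined")
    f = (m0_measured - m0_baseline) / denom
    if f < 0.0:
        return 0.0, True
    if f > f_cap:
        return f_cap, True
    return f, False


def rate_constant(f: float, t: float, f_cap: float = F_CAP_DEFAULT) -> tuple[float, float, bool]:
    """First-order replacement: k = -ln(1-f)/t, FSR = 100*k (%/day).

    Returns ``(k, fsr, capped)``; f at or above ``f_cap`` is capped (and
    flagged) rather than rejected so downstream filters see every peptide.
    """
    if t <= 0:
        raise ValueError("label duration t must be positive")
    if f < 0:
        raise ValueError("f must be >= 0")
    capped = False
    if f >= f_cap:
        f = f_cap
        capped = True
    k = -math.log1p(-f) / t
    return k, 100.0 * k, capped


def dna_fraction_new(measured_enrichment: float, asymptote_enrichment: float) -> float:
    """Fraction of newly divided cells (%) from deoxyribose 2H enrichment.

    The asymptote is the fully-turned-over reference enrichment at the
    animal's body-water p; the ratio is clamped to [0, 100] %.
    """
    if asymptote_enrichment <= 0:
        raise ValueError("asymptotic enrichment must be positive")
    return float(np.clip(100.0 * measured_enrichment / asymptote_enrichment, 0.0, 100.0))


# ---------------------------------------------------------------------------
# table-level kinetics
# ---------------------------------------------------------------------------

def compute_peptide_kinetics(
    isotopomers: pd.DataFrame,
    peptides: Mapping[str, PeptideSpec],
    body_water: Mapping[str, float],
    stages: Mapping[str, StageDesign] = DEFAULT_STAGES,
    k_window: int = 4,
    f_cap: float = F_CAP_DEFAULT,
) -> pd.DataFrame:
    """Per-measurement f, k and FSR from an isotopomer abundance table.

    ``isotopomers`` columns: peptide, protein_accession, animal_id, limb,
    stage, M0..M3 (fractional abundances; renormalized over the window here).
    ``body_water`` maps animal_id -> p.  Raises on animals without a
    body-water record or stages without a design.
    """
    required = {"peptide", "protein_accession", "animal_id", "limb", "stage"}
    missing = required - set(isotopomers.columns)
    if missing:
        raise ValueError(f"isotopomer table missing columns: {sorted(missing)}")
    m_cols = [f"M{i}" for i in range(k_window)]
    if not set(m_cols) <= set(isotopomers.columns):
        raise ValueError(f"isotopomer table missing abundance columns {m_cols}")

    env = isotopomers[m_cols].to_numpy(float)
    env = env / env.sum(axis=1, keepdims=True)

    baseline_cache: dict[str, float] = {}
    asymptote_cache: dict[tuple[str, str], float] = {}

    rows = []
    for idx, rec in enumerate(isotopomers.itertuples(index=False)):
        pep = peptides.get(rec.peptide)
        if pep is None:
            raise ValueError(f"no PeptideSpec for peptide {rec.peptide!r}")
        if rec.animal_id not in body_water:
            raise ValueError(f"missing body-water enrichment for animal {rec.animal_id!r}")
        if rec.stage not in stages:
            raise ValueError(f"no stage design for stage {rec.stage!r}")
        p = body_water[rec.animal_id]
        if rec.peptide not in baseline_cache:
            baseline_cache[rec.peptide] = float(natural_distribution(pep.formula, k_window)[0])
        key = (rec.peptide, rec.animal_id)
        if key not in asymptote_cache:
            asymptote_cache[key] = float(
                labeled_distribution(pep.formula, pep.n_sites, p, k_window)[0]
            )
        m0_base = baseline_cache[rec.peptide]
        m0_asym = asymptote_cache[key]
        f, clamped = fraction_new(env[idx, 0], m0_base, m0_asym, f_cap)
        t = stages[rec.stage].t
        k, fsr, capped = rate_constant(f, t, f_cap)
        rows.append(
            {
                "peptide": rec.peptide,
                "protein_accession": rec.protein_accession,
                "animal_id": rec.animal_id,
                "limb": rec.limb,
                "stage": rec.stage,
                "p": p,
                "t_days": t,
                "f": f,
                "k_per_day": k,
                "fsr_pct_per_day": fsr,
                "fsr_linear_pct_per_day": 100.0 * f / t,
                "clamped": clamped or capped,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RollupResult:
    """Protein-level FSR roll-up with the filter audit trail.

    ``samples`` holds the animal-level means (one row per protein x sample)
    with the peptide-filter verdict, so group comparisons can reuse the same
    filtered values the roll-up saw.
    """

    proteins: pd.DataFrame
    rejects: pd.DataFrame
    samples: pd.DataFrame
    ledger: dict[str, int] = field(default_factory=dict)


def protein_rollup(
    peptide_kinetics: pd.DataFrame,
    min_peptides: int = 2,
    min_animals: int = 2,
) -> RollupResult:
    """Roll peptide FSRs up to proteins with the study's two filters.

    Within each sample (animal x limb x stage) a protein needs at least
    ``min_peptides`` peptide isotope measurements; its animal-level FSR is
    the unweighted mean of those peptide FSRs.  Within each group
    (protein x stage x limb) at least ``min_animals`` animal-level values are
    required.  Groups failing either rule land in the rejects table with the
    failed rule; the ledger satisfies
    ``proteins_in == compared + excluded_peptide_filter + excluded_animal_filter``.
    """
    per_sample = (
        peptide_kinetics.groupby(
            ["protein_accession", "stage", "limb", "animal_id"], sort=True
        )
        .agg(
            n_peptide_measurements=("fsr_pct_per_day", "size"),
            fsr_pct_per_day=("fsr_pct_per_day", "mean"),
        )
        .reset_index()
    )
    per_sample["passes_peptide_filter"] = (
        per_sample["n_peptide_measurements"] >= min_peptides
    )

    protein_rows, reject_rows = [], []
    n_compared = n_excl_pep = n_excl_animal = 0
    for (acc, stage, limb), grp in per_sample.groupby(
        ["protein_accession", "stage", "limb"], sort=True
    ):
        passing = grp[grp["passes_peptide_filter"]]
        if passing.empty:
            n_excl_pep += 1
            reject_rows.append(
                {
                    "protein_accession": acc,
                    "stage": stage,
                    "limb": limb,
                    "rule": f"<{min_peptides} peptide measurements",
                    "n_animals": int(grp["animal_id"].nunique()),
                    "n_peptide_measurements": int(grp["n_peptide_measurements"].sum()),
                }
            )
            continue
        n_animals = int(passing["animal_id"].nunique())
        if n_animals < min_animals:
            n_excl_animal += 1
            reject_rows.append(
                {
                    "protein_accession": acc,
                    "stage": stage,
                    "limb": limb,
                    "rule": f"<{min_animals} animals",
                    "n_animals": n_animals,
                    "n_peptide_measurements": int(passing["n_peptide_measurements"].sum()),
                }
            )
            continue
        n_compared += 1
        vals = passing["fsr_pct_per_day"].to_numpy(float)
        protein_rows.append(
            {
                "protein_accession": acc,
                "stage": stage,
                "limb": limb,
                "mean_fsr_pct_per_day": float(vals.mean()),
                "sd_fsr_pct_per_day": float(vals.std(ddof=1)),
                "n_animals": n_animals,
                "n_peptide_measurements": int(passing["n_peptide_measurements"].sum()),
            }
        )

    proteins = pd.DataFrame(
        protein_rows,
        columns=[
            "protein_accession",
            "stage",
            "limb",
            "mean_fsr_pct_per_day",
            "sd_fsr_pct_per_day",
            "n_animals",
            "n_peptide_measurements",
        ],
    )
    rejects = pd.DataFrame(
        reject_rows,
        columns=[
            "protein_accession",
            "stage",
            "limb",
            "rule",
            "n_animals",
            "n_peptide_measurements",
        ],
    )
    ledger = {
        "proteins_in": n_compared + n_excl_pep + n_excl_animal,
        "compared": n_compared,
        "excluded_peptide_filter": n_excl_pep,
        "excluded_animal_filter": n_excl_animal,
    }
    return RollupResult(
        proteins=proteins, rejects=rejects, samples=per_sample, ledger=ledger
    )
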