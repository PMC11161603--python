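"""Peptide elemental composition and natural-abundance mass isotopomer envelopes.

A tryptic peptide's isotope envelope (M0, M1, M2, ...) is the probability
distribution of its aggregate nominal mass shift, obtained by convolving the
per-element multinomial isotope distributions.  The instrument workflow this
package models extracts only the first four isotopomers (M0-M3), so envelopes
are truncated to a configurable window ``K`` and renormalized within it.

Mass-shift aggregation is by integer nominal shift; fine structure within one
isotopomer is summed, which is adequate for unit-resolution envelope fractions.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "ElementalFormula",
    "WATER",
    "isotope_table",
    "amino_acid_table",
    "peptide_formula",
    "natural_distribution",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping[str, int]):
    """Immutable element -> count mapping with formula arithmetic.

    Counts are non-negative integers; zero counts are dropped.  Supports
    ``+`` and ``-`` (subtraction rejects negative results) so that peptide
    condensation (``A + B - WATER``) is expressible directly.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kwargs:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n > 0}

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse e.g. ``"C2H5NO2"`` (Hill-style, no parentheses)."""
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def get(self, el: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(el, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
        return ElementalFormula(out)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def total_atoms(self) -> int:
        return sum(self._counts.values())

    def __repr__(self) -> str:
        body = "".join(f"{el}{n if n > 1 else ''}" for el, n in self._counts.items())
        return f"ElementalFormula({body or 'empty'})"


WATER = ElementalFormula(H=2, O=1)


def _load_data(name: str) -> dict:
    with resources.files("fluxprot.data").joinpath(name).open("r") as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def isotope_table() -> dict[str, tuple[tuple[int, float], ...]]:
    """Natural-abundance table: element -> ((mass shift, fraction), ...).

    Loaded from the package's versioned data file; abundances for each
    element sum to 1 within 1e-9.
    """
    raw = _load_data("isotope_abundances.json")["elements"]
    table = {el: tuple((int(s), float(a)) for s, a in pairs) for el, pairs in raw.items()}
    for el, pairs in table.items():
        total = sum(a for _, a in pairs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances for {el} sum to {total}, not 1")
    return table


@lru_cache(maxsize=1)
def amino_acid_table() -> tuple[dict[str, ElementalFormula], dict[str, tuple[str, ElementalFormula]]]:
    """(residue formulas, fixed modifications) for the 20 canonical residues.

    Each modification maps name -> (target residue letter, delta formula);
    carbamidomethylation of Cys (+C2H3NO, from iodoacetamide alkylation)
    is the only fixed modification in the default workflow.
    """
    raw = _load_data("amino_acids.json")
    residues = {aa: ElementalFormula(counts) for aa, counts in raw["residues"].items()}
    mods = {
        name: (spec["target"], ElementalFormula(spec["delta"]))
        for name, spec in raw["modifications"].items()
    }
    return residues, mods


def peptide_formula(
    sequence: str,
    mods: Iterable[str] = (),
) -> ElementalFormula:
    """Elemental formula of a free peptide: residue sum + one H2O + mod deltas.

    Parameters
    ----------
    sequence:
        Residue string in one-letter code; must be non-empty and contain only
        canonical residues.
    mods:
        Names of fixed modifications to apply (e.g. ``["carbamidomethyl"]``);
        each modification's delta is added once per occurrence of its target
        residue.  Variable modifications are not supported.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    residues, known_mods = amino_acid_table()
    counts: dict[str, int] = {"H": 2, "O": 1}
    for ch in sequence:
        try:
            res = residues[ch]
        except KeyError:
            raise ValueError(f"unknown residue letter {ch!r} in sequence {sequence!r}") from None
        for el, n in res.items():
            counts[el] = counts.get(el, 0) + n
    for mod in mods:
        try:
            target, delta = known_mods[mod]
        except KeyError:
            raise ValueError(f"unknown fixed modification {mod!r}") from None
        times = sequence.count(target)
        for el, n in delta.items():
            counts[el] = counts.get(el, 0) + n * times
    return ElementalFormula(counts)


def _convolve_trunc(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    # lower K coefficients of a convolution are exact under truncation
    return np.convolve(a, b)[:k]


def _poly_power_trunc(base: np.ndarray, count: int, k: int) -> np.ndarray:
    out = np.zeros(k)
    out[0] = 1.0
    acc = base[:k].copy()
    while count:
        if count & 1:
            out = _convolve_trunc(out, acc, k)
        count >>= 1
        if count:
            acc = _convolve_trunc(acc, acc, k)
    return out


def element_shift_poly(element: str, k: int) -> np.ndarray:
    """Single-atom mass-shift distribution for ``element``, truncated to ``k``."""
    poly = np.zeros(k)
    for shift, ab in isotope_table()[element]:
        if shift < k:
            poly[shift] += ab
    return poly


@lru_cache(maxsize=4096)
def _element_envelope(element: str, count: int, k: int) -> tuple[float, ...]:
    return tuple(_poly_power_trunc(element_shift_poly(element, k), count, k))


def natural_distribution(
    formula: ElementalFormula | Mapping[str, int],
    k: int = 4,
    renormalize: bool = True,
) -> np.ndarray:
    """Natural-abundance envelope M0..M(k-1) by exact truncated convolution.

    With ``renormalize=True`` (default) the first ``k`` isotopomer
    probabilities are rescaled to sum to 1 over the extracted window, matching
    an M0-M3 extraction; with ``renormalize=False`` the raw probabilities of
    aggregate shift 0..k-1 are returned (their sum is < 1 for any non-empty
    formula).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    env = np.zeros(k)
    env[0] = 1.0
    for el, count in formula.items():
        if el not in isotope_table():
            raise ValueError(f"no isotope data for element {el!r}")
        env = _convolve_trunc(env, np.asarray(_element_envelope(el, count, k)), k)
    if renormalize:
        env = env / env.sum()
    return env
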