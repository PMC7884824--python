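"""Molecular-formula arithmetic, adduct m/z computation and MS annotation.

Covers the MS1 stage (matching measured peaks against a compound library at a
ppm tolerance, using a configurable set of adduct rules) and the MS2 stage
(assigning neutral losses such as CO, CO2 or H2O to precursor/fragment pairs).
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "AdductRule",
    "Peak",
    "CompoundRecord",
    "MassAnnotation",
    "FragmentAnnotation",
    "NEGATIVE_ADDUCTS",
    "POSITIVE_ADDUCTS",
    "DEFAULT_ADDUCTS",
    "DEFAULT_LOSSES",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_peaks",
    "annotate_neutral_losses",
    "read_peak_table",
    "read_compound_library",
    "write_annotations",
]

#: Monoisotopic atomic masses (Da), CODATA/NIST.  Carbon-12 is exact by
#: definition of the dalton.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "S": 31.97207100,
    "P": 30.97376163,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.00727646688  # H minus one electron

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element-symbol -> count mapping with Hill-order serialization."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts or all(c == 0 for c in counts.values()):
            raise ValueError("formula must contain at least one atom")
        for sym, n in counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"element count must be a positive integer: {sym}={n!r}")
        object.__setattr__(self, "counts", counts)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then other elements alphabetically."""
        counts = dict(self.counts)
        parts = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(s for s in counts if s not in ("C", "H"))
        else:
            order = sorted(counts)
        for sym in order:
            n = counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string like ``"C4H6O5"``.

    Underscores and whitespace are ignored so formulas copied from formatted
    tables (``C_4_H_6_O_5_``) parse as well.  Repeated symbols accumulate.
    """
    cleaned = text.replace("_", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"zero count for element {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(cleaned):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass (Da): sum of count x most-abundant-isotope mass."""
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in f.counts.items())


@dataclass(frozen=True)
class AdductRule:
    """A charged-species rule: observed m/z = (M + mass_shift) / charge."""

    name: str
    polarity: str  # "pos" | "neg"
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos' or 'neg': {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge magnitude must be >= 1")


def _neutral_mass(formula: str) -> float:
    return monoisotopic_mass(parse_formula(formula))


# Proton-transfer convention with electron-mass correction: [M+H]+ gains a
# proton (H minus an electron), [M-H]- loses one, [M]+ loses an electron,
# anion attachments add the deprotonated-acid mass.
NEGATIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M-H]-", "neg", -PROTON_MASS),
    AdductRule("[M+HCOO]-", "neg", _neutral_mass("CH2O2") - PROTON_MASS),
    AdductRule("[M+CH3COO]-", "neg", _neutral_mass("C2H4O2") - PROTON_MASS),
)

POSITIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", "pos", PROTON_MASS),
    AdductRule("[M+Na]+", "pos", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS),
    AdductRule("[M]+", "pos", -ELECTRON_MASS),
)

DEFAULT_ADDUCTS: tuple[AdductRule, ...] = NEGATIVE_ADDUCTS + POSITIVE_ADDUCTS

ADDUCTS_BY_NAME: Mapping[str, AdductRule] = {r.name: r for r in DEFAULT_ADDUCTS}


def adduct_mz(f: MolecularFormula, rule: AdductRule) -> float:
    """Theoretical m/z of formula ``f`` ionized under ``rule``."""
    return (monoisotopic_mass(f) + rule.mass_shift) / rule.charge


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative deviation, (measured - theoretical)/theoretical x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Peak:
    rt_min: float
    mz: float
    polarity: str  # "pos" | "neg"
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos' or 'neg': {self.polarity!r}")

    def in_scan_range(self, lo: float = 50.0, hi: float = 1500.0) -> bool:
        return lo <= self.mz <= hi


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    formula: MolecularFormula
    source: str = ""


@dataclass(frozen=True)
class MassAnnotation:
    peak: Peak
    compound_id: str
    adduct: str
    theoretical_mz: float
    ppm: float


def annotate_peaks(
    peaks: Sequence[Peak],
    library: Sequence[CompoundRecord],
    rules: Sequence[AdductRule] = DEFAULT_ADDUCTS,
    tol: float = 10.0,
    scan_range: Optional[tuple[float, float]] = None,
) -> list[MassAnnotation]:
    """Match peaks against a compound library under a set of adduct rules.

    Returns every (peak, compound, adduct) triple whose adduct polarity equals
    the peak polarity and whose |ppm error| <= ``tol``.  Candidates for each
    peak are sorted by |ppm error| ascending; peaks keep input order.

    ``scan_range`` optionally drops peaks outside an (lo, hi) m/z window
    before matching (off by default).
    """
    if tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not rules:
        raise ValueError("adduct rule set is empty")
    if not library:
        warnings.warn("empty compound library: no annotations possible")
        return []

    # theoretical m/z precomputed once per (compound, rule)
    theo = [
        (comp.id, rule, adduct_mz(comp.formula, rule))
        for comp in library
        for rule in rules
    ]
    out: list[MassAnnotation] = []
    for peak in peaks:
        if scan_range is not None and not peak.in_scan_range(*scan_range):
            continue
        cands = []
        for comp_id, rule, mz in theo:
            if rule.polarity != peak.polarity:
                continue
            err = ppm_error(peak.mz, mz)
            if abs(err) <= tol:
                cands.append(MassAnnotation(peak, comp_id, rule.name, mz, err))
        cands.sort(key=lambda a: abs(a.ppm))
        out.extend(cands)
    return out


#: Named neutral losses (Da), monoisotopic.
DEFAULT_LOSSES: Mapping[str, float] = {
    "H2O": _neutral_mass("H2O"),
    "CO": _neutral_mass("CO"),
    "CO2": _neutral_mass("CO2"),
    "NH3": _neutral_mass("NH3"),
}


@dataclass(frozen=True)
class FragmentAnnotation:
    precursor_mz: float
    fragment_mz: float
    nominal_loss: int
    exact_loss: float
    loss_name: Optional[str] = None

    @property
    def matched(self) -> bool:
        return self.loss_name is not None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _combo_name(combo: Sequence[str]) -> str:
    # collapse repeats: ("CO", "CO") -> "2CO"; mixed -> "CO+H2O"
    counts: dict[str, int] = {}
    for name in combo:
        counts[name] = counts.get(name, 0) + 1
    parts = [
        name if n == 1 else f"{n}{name}"
        for name, n in sorted(counts.items())
    ]
    return "+".join(parts)


def annotate_neutral_losses(
    precursor: float,
    fragments: Iterable[float],
    losses: Optional[Mapping[str, float]] = None,
    max_combo: int = 3,
    tol: float = 0.01,
) -> list[FragmentAnnotation]:
    """Assign named neutral losses to precursor -> fragment transitions.

    Each fragment gets its nominal integer loss (round half away from zero)
    and, when a combination of up to ``max_combo`` named losses matches, the
    composite loss name.  Unmatched fragments are flagged, never dropped.

    Exact losses are matched within ``tol`` Da.  When the computed loss is
    exactly integral — i.e. the caller passed nominal (unit-resolution) m/z
    values, as printed in MS2 columns — matching falls back to comparing the
    rounded nominal mass of each loss combination, since sub-dalton agreement
    is unobservable at that input precision.
    """
    if losses is None:
        losses = DEFAULT_LOSSES
    combos: list[tuple[float, str, int]] = []
    for size in range(1, max_combo + 1):
        for combo in combinations_with_replacement(sorted(losses), size):
            mass = sum(losses[name] for name in combo)
            combos.append((mass, _combo_name(combo), size))

    out: list[FragmentAnnotation] = []
    for frag in fragments:
        if frag > precursor:
            raise ValueError(
                f"fragment m/z {frag} exceeds precursor m/z {precursor}"
            )
        exact = precursor - frag
        nominal = _round_half_away(exact)
        integral = abs(exact - round(exact)) < 1e-9
        best: Optional[tuple[float, int, str]] = None
        for mass, name, size in combos:
            if integral:
                if _round_half_away(mass) != nominal:
                    continue
                diff = abs(mass - exact)
            else:
                diff = abs(mass - exact)
                if diff > tol:
                    continue
            key = (diff, size, name)
            if best is None or key < best:
                best = key
        out.append(
            FragmentAnnotation(
                precursor_mz=precursor,
                fragment_mz=frag,
                nominal_loss=nominal,
                exact_loss=exact,
                loss_name=best[2] if best else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# File formats

def _data_rows(path, **kwargs):
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return csv.DictReader(lines, **kwargs)


def read_peak_table(path) -> list[Peak]:
    """Read a peak table CSV with columns rt_min, mz, polarity[, intensity]."""
    peaks = []
    for row in _data_rows(path):
        intensity = row.get("intensity")
        peaks.append(
            Peak(
                rt_min=float(row["rt_min"]),
                mz=float(row["mz"]),
                polarity=row["polarity"],
                intensity=float(intensity) if intensity not in (None, "") else None,
            )
        )
    return peaks


def read_compound_library(path) -> list[CompoundRecord]:
    """Read a compound library TSV with columns id, name, formula[, source]."""
    lib = []
    for row in _data_rows(path, delimiter="\t"):
        lib.append(
            CompoundRecord(
                id=row["id"],
                name=row["name"],
                formula=parse_formula(row["formula"]),
                source=row.get("source", "") or "",
            )
        )
    return lib


def write_annotations(annotations: Sequence[MassAnnotation], path, header_comment: str = "") -> None:
    """Write annotations as TSV (m/z to 6 decimal places)."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["rt_min", "mz", "polarity", "compound_id", "adduct", "theoretical_mz", "ppm_error"]
        )
        for a in annotations:
            w.writerow(
                [
                    a.peak.rt_min,
                    f"{a.peak.mz:.6f}",
                    a.peak.polarity,
                    a.compound_id,
                    a.adduct,
                    f"{a.theoretical_mz:.6f}",
                    f"{a.ppm:.4f}",
                ]
            )
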