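"""Relative lipid quantification against class-specific internal standards.

Species are identified by sum composition ("PC 38:4" = phosphatidylcholine,
38 acyl carbons, 4 double bonds); sn-resolved labels ("PC 16:0/20:4") are
accepted and collapsed to their sum composition, bare acyl labels ("20:4" =
arachidonate) parse with no class. Quantification is semi-quantitative: each
species' signal is divided by the intensity of its lipid class' internal
standard, class totals are sums of those ratios, and phosphatidylcholine
(PC) composition is expressed as percent of total PC. The PUFA fraction is
the share of PC species with more than ``db_threshold`` (default 2) double
bonds — the polyunsaturated pool.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

#: closed set of supported lipid classes
LIPID_CLASSES = frozenset(
    {"PC", "LPC", "PE", "PS", "PI", "PG", "SM", "CL", "DAG", "TAG", "CE"}
)

_SUM = re.compile(r"^(?:(?P<cls>[A-Z]+)\s+)?(?P<c>\d+):(?P<d>\d+)$")
_SN = re.compile(
    r"^(?P<cls>[A-Z]+)\s+(?P<c1>\d+):(?P<d1>\d+)/(?P<c2>\d+):(?P<d2>\d+)$"
)
_ETHER = re.compile(r"^[A-Z]+\s+[OP]-")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition resolution; ``lipid_class`` is None for a
    bare fatty acyl."""

    lipid_class: str | None
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.lipid_class is not None and self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double bonds must be non-negative")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double bonds ({self.double_bonds}) exceed carbons ({self.carbons})"
            )

    def __str__(self) -> str:
        comp = f"{self.carbons}:{self.double_bonds}"
        return comp if self.lipid_class is None else f"{self.lipid_class} {comp}"


@dataclass(frozen=True)
class SpeciesQuant:
    """Signal intensity of one species with its class internal-standard
    intensity from the same sample."""

    species: LipidSpecies
    intensity: float
    standard_intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("species intensity must be non-negative")
        if self.standard_intensity <= 0:
            raise ValueError("internal-standard intensity must be positive")


def parse_species_label(label: str) -> LipidSpecies:
    """Parse "CLASS C:D", sn-resolved "CLASS C1:D1/C2:D2" or bare "C:D".

    Ether/plasmalogen shorthand (O-/P- prefixes) is outside the grammar and
    rejected.
    """
    label = label.strip()
    if _ETHER.match(label):
        raise ValueError(f"ether/plasmalogen species not supported: {label!r}")
    m = _SN.match(label)
    if m:
        return LipidSpecies(
            m["cls"], int(m["c1"]) + int(m["c2"]), int(m["d1"]) + int(m["d2"])
        )
    m = _SUM.match(label)
    if not m:
        raise ValueError(f"malformed lipid species label: {label!r}")
    return LipidSpecies(m["cls"], int(m["c"]), int(m["d"]))


def ratio_to_internal_standard(quant: SpeciesQuant) -> float:
    """Species signal relative to its class internal standard."""
    return quant.intensity / quant.standard_intensity


def class_totals(quants) -> dict[str, float]:
    """Per-class sum of species/standard ratios (relative class abundance)."""
    totals: dict[str, float] = defaultdict(float)
    for q in quants:
        if q.species.lipid_class is None:
            raise ValueError(f"species {q.species} carries no lipid class")
        totals[q.species.lipid_class] += ratio_to_internal_standard(q)
    return dict(totals)


def _pc_only(quants) -> list[SpeciesQuant]:
    pc = [q for q in quants if q.species.lipid_class == "PC"]
    if not pc:
        raise ValueError("no PC species in input")
    return pc


def pc_composition_percent(quants) -> dict[LipidSpecies, float]:
    """Each PC species' share of total PC, in percent (sums to 100)."""
    pc = _pc_only(quants)
    ratios: dict[LipidSpecies, float] = defaultdict(float)
    for q in pc:
        ratios[q.species] += ratio_to_internal_standard(q)
    total = sum(ratios.values())
    if total <= 0:
        raise ValueError("total PC signal is zero")
    return {sp: r / total * 100.0 for sp, r in ratios.items()}


def pufa_fraction(quants, db_threshold: int = 2) -> float:
    """Percent of total PC carried by species with > ``db_threshold`` double
    bonds (the PUFA-containing pool)."""
    shares = pc_composition_percent(quants)
    return sum(pct for sp, pct in shares.items() if sp.double_bonds > db_threshold)


# -- tabular I/O -----------------------------------------------------------


def read_quant_tables(quants_path, standards_path) -> dict[str, list[SpeciesQuant]]:
    """Join a species table (label, intensity, sample_id) with a standards
    table (lipid_class, intensity, sample_id) into per-sample quant lists.

    A class whose internal standard is absent for a sample fails only the
    species of that class (raised per sample on access)."""
    species = pd.read_csv(quants_path, sep="\t")
    standards = pd.read_csv(standards_path, sep="\t")
    std_lookup = {
        (r.sample_id, r.lipid_class): float(r.intensity)
        for r in standards.itertuples(index=False)
    }
    out: dict[str, list[SpeciesQuant]] = defaultdict(list)
    for r in species.itertuples(index=False):
        sp = parse_species_label(r.label)
        key = (r.sample_id, sp.lipid_class)
        if key not in std_lookup:
            raise ValueError(
                f"no internal standard for class {sp.lipid_class!r} in sample "
                f"{r.sample_id!r}"
            )
        out[r.sample_id].append(SpeciesQuant(sp, float(r.intensity), std_lookup[key]))
    return dict(out)


def composition_frame(quants) -> pd.DataFrame:
    """PC composition of one sample as a tidy table."""
    shares = pc_composition_percent(quants)
    rows = sorted(
        ((str(sp), sp.carbons, sp.double_bonds, pct) for sp, pct in shares.items()),
        key=lambda r: (r[1], r[2]),
    )
    return pd.DataFrame(rows, columns=["species", "carbons", "double_bonds", "pct_of_total_pc"])
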