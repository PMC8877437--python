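"""Mass-delta biotransformation rules and parent-mass dereplication.

A biotransformation rule is a named, signed monoisotopic mass difference
applied on the m/z axis (substrate -> product).  All arithmetic assumes a
uniform singly protonated [M+H]+ adduct, under which the proton cancels
out of any substrate-product difference, so rule deltas apply directly to
precursor m/z values.

Rule deltas are computed from standard element monoisotopic masses (via
the formula-change string), never typed in as rounded decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pmass

#: Mass of a proton in Da ([M+H]+ = M + PROTON_MASS).
PROTON_MASS = 1.00727646688


def formula_change_mass(formula_change: str) -> float:
    """Signed monoisotopic mass of a gain/loss string such as ``-CO2`` or
    ``+CH2`` (ASCII or Unicode minus), from element monoisotopic masses."""
    s = formula_change.strip().replace("−", "-")
    m = re.fullmatch(r"([+-])\s*([A-Za-z0-9]+)", s)
    if not m:
        raise ValueError(f"cannot parse formula change {formula_change!r}; expected e.g. '+CH2' or '-CO2'")
    sign = 1.0 if m.group(1) == "+" else -1.0
    return sign * _pmass.calculate_mass(formula=m.group(2))


@dataclass(frozen=True)
class BiotransformRule:
    """A named biotransformation as a signed substrate->product mass delta."""

    rule_name: str
    formula_change: str
    mass_delta: float
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.mass_delta == 0:
            raise ValueError(f"rule {self.rule_name!r} has zero mass delta")


_BUILTIN_SPECS = [
    # (name, formula change) — deltas derived from element masses below
    ("decarboxylation", "-CO2"),
    ("dehydroxylation", "-O"),
    ("O-methylation", "+CH2"),
    ("double-bond reduction", "+H2"),
    ("beta-oxidation", "-C2H4"),
    ("glucuronidation", "+C6H8O6"),
]


def builtin_rules() -> list[BiotransformRule]:
    """The built-in rule set covering the common gut-microbial reactions on
    dietary phenolics: decarboxylation (-CO2), dehydroxylation (-O),
    catechol O-methylation (+CH2), alpha,beta double-bond reduction (+H2),
    beta-oxidation of a carboxylic acid side chain (-C2H4) and
    glucuronidation (+C6H8O6)."""
    return [
        BiotransformRule(name, fc, formula_change_mass(fc), source="builtin")
        for name, fc in _BUILTIN_SPECS
    ]


def read_rules(path: str | Path, source: str = "user") -> list[BiotransformRule]:
    """Read a rule table CSV with columns rule_name, formula_change,
    mass_delta (mass_delta recomputed from formula_change when parseable)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        fc = str(row["formula_change"])
        try:
            delta = formula_change_mass(fc)
        except ValueError:
            delta = float(row["mass_delta"])
        out.append(BiotransformRule(str(row["rule_name"]), fc, delta, source=source))
    names = [r.rule_name for r in out]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate rule names in {path}")
    return out


def write_rules(rules: Iterable[BiotransformRule], path: str | Path) -> None:
    pd.DataFrame(
        [(r.rule_name, r.formula_change, r.mass_delta) for r in rules],
        columns=["rule_name", "formula_change", "mass_delta"],
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class CompoundRecord:
    """A reference compound with its neutral monoisotopic mass."""

    compound_name: str
    monoisotopic_mass: float
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"nonpositive mass for compound {self.compound_name!r}")

    @property
    def adduct_mz(self) -> float:
        """[M+H]+ m/z."""
        return self.monoisotopic_mass + PROTON_MASS


def read_compound_db(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        smiles = row.get("smiles")
        if smiles is not None and (pd.isna(smiles) or str(smiles) == ""):
            smiles = None
        out.append(CompoundRecord(str(row["compound_name"]), float(row["monoisotopic_mass"]),
                                  smiles=None if smiles is None else str(smiles)))
    return out


def write_compound_db(db: Iterable[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(c.compound_name, c.monoisotopic_mass, c.smiles or "") for c in db],
        columns=["compound_name", "monoisotopic_mass", "smiles"],
    ).to_csv(path, index=False)


@dataclass
class SubstrateAnnotation:
    """A database hit for a molecular-network node's precursor mass."""

    node_id: str
    compound: CompoundRecord
    mass_error: float
    match_level: str = "parent_mass_only"


def predict_product_mzs(
    substrate_mz: float, rules: Sequence[BiotransformRule]
) -> list[tuple[BiotransformRule, float]]:
    """Predicted product m/z for each rule applied to a substrate m/z;
    candidates with nonpositive product m/z are dropped."""
    out = []
    for r in rules:
        product = substrate_mz + r.mass_delta
        if product > 0:
            out.append((r, product))
    return out


def match_rule(
    substrate_mz: float,
    product_mz: float,
    rules: Sequence[BiotransformRule],
    tol: float = 0.02,
) -> list[tuple[BiotransformRule, float]]:
    """Rules whose mass delta explains product - substrate within ``tol``
    Da, as (rule, signed mass error) sorted by absolute error."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    observed = product_mz - substrate_mz
    hits = [(r, observed - r.mass_delta) for r in rules if abs(observed - r.mass_delta) <= tol]
    hits.sort(key=lambda h: (abs(h[1]), h[0].rule_name))
    return hits


def dereplicate_substrate(
    node, db: Sequence[CompoundRecord], parent_tol: float = 0.002
) -> list[SubstrateAnnotation]:
    """Parent-mass dereplication of a molecular-network node against a
    compound database.

    Every compound whose [M+H]+ m/z lies within ``parent_tol`` of the
    node's precursor is returned, sorted by absolute mass error.  Below a
    precursor of 200 Da only parent-mass evidence is available, so the
    match level is always ``parent_mass_only`` there; no in-silico
    fragmentation is attempted at higher masses either, and the match
    level records that.
    """
    if parent_tol <= 0:
        raise ValueError("parent_tol must be positive")
    prec = float(node.precursor_mz)
    hits = []
    for c in db:
        err = prec - c.adduct_mz
        if abs(err) <= parent_tol:
            hits.append(SubstrateAnnotation(
                node_id=str(getattr(node, "node_id", "")),
                compound=c,
                mass_error=err,
                match_level="parent_mass_only",
            ))
    hits.sort(key=lambda a: (abs(a.mass_error), a.compound.compound_name))
    return hits
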