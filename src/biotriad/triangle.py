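"""Golden-triangle extraction: integrating the three evidence layers.

A golden triangle is a triplet (microbial feature, substrate node,
product node) where the microbe is negatively correlated with the
substrate, positively correlated with the product, and the substrate and
product are neighbours in the molecular network.  A relaxed "same sign"
mode additionally admits triangles where both correlations share a sign,
which occurs for reactions where more substrate also means more product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from biotriad.association import AssociationEdge
from biotriad.molnet import MolecularNetwork, NetworkEdge
from biotriad.rules import (
    BiotransformRule,
    CompoundRecord,
    SubstrateAnnotation,
    dereplicate_substrate,
    match_rule,
)

logger = logging.getLogger(__name__)

MODES = ("canonical", "same_sign")


@dataclass
class GoldenTriangle:
    """One candidate biotransformation."""

    microbial_feature_id: str
    substrate_node_id: str
    product_node_id: str
    rho_s: float
    p_s: float
    rho_p: float
    p_p: float
    edge_cosine: float
    substrate_mz: float
    product_mz: float
    mass_delta: float
    matched_rules: list[tuple[str, float]] = field(default_factory=list)
    substrate_annotations: list[SubstrateAnnotation] = field(default_factory=list)
    mode: str = "canonical"
    gut_unique_product: bool = False

    @property
    def rule_unmatched(self) -> bool:
        return not self.matched_rules

    @property
    def strength(self) -> float:
        return max(abs(self.rho_s), abs(self.rho_p))


@dataclass
class _NodeStub:
    node_id: str
    precursor_mz: float


def _orient(
    edge: NetworkEdge,
    rho_u: float,
    rho_v: float,
    mz: Mapping[str, float],
    rules: Sequence[BiotransformRule],
    tol: float,
    mode: str,
    annotated: set[str],
) -> tuple[str, str] | None:
    """Pick (substrate, product) orientation for an undirected spectral
    edge, or None when the sign pattern admits no triangle.

    Canonical pattern (rho_s < 0 < rho_p) decides the orientation
    outright.  In same-sign mode ambiguous orientations are resolved by
    which direction a rule explains, then by which endpoint carries a
    compound-database annotation, then by the heavier precursor as
    substrate.
    """
    u, v = edge.node_a, edge.node_b
    if rho_u < 0 < rho_v:
        return u, v
    if rho_v < 0 < rho_u:
        return v, u
    if mode != "same_sign":
        return None
    if rho_u == 0 or rho_v == 0 or (rho_u > 0) != (rho_v > 0):
        return None
    for s, p in ((u, v), (v, u)):
        if match_rule(mz[s], mz[p], rules, tol) and not match_rule(mz[p], mz[s], rules, tol):
            return s, p
    if u in annotated and v not in annotated:
        return u, v
    if v in annotated and u not in annotated:
        return v, u
    return (u, v) if mz[u] >= mz[v] else (v, u)


def find_golden_triangles(
    assoc: Sequence[AssociationEdge],
    net: MolecularNetwork,
    feature_map: Mapping[str, str],
    rules: Sequence[BiotransformRule],
    tol: float = 0.02,
    mode: str = "canonical",
    require_rule: bool = True,
    compound_db: Sequence[CompoundRecord] | None = None,
    annotation_tol: float = 0.002,
) -> list[GoldenTriangle]:
    """Enumerate golden triangles over the three inputs.

    For every molecular-network edge (u, v) and every microbial feature
    correlated (via ``feature_map``) with both endpoints, the triplet is
    emitted when the correlation signs fit the active mode.  When several
    LC-MS features map to one node, the association with the largest
    |rho| represents that (microbe, node) pair.  Triangles whose mass
    delta no rule explains within ``tol`` are dropped when
    ``require_rule`` is set, otherwise retained flagged as unmatched.
    Output is deterministic: sorted by max(|rho_s|, |rho_p|) descending,
    then ids.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    node_index = {n.node_id: n for n in net.nodes}
    mz = {n.node_id: n.precursor_mz for n in net.nodes}

    annotated: set[str] = set()
    if compound_db:
        for n in net.nodes:
            if dereplicate_substrate(n, compound_db, annotation_tol):
                annotated.add(n.node_id)

    # (microbe, node) -> strongest association edge
    best: dict[tuple[str, str], AssociationEdge] = {}
    skipped = 0
    for e in assoc:
        node_id = feature_map.get(e.molecular_feature_id)
        if node_id is None or node_id not in node_index:
            skipped += 1
            continue
        key = (e.microbial_feature_id, node_id)
        cur = best.get(key)
        if cur is None or (abs(e.rho), cur.molecular_feature_id) > (abs(cur.rho), e.molecular_feature_id):
            best[key] = e
    if skipped:
        logger.info("%d association edges referenced unmapped features", skipped)

    microbes_by_node: dict[str, set[str]] = {}
    for (m, node_id) in best:
        microbes_by_node.setdefault(node_id, set()).add(m)

    triangles: list[GoldenTriangle] = []
    for edge in net.edges:
        shared = microbes_by_node.get(edge.node_a, set()) & microbes_by_node.get(edge.node_b, set())
        for m in sorted(shared):
            e_u = best[(m, edge.node_a)]
            e_v = best[(m, edge.node_b)]
            oriented = _orient(edge, e_u.rho, e_v.rho, mz, rules, tol, mode, annotated)
            if oriented is None:
                continue
            s, p = oriented
            e_s = e_u if s == edge.node_a else e_v
            e_p = e_v if s == edge.node_a else e_u
            hits = match_rule(mz[s], mz[p], rules, tol)
            if require_rule and not hits:
                continue
            product_node = node_index[p]
            triangles.append(GoldenTriangle(
                microbial_feature_id=m,
                substrate_node_id=s,
                product_node_id=p,
                rho_s=e_s.rho, p_s=e_s.p_value,
                rho_p=e_p.rho, p_p=e_p.p_value,
                edge_cosine=edge.cosine,
                substrate_mz=mz[s],
                product_mz=mz[p],
                mass_delta=mz[p] - mz[s],
                matched_rules=[(r.rule_name, err) for r, err in hits],
                mode=mode,
                gut_unique_product=product_node.cohort_tags == {"gut"},
            ))
    triangles.sort(key=lambda t: (-t.strength, t.microbial_feature_id,
                                  t.substrate_node_id, t.product_node_id))
    return triangles


def annotate_triangles(
    triangles: Sequence[GoldenTriangle],
    compound_db: Sequence[CompoundRecord],
    parent_tol: float = 0.002,
) -> list[GoldenTriangle]:
    """Fill each triangle's substrate annotations by parent-mass
    dereplication; triangles without a database hit keep an empty list
    (never dropped)."""
    for t in triangles:
        stub = _NodeStub(t.substrate_node_id, t.substrate_mz)
        t.substrate_annotations = dereplicate_substrate(stub, compound_db, parent_tol)
    return list(triangles)


_REPORT_COLUMNS = [
    "substrate_annotation", "rule", "microbial_feature_id",
    "substrate_node_id", "product_node_id",
    "rho_s", "rho_p", "p_s", "p_p", "cosine",
    "substrate_mz", "product_mz", "mass_delta", "rule_mass_error",
    "gut_unique_product", "mode",
]


def report_triangles(triangles: Sequence[GoldenTriangle], out_path: str | Path) -> pd.DataFrame:
    """Write the candidate table as CSV (one row per triangle, header-only
    when empty) and return it as a DataFrame."""
    rows = []
    for t in triangles:
        rows.append({
            "substrate_annotation": ";".join(a.compound.compound_name for a in t.substrate_annotations),
            "rule": ";".join(name for name, _ in t.matched_rules) or "unmatched",
            "microbial_feature_id": t.microbial_feature_id,
            "substrate_node_id": t.substrate_node_id,
            "product_node_id": t.product_node_id,
            "rho_s": t.rho_s, "rho_p": t.rho_p,
            "p_s": t.p_s, "p_p": t.p_p,
            "cosine": t.edge_cosine,
            "substrate_mz": t.substrate_mz,
            "product_mz": t.product_mz,
            "mass_delta": t.mass_delta,
            "rule_mass_error": t.matched_rules[0][1] if t.matched_rules else float("nan"),
            "gut_unique_product": t.gut_unique_product,
            "mode": t.mode,
        })
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(out_path, index=False)
    return df
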