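"""End-to-end orchestration: tables + spectra in, ranked triangles out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from biotriad.association import AssociationEdge, build_association_network
from biotriad.feature_io import CountMatrix, IntensityMatrix, Spectrum, \
    align_samples, filter_rare_features
from biotriad.molnet import MolecularNetwork, build_molecular_network, \
    cluster_spectra, match_features_to_nodes, merge_networks
from biotriad.rules import BiotransformRule, CompoundRecord, builtin_rules
from biotriad.triangle import GoldenTriangle, annotate_triangles, find_golden_triangles


@dataclass
class PipelineResult:
    triangles: list[GoldenTriangle]
    network: MolecularNetwork
    assoc_edges: list[AssociationEdge]
    feature_map: dict[str, str]


def run_pipeline(
    molecules: IntensityMatrix,
    microbes: CountMatrix,
    gut_spectra: Sequence[Spectrum],
    food_spectra: Sequence[Spectrum] | None = None,
    compound_db: Sequence[CompoundRecord] | None = None,
    rules: Sequence[BiotransformRule] | None = None,
    p_threshold: float = 1e-4,
    rho_threshold: float = 0.1,
    cosine_threshold: float = 0.7,
    precursor_tol: float = 0.02,
    fragment_tol: float = 0.02,
    min_matched_peaks: int = 6,
    feature_mass_tol: float = 0.02,
    rule_tol: float = 0.02,
    parent_tol: float = 0.002,
    mode: str = "canonical",
    require_rule: bool = True,
) -> PipelineResult:
    """Run the full discovery pipeline.

    Steps: align samples, drop features present in < 2 samples, cluster
    each cohort's spectra into consensus nodes, build (and, when a food
    cohort is given, merge) the molecular network, map LC-MS features to
    nodes by precursor mass, screen all molecule-microbe pairs with the
    Spearman test, extract golden triangles, and dereplicate substrates
    against the compound database.
    """
    if rules is None:
        rules = builtin_rules()
    molecules, microbes = align_samples(molecules, microbes)
    molecules = filter_rare_features(molecules)

    gut_nodes = cluster_spectra(gut_spectra, precursor_tol=precursor_tol,
                                fragment_tol=fragment_tol, node_prefix="gut")
    gut_net = build_molecular_network(gut_nodes, cosine_threshold=cosine_threshold,
                                      fragment_tol=fragment_tol,
                                      min_matched_peaks=min_matched_peaks)
    if food_spectra:
        food_nodes = cluster_spectra(food_spectra, precursor_tol=precursor_tol,
                                     fragment_tol=fragment_tol, node_prefix="food")
        food_net = build_molecular_network(food_nodes, cosine_threshold=cosine_threshold,
                                           fragment_tol=fragment_tol,
                                           min_matched_peaks=min_matched_peaks)
        net = merge_networks(gut_net, food_net, mass_tol=precursor_tol,
                             fragment_tol=fragment_tol,
                             cosine_threshold=cosine_threshold,
                             min_matched_peaks=min_matched_peaks)
    else:
        net = gut_net

    feature_map = match_features_to_nodes(molecules, net, mass_tol=feature_mass_tol)
    assoc = build_association_network(molecules, microbes,
                                      p_threshold=p_threshold,
                                      rho_threshold=rho_threshold)
    triangles = find_golden_triangles(assoc, net, feature_map, rules,
                                      tol=rule_tol, mode=mode,
                                      require_rule=require_rule,
                                      compound_db=compound_db,
                                      annotation_tol=parent_tol)
    if compound_db:
        triangles = annotate_triangles(triangles, compound_db, parent_tol=parent_tol)
    return PipelineResult(triangles=triangles, network=net,
                          assoc_edges=assoc, feature_map=feature_map)
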