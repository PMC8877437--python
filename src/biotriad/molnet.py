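"""Molecular networking: consensus clustering and modified-cosine edges.

Spectra are first clustered into consensus nodes (near-identical scans of
the same molecule merged), then node pairs are scored with the
modification-tolerant (modified) cosine: fragment peaks may match either
directly or shifted by the precursor mass difference, so a substrate and
its single-site modification product still score highly.  Node pairs
scoring at or above the cosine threshold with enough matched peaks become
network edges.  Precursor differences are interpreted on the m/z axis
under a uniform singly charged [M+H]+ assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.optimize import linear_sum_assignment

from biotriad.feature_io import IntensityMatrix, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class ConsensusNode:
    """A cluster of merged spectra acting as one molecular-network node."""

    node_id: str
    precursor_mz: float
    representative_peaks: np.ndarray
    member_ids: list[str]
    cohort_tags: set[str] = field(default_factory=set)
    mapped_feature_id: str | None = None

    @property
    def representative(self) -> Spectrum:
        return Spectrum(
            spectrum_id=self.node_id,
            precursor_mz=self.precursor_mz,
            peaks=self.representative_peaks,
            cohort_tag="|".join(sorted(self.cohort_tags)),
        )

    @property
    def cohort_label(self) -> str:
        """'intersection' if members span both cohorts, else '<tag>-unique'."""
        if len(self.cohort_tags) > 1:
            return "intersection"
        if self.cohort_tags:
            return f"{next(iter(self.cohort_tags))}-unique"
        return "unknown"


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    mass_delta: float


@dataclass
class MolecularNetwork:
    """Undirected spectral-similarity graph over consensus nodes."""

    nodes: list[ConsensusNode]
    edges: list[NetworkEdge]

    def node(self, node_id: str) -> ConsensusNode:
        return self._index[node_id]

    @property
    def _index(self) -> dict[str, ConsensusNode]:
        return {n.node_id: n for n in self.nodes}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, precursor_mz=n.precursor_mz,
                       cohort=n.cohort_label, n_members=len(n.member_ids))
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, cosine=e.cosine,
                       matched_peaks=e.matched_peaks, mass_delta=e.mass_delta)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edges_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(
            [(e.node_a, e.node_b, e.cosine, e.matched_peaks, e.mass_delta) for e in self.edges],
            columns=["node_a", "node_b", "cosine", "matched_peaks", "mass_delta"],
        ).to_csv(path, index=False)


def _unit_sqrt_weights(spectrum: Spectrum, label: str) -> np.ndarray:
    if spectrum.peaks.shape[0] == 0:
        raise ValueError(f"empty peak list in spectrum {label!r}")
    w = np.sqrt(spectrum.intensities)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError(f"all-zero intensities in spectrum {label!r}")
    return w / norm


def _cosine_core(a: Spectrum, b: Spectrum, fragment_tol: float,
                 allow_shift: bool) -> tuple[float, int]:
    """Shared machinery for plain and modified cosine.

    Candidate peak pairs (direct and, optionally, precursor-shifted) are
    scored by the product of unit-normalized sqrt-intensities; a maximum
    total-score one-to-one assignment over candidates gives the score.
    """
    wa = _unit_sqrt_weights(a, a.spectrum_id)
    wb = _unit_sqrt_weights(b, b.spectrum_id)
    mza, mzb = a.mz, b.mz
    shift = a.precursor_mz - b.precursor_mz

    pairs: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()

    def collect(offset: float) -> None:
        # mzb sorted ascending: window lookup per a-peak
        lo = np.searchsorted(mzb, mza - offset - fragment_tol, side="left")
        hi = np.searchsorted(mzb, mza - offset + fragment_tol, side="right")
        for i in range(mza.size):
            for j in range(lo[i], hi[i]):
                if (i, j) not in seen:
                    seen.add((i, j))
                    pairs.append((i, j, wa[i] * wb[j]))

    collect(0.0)
    if allow_shift and shift != 0.0:
        collect(shift)

    if not pairs:
        return 0.0, 0
    rows = {i for i, _, _ in pairs}
    cols = {j for _, j, _ in pairs}
    if len(rows) == len(pairs) and len(cols) == len(pairs):
        # conflict-free: every candidate pair can be taken
        score = sum(s for _, _, s in pairs)
        return float(min(score, 1.0)), sum(1 for _, _, s in pairs if s > 0)
    ri = {i: k for k, i in enumerate(sorted(rows))}
    cj = {j: k for k, j in enumerate(sorted(cols))}
    cost = np.zeros((len(ri), len(cj)))
    for i, j, s in pairs:
        cost[ri[i], cj[j]] = max(cost[ri[i], cj[j]], s)
    r, c = linear_sum_assignment(cost, maximize=True)
    chosen = cost[r, c]
    score = float(chosen.sum())
    matched = int((chosen > 0).sum())
    return min(score, 1.0), matched


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02) -> tuple[float, int]:
    """Modification-tolerant cosine similarity in [0, 1] and the matched
    peak count.  Symmetric; equals the plain cosine when the precursors
    are equal."""
    return _cosine_core(a, b, fragment_tol, allow_shift=True)


def plain_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02) -> tuple[float, int]:
    """Direct (unshifted) cosine similarity and matched peak count."""
    return _cosine_core(a, b, fragment_tol, allow_shift=False)


def _merge_peaks(peak_sets: Sequence[np.ndarray], fragment_tol: float) -> np.ndarray:
    """Intensity-weighted merge of several peak lists, binned at the
    fragment tolerance: consecutive sorted peaks closer than the tolerance
    share a bin; bin m/z is the intensity-weighted mean and bin intensity
    the mean total per member."""
    stacked = np.vstack(peak_sets)
    stacked = stacked[np.argsort(stacked[:, 0], kind="stable")]
    merged: list[tuple[float, float]] = []
    bin_mz: list[float] = []
    bin_int: list[float] = []
    for mz, inten in stacked:
        if bin_mz and mz - bin_mz[-1] > fragment_tol:
            w = np.asarray(bin_int)
            m = np.asarray(bin_mz)
            merged.append((float((m * w).sum() / w.sum()), float(w.sum())))
            bin_mz, bin_int = [], []
        bin_mz.append(float(mz))
        bin_int.append(float(inten))
    if bin_mz:
        w = np.asarray(bin_int)
        m = np.asarray(bin_mz)
        merged.append((float((m * w).sum() / w.sum()), float(w.sum())))
    out = np.asarray(merged)
    out[:, 1] /= len(peak_sets)
    return out


def cluster_spectra(
    spectra: Sequence[Spectrum],
    precursor_tol: float = 0.02,
    merge_cosine: float = 0.95,
    fragment_tol: float = 0.02,
    node_prefix: str = "node",
) -> list[ConsensusNode]:
    """Greedy single-pass consensus clustering.

    Spectra are processed in descending total-intensity order (ties broken
    by spectrum id); each joins the first existing node whose consensus
    precursor lies within ``precursor_tol`` and whose representative
    spectrum scores >= ``merge_cosine`` under the plain cosine, otherwise
    it seeds a new node.  Deterministic; output partitions the input.
    """
    if not spectra:
        raise ValueError("no spectra to cluster")
    order = sorted(spectra, key=lambda s: (-s.total_intensity, s.spectrum_id))
    members: list[list[Spectrum]] = []
    precursors: list[float] = []
    reps: list[np.ndarray] = []
    for s in order:
        placed = False
        for k in range(len(members)):
            if abs(s.precursor_mz - precursors[k]) > precursor_tol:
                continue
            rep = Spectrum("rep", precursors[k], reps[k])
            score, _ = plain_cosine(s, rep, fragment_tol)
            if score >= merge_cosine:
                members[k].append(s)
                precursors[k] = float(np.median([m.precursor_mz for m in members[k]]))
                reps[k] = _merge_peaks([m.peaks for m in members[k]], fragment_tol)
                placed = True
                break
        if not placed:
            members.append([s])
            precursors.append(s.precursor_mz)
            reps.append(s.peaks.copy())
    width = max(4, len(str(len(members))))
    nodes = []
    for k in range(len(members)):
        nodes.append(ConsensusNode(
            node_id=f"{node_prefix}_{k:0{width}d}",
            precursor_mz=precursors[k],
            representative_peaks=reps[k],
            member_ids=[m.spectrum_id for m in members[k]],
            cohort_tags={m.cohort_tag for m in members[k] if m.cohort_tag},
        ))
    return nodes


def build_molecular_network(
    nodes: Sequence[ConsensusNode],
    cosine_threshold: float = 0.7,
    fragment_tol: float = 0.02,
    min_matched_peaks: int = 6,
) -> MolecularNetwork:
    """All-pairs modified-cosine thresholding over consensus nodes.

    An edge (u, v) is present iff modified_cosine >= cosine_threshold and
    the matched peak count >= min_matched_peaks.  No self-loops.
    """
    if not nodes:
        raise ValueError("no nodes")
    nodes = sorted(nodes, key=lambda n: n.node_id)
    edges = []
    reps = [n.representative for n in nodes]
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            score, matched = modified_cosine(reps[i], reps[j], fragment_tol)
            if score >= cosine_threshold and matched >= min_matched_peaks:
                edges.append(NetworkEdge(
                    node_a=nodes[i].node_id,
                    node_b=nodes[j].node_id,
                    cosine=score,
                    matched_peaks=matched,
                    mass_delta=abs(nodes[i].precursor_mz - nodes[j].precursor_mz),
                ))
    return MolecularNetwork(nodes=list(nodes), edges=edges)


def merge_networks(
    gut: MolecularNetwork,
    food: MolecularNetwork,
    mass_tol: float = 0.02,
    fragment_tol: float = 0.02,
    cosine_threshold: float = 0.7,
    min_matched_peaks: int = 6,
    mass_only: bool = False,
) -> MolecularNetwork:
    """Merge two cohort networks into one.

    A gut node and a food node are unified into a single intersection node
    when their precursors agree within ``mass_tol`` and (unless
    ``mass_only``) their representative spectra reach the cosine
    threshold under plain cosine.  Matching is greedy 1:1, best pairs
    first.  Edges are recomputed across the merged node set.
    """
    candidates = []
    for g in gut.nodes:
        for f in food.nodes:
            if abs(g.precursor_mz - f.precursor_mz) > mass_tol:
                continue
            if mass_only:
                score = 1.0
            else:
                score, _ = plain_cosine(g.representative, f.representative, fragment_tol)
                if score < cosine_threshold:
                    continue
            candidates.append((score, -abs(g.precursor_mz - f.precursor_mz),
                               g.node_id, f.node_id))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_g: set[str] = set()
    used_f: set[str] = set()
    matches: dict[str, str] = {}
    for _, _, gid, fid in candidates:
        if gid in used_g or fid in used_f:
            continue
        used_g.add(gid)
        used_f.add(fid)
        matches[gid] = fid

    food_index = {n.node_id: n for n in food.nodes}
    merged_nodes: list[ConsensusNode] = []
    for g in gut.nodes:
        if g.node_id in matches:
            f = food_index[matches[g.node_id]]
            merged_nodes.append(ConsensusNode(
                node_id=g.node_id,
                precursor_mz=float(np.median([g.precursor_mz, f.precursor_mz])),
                representative_peaks=_merge_peaks(
                    [g.representative_peaks, f.representative_peaks], fragment_tol),
                member_ids=g.member_ids + f.member_ids,
                cohort_tags=g.cohort_tags | f.cohort_tags,
            ))
        else:
            merged_nodes.append(g)
    for f in food.nodes:
        if f.node_id not in used_f:
            merged_nodes.append(f)
    logger.info("merged networks: %d intersection nodes, %d total",
                len(matches), len(merged_nodes))
    return build_molecular_network(
        merged_nodes, cosine_threshold=cosine_threshold,
        fragment_tol=fragment_tol, min_matched_peaks=min_matched_peaks)


def match_features_to_nodes(
    m: IntensityMatrix,
    net: MolecularNetwork,
    mass_tol: float = 0.02,
) -> dict[str, str]:
    """Map LC-MS features to molecular-network nodes by precursor mass.

    Each feature maps to the node with the smallest |delta m/z| within
    ``mass_tol`` (ties: larger node member count, then lexicographic node
    id); unmatched features are left out and their count logged.
    """
    if m.feature_mz is None:
        raise ValueError("intensity matrix carries no precursor m/z metadata")
    node_mz = np.array([n.precursor_mz for n in net.nodes])
    mapping: dict[str, str] = {}
    unmatched = 0
    for fid, fmz in zip(m.feature_ids, m.feature_mz):
        d = np.abs(node_mz - fmz)
        within = np.flatnonzero(d <= mass_tol)
        if within.size == 0:
            unmatched += 1
            continue
        best = min(within, key=lambda k: (d[k], -len(net.nodes[k].member_ids),
                                          net.nodes[k].node_id))
        mapping[fid] = net.nodes[best].node_id
    if unmatched:
        logger.info("%d features had no molecular-network node within %.3g Da",
                    unmatched, mass_tol)
    return mapping
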