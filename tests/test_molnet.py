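import numpy as np
import pytest

from biotriad import (
    build_molecular_network,
    cluster_spectra,
    match_features_to_nodes,
    merge_networks,
    modified_cosine,
    plain_cosine,
)
from biotriad.feature_io import IntensityMatrix
from conftest import make_spectrum, oracle_modified_cosine


def _random_spectrum(rng, n_peaks, precursor, sid):
    mzs = np.sort(rng.uniform(60, precursor - 10, size=n_peaks))
    return make_spectrum(mzs, rng.uniform(1, 100, size=n_peaks), precursor, sid)


def test_self_similarity_is_one():
    rng = np.random.default_rng(0)
    for k in range(5):
        s = _random_spectrum(rng, 10, 400.0, f"s{k}")
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 10


def test_disjoint_spectra_score_zero():
    a = make_spectrum([100.0, 110.0], [5.0, 5.0], 300.0)
    b = make_spectrum([150.0, 160.0], [5.0, 5.0], 300.0)
    assert modified_cosine(a, b) == (0.0, 0)


def test_empty_peak_list_is_a_hard_error():
    a = make_spectrum([100.0], [1.0], 200.0)
    b = make_spectrum(np.empty((0,)), np.empty((0,)), 200.0)
    with pytest.raises(ValueError, match="empty"):
        modified_cosine(a, b)


def test_shifted_peaks_match_through_the_precursor_delta():
    """A product spectrum whose fragments all carry the modification still
    reaches cosine 1 against the substrate."""
    a = make_spectrum([100.0, 150.0, 200.0], [1.0, 2.0, 3.0], 300.0)
    b = make_spectrum([114.0, 164.0, 214.0], [1.0, 2.0, 3.0], 314.0)
    score, matched = modified_cosine(a, b)
    assert score == pytest.approx(1.0, abs=1e-12)
    assert matched == 3
    # without the shift the same pair matches nothing
    assert plain_cosine(a, b)[0] == 0.0


def test_modified_cosine_is_symmetric_and_bounded():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = _random_spectrum(rng, 6, 350.0, "a")
        b = _random_spectrum(rng, 6, 364.0, "b")
        sab, mab = modified_cosine(a, b)
        sba, mba = modified_cosine(b, a)
        assert sab == pytest.approx(sba, abs=1e-12)
        assert mab == mba
        assert 0.0 <= sab <= 1.0


def test_equal_precursors_reduce_to_plain_cosine():
    rng = np.random.default_rng(6)
    for _ in range(10):
        a = _random_spectrum(rng, 5, 320.0, "a")
        b = _random_spectrum(rng, 5, 320.0, "b")
        assert modified_cosine(a, b)[0] == pytest.approx(plain_cosine(a, b)[0], abs=1e-12)


def test_score_matches_brute_force_assignment_oracle():
    """On tiny spectra the one-to-one peak assignment must be globally
    optimal: compare against exhaustive search over all assignments,
    including crowded spectra where direct and shifted matches conflict."""
    rng = np.random.default_rng(7)
    for trial in range(40):
        na, nb = rng.integers(2, 7), rng.integers(2, 7)
        # crowded m/z range (span 30) around a small shift forces conflicts
        a = make_spectrum(rng.uniform(100, 130, na), rng.uniform(1, 10, na), 200.0, "a")
        b = make_spectrum(rng.uniform(100, 130, nb), rng.uniform(1, 10, nb),
                          200.0 + rng.choice([0.0, 2.0, 14.0]), "b")
        tol = 5.0 if trial % 2 else 1.0
        got_score, got_matched = modified_cosine(a, b, fragment_tol=tol)
        exp_score, exp_matched = oracle_modified_cosine(a, b, tol)
        assert got_score == pytest.approx(exp_score, abs=1e-10)


def test_agreement_with_matchms_reference():
    """Cross-check against an independent molecular-networking library on
    conflict-free spectra (sqrt weighting applied up front)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(8)
    for _ in range(10):
        mzs = np.sort(rng.uniform(100, 300, size=8))
        ia, ib = rng.uniform(1, 100, size=8), rng.uniform(1, 100, size=8)
        keep = rng.random(8) < 0.7
        a = make_spectrum(mzs, ia, 350.0, "a")
        b = make_spectrum(mzs[keep] + 12.5, ib[keep], 362.5, "b")
        ref_a = matchms.Spectrum(mz=a.mz, intensities=np.sqrt(a.intensities),
                                 metadata={"precursor_mz": a.precursor_mz},
                                 metadata_harmonization=False)
        ref_b = matchms.Spectrum(mz=b.mz, intensities=np.sqrt(b.intensities),
                                 metadata={"precursor_mz": b.precursor_mz},
                                 metadata_harmonization=False)
        expected = float(ModifiedCosine(tolerance=0.02).pair(ref_a, ref_b)["score"])
        assert modified_cosine(a, b)[0] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# clustering

def test_identical_copies_collapse_to_one_node():
    base = make_spectrum([100.0, 120.0, 140.0], [10.0, 20.0, 30.0], 250.0, "s0")
    copies = [make_spectrum(base.mz, base.intensities, 250.0, f"s{k}") for k in range(5)]
    nodes = cluster_spectra(copies)
    assert len(nodes) == 1
    assert sorted(nodes[0].member_ids) == [f"s{k}" for k in range(5)]
    assert nodes[0].precursor_mz == pytest.approx(250.0)


def test_distant_precursors_never_merge():
    a = make_spectrum([100.0, 120.0], [1.0, 1.0], 250.0, "a")
    b = make_spectrum([100.0, 120.0], [1.0, 1.0], 260.0, "b")
    assert len(cluster_spectra([a, b], precursor_tol=0.02)) == 2


def test_planted_partition_recovered():
    """12 spectra in 3 groups (within-group near-identical, between-group
    unrelated) cluster into exactly 3 nodes reproducing the partition."""
    rng = np.random.default_rng(10)
    spectra, want = [], {}
    for g in range(3):
        mzs = np.sort(rng.uniform(60, 200, size=8))
        intens = rng.uniform(20, 100, size=8)
        prec = 250.0 + 30.0 * g
        for k in range(4):
            sid = f"g{g}_m{k}"
            jit = intens * np.exp(rng.normal(0, 0.02, size=8))
            spectra.append(make_spectrum(mzs, jit, prec + rng.uniform(-0.005, 0.005), sid))
            want[sid] = g
    nodes = cluster_spectra(spectra, precursor_tol=0.02, merge_cosine=0.95)
    assert len(nodes) == 3
    for n in nodes:
        groups = {want[m] for m in n.member_ids}
        assert len(groups) == 1 and len(n.member_ids) == 4


def test_clustering_partitions_the_input():
    rng = np.random.default_rng(11)
    spectra = [_random_spectrum(rng, 6, 200 + 5 * k, f"s{k}") for k in range(20)]
    nodes = cluster_spectra(spectra)
    all_members = [m for n in nodes for m in n.member_ids]
    assert sorted(all_members) == sorted(s.spectrum_id for s in spectra)


# ---------------------------------------------------------------------------
# network construction

def test_edge_requires_cosine_at_or_above_threshold():
    """A node pair scoring just below the threshold gets no edge; at the
    threshold (score >= threshold) it does."""
    rng = np.random.default_rng(12)
    base_mz = np.sort(rng.uniform(60, 180, size=8))
    intens = rng.uniform(20, 100, size=8)
    a = make_spectrum(base_mz, intens, 250.0, "a")
    b = make_spectrum(base_mz[:6], intens[:6] * 1.5, 250.0, "b")
    nodes = cluster_spectra([a, b], precursor_tol=0.02, merge_cosine=0.999)
    assert len(nodes) == 2
    score, matched = modified_cosine(nodes[0].representative, nodes[1].representative)
    assert matched >= 6
    below = build_molecular_network(nodes, cosine_threshold=score + 1e-6)
    at = build_molecular_network(nodes, cosine_threshold=score)
    assert below.edges == []
    assert len(at.edges) == 1 and at.edges[0].cosine == pytest.approx(score)


def test_network_equals_all_pairs_thresholding():
    rng = np.random.default_rng(13)
    spectra = []
    base = np.sort(rng.uniform(60, 180, size=8))
    intens = rng.uniform(20, 100, size=8)
    for k in range(8):
        # overlapping families: perturb a shared template to varying degree
        drop = rng.random(8) < 0.2 * (k % 4)
        mzs = base[~drop] + rng.normal(0, 0.002, size=(~drop).sum())
        spectra.append(make_spectrum(mzs, intens[~drop], 220.0 + 3 * k, f"s{k}"))
    nodes = cluster_spectra(spectra, precursor_tol=0.02)
    net = build_molecular_network(nodes, cosine_threshold=0.6, min_matched_peaks=4)
    expected = set()
    snodes = sorted(nodes, key=lambda n: n.node_id)
    for i in range(len(snodes)):
        for j in range(i + 1, len(snodes)):
            s, m = modified_cosine(snodes[i].representative, snodes[j].representative)
            if s >= 0.6 and m >= 4:
                expected.add((snodes[i].node_id, snodes[j].node_id))
    assert {(e.node_a, e.node_b) for e in net.edges} == expected
    for e in net.edges:
        assert e.mass_delta == pytest.approx(
            abs(net.node(e.node_a).precursor_mz - net.node(e.node_b).precursor_mz))


def test_raising_cosine_threshold_never_adds_edges(noisefree_cohort):
    nodes = cluster_spectra(noisefree_cohort.gut_spectra)
    loose = build_molecular_network(nodes, cosine_threshold=0.5)
    tight = build_molecular_network(nodes, cosine_threshold=0.9)
    loose_set = {(e.node_a, e.node_b) for e in loose.edges}
    tight_set = {(e.node_a, e.node_b) for e in tight.edges}
    assert tight_set <= loose_set


# ---------------------------------------------------------------------------
# cohort merging

def _tiny_network(rng, precursors, prefix):
    spectra = [_random_spectrum(rng, 8, p, f"{prefix}{k}")
               for k, p in enumerate(precursors)]
    for s in spectra:
        s.cohort_tag = prefix
    nodes = cluster_spectra(spectra, node_prefix=prefix)
    return build_molecular_network(nodes)


def test_merge_disjoint_mass_ranges_keeps_all_nodes():
    rng = np.random.default_rng(14)
    gut = _tiny_network(rng, [200.0, 210.0, 220.0], "gut")
    food = _tiny_network(rng, [400.0, 410.0], "food")
    merged = merge_networks(gut, food)
    assert len(merged.nodes) == 5
    assert all(n.cohort_label != "intersection" for n in merged.nodes)


def test_merge_duplicated_network_intersects_everywhere():
    rng = np.random.default_rng(15)
    gut = _tiny_network(rng, [200.0, 210.0, 220.0], "gut")
    food_nodes = []
    for n in gut.nodes:
        food_nodes.append(type(n)(
            node_id=n.node_id.replace("gut", "food"),
            precursor_mz=n.precursor_mz,
            representative_peaks=n.representative_peaks.copy(),
            member_ids=[m + "_f" for m in n.member_ids],
            cohort_tags={"food"},
        ))
    food = build_molecular_network(food_nodes)
    merged = merge_networks(gut, food)
    assert len(merged.nodes) == 3
    assert all(n.cohort_label == "intersection" for n in merged.nodes)


def test_merge_recovers_planted_shared_compounds(noisefree_cohort):
    """The cohort plants its substrates (not products) in the food cohort:
    after merging, intersection nodes are exactly the substrates."""
    c = noisefree_cohort
    gut = build_molecular_network(cluster_spectra(c.gut_spectra, node_prefix="gut"))
    food = build_molecular_network(cluster_spectra(c.food_spectra, node_prefix="food"))
    merged = merge_networks(gut, food)
    inter = [n for n in merged.nodes if n.cohort_label == "intersection"]
    sub_mzs = sorted(t.substrate_compound.adduct_mz for t in c.truth)
    planted_inter = sorted(n.precursor_mz for n in inter
                           if any(abs(n.precursor_mz - m) < 0.01 for m in sub_mzs))
    assert len(planted_inter) == len(sub_mzs)
    assert len(merged.nodes) <= len(gut.nodes) + len(food.nodes)


# ---------------------------------------------------------------------------
# feature-to-node mapping

def test_feature_node_matching_tolerance():
    s = make_spectrum([100.0, 120.0], [5.0, 5.0], 165.060, "s")
    net = build_molecular_network(cluster_spectra([s]))
    near = IntensityMatrix(["f"], ["s1", "s2", "s3"], np.ones((1, 3)),
                           feature_mz=np.array([165.054]))
    far = IntensityMatrix(["f"], ["s1", "s2", "s3"], np.ones((1, 3)),
                          feature_mz=np.array([165.10]))
    assert match_features_to_nodes(near, net, mass_tol=0.02) == {"f": net.nodes[0].node_id}
    assert match_features_to_nodes(far, net, mass_tol=0.02) == {}


def test_jittered_features_map_one_to_one(noisefree_cohort):
    c = noisefree_cohort
    net = build_molecular_network(cluster_spectra(c.gut_spectra, node_prefix="gut"))
    mapping = match_features_to_nodes(c.molecules, net, mass_tol=0.02)
    assert len(mapping) == c.molecules.n_features
    assert len(set(mapping.values())) == c.molecules.n_features
    for fid, nid in mapping.items():
        i = c.molecules.feature_ids.index(fid)
        assert abs(net.node(nid).precursor_mz - c.molecules.feature_mz[i]) <= 0.02
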