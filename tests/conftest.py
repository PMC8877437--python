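import itertools

import numpy as np
import pytest

from biotriad import Spectrum, simulate_cohort


def make_spectrum(mzs, intensities, precursor, sid="s", tag=""):
    return Spectrum(sid, precursor, np.column_stack([np.asarray(mzs, float),
                                                     np.asarray(intensities, float)]),
                    cohort_tag=tag)


@pytest.fixture
def spectrum_factory():
    return make_spectrum


@pytest.fixture(scope="session")
def noisefree_cohort():
    """The reference planted cohort: 200 samples, 30 microbes, 100
    molecules, 5 planted biotransformations, no intensity noise."""
    return simulate_cohort(n_samples=200, n_microbes=30, n_molecules=100,
                           n_planted=5, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_cohort():
    return simulate_cohort(n_samples=200, n_microbes=30, n_molecules=100,
                           n_planted=5, noise_sd=0.2, seed=11)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_average_ranks(x):
    """Average ranks computed from scratch (sort + tie groups)."""
    x = list(map(float, x))
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def oracle_spearman(x, y):
    return oracle_pearson(oracle_average_ranks(x), oracle_average_ranks(y))


def oracle_modified_cosine(a: Spectrum, b: Spectrum, tol: float):
    """Exhaustive search over all one-to-one peak assignments (tiny spectra
    only)."""
    wa = np.sqrt(a.intensities)
    wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensities)
    wb = wb / np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    cands = []
    for i in range(len(a.mz)):
        for j in range(len(b.mz)):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= tol or abs(d - shift) <= tol:
                cands.append((i, j, wa[i] * wb[j]))
    best = [0.0, 0]

    def rec(k, used_i, used_j, score, count):
        if k == len(cands):
            if score > best[0] + 1e-15:
                best[0], best[1] = score, count
            return
        rec(k + 1, used_i, used_j, score, count)
        i, j, s = cands[k]
        if i not in used_i and j not in used_j:
            rec(k + 1, used_i | {i}, used_j | {j}, score + s, count + 1)

    rec(0, frozenset(), frozenset(), 0.0, 0)
    return min(best[0], 1.0), best[1]


def oracle_exact_spearman_pvalue(rho_obs, n):
    """Two-sided permutation p-value by enumerating all n! rank orders."""
    ranks = list(range(1, n + 1))
    count = total = 0
    for perm in itertools.permutations(ranks):
        r = oracle_pearson(ranks, list(perm))
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total
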