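"""Molecule-microbe association network via Spearman correlation screening.

For every (molecular feature, microbial feature) pair the null hypothesis
is that the two abundance vectors are independent across samples; pairs
with a two-sided p-value below the threshold and an absolute rank
correlation above the rho threshold become edges of a bipartite
association network.  Raw p-values are thresholded by default (no
multiple-testing correction); an optional Benjamini-Hochberg mode is
available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from biotriad.feature_io import CountMatrix, IntensityMatrix

logger = logging.getLogger(__name__)

#: Below this sample count the exact permutation null is enumerated.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class AssociationEdge:
    """A surviving molecule-microbe association."""

    molecular_feature_id: str
    microbial_feature_id: str
    rho: float
    p_value: float
    n: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: the Pearson correlation of average-ranked
    values.  Returns NaN when either vector is constant (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.clip(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)), -1.0, 1.0))


@lru_cache(maxsize=16)
def _exact_null_rho(n: int) -> np.ndarray:
    """Null distribution of Spearman's rho over all n! rank permutations
    (untied ranks)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for Spearman's rho at sample size n.

    For n <= 9 the exact permutation distribution over all rank
    permutations is enumerated; for larger n the t-distribution
    approximation t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees
    of freedom is used.  |rho| = 1 returns the smallest representable
    positive float rather than zero.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if math.isnan(rho):
        return float("nan")
    if abs(rho) > 1 + 1e-12:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return math.ulp(0.0)
    if n <= EXACT_PERMUTATION_MAX_N:
        null = _exact_null_rho(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return max(p, math.ulp(0.0))
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return min(max(p, math.ulp(0.0)), 1.0)


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, centered and unit-scaled; returns the
    standardized matrix and a boolean mask of constant (skipped) rows."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def build_association_network(
    mol: IntensityMatrix,
    mic: CountMatrix,
    p_threshold: float = 1e-4,
    rho_threshold: float = 0.1,
    use_bh: bool = False,
) -> list[AssociationEdge]:
    """All (molecule, microbe) pairs passing p < p_threshold and
    |rho| > rho_threshold, as edges sorted by (molecular id, microbial id).

    Matrices must already be sample-aligned.  Constant features are
    skipped with a logged count.  With ``use_bh`` the p-threshold is
    applied to Benjamini-Hochberg adjusted values instead of raw ones.
    """
    if list(mol.sample_ids) != list(mic.sample_ids):
        raise ValueError("matrices are not sample-aligned; call align_samples first")
    n = mol.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")

    zm, const_m = _rank_standardize(mol.values)
    zo, const_o = _rank_standardize(mic.values)
    n_const = int(const_m.sum()) + int(const_o.sum())
    if n_const:
        logger.info("skipped %d constant features in association screening", n_const)

    rho = np.clip(zm @ zo.T, -1.0, 1.0)

    if n <= EXACT_PERMUTATION_MAX_N:
        pv = np.empty_like(rho)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                pv[i, j] = spearman_pvalue(rho[i, j], n)
    else:
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
        pv = 2.0 * stats.t.sf(np.abs(t), n - 2)
        pv[np.abs(rho) >= 1.0] = math.ulp(0.0)
        pv = np.clip(pv, math.ulp(0.0), 1.0)

    valid = ~const_m[:, None] & ~const_o[None, :]
    if use_bh:
        flat = pv[valid]
        order = np.argsort(flat)
        m = flat.size
        adj = np.empty(m)
        ranked = flat[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        screen_p = np.full_like(pv, 1.0)
        screen_p[valid] = np.minimum(adj, 1.0)
    else:
        screen_p = pv

    keep = valid & (screen_p < p_threshold) & (np.abs(rho) > rho_threshold)
    edges = [
        AssociationEdge(mol.feature_ids[i], mic.feature_ids[j],
                        float(rho[i, j]), float(pv[i, j]), n)
        for i, j in np.argwhere(keep)
    ]
    edges.sort(key=lambda e: (e.molecular_feature_id, e.microbial_feature_id))
    return edges


def write_edges(edges: Sequence[AssociationEdge], path: str | Path) -> None:
    pd.DataFrame(
        [(e.molecular_feature_id, e.microbial_feature_id, e.rho, e.p_value, e.n) for e in edges],
        columns=["molecular_feature_id", "microbial_feature_id", "rho", "p_value", "n"],
    ).to_csv(path, index=False)


def read_edges(path: str | Path) -> list[AssociationEdge]:
    df = pd.read_csv(path)
    return [
        AssociationEdge(str(r.molecular_feature_id), str(r.microbial_feature_id),
                        float(r.rho), float(r.p_value), int(r.n))
        for r in df.itertuples(index=False)
    ]
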