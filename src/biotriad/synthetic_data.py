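"""Synthetic paired microbiome/metabolome cohorts with planted biotransformations.

The generator embodies the biological hypothesis the pipeline tests: for
each planted biotransformation a microbe consumes a substrate and makes a
product, so across samples the substrate intensity decreases and the
product intensity increases monotonically with the microbe's abundance.
Substrate and product additionally share fragment peaks (a subset shifted
by the reaction's mass delta), so their spectra are neighbours in the
molecular network; the food cohort contains substrates but never planted
products, making products gut-unique.

Microbial abundances are lognormal with Poisson count sampling; molecule
intensities carry multiplicative lognormal noise of scale ``noise_sd``
(mass-spec intensities are positive and right-skewed).  The microbe
effect enters through a Hill-type saturating response, which is monotone
— all a rank-correlation screen requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from biotriad.feature_io import CountMatrix, IntensityMatrix, Spectrum, \
    write_count_matrix, write_intensity_matrix, write_spectra
from biotriad.rules import BiotransformRule, CompoundRecord, builtin_rules, write_compound_db
from biotriad.triangle import GoldenTriangle

#: Hill exponent of the saturating microbe-effect curve.
HILL_EXPONENT = 2.0


@dataclass
class PlantedBiotransformation:
    """Ground truth for one planted (microbe, substrate, product) triplet."""

    microbe_id: str
    substrate_compound: CompoundRecord
    rule: BiotransformRule
    effect_strength: float
    product_mz: float
    substrate_feature_id: str = ""
    product_feature_id: str = ""


@dataclass
class SyntheticCohort:
    molecules: IntensityMatrix
    microbes: CountMatrix
    spectra: list[Spectrum]
    compound_db: list[CompoundRecord]
    truth: list[PlantedBiotransformation]
    seed: int

    @property
    def gut_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.cohort_tag == "gut"]

    @property
    def food_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.cohort_tag == "food"]


def _separated_draws(rng: np.random.Generator, n: int, low: float, high: float,
                     min_sep: float, avoid: Sequence[float] = ()) -> np.ndarray:
    """Uniform draws in [low, high] pairwise separated by min_sep and away
    from every value in ``avoid``."""
    out: list[float] = []
    taken = list(avoid)
    for _ in range(10000):
        if len(out) == n:
            break
        x = float(rng.uniform(low, high))
        if all(abs(x - t) >= min_sep for t in taken):
            out.append(x)
            taken.append(x)
    if len(out) < n:
        raise RuntimeError("could not place separated draws; widen the mass range")
    return np.array(out)


def _fragment_spectrum(rng: np.random.Generator, precursor: float,
                       spectrum_id: str, cohort: str) -> Spectrum:
    """A random decoy fragmentation spectrum below its precursor."""
    k = 8
    mzs = _separated_draws(rng, k, 70.0, max(precursor - 20.0, 90.0), 1.0)
    intens = rng.uniform(10.0, 100.0, size=k)
    return Spectrum(spectrum_id, precursor, np.column_stack([mzs, intens]),
                    cohort_tag=cohort)


def _substrate_product_spectra(
    rng: np.random.Generator,
    substrate_mz: float,
    product_mz: float,
    sid: str,
    pid: str,
) -> tuple[Spectrum, Spectrum]:
    """A substrate spectrum and a product spectrum sharing 6 dominant
    fragments, half of them shifted by the reaction delta, so their
    modified cosine clears the 0.7 network threshold."""
    delta = product_mz - substrate_mz
    n_shared, n_sub_only, n_prod_only = 6, 4, 2
    frag_lo, frag_hi = 70.0, max(substrate_mz - 50.0, 95.0)
    mzs = _separated_draws(rng, n_shared + n_sub_only, frag_lo, frag_hi, 1.5)
    shared_mz, sub_only_mz = mzs[:n_shared], mzs[n_shared:]
    shared_int = rng.uniform(50.0, 100.0, size=n_shared)
    sub_only_int = rng.uniform(5.0, 20.0, size=n_sub_only)
    sub_peaks = np.column_stack([
        np.concatenate([shared_mz, sub_only_mz]),
        np.concatenate([shared_int, sub_only_int]),
    ])
    # product: 3 fragments unshifted, 3 carry the modified site
    prod_shared_mz = shared_mz.copy()
    prod_shared_mz[3:] = prod_shared_mz[3:] + delta
    prod_only_mz = _separated_draws(rng, n_prod_only, frag_lo, frag_hi, 1.5,
                                    avoid=list(prod_shared_mz))
    prod_only_int = rng.uniform(5.0, 15.0, size=n_prod_only)
    prod_peaks = np.column_stack([
        np.concatenate([prod_shared_mz, prod_only_mz]),
        np.concatenate([shared_int, prod_only_int]),
    ])
    return (
        Spectrum(sid, substrate_mz, sub_peaks, cohort_tag="gut"),
        Spectrum(pid, product_mz, prod_peaks, cohort_tag="gut"),
    )


def _food_copy(rng: np.random.Generator, s: Spectrum, new_id: str) -> Spectrum:
    """The same molecule re-measured in the food cohort: tiny m/z and
    intensity perturbations at instrument scale."""
    peaks = s.peaks.copy()
    peaks[:, 0] += rng.normal(0.0, 0.003, size=len(peaks))
    peaks[:, 1] *= np.exp(rng.normal(0.0, 0.05, size=len(peaks)))
    prec = s.precursor_mz + float(rng.uniform(-0.002, 0.002))
    return Spectrum(new_id, prec, peaks, cohort_tag="food")


def simulate_cohort(
    n_samples: int = 200,
    n_microbes: int = 30,
    n_molecules: int = 100,
    n_planted: int = 5,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a fully reproducible paired cohort with planted
    biotransformations.

    Parameters
    ----------
    n_samples : subjects with paired metabolomics and microbiome profiles.
    n_microbes : microbial features (lognormal abundance, Poisson counts).
    n_molecules : molecular features; each planted biotransformation uses
        two of them (substrate + product), the rest are independent decoys.
    n_planted : planted (microbe, substrate, product) triplets; rules are
        cycled from the builtin rule set.
    noise_sd : scale of the multiplicative lognormal intensity noise;
        0 gives the noise-free limit where every planted triplet is
        recoverable by construction.
    seed : single seed for the whole cohort; same inputs => same cohort.
    """
    if n_samples < 10:
        raise ValueError(f"need n_samples >= 10, got {n_samples}")
    if n_planted > min(n_microbes, n_molecules // 2):
        raise ValueError(
            f"n_planted={n_planted} infeasible for {n_microbes} microbes and "
            f"{n_molecules} molecules (need n_planted <= min(n_microbes, n_molecules/2))"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rules = builtin_rules()

    # --- reference compounds: planted substrates plus database decoys
    sub_masses = _separated_draws(rng, n_planted, 180.0, 400.0, 5.0)
    compound_db = [
        CompoundRecord(f"compound_{k:02d}", float(sub_masses[k]))
        for k in range(n_planted)
    ]
    decoy_masses = _separated_draws(rng, 10, 150.0, 450.0, 5.0, avoid=list(sub_masses))
    compound_db += [
        CompoundRecord(f"db_decoy_{k:02d}", float(m)) for k, m in enumerate(decoy_masses)
    ]

    # --- planted triplets
    microbe_ids = [f"otu_{m:03d}" for m in range(n_microbes)]
    truth: list[PlantedBiotransformation] = []
    for k in range(n_planted):
        rule = rules[k % len(rules)]
        sub = compound_db[k]
        truth.append(PlantedBiotransformation(
            microbe_id=microbe_ids[k],
            substrate_compound=sub,
            rule=rule,
            effect_strength=float(rng.uniform(0.6, 1.0)),
            product_mz=sub.adduct_mz + rule.mass_delta,
            substrate_feature_id=f"mol_sub_{k:02d}",
            product_feature_id=f"mol_prod_{k:02d}",
        ))

    # --- microbial abundances: lognormal latent, Poisson counts
    log_mean = rng.normal(math.log(500.0), 0.5, size=n_microbes)
    latent = np.exp(rng.normal(log_mean[:, None], 1.0, size=(n_microbes, n_samples)))
    counts = rng.poisson(latent).astype(float)
    microbes = CountMatrix(microbe_ids, [f"sample_{s:03d}" for s in range(n_samples)],
                           counts, feature_kind="taxon")

    def hill(a: np.ndarray) -> np.ndarray:
        k50 = np.median(a)
        return a ** HILL_EXPONENT / (a ** HILL_EXPONENT + k50 ** HILL_EXPONENT)

    # --- molecule intensities
    feature_ids: list[str] = []
    feature_mz: list[float] = []
    rows: list[np.ndarray] = []
    spectra: list[Spectrum] = []

    planted_mzs: list[float] = []
    for t in truth:
        planted_mzs += [t.substrate_compound.adduct_mz, t.product_mz]

    for k, t in enumerate(truth):
        a = latent[k]
        g = hill(a)
        base_s = float(rng.lognormal(math.log(1e5), 0.3))
        base_p = float(rng.lognormal(math.log(1e5), 0.3))
        noise_s = np.exp(rng.normal(0.0, noise_sd, size=n_samples)) if noise_sd > 0 else 1.0
        noise_p = np.exp(rng.normal(0.0, noise_sd, size=n_samples)) if noise_sd > 0 else 1.0
        feature_ids.append(t.substrate_feature_id)
        feature_mz.append(t.substrate_compound.adduct_mz)
        rows.append(base_s * (1.0 - t.effect_strength * g) * noise_s)
        feature_ids.append(t.product_feature_id)
        feature_mz.append(t.product_mz)
        rows.append(base_p * t.effect_strength * g * noise_p)
        s_spec, p_spec = _substrate_product_spectra(
            rng, t.substrate_compound.adduct_mz, t.product_mz,
            f"gut_{t.substrate_feature_id}", f"gut_{t.product_feature_id}")
        spectra += [s_spec, p_spec]

    n_decoys = n_molecules - 2 * n_planted
    decoy_mz = _separated_draws(rng, n_decoys, 120.0, 500.0, 0.5, avoid=planted_mzs)
    for j in range(n_decoys):
        fid = f"mol_decoy_{j:03d}"
        base = float(rng.lognormal(math.log(1e5), 0.3))
        feature_ids.append(fid)
        feature_mz.append(float(decoy_mz[j]))
        rows.append(base * np.exp(rng.normal(0.0, 1.0, size=n_samples)))
        spectra.append(_fragment_spectrum(rng, float(decoy_mz[j]), f"gut_{fid}", "gut"))

    molecules = IntensityMatrix(feature_ids, list(microbes.sample_ids),
                                np.vstack(rows), feature_mz=np.asarray(feature_mz))

    # --- food cohort: substrates and some decoys, never planted products
    for t in truth:
        gut_sub = next(s for s in spectra if s.spectrum_id == f"gut_{t.substrate_feature_id}")
        spectra.append(_food_copy(rng, gut_sub, f"food_{t.substrate_feature_id}"))
    for j in range(0, n_decoys, 2):
        gut_decoy = next(s for s in spectra if s.spectrum_id == f"gut_mol_decoy_{j:03d}")
        spectra.append(_food_copy(rng, gut_decoy, f"food_mol_decoy_{j:03d}"))

    return SyntheticCohort(molecules=molecules, microbes=microbes, spectra=spectra,
                           compound_db=compound_db, truth=truth, seed=seed)


def evaluate_recovery(
    truth: Sequence[PlantedBiotransformation],
    found: Sequence[GoldenTriangle],
    mz_tol: float = 0.01,
) -> tuple[float, float, dict[str, int]]:
    """Score found triangles against the planted ground truth.

    A found triangle is a true positive iff its microbe matches a planted
    triplet and its substrate/product node precursors lie within
    ``mz_tol`` of the planted substrate [M+H]+ and product m/z.  Returns
    (precision, recall, confusion); recall is NaN for empty truth,
    precision NaN when nothing was found.
    """
    matched: set[int] = set()
    tp = fp = 0
    for t in found:
        hit = None
        for i, pl in enumerate(truth):
            if (t.microbial_feature_id == pl.microbe_id
                    and abs(t.substrate_mz - pl.substrate_compound.adduct_mz) <= mz_tol
                    and abs(t.product_mz - pl.product_mz) <= mz_tol):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            tp += 1
            matched.add(hit)
    confusion = {"tp": tp, "fp": fp, "fn": len(truth) - len(matched)}
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = len(matched) / len(truth) if truth else float("nan")
    return precision, recall, confusion


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text fixtures: CSV matrices, gut/food MGF
    files, the compound DB and a truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_intensity_matrix(cohort.molecules, outdir / "molecules.csv")
    write_count_matrix(cohort.microbes, outdir / "microbes.csv")
    write_spectra(cohort.gut_spectra, outdir / "gut.mgf")
    write_spectra(cohort.food_spectra, outdir / "food.mgf")
    write_compound_db(cohort.compound_db, outdir / "compounds.csv")
    pd.DataFrame(
        [(t.microbe_id, t.substrate_compound.compound_name,
          t.substrate_compound.adduct_mz, t.rule.rule_name, t.effect_strength,
          t.product_mz, t.substrate_feature_id, t.product_feature_id)
         for t in cohort.truth],
        columns=["microbe_id", "substrate_name", "substrate_adduct_mz", "rule",
                 "effect_strength", "product_mz", "substrate_feature_id",
                 "product_feature_id"],
    ).to_csv(outdir / "truth.csv", index=False)
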