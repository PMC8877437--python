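# Methods

## The model

`biotriad` looks for microbial biotransformations — a gut microbe
enzymatically converting a dietary substrate molecule into a product —
without culturing anything, using only observational cohort data: an
LC-MS/MS metabolomics profile and a 16S (or shotgun-derived enzyme)
profile measured on the same subjects.

The working hypothesis has three parts. If microbe *y* converts substrate
*s* into product *p*, then across subjects

1. the abundance of *s* decreases with the abundance of *y* (the microbe
   consumes it): Spearman ρ(s, y) < 0;
2. the abundance of *p* increases with the abundance of *y* (the microbe
   makes it): ρ(p, y) > 0;
3. *s* and *p* are structurally similar (one reaction apart), so their
   tandem-MS spectra are similar and they are neighbours in a molecular
   network.

A triplet satisfying all three is a *golden triangle*. A fourth, chemical
constraint sharpens it: the precursor mass difference m/z(p) − m/z(s)
must match the mass delta of a known biotransformation reaction (loss of
CO₂ for decarboxylation, loss of O for dehydroxylation, gain of CH₂ for
O-methylation, ...). Substrates are finally identified by parent-mass
lookup against a compound database, giving a human-readable candidate
table.

A relaxed *same-sign* mode also admits triangles where both correlations
share a sign; this pattern arises for reactions where a higher substrate
supply simply yields more product, and it is reported as its own mode,
never silently mixed with the canonical one.

## Statistical screening (association network)

Each (molecular feature, microbial feature) pair is tested with
Spearman's rank correlation: ρ is the Pearson correlation of
average-ranked values (ties receive average ranks; zeros participate as
true zero measurements, with no zero-inflation model). The two-sided
p-value uses the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of
freedom; for n ≤ 9 the exact permutation null over all n! rank orders is
enumerated instead (the exact null assumes untied ranks — the
(ρ, n)-valued interface cannot see ties). |ρ| = 1 maps to the smallest
representable positive float, never 0. An edge survives when
p < 10⁻⁴ **and** |ρ| > 0.1 (both configurable; raw p-values by default,
matching the screening character of the method — an optional
Benjamini–Hochberg mode exists but is off). Constant features are
skipped and counted. The screen is a dense vectorised rank-matrix
product; no approximate pre-filter is used at desk scale.

## Spectral side (molecular network)

*Clustering.* Near-identical scans are merged into consensus nodes by a
deterministic greedy single pass: spectra are processed in descending
total-intensity order (ties by spectrum id); a spectrum joins the first
node whose consensus precursor is within the precursor tolerance
(0.02 Da, the qTOF setting) and whose representative spectrum reaches the
merge cosine (default 0.95, plain cosine — "identical spectra" merging);
otherwise it seeds a new node. Representative peaks are an
intensity-weighted merge of the members, binned at the fragment
tolerance; the node precursor is the median of member precursors.

*Scoring.* The modified (modification-tolerant) cosine allows a fragment
in spectrum *a* to match a fragment in *b* either directly
(|Δm/z| ≤ tol) or shifted by the precursor difference, so fragments
retaining the modified site still pair up. Peak weights are
unit-normalised √intensities (standard for qTOF spectral matching).
Among candidate peak pairs a maximum-total-score one-to-one assignment is
taken — solved exactly with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`), not greedily, with a fast exit
when no candidate pairs conflict. The score is symmetric, bounded in
[0, 1], and reduces to the plain cosine at equal precursors.

*Edges.* Node pairs with modified cosine ≥ 0.7 **and** ≥ 6 matched peaks
become edges. The matched-peak floor is the standard molecular-networking
default and suppresses single-peak spurious edges; the fragment tolerance
defaults to the precursor tolerance (0.02 Da).

*Cohort merging.* Gut and food networks are merged to label provenance: a
gut node and a food node are unified when their precursors agree within
the mass tolerance and their representatives reach the cosine threshold
(a mass-only mode is available). Matching is greedy 1:1, best cosine
first. Every surviving node is labelled `intersection`, `gut-unique` or
`food-unique`; a product found only in the gut cohort is flagged on the
triangle (`gut_unique_product`) as circumstantial evidence of in-host
production — a flag, not a filter. Edges are recomputed across the
merged node set.

*Feature mapping.* LC-MS intensity features are linked to network nodes
by smallest |Δm/z| within 0.02 Da (ties: larger node, then lexicographic
id). Retention time is carried through IO but not used for matching; its
unit is treated as opaque. All precursor arithmetic assumes singly
charged [M+H]⁺ species; multiply charged ions are out of scope.

## Rule engine and dereplication

Rules are signed monoisotopic mass deltas applied on the m/z axis (the
proton of the [M+H]⁺ adduct cancels in any substrate−product difference).
Builtin deltas are computed from element monoisotopic masses via the
formula-change string (e.g. −CO₂ → −43.98983 Da), never typed in as
rounded decimals; the 0.02 Da matching tolerance absorbs rounding in
literature-quoted values such as 43.989. Structure-aware applicability
(does the molecule actually carry a carboxyl group?) is out of scope;
matching is mass-only with optional SMILES pass-through. Substrate
dereplication is parent-mass-only against the compound database at a
0.002 Da tolerance; since no in-silico fragmentation is performed, every
annotation carries match level `parent_mass_only`.

## Triangle extraction

For every network edge and every microbe associated (through the feature
map) with both endpoints, the sign pattern decides substrate/product
orientation; when several features map to one node the association with
the largest |ρ| represents the pair. In same-sign mode, ambiguous
orientation is resolved by which direction a rule explains, then by which
endpoint has a database annotation, then by the heavier precursor as
substrate. Candidates whose mass delta no rule explains within the
tolerance are dropped by default (`require_rule=True`); with
`--no-require-rule` they are retained and flagged. Output is
deterministic: sorted by max(|ρ_s|, |ρ_p|) descending, then ids. No
further selection beyond the thresholds is applied; all survivors are
reported. An enzyme-abundance matrix (`feature_kind="enzyme"`) flows
through the identical code path — no special handling is needed.

## Synthetic cohorts

The generator (`simulate_cohort`) embodies the hypothesis generatively so
every stage is testable without downloads. Defaults: 200 subjects, 30
microbes, 100 molecules, 5 planted biotransformations, noise 0.2.

- Microbes: per-microbe lognormal latent abundance (log-mean ~
  N(log 500, 0.5), per-sample log-sd 1.0), Poisson count sampling on the
  latent mean — counts are large enough that ranks track the latent
  abundance closely.
- Planted molecules: substrate intensity = baseline·(1 − e·g(a)), product
  = baseline·e·g(a), with effect strength e ∈ (0.6, 1], and g a Hill
  curve with exponent 2 and half-saturation at the median abundance. Only
  monotonicity matters to a rank screen; the Hill form is a documented
  free choice. Multiplicative lognormal noise of scale `noise_sd` is
  applied (intensities are positive and right-skewed); `noise_sd = 0` is
  the noise-free limit in which every planted triplet is recoverable by
  construction.
- Decoy molecules: independent lognormal intensities; their m/z values
  are rejection-sampled away (≥ 0.05 Da) from all planted masses.
- Spectra: substrate/product pairs share 6 dominant fragments, 3 of them
  shifted by the rule delta, plus low-intensity unique peaks — their
  modified cosine clears 0.7 with ≥ 6 matched peaks. Decoys get
  independent random fragments. The food cohort receives re-measured
  copies of substrates (instrument-scale m/z and intensity jitter) and
  half the decoys, never planted products, so products come out
  gut-unique.
- One `numpy` Generator seeded once per cohort; no global random state.

What the generator does **not** emulate: real taxonomic composition and
compositionality of counts, retention-time drift, adduct/isotope
multiplicity, chimeric spectra, batch effects, and correlated microbes.
Passing the recovery tests therefore demonstrates correctness of the
pipeline's logic under its own assumptions, not field performance on real
cohorts, where confounding and compositional effects will reduce
precision.

## Numerical choices and degenerate inputs

- Presence means intensity strictly > 0; blank CSV cells read as 0 with a
  logged count; features present in < 2 samples are discarded (boundary:
  exactly 2 is kept).
- Sample alignment is exact string match after whitespace trimming,
  sorted canonical order, hard error below 3 shared samples.
- CSV writes use `%.17g` and reads parse with Python `float()` so
  write-then-read is bit-exact.
- All tie-breaks (clustering order, node ids, feature mapping, triangle
  sort) are deterministic, so a fixed-seed cohort yields byte-identical
  output CSVs across runs.
- Scans without a precursor are skipped with a logged count; empty peak
  lists are a hard error in similarity scoring.

## Problem sizes

The test suite and the reference analyses run at desk scale: cohorts of
200 subjects × 30 microbes × 100 molecules (≈ 210 spectra), chosen so the
all-pairs spectral comparison and the dense rank screen complete in
seconds while leaving every code path exercised. All thresholds retain
their field-standard defaults (p < 10⁻⁴, |ρ| > 0.1, cosine ≥ 0.7,
precursor/fragment/rule tolerance 0.02 Da, dereplication 0.002 Da).
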