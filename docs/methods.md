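# Methods

This note documents the models, conventions and numerical choices behind
`aquatox`, and what the synthetic benchmarks do and do not demonstrate.

## Endpoint, transform and labels

The modelling target is the acute aquatic toxicity of the most sensitive
species, expressed as an L(E)C50 in mg/L, transformed to
`tox = −ln(LC50)` so that larger values mean more toxic.  The transform is
a strict monotone bijection; `exp(−tox)` recovers the concentration.
Screening labels follow the regulatory short-cut thresholds on the raw
mg/L value (not the transform): **T** (toxic) below 0.01 mg/L, **PT**
(potentially toxic) below 0.1 mg/L, **NT** otherwise.  Both cutoffs are
configurable (`ThresholdConfig`); the boundary semantics are
`lc50 < t_cut → T`, `t_cut ≤ lc50 < pt_cut → PT`, `lc50 ≥ pt_cut → NT`,
so exactly one label applies to every positive concentration.

## Structural domain

The supported chemistry is saturated aliphatic C/H/O/N molecules.
"Saturated" is interpreted as a carbon-skeleton property: no aromatic
atoms and no carbon–carbon double or triple bonds, while heteroatom
multiple bonds (C=O, N=O) are permitted — a strict all-single-bond reading
would exclude aliphatic acids, esters and amides, which plausibly belong
to the domain.  The filter reports a reason code (`element:X`, `aromatic`,
`cc_multiple_bond`) for every rejection and is a fixed point on its own
output.

## Descriptors

The audit and the models consume *named numeric columns*; the default
provider supplies a 93-name panel: 13 rule-relevant descriptors plus 80
standard RDKit topological/electronic descriptors.  RDKit supplies logP
(Crippen), molar refractivity, TPSA and MW directly.  The
autocorrelation, E-state and ETA families are implemented natively from
their published formula families:

* `AATSC0p` — averaged centered Moreau–Broto autocorrelation at lag 0,
  polarizability-weighted, over the hydrogen-inclusive graph:
  `Σ(w_i − w̄)² / N`.
* `GATS1p`, `GATS1i` — Geary autocorrelation at lag 1
  (`[Σ_bonds (w_i−w_j)²/2B] / [Σ_i (w_i−w̄)²/(N−1)]`), weighted by atomic
  polarizability and first ionization energy respectively (CRC atomic
  values; H, C, N, O, F, P, S, Cl, Br tabulated, anything else fails
  loudly).
* `Mi` — mean first ionization energy scaled on carbon, over all atoms
  including hydrogens.
* `SHBd` — sum of Kier–Hall E-state indices over hydrogen-bond-donor
  heavy atoms (N/O carrying ≥ 1 H); `maxHBint2` — the largest
  donor-E-state + acceptor-E-state sum over donor/acceptor pairs at
  topological distance 2 (0 when no pair exists).
* `ETA_Alpha` — sum over heavy atoms of the ETA core count
  `α = (Z − Z_v)/Z_v · 1/(PN − 1)`; `ETA_dEpsilon_A` — mean of
  `ε = −α + 0.3·Z_v` over heavy atoms minus the mean over all atoms, an
  electronegative-atom-content measure; `ETA_EtaP_B` — excess heavy-atom
  degree beyond two per heavy atom, a branching measure.

These native definitions are deterministic, documented and monotone in the
chemistry they encode; they are not bit-compatible with any external
descriptor software, which is acceptable because every consumer in the
package (kNN distances after z-scaling, rank-based compliance) uses them
relationally.  Constant-for-the-dataset columns are flagged, not silently
dropped; missing or non-finite values raise.

Fingerprints are circular (Morgan), radius 2, 2048 bits by default.

## kNN models

`KnnToxicityRegressor` ranks training molecules by Manhattan distance on
z-scaled descriptors (`mode="descriptor"`) or by Tanimoto similarity on
binary fingerprints (`mode="fingerprint"`).  Numerical conventions:

* Descriptor z-scaling is fitted on training rows only; zero-variance
  columns are excluded from the distance (their information content is
  nil and they would produce 0/0).  A fully constant training matrix is
  rejected.
* Two all-zero fingerprints have Tanimoto similarity 1.0 by convention.
* All ranking ties break toward the lower training index, making results
  reproducible across runs and platforms.
* Predictions are the unweighted mean of the k neighbors' training
  targets (minimal assumption; a distance-weighted mean is available
  behind `weights="distance"`).  Unweighted predictions therefore always
  lie within the range of the training targets.
* Leave-one-out evaluation is supported by an explicit per-query
  exclusion index rather than a distance-zero heuristic.

`select_k` scans a candidate grid over validation fractions restricted to
[0.05, 0.30] with a seeded shuffle splitter, scores each cell with R²
(default) or Spearman, and returns the k with the best mean score (ties
toward the smaller k) together with the full score table for audit.  The
neighbor counts found by the original large-scale screens ship as presets
(`FINAL_K_DESC = (2, 4, 5, 6, 8)`, `FINAL_K_FPN = (2, 5, 7, 12, 14)`).

## Prior-knowledge model

`PriorKnowledgeModel` composes a linear group-contribution fish model
(intercept + coefficients over SMARTS fragment counts, optionally plus
whole-molecule descriptor terms) with a linear fish→daphnia interspecies
map.  Every component declares its scale — a transform (`linear`,
`neg_log10`, `neg_ln`) plus concentration units (`mg_per_L`, `mmol_per_L`,
`mol_per_L`) — and composition validates the declaration chain; crossing
between molar and mass units requires the molecule's molar mass and
round-trips to ≤ 1e−9.  The published coefficients this model family is
normally parameterised with are consumed from YAML configuration.  The
shipped default is a **placeholder** baseline-narcosis calibration,
`−log10(LC50 mmol/L) = 0.85·logP + 1.39` with an identity interspecies
map: it keeps the pipeline runnable without external sources, reproduces
the qualitative narcosis behaviour (predicted toxicity rises monotonically
along a homologous alcohol series), but is not calibrated to any dataset —
its absolute level is intentionally not trusted anywhere in the package.

## Hybridization schemes

* **H0** removes training molecules with MW strictly above a threshold
  before fitting the descriptor kNN.  Default 300 g/mol — the mass above
  which the MW–toxicity correlation is known to degrade in screening
  data; the synthetic benchmarks use the (1 − contamination) quantile of
  the training MW instead, because the generator's C2–C16 skeletons top
  out below 300 g/mol and the quantile is the generator's design point
  for where the pathology starts.
* **H1** runs the descriptor kNN in the reduced six-descriptor space
  (LogP, AATSC0p, TPSA, ETA_dEpsilon_A, SHBd, Mi).  H0/H1 retrain the
  model on the modified data/feature set; they do not post-filter
  predictions.
* **H2** routes each query by its computed logP: inside the closed band
  [1.5, 4.0] the fingerprint kNN answers, outside the PKM answers.  The
  band edges are inclusive by documented convention ("between" is
  ambiguous); both bounds and the logP source column are configurable.
  The router adds no arithmetic — each prediction is bitwise the routed
  pure model's output, which is tested.
* **H3** selects as neighbors the k training molecules whose PKM
  predictions are closest to the query's PKM prediction (ties toward the
  lower index) and averages their observed toxicities.  With a PKM that
  returns a single descriptor this reduces exactly to 1-D descriptor kNN,
  which is used as an equivalence test.

## Rule-based post-assessment

The 16 encoded trend rules pair a feature with an expected sign; three are
*scoped* (carbon count in N-containing molecules, carbon count in
ether-containing molecules, N-CH3 count in N-containing molecules) and
correlate only over molecules satisfying the scope predicate.  The
compliance matrix holds the Spearman coefficient of each rule feature
against each model's predictions (ties averaged); cells with fewer than 3
in-scope molecules or constant inputs are undefined (NaN), never zero.

Rule affinity condenses the matrix: per rule, `s = expected_sign · ρ` is
min-max normalised across models (sign adjustment first, so that
perfectly matching a *decreasing* trend scores 1, not 0; a degenerate
range normalises to 0.5 because an uninformative rule should not separate
models), and the normalised values are summed over all fully defined
rules.  Affinity is invariant to model/rule relabeling and bounded by
[0, n_scored_rules].  The observed-data column appears in the matrix as a
reference but is excluded from affinity scoring.

Balanced accuracy is macro recall over the classes present in the truth;
precision and recall are support-weighted, which accounts for the strong
NT-majority imbalance of screening data.  These conventions are
swappable at the function level.

## Synthetic generator

The generator emulates the composition of the screening domain: branched
alkyl skeletons of 2–16 carbons (random attachment, 70 % chain
extension / 30 % random branch) decorated independently with hydroxyl
(p = 0.4), methoxy ether (0.3), primary amine (0.3) and dimethylamino
(0.25) groups.  Toxicity follows

    tox = −2.0 + 0.9·logP + 0.005·MW − 0.8·n_NCH3 + N(0, 0.3²)

The logP slope is in the baseline-narcosis range; the MW term adds a mild
independent size effect; the N-methyl coefficient −0.8 encodes the marked
detoxifying effect of N-methylation and is deliberately strong enough to
dominate the collateral logP/MW increase contributed by the dimethylamino
group itself, so the scoped negative trend is recoverable from data.
The optional contamination replaces the noiseless toxicity of the highest-
MW fraction with the median value before noise, reproducing the flat
MW–toxicity regime that motivates H0.  Benchmarks use n = 500 molecules
with an 80/20 split — large enough for stable rank statistics and kNN
neighborhoods while keeping a full pipeline run in seconds.

What passing synthetic benchmarks shows: the pipeline wiring, the exact
contracts (neighbor search, routing, thresholds), the recoverability of
planted monotone trends, and that MW-outlier filtering repairs a planted
MW pathology.  What it does not show: performance on real mixed-species
screening data, whose noise is non-Gaussian, whose trends are confounded,
and whose chemistry (reactive MoAs, ionisable compounds) the generator
deliberately omits.

## Text mining

Input is pre-extracted UTF-8 text (PDF handling is out of scope).
Cleaning removes everything up to and including a body-start heading
(default "Introduction") and from the last references heading onward,
then collapses whitespace.  Sentence segmentation is a deterministic
rule-based splitter on `.!?` with protected abbreviations and decimal
numbers.  Key phrases use RAKE scoring (word score = degree/frequency,
phrase score = sum; ties lexicographic) over a builtin stopword list.
Relevance requires, within the same sentence, at least one whole-token
main-term match and one token-prefix connection-stem match, both
case-insensitive; prefix matching reproduces the truncated-lemma stem
list.  The same-sentence co-occurrence requirement is the stricter of the
plausible readings; a window-based variant would only enlarge the
selection.

## Known limitations

* The native descriptor implementations are formula-family faithful but
  not numerically interchangeable with external descriptor packages.
* The shipped PKM calibration is a placeholder; absolute H2/H3 accuracy
  on real data requires substituting published GC and interspecies
  coefficients via YAML.
* No applicability-domain estimation, no 3D descriptors, no tautomer or
  pKa handling, no statistical significance testing of compliance
  correlations.
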