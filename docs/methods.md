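# Methods

`engineerweb` quantifies the functional roles of an ecosystem-engineer
species in coastal soft-bottom habitats along three axes: does the
engineered habitat hold more prey energy, does it restructure the food
web, and does it shelter juvenile fish?  The package implements the full
quantitative chain for a two-bay, three-habitat trawl survey design
(an engineered *Haploops*-type habitat plus two uncolonised reference
habitats per bay) and ships a synthetic-study generator with known
ground truth so every stage can be validated without field data.

## Study design and data model

A study consists of four tables: a haul x species community matrix with
aligned biomass (kg km⁻²) and density (ind km⁻²) layers; a per-replicate
stable-isotope table (δ¹³C, δ¹⁵N in ‰, with role `source`/`prey`/
`predator`/`both` and a per-species biomass weight for consumers); a
per-species coefficient table (mass energy *E* in kJ/g wet mass,
productivity π in /yr, regeneration *R* and accessibility *A* in [0, 1]);
and fish length/weight records.  Absence of a (haul, species) row means
biomass zero — trawl catches are treated as censuses of the swept area —
and isotope replicates are never imputed.  Bays are processed
independently throughout: each bay has its own species pool and the
design gives no basis for pooling them.

All randomised stages draw generators derived deterministically from a
single run seed (CRC-mixed per-stage seed sequences), so a full report
regenerates bit-identically from config plus data.

## Prey energy accounting (ABEC)

The Available Benthic Energy Coefficient of prey species *i* is
ABEC_i = E_i · π_i · R_i · A_i (kJ g⁻¹ yr⁻¹).  Habitat-scale supply is

    ABEC×B   = Σ_i ABEC_i · B̄_i · 10³   (kJ km⁻² yr⁻¹)
    ABEC×B×S = ABEC×B · S               (kJ yr⁻¹)

where B̄_i is the arithmetic mean biomass over the habitat's hauls
(hauls are equally weighted; swept areas are near-equal by design) and
*S* the habitat surface in km².  The 10³ g/kg factor bridges biomass in
kg km⁻² to *E* in kJ/g.  Coefficients are inputs: the package does not
re-derive *E* or π from taxon-level empirical models, nor adjust π for
temperature.  Cumulative prey richness SR_cum over *k* hauls (default 3)
is estimated by Monte-Carlo subsampling without replacement (default
10,000 draws) and returned exactly when only one subset exists.

## Community structure

Per-haul predator diversity: species richness, Simpson diversity in the
complement form 1 − Σp², and Pielou evenness (−Σp ln p)/ln SR, flagged
undefined rather than zeroed when SR < 2.  Habitat effects are tested
with one-way PERMANOVA: pseudo-F from among/within sums of squared
distances, p-value by label permutation with the add-one convention
p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) (10,000 permutations by default).
Distances are Euclidean on per-index standardised diversity matrices and
Bray–Curtis on density matrices, the standard pairing for index versus
abundance data; no abundance transformation is applied by default.
Before each PERMANOVA a homogeneity-of-dispersion check is run:
principal-coordinate embedding (with the usual negative-eigenvalue
correction), distances to group centroids, permutation F-test.  Post hoc
pairwise PERMANOVAs use a Bonferroni-adjusted threshold.  Correspondence
analysis of the fish density table exposes principal coordinates,
per-axis inertia and cos² (for display filtering at cos² > 0.4);
invertebrate competitor densities are projected as supplementary columns
through the transition formulas, without influencing the axes.

## Isotopic functional indices

Communities are species-mean point sets in (δ¹³C, δ¹⁵N) space.  Five
indices are computed:

- **SEA** (‰²): standard ellipse area, π√(λ₁λ₂) with λ the eigenvalues
  of the sample covariance (n−1 denominator).  Uncorrected by default; a
  flag applies the (n−1)/(n−2) small-sample correction.
- **NR** (‰): the δ¹⁵N range, a trophic-chain-length proxy.
- **IDiv, IDis, IEve**: biomass-weighted divergence, dispersion and
  evenness.  With hull-centroid distances d_i, d̄ their unweighted mean,
  and weights w_i, IDiv = (Σw_i(d_i−d̄) + d̄)/(Σw_i|d_i−d̄| + d̄);
  IDis = Σw_i‖x_i − G_w‖ about the weighted centroid; IEve rescales the
  clamped branch weights of the minimum spanning tree,
  (Σ min(PEW_l, 1/(S−1)) − 1/(S−1))/(1 − 1/(S−1)) with
  PEW_l ∝ length_l/(w_i+w_j).  The clamp is essential: PEW sums to one,
  so the unclamped expression is identically 1.

SEA and NR are computed in raw ‰; the weighted trio in min–max-scaled
space with pooled extrema across the communities being compared, so
values are comparable between habitats.  MST ties break on lexicographic
species order for determinism.  At the food-web scope all signatures
(sources included) enter SEA and NR, while the weight-free sources are
excluded from the biomass-weighted trio.  A warning is emitted below 20
species, the point where these indices lose accuracy; the pipeline skips
prey-scope indices for a bay when any habitat falls below that count.

Habitat pairs are compared by a two-tailed permutation test: species
rows (point and weight together — the pairing is what the indices
measure) are pooled and reallocated into groups of the original sizes,
weights renormalised per group, both indices recomputed;
pseudo-p = (#{|Δperm| ≥ |Δobs|}+1)/(n_perm+1), with Bonferroni division
of α by the number of tests.  Axis scaling is computed once on the
pooled pair and is therefore permutation-invariant.  Food-web-scope
tests permute consumer rows only: the organic-matter sources are fixed
low-δ¹⁵N endpoints common to every habitat, hence not exchangeable under
the null; including them roughly triples the permuted NR standard
deviation and masks genuine chain-length differences.  Permutations that
produce a degenerate hull are redrawn and counted.

## Diet mixing model

Sources are built by Ward clustering (Euclidean, standardised columns)
of prey species on the (E·π·R, A) plane, cut at K = 3 — the number of
isotopes plus one, so the noise-free system is exactly determined —
ordered by ascending energy and summarised by the member species'
replicate signatures (pooled per habitat by default, per bay as an
option).  Each source set carries two flags: the group with the highest
accessible biomass (Σ B_i·A_i) and the highest energy supply
(Σ B_i·ABEC_i).  For general Ward cuts the group count is chosen where
the relative loss of inertia between successive partitions is highest
(each merge adds h²/2 to within-group inertia; the cut precedes the
largest ratio of successive losses), searched over k ∈ [2, min(8, n−1)].

The mixing likelihood per consumer replicate j and isotope e is

    X_je ~ Normal( Σ_k p_k (μ_ke + Δ_e),  √(Σ_k p_k² σ_ke² + τ_e²) )

with diet proportions p ~ Dirichlet(1,1,1), residual sds
τ_e ~ Uniform(0, 20 ‰), and Δ the trophic enrichment factor.  Three
literature presets are provided — TEF1 (+1, +4), TEF2 (+2, +3), TEF3
(+1.5, +3.4) ‰ in (δ¹³C, δ¹⁵N) — and a sensitivity harness refits under
all three and reports the spread of posterior means.  TEF uncertainty
itself defaults to zero (source sds and τ already absorb signature
uncertainty); a config hook can widen it.  Sampling is random-walk
Metropolis on the additive-log-ratio transform of p jointly with
logit-transformed τ (Jacobians included), four independent chains of
40,000 iterations (burn-in 20,000, thin 10) by default; tests and the
acceptance script use 4×8,000/4,000/10, which the recovery checks show
is ample for these 4-parameter posteriors.  Split-chain R̂ and effective
sample sizes are computed with arviz; R̂ > 1.1 flags the result rather
than discarding it.  Warnings also mark consumer groups smaller than
2K = 6 replicates (prior-dominated posteriors) and consumer centroids
outside the TEF-corrected source polygon.  The preferred source is the
highest posterior median; a gap under 0.05 between the top two medians
is reported as co-preference (the threshold is a documented convention).

## Size spectra

Juvenile records are those at or below a per-species maximum length
(the length at age two); species without a threshold pass with a
warning.  Spectra are half-open fixed-width bins anchored at zero,
2 cm wide by default (the scale at which the engineered-versus-outside
modal contrast manifests); modal ties break toward the smaller bin.
Two spectra are compared on their common binning by a chi-squared
homogeneity test of the full binned distributions; a secondary 2×2
statistic restricted to inside-versus-outside the union of modal bins
is reported alongside, since "the modes differ" can be read either way.
`mode_differs` requires both a different modal bin and p < α.  Species
shares of the modal bin rank who carries the mode.  Mobility-group
spectra (movement classes M1 ≤ 0.1 km to M4 > 10 km over the 3–4-week
isotopic integration window) are produced only for groups with ≥ 30
records.  Fulton's condition index K = 100·W/L³ and the square-lattice
tube-spacing estimate 100/√density (cm, density per m²) round out the
refuge analysis.

## Synthetic studies

The generator emulates the survey's statistical skeleton: three
organic-matter sources (defaults span ~6 ‰ in δ¹³C and ~4 ‰ in δ¹⁵N so
the mixing polygon is well-conditioned); three prey guilds as fixed
source mixtures shifted by one TEF step; predators as mixtures of the
guild means (default diet 0.2/0.5/0.3) shifted by a second TEF step;
Gaussian species- (0.5 ‰) and replicate-level (0.3 ‰) noise, three
replicates per species.  Biomass is log-normal (median ≈ 20 kg km⁻²
per species, σ_log = 1) with per-haul occupancy 0.85 and log-normal
haul scatter; the engineered habitat defaults to 8× biomass, the most
species, and six hauls versus three.  Coefficients are drawn in three
energy/accessibility blocks aligned with the guilds (low-energy
accessible, intermediate, high-energy inaccessible).  Juvenile lengths
are log-normal (σ_log = 0.22) truncated at the species maximum; one
dominant species per habitat carries the length mode (5× records,
other species medians scattered ×lognormal(0, 0.10) around the habitat
mode) so the recorded ground-truth modal bin genuinely is the mode of
the generated data — modal lengths are stated as modal-bin midpoints at
2-cm binning (7 inside, 9 outside by default) to keep the planted mode
off bin edges.  `perturb_habitat` applies controlled effects (δ¹⁵N
chain extension, biomass scaling, modal shift) to a single habitat with
ground truth updated, for power and recovery experiments.

What the generator does not emulate: spatial structure within habitats,
temporal variability, gear selectivity, diet variation among predator
individuals, and isotope–biomass correlations beyond the guild
structure.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated model, not robustness to
every pathology of field data.

## Numerical choices and limitations

- Permutation p-values can never be zero (add-one convention); the
  smallest attainable p is 1/(n_perm+1).
- Collinear point sets give SEA = 0 with a degeneracy flag, not an
  error; degenerate hulls make IDiv NaN with a warning.
- Zero-weight species stay in the index geometry but contribute nothing
  to weighted sums; two adjacent zero-weight species make IEve
  undefined.
- The wide community layout and the tab dialect are conveniences; the
  long CSV layout is canonical.  Numeric round-trips hold to 12
  significant digits.
- Default simulation sizes (500 null simulations × 999 permutations for
  calibration checks, 10,000 fuzzed sets for index bounds, 20 consumers
  for mixing recovery) were chosen to bound Monte-Carlo error well below
  the effect sizes being checked while keeping a full validation run in
  minutes on one core.
- The mixing model assumes a global TEF, no concentration dependence
  and no hierarchy across consumers; mobility groups are fitted
  independently.
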