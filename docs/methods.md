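# Methods

## Model and scope

All analyses operate on compartmentalized stoichiometric models under
the standard FBA assumptions: pseudo-steady state (S·v = 0), flux bounds
lb ≤ v ≤ ub, and a linear objective — normally the biomass reaction,
whose flux is the growth rate μ (h⁻¹). Fluxes are in mmol/gDW/h, mass
fractions in g/gDW, molecular weights in g/mmol. Models are plain
`cobra.Model` objects; SBML Level 3 (FBC) and COBRA JSON are the
interchange formats. LP feasibility/optimality tolerance is 1e-9
(GLPK via optlang); equality assertions in tests use 1e-6 absolute
unless a quantity is exact by construction.

Gene–protein-reaction rules are ignored throughout: nothing here uses
them computationally, and transporter GPRs are unreliable in published
reconstructions anyway.

## BOF construction

A composition table (timepoint × component mass fractions, with
metabolite ids, class labels and molecular weights) is converted per
timepoint into stoichiometric coefficients p_i = f_i / MW_i. Components
are screened one by one, in **descending mass-fraction order** — the
screening is order-dependent in principle and no canonical order exists,
so a deterministic one is imposed; the test suite checks that the
exclusion set is stable under input reordering on the synthetic system,
it does not prove it in general. A component is excluded when (a) a
demand reaction for it cannot carry ≥ 1e-6 flux (not producible at
all), or (b) with the partial BOF installed the FBA optimum falls below
1e-9 or the LP turns infeasible. Surviving fractions are rescaled to
sum to 1 g/gDW before coefficient conversion, so every built BOF
satisfies Σ p_i·MW_i = 1 g/gDW to 1e-9; the GAM ATP hydrolysis term
(ATP + H2O → ADP + Pi + H) passes through unrescaled.

Tables with a number of timepoints other than six can be linearly
interpolated onto six relative-time stages (replete 1–2, transition
3–4, deplete 5–6), since culture time courses are compared on relative
rather than absolute time.

In time-course runs, exchanges of nitrogen-containing but carbon-free
species (ammonia/nitrate-style nitrogen sources) are opened to ±1000 so
that composition, not a nitrogen bound, drives the dynamics. The rule
deliberately excludes organic N-carriers: opening an exchange whose
species also carries carbon would remove the carbon limit itself.

## Loopless time course and clustering

Each timepoint's solution is post-processed CycleFreeFlux-style: a
secondary LP minimizes total internal flux at fixed exchanges and fixed
objective, which removes thermodynamically infeasible cycles without
MILP machinery. This is a post-hoc cleanup of one optimum, not a
guarantee that every alternate optimum is loopless.

Flux variation is the **signed** difference v_{r,t} − v_{r,t0}
(baseline t0 by default; consecutive-timepoint differences are a config
option). "Absolute" here means absolute rather than relative units, not
magnitude: after per-reaction standardization a magnitude-only variation
would make monotone up- and down-trends indistinguishable, collapsing
exactly the distinction (rising lipid/carbohydrate synthesis vs falling
protein synthesis) the clustering exists to show. A `magnitude=True`
option computes |Δ| for analyses that only care about the size of a
change.

Rows are standardized with the population SD (÷ n, the common
clustergram convention — a dialect choice); constant rows are dropped,
not divided by zero. Clustering is agglomerative with Euclidean
distance and average (UPGMA) linkage via `scipy.cluster.hierarchy`;
the test suite cross-checks the dendrogram against a naive O(n³)
re-implementation. Row-only standardization is used (no column
standardization).

## Element loads

The load of element e in compartment c is the inbound molar flux over
all transport reactions (reactions whose participants span ≥ 2
compartments): l = max(v_r·γ_{i,r}, 0)·N_i^e for each transported
metabolite i located in c, summed over reactions and metabolites. Only
net-production terms are counted — under pseudo-steady state the mass
balance closes, so inbound flux is the whole story; accumulation cannot
be measured in this framework. For a reversible transporter carrying
negative flux the production side follows sign(v·γ), which makes loads
invariant to the direction convention a transporter happens to be
written in (asserted in tests).

Metabolites without formulas contribute zero load and are reported in a
warning rather than raising: BOF pool pseudo-species routinely lack
formulas, and silently erroring on them would make most published
models unusable. Whether protons and water should count is genuinely
ambiguous (they dominate H and O loads); they are included by default
and excluded with `include_currency=False`.

Carbon/nitrogen loads are "activity"; relative activity is L_t/L_1,
flagged undefined (NaN, never Inf) when the initial load is zero.

## Sensitivity and codependence

S_i is the OLS slope of μ against p_i (intercept fitted, not reported).
For each of 100 hypothetical backgrounds, every other component's mass
fraction is drawn uniformly from its observed range and the vector is
renormalized to mass closure; then the target's fraction sweeps 10
evenly spaced values over its own observed range **without**
renormalizing the others — renormalizing during the sweep would covary
all coefficients and contaminate the partial derivative ∂μ/∂p_i. Ten
grid points balance regression stability against LP count; backgrounds
with fewer than three feasible grid points are skipped and logged.
D_i is the range (max − min) of the 100 slopes. Randomness comes from
one master seed with per-background substreams derived by counter, so
evaluation order cannot change the draws.

On the synthetic system the slope is a secant of the convex curve
μ = U/(base + k_i p_i), so it matches the analytic derivative at the
range midpoint only for narrow ranges (`ToySpec.narrowed`); the 5%
recovery check and the exact rank-order check are run in that regime.
With non-degenerate ranges every S_i depends on the background (μ is a
joint function of all coefficients), so the D_i ≈ 0 check uses frozen
(min = max) ranges for all non-target components — the configuration in
which background-independence provably holds.

## Biosynthetic cost

A_i = ∂r_ATP/∂r_i by finite difference: solve for μ*, **fix** the
biomass flux to 0.95 μ* (equality, not just a lower bound — with a free
upper bound the solver would trade growth for hydrolysis flux), switch
the objective to ATP hydrolysis, record r_base, add a demand for the
metabolite **pinned at exactly δ** (default 1e-4 mmol/gDW/h; pinning
matters for metabolites whose synthesis releases energy, which would
otherwise be overproduced), re-maximize to get r_forced, and report
(r_base − r_forced)/δ in mmol ATP per mmol metabolite. The quotient is
read as a derivative, not a percentage — that is the only reading with
the stated units. Negative costs are legitimate and reported. All
modifications happen inside a model context, so the input model is
unchanged afterwards (asserted bound-for-bound in tests).

NADH/NADPH costs use the same construction with the corresponding
oxidation reaction. ΔG_f values for cost-driver correlations are
user-supplied via TSV; no group-contribution estimation is attempted.

## Near-optimal sampling and regulation calls

The sampler draws from {S·v = 0, lb ≤ v ≤ ub, v_obj ≥ 0.9 μ*} by
hit-and-run in null-space coordinates: v = v0 + N·z with N an
orthonormal basis of null(S) (SVD), so mass balance holds to machine
precision and each chord is bounded by the box constraints alone.
Directions are isotropic in z; each step lands uniformly on the chord
through the current point, whose stationary distribution is uniform on
the polytope. The chain starts at the FBA vertex, discards 1000 warm-up
steps and keeps every thinning-th iterate (default 10). Reversible
reactions are sampled natively in signed form. A fixed seed makes
chains bit-reproducible. Degenerate polytopes (a point, e.g. at
fraction = 1 on the toy) are handled: zero-length chords leave the
point in place.

Isotropic directions were chosen over adaptively centered (ACHR-style)
ones deliberately: on the low-dimensional, strongly coupled polytopes
of small models the adaptive variant is fragile (directions built from
nearly coincident points degenerate numerically), while plain
hit-and-run is provably uniform and mixes quickly — measured integrated
autocorrelation times on the synthetic system are ≈ 1.8 thinned samples
at thinning 10 and ≈ 1.0 at thinning 50.

Regulation between two timepoints: per reaction, one-tailed paired
t tests in both directions (pairing by sample index — what "paired"
can mean across two independent chains is a convention; an unpaired
Welch option exists). Up if p_right < α, down if p_left < α, α = 0.05
per reaction with no multiple-testing correction by default
(Benjamini–Hochberg available). Zero-variance differences are `ns`
with p undefined, except a constant nonzero shift, which is the
strongest possible signal and is called with p = 0. The calls are
antisymmetric under swapping the timepoints (asserted).

Because both tails are tested at α, the expected false-call rate under
identical conditions is α **per direction**. Reactions on a small
polytope are heavily flux-coupled — affine functions of one another —
so their tests are not independent trials: calibration is therefore
checked at the level of coupled groups (reactions whose sample vectors
correlate with |ρ| ≈ 1 act as one test; the default toy has 5 such
groups among 25 variable reactions), pooled over independent chain
pairs, with a cluster-robust 99% t-interval across pairs around the
nominal 5%. Chains for calibration use thinning 100, where samples are
indistinguishable from iid; at the default thinning 10 the paired t is
measurably anti-conservative (≈ 15% per direction on the toy), which
is worth knowing when interpreting single-run call counts.

## The synthetic study system

Three compartments (e/c/m). One substrate (C6H13NO5, glucosamine-like,
0.179 g/mmol) enters e→c at up to U = 10 mmol/gDW/h. Respiration in m
converts substrate + O2 into CO2/H2O/NH3 plus Y = 10 ATP (ADP/Pi/H
imported, ATP exported by an ANT-style antiporter). Four precursors are
polymerized in c, each consuming c_j substrate and a_j ATP per mmol and
retaining m_j substrate units (excess carbon is oxidized, as in
fatty-acid synthesis): protein-like (m=2, c=2, a=8), lipid-like (m=2,
c=4, a=2), carbohydrate-like (m=1, c=1, a=1), nucleotide-like (m=2,
c=2, a=5). Every metabolite carries a formula and every non-boundary
reaction balances elementally (asserted), so loads are computable
exactly. GAM defaults to 0 so the growth closed form stays transparent.

Closed forms, used as oracles throughout:
μ = U / (Σ_j p_j k_j + gam/Y) with k_j = c_j + a_j/Y;
∂μ/∂p_i = −U·k_i/(Σ_j p_j k_j + gam/Y)²; ATP cost A_j = a_j + Y·c_j;
and the full optimal flux vector (hence all element loads) in terms of
μ and the stoichiometry.

The default six-stage trend moves protein 0.55→0.25 g/gDW while lipid
(0.10→0.30) and carbohydrate (0.25→0.35) rise and nucleotides stay at
0.10; columns sum to 1 at every stage. The parameters are chosen so the
starvation phenotype is qualitatively right: lipid is the most
expensive component per gram (so μ falls), yet per-gram ATP demand
falls as protein is replaced (so mitochondrial substrate import, and
with it every mitochondrial element load, declines monotonically);
lipid/carbohydrate synthesis fluxes rise while protein synthesis falls,
giving the clustering and the regulation tests a generator-encoded
truth to recover. An optional two-reaction futile cycle exercises the
loopless post-processing.

What the toy does **not** emulate: kinetics and nutrient-depletion
dynamics between stages, pool degradation (autophagy, chlorosis),
alternative pathways with distinct costs, >3 compartments, and
realistic network degeneracy. Passing tests therefore demonstrate that
each computation is implemented correctly against its mathematical
definition, not that published organism-scale results are reproduced —
the latter would require the published models and composition datasets.

## Problem sizes and defaults

The toy model has 25 reactions (29 metabolites); acceptance checks use
20 random system draws for the FBA oracle, 100 backgrounds × 10 grid
points for sensitivity, 5000 sampler points per chain, 10 independent
chain pairs for t-test calibration, and 6-stage time courses — sizes at
which every oracle (vertex enumeration, brute-force summation, naive
UPGMA) is exact and fast. Pipeline defaults mirror the study
parameters: n_bofs=100, n_grid=10, growth fix 0.95, δ=1e-4,
sampling fraction 0.9, n_samples=5000, α=0.05.
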