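# Methods

## Constraint-based model and FBA conventions

A metabolic model is a set of metabolites (cytosolic or extracellular)
and reactions with signed stoichiometric coefficients; the coefficients
form the stoichiometric matrix **S** (metabolites × reactions). At
steady state production equals consumption for every intracellular
metabolite, S·v = 0, and flux balance analysis maximises (or minimises)
one reaction's flux over that subspace intersected with the per-reaction
bounds lb ≤ v ≤ ub. All fluxes and bounds are in arbitrary units (a.u.);
objective values are comparable within a model, not across models.

Conventions, fixed throughout the package:

* **Exchange reactions** are single-metabolite boundary reactions on an
  extracellular metabolite. Negative flux is uptake, positive is
  secretion. (A single-metabolite drain on a *cytosolic* metabolite —
  a biomass or maintenance sink — is deliberately not an exchange.)
* **Reversibility** is encoded purely by the bounds (reversible ⇔
  lb < 0 < ub); there is no separate flag to fall out of sync.
* **Media**: applying a medium first closes every exchange uptake
  (lb = 0) and opens secretion everywhere (ub = 1000), then opens the
  listed components: non-limiting base components at lb = −1000,
  limited-uptake components (L-threonine, bound 1) at lb = −bound, and
  sugars at lb = −budget/#sugars with a default total budget of
  10 a.u. — the top of the conventional 0–10 uptake-scan range — split
  equimolarly across mixtures. A component with no exchange reaction is
  a structured "no import route" outcome: inside the growth table the
  component is dropped (keeping the remaining sugars' equimolar shares)
  and flagged, the way an untransportable compound simply goes unused in
  a culture; the growth threshold for a yes/no call is 1e-6 a.u., far
  below any growing optimum (~1 a.u. and up on the bundled network).

### Numerics

The LP is solved with scipy's HiGHS interface on the sparse S
(equalities) plus bounds. Solver feasibility is HiGHS's default
(~1e-9); optimal solutions are verified to satisfy |S·v|∞ ≤ 1e-6 and
reported-equality comparisons use 1e-6. Ties among optimal vertices are
not resolved: only the objective value and FVA ranges are contracts, the
flux vector is one representative vertex. FVA fixes the objective via
`v_obj ≥ fraction × optimum − 1e-9`; the slack avoids spurious
infeasibility when the optimum sits exactly on a vertex. Infeasible and
unbounded statuses are reported as such; a numerically failed solve
raises rather than returning a silent zero. No thermodynamic or loop
constraints are imposed — loops show up in FVA ranges, they are not
removed.

## The amino-sugar core network

The bundled fixture network (`make_toy_model(ToyModelSpec(...))`, ~36
reactions) abstracts the organism's catabolism of mucin sugars:

* uptake and activation of glucose/fructose (1 ATP) and of
  GlcNAc/GalNAc (1.5 ATP, covering uptake + phosphorylation);
* the amino-sugar node: GlcNAc6P deacetylase (→ GlcN6P + acetate),
  GlcN6P N-acetyltransferase (acetyl-CoA-dependent), **irreversible**
  NagB deamination GlcN6P → Fru6P + NH₄, UDP-GlcNAc synthesis (1 ATP)
  with a separate no-ATP-return catabolic route back, and the
  reversible UDP-GlcNAc ⇌ UDP-GalNAc 4-epimerase through which GalNAc
  enters;
* lumped glycolysis Fru6P → acetyl-CoA + 2 ATP + 1 NADH, acetate kinase
  (+1 ATP) and a propionate branch consuming 1 NADH — the redox coupling
  forces co-production of both acids, as in a fermentative redox
  balance;
* biomass draining 0.05 UDP-GlcNAc + 0.05 L-threonine + 1 ATP per unit
  flux, plus an ATP maintenance sink.

Two optional elements reproduce the study's counterfactuals: `with_glms`
adds the GlmS amination Fru6P + Gln → GlcN6P + Glu (the uncurated "v1"
state; the shipped JSON curation recipe deletes exactly this reaction),
and `with_glcn_transporter` adds the GlcN exchange, transporter and
kinase that the annotated genome lacks (without it the GlcN exchange
does not exist at all, so GlcN media surface the "no import route"
outcome).

Design notes. The stoichiometric coefficients are fixture constants:
the biology fixes the topology, not the numbers. They were chosen once
so that (i) fermenting any sugar yields net ATP, (ii) a glucose/GlcNAc
mixture out-grows GlcNAc alone (glucose is the cheaper energy source
while the amino sugar is reserved for precursor synthesis), and (iii)
GlcNAc and GalNAc give similar optima; all are overridable through
`ToyModelSpec.yields`. The epimerase is present in both versions because
the uncurated model also grew on GalNAc; the epimerase-addition curation
step is exercised in the unit tests instead. Glutamine appears in the
base medium as a non-limiting component: the network has no nitrogen
assimilation pathway of its own, so the amide donor for the (v1-only)
GlmS reaction must come from the medium. The defined mineral medium it
mimics contains no glutamine — this is a fixture abstraction, not a
claim about the real medium.

## Growth-rate estimation

μ is the slope of ln(OD600) versus time over an automatically selected
exponential window, per replicate, pooled as the across-replicate mean
(SD across replicates reported alongside). The window rule:

1. subtract the blank, drop points below the detection floor
   (OD 0.01 — log of near-zero noise is meaningless);
2. if the curve saturates (max ≥ 2× the starting OD), drop everything
   after the maximum (stationary phase / decline);
3. candidate windows are runs of ≥ 4 consecutive points with OD within
   `window_fold` = 3× of the starting OD, log-linear R² ≥ 0.98,
   positive slope, and a total rise of at least one doubling (the rise
   requirement screens out chance alignments of flat noise); the
   longest qualifying window wins, ties broken by R²;
4. fallback: growth too shallow to ever double (e.g. μ ≈ 0.005 h⁻¹
   over 60 h) cannot satisfy rule 3, so the whole retained curve is
   fitted and accepted iff the slope is positive with one-sided
   p < 1e-3; otherwise the replicate is no-growth with μ = 0;
5. a condition is called no-growth when fewer than half its replicates
   show growth — irreproducible growth is not called.

All parameters are exposed in `GrowthRateConfig`. The estimator is
exact on pure exponentials and scale-invariant (only the absolute
detection floor breaks exact scale invariance, by construction).

**Known bias.** On a logistic culture the log-slope at OD x is
μ(1 − x/K); with inoculum OD 0.02 and capacity 0.5 even the earliest
usable window sits at 4–12% of K, so the window estimate understates μ
by ~5–10%. Narrowing the window reduces this bias but inflates variance
(fewer points); 3× starting OD is the compromise used. Estimates on
saturating synthetic cultures therefore sit systematically a few percent
below the generating μ — well inside the across-replicate SDs reported
for the growth experiments this emulates.

## Enzyme kinetics

The primary estimator mirrors the classical bench procedure: per
replicate, 1/v is regressed on 1/[S] by *unweighted* ordinary least
squares (no weighting scheme is assumed), Km = slope/intercept,
Vmax = 1/intercept; a non-positive intercept marks the fit invalid.
Replicates are fitted separately and pooled (mean, SE = SD/√n) so the
pooled estimate has a spread comparable to a "mean ± SD, n" table.
Because the reciprocal transform amplifies noise at low rates, a
nonlinear least-squares fit of v = Vmax·[S]/(Km + [S]) serves as the
robust cross-check (the test suite asserts the double-reciprocal Km is
the more variable of the two at equal noise). Two-substrate assays fix
the co-substrate at a saturating level (≥ 5× its own Km), making Km for
the varied substrate an apparent constant.

Activator comparisons use Welch's two-sample t-test on replicate-level
Km estimates; "no influence" ⇔ p > 0.05. Two degenerate cases are
defined explicitly (the t statistic is 0/0): identical zero-variance
samples give p = 1, distinct zero-variance samples give p = 0. Absence
of activity on a substrate pair (the glutamine-dependent amination) is
encoded as a one-sided Welch test of assay rates against the no-enzyme
blank.

## Fermentation read-outs

SCFA production is measured endpoint-to-endpoint (final − initial
concentration, floored at 0) and the acetate:propionate ratio taken
directly — matching how molar ratio bands like 1.5:1–2:1 are quoted.
A fermentation with no propionate production returns a structured
undefined-ratio result rather than a number. Consumption rates are the
negative slope of concentration over the depletion phase (from t₀ until
the concentration first falls below 5% of its initial value); the 95%
CI uses the t-distribution (depletion phases are short — a normal
quantile would badly understate slope uncertainty), and two sugars are
"consumed at equal rates" when their CIs overlap.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed), bit-for-bit
reproducible via `numpy.random.default_rng`. Defaults are the study
conditions:

| quantity | default | note |
| --- | --- | --- |
| OD600 curves | logistic-capped exponential, od₀ = 0.02, K = 0.5, 2 h grid over 60 h | multiplicative mean-one log-normal noise, CV 3% |
| fermentations | linear sugar decay to exhaustion, fixed acid yields | additive Gaussian noise, SD = CV × initial sugar, floored at 0 |
| assay rates | 8 concentrations log-spaced over 0.1×–10× Km, triplicate | multiplicative mean-one log-normal noise, CV 5% |
| ground truths | μ: 0.122 / 0.056 / 0.084 / 0.005 h⁻¹ (and flat controls); Km: 5.5 / 41.3 / 2.4 mM; acid yields 1:1, 1.75:1, 1:2 | the measured study values |

Log-normal noise is used for both OD and rates (the positivity it
guarantees keeps the log and reciprocal transforms defined); HPLC-style
concentration noise is additive and floored at zero. What the
generators deliberately do **not** emulate: lag phases, death phases,
instrument drift, heteroscedastic HPLC error, or transcriptional
adaptation between sugars — so passing recovery tests demonstrates the
estimators, not robustness to every pathology of real plate-reader
data.

## Problem sizes and verification

The solver is cross-checked against an independent dense LP formulation
(cobrapy + GLPK) on 100 random networks of ≤ 12 reactions with finite
bounds (statuses must match; optima to 1e-6 relative). Km recovery is
assessed as the median pooled estimate over 200 seeded triplicate
simulations per substrate; the activator null over 1000 seeded
comparisons (n = 3 vs n = 2 replicates, 10% CV); growth-rate recovery
on triplicate curves per condition. The full pipeline is deterministic
under a fixed seed: identical configs produce byte-identical report
bodies, with the config hash recorded in the report's provenance block.

## Limitations

* Growth optima of the bundled core network are in arbitrary units on
  the network's own scale; they reproduce the qualitative growth
  pattern, not the numeric optima of the deposited genome-scale model
  (which is not bundled — `read_model` ingests it when available, and
  the quantitative benchmark test documents the expected values).
* The flux-comparison classification (higher/lower/similar at ±10% of
  the largest across-media midpoint) summarises FVA midpoints; for
  degenerate optima the midpoint of a wide range is a coarse summary.
* The double-reciprocal estimator is kept unweighted by design
  (fidelity to the bench procedure); its statistical fragility is
  documented by the nonlinear cross-check rather than repaired.
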