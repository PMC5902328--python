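# mucimin

Constraint-based minimal-medium design and growth-phenotype analysis for
*Akkermansia muciniphila*.

*A. muciniphila* is a mucin-degrading gut symbiont whose abundance is
inversely associated with metabolic disease. Growing it outside its
mucosal niche on a fully defined medium is a prerequisite for
physiological studies and therapeutic applications — and turns out to
hinge on one missing enzyme: the organism encodes no functional GlmS
(glucosamine-6-phosphate synthase, Fru6P + Gln → GlcN6P + Glu,
EC 2.6.1.16), and its only candidate for the interconversion, the NagB
homologue, works essentially only in the deaminating direction
(GlcN6P → Fru6P + NH₄). Peptidoglycan precursors (UDP-GlcNAc) therefore
cannot be made from plain hexoses: an exogenous amino sugar — GlcNAc or
GalNAc, both abundant in mucin — is required for growth, together with
L-threonine.

This package implements the full in-silico side of that analysis as a
tested pipeline:

* **`mucimin.model`** — metabolic-model data structures, SBML (Level 2/3)
  and TSV-table I/O, validation, curation (edit scripts with replayable
  logs) and model diffing.
* **`mucimin.fba`** — flux balance analysis (maximise c·v subject to
  S·v = 0, lb ≤ v ≤ ub, solved with HiGHS), flux variability analysis at
  a fixed fraction of the optimum, and reaction knockouts.
* **`mucimin.media`** — medium recipes as exchange-reaction bounds
  (secretion open at +1000 a.u.; non-limiting components at −1000;
  L-threonine capped at 1; sugars sharing an equimolar budget of
  10 a.u.), growth prediction across media, nutrient-essentiality and
  uptake scans, and FVA-based flux comparison across substrates.
* **`mucimin.kinetics`** — Km/Vmax estimation by double-reciprocal
  (Lineweaver–Burk) regression pooled over replicates, a nonlinear
  Michaelis–Menten cross-check, and Welch t-tests for activator effects.
* **`mucimin.growth`** — specific growth rates μ (h⁻¹) from OD600 curves
  by exponential-window log-linear regression, SCFA
  (acetate:propionate) production ratios and sugar-consumption rates
  from concentration time series.
* **`mucimin.synth`** — seeded generators for every input: toy metabolic
  networks (including an amino-sugar core network that reproduces the
  GlmS phenotype), logistic growth curves, fermentation time series and
  Michaelis–Menten assay tables.
* **`mucimin.pipeline` / `mucimin` CLI** — one-shot orchestration of
  curation, media simulation, flux comparison and all experiment
  analyses into a deterministic report.

The numbered scripts under `analysis/` walk through the study stage by
stage (curation audit, growth table, flux comparison, growth rates,
SCFA ratios, enzyme kinetics) and write their tables under `results/`.

## Worked example

```python
from mucimin import MediumSpec, predict_growth, make_toy_model, ToyModelSpec
from mucimin.pipeline import packaged_media

media = packaged_media()                      # the six benchmark media
v2 = make_toy_model(ToyModelSpec())           # curated core (no GlmS)
for name in ("glucose", "glcnac", "glcnac_glucose", "galnac"):
    p = predict_growth(v2, media[name])
    print(f"{name:16s} grows={'y' if p.grows else 'n'}  mu={p.mu_au:.2f} a.u.")
```

prints

```
glucose          grows=n  mu=0.00 a.u.
glcnac           grows=y  mu=4.35 a.u.
glcnac_glucose   grows=y  mu=6.52 a.u.
galnac           grows=y  mu=4.55 a.u.
```

— glucose alone supports no biomass because nothing can aminate Fru6P,
GlcNAc and GalNAc restore growth by feeding the UDP-GlcNAc pool
directly, and replacing half the GlcNAc with glucose *increases* the
optimum because glucose is the cheaper energy source while GlcNAc is
reserved for precursor synthesis. Restoring the GlmS reaction
(`ToyModelSpec(with_glms=True)`, the uncurated "v1" state) flips the
glucose row to growth; adding a hypothetical GlcN transporter
(`with_glcn_transporter=True`) is the single change needed for GlcN
media to support growth. Growth optima are in the model's arbitrary
units (a.u.) and are comparable only within a model.

The same session, end to end, from the shell:

```bash
mucimin simulate-media --out growth_table.tsv
mucimin report --seed 1 --out results/report
```

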