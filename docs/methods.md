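# Methods

## Model

`monoperm` treats a Caco-2/MDCK monolayer on a permeable filter support as a
resistance network between a well-mixed donor and acceptor compartment. Each
barrier obeys the homogeneous solubility-diffusion relation
`R = h / (ε K D)` — thickness over (porosity × partition coefficient ×
diffusivity) — and the apparent permeability is the parallel sum of three
serial chains (paracellular, lateral, cytosolic). All internal arithmetic is
CGS (cm, s, g); temperatures in K, potentials in mV; parameters quoted in Å
or μm are converted at the point of use. Logarithms are base 10 throughout.

Assumptions inherited by every prediction:

- **Steady state, passive transport only.** No efflux/uptake transporters,
  no metabolism, no lysosomal trapping. Experimental records with efflux
  ratio ≥ 2 are excluded during curation for that reason.
- **pH partition hypothesis.** All aqueous compartments sit at pH 7.4
  (including the cytosol); only the neutral microspecies crosses lipid, and
  the acid-base interconversion at the membrane surface is instantaneous.
- **Lumped hydrodynamics.** The apical and basal unstirred water layers are
  one resistance, `1/(χ_UWL ν^α)`, shared serially by all three pathways.
  That shared term double-counts the UWL across parallel pathways; it is the
  stated network topology of the model, kept deliberately.

## Parameters that matter

| parameter | default | unit | why this value |
|---|---|---|---|
| `chi_uwl`, `alpha` | 2e-6, 0.6 | cm/s, — | hydrodynamic refit of literature stirring data; reported ranges are 0.57–4.1e-6 and 0.5–1.0 |
| `default_rpm` | 150 | rpm | stirring below 150 rpm is experimentally indistinguishable; unreported speeds default here |
| `eps_over_delta`, `eps_over_delta2` | 0.78, 0.05 | 1/cm | porosity/path-length of the primary (sieved, field-weighted) and secondary (open) tight-junction pore populations; treated as dimensional (1/cm) so the pore permeability comes out in cm/s |
| `r_pore` | 12.9 | Å | typical tight-junction pore radius |
| `delta_phi`, `kappa` | 30, 0.037414 | mV, 1/mV | pore potential drop; κ = F/(N_A k_B T) at 310 K. The tabulated κ is kept as the canonical default; `derived_kappa()` recomputes it from CODATA constants (0.037434, identical to 3 s.f.) |
| `eta` | 0.6913e-3 | N·s/m² | *dynamic* viscosity of water at 37 °C — the hydrodynamic radius must use dynamic, not kinematic, viscosity |
| `h_cytosol` | 15e-4 | cm | sphere-equivalent cell diameter from averaged MDCK/Caco-2 cell volumes |
| `cytosol_d_factor` | 0.25 | — | cytosolic crowding slows diffusion to a quarter of the pure-water value |
| `h_filter`, `eps_filter` | 10e-4, 0.13 | cm, — | translucent polycarbonate filter; clear filters would be 0.05 |
| `h_membrane`, `h_hexlike` | 55, 15 | Å | full bilayer height (lateral geometry) vs the alkane-like inner slab that carries the transmembrane resistance |
| `microvilli_factor` | 24 | — | apical surface amplification; applied unconditionally — for lipophiles the ABL dominates anyway, so any P_m overestimate is inconsequential |
| `ionized_cutoff` | 1e-4 | — | neutral fractions below 0.01% are treated as zero (the resolution limit of standard pKa/microspecies predictors) |
| `default_d_lateral` | 1e-8 | cm²/s | no per-chemical model for lateral membrane diffusion exists; 1e-8 cm²/s is the typical FRAP-scale lateral diffusivity of small membrane-bound solutes. Supplied per chemical when known; `lateral_enabled: false` removes the pathway entirely (its contribution is negligible for almost all chemicals, so disabling it is a defensible simplification) |

## Numerical choices and edge cases

- **Infinite resistances are literal `inf`**, not sentinels, so closed
  pathways (fully ionized → no transmembrane or lateral route;
  zwitterion-dominated → membrane blocked) drop out of the conductance sum
  exactly. A chemical with all three pathways closed raises an error.
- **Renkin sieving is clamped to 0 for r_hydr ≥ r_pore**; the polynomial is
  non-physical beyond full occlusion. On [0, 1) it is evaluated as printed
  (coefficients 2.104, 2.09, 0.95).
- **Field weights use `expm1`** so the Δφ → 0 limit of `x/(1−e^(−x))`
  is accurate to machine precision (naive evaluation loses ~6 digits at
  μV-scale potentials).
- **Speciation clamping** below the 1e-4 cutoff redistributes the residual
  neutral mass proportionally over *all* nonzero non-neutral fractions,
  zwitterion included — a near-pure zwitterion has no charged fraction that
  could receive it. The operation is idempotent and mass-conserving to 1e-9.
- **Zwitterion rule**: the zwitterionic fraction counts as neutral in the
  pore-field factor but contributes nothing to transmembrane or lateral
  flux; when it exceeds the genuine neutral fraction the membrane resistance
  is set to infinity (zwitterionic amino acids permeate bilayers like alkali
  ions, ~10⁻¹²–10⁻¹⁴ cm/s).
- **Route classification ties** (measure-zero, but tests need determinism)
  resolve in the order cytosolic > paracellular > lateral.
- **R²** defaults to squared Pearson correlation; `r2_kind="cod"` gives the
  coefficient of determination 1 − SS_res/SS_tot for users who want offset
  sensitivity.
- **Monotonicity caveat**: P_app is provably non-decreasing in K_hexw,
  K_lipw, stirring and each diffusivity, and in f_neutral *when the
  complement is anionic*. A cationic complement is accelerated through the
  negatively lined pore (E > 1), so raising the neutral fraction at a
  cation's expense can lower the paracellular conductance faster than it
  opens the membrane route — the property tests state the invariant in its
  correct (anion-complement) form.

## Curation and evaluation protocol

Literature records are curated in three steps: (1) drop efflux ratio ≥ 2;
(2) average replicates (including both transport directions) as arithmetic
means of **linear-scale** P_app within each source, then pool the per-source
means across sources and cell lines; (3) key the result by (chemical,
effective stirring speed), where reported speeds ≥ 150 rpm stay separate
modelling conditions and everything milder pools at the 150 rpm default. The
procedure is idempotent. An optional exclusion list handles chemicals whose
predicted speciation is known to be unreliable.

The BLM protocol evaluates the membrane submodel in isolation against
black-lipid-membrane permeabilities of neutral species: molecules under
50 g/mol are excluded (their permeation reflects polymer-like membrane
behaviour the liquid-hydrocarbon slab cannot represent), predictions are the
exact log-linear form `log P_m = log K_hexw + log D_hex − log h_hexlike`,
and RMSE/R² are reported over the survivors.

## Synthetic data: what it does and does not show

`generate_chemicals(n, seed)` emulates the statistical structure of a
curated monolayer compilation: MW uniform on [50, 800] g/mol, log K_hexw on
[−8, 4], log K_lipw on [−1, 6], aqueous diffusivity on an MW^−0.45 power law
around 7e-6 cm²/s with 0.1-log-unit scatter, hexadecane diffusivity 0.3–1×
the aqueous value, and speciation drawn from the six-species simplex with
explicit mass at the pure-ion and pure-zwitterion corners. Four corner
chemicals (pure cation, pure zwitterion, neutral lipophile, neutral
hydrophile) are always injected so every classification branch is exercised.
`generate_pseudo_experiment` runs the forward model and perturbs log P_app
with Gaussian noise (0.3 log units by default, the scale of within-source
replicate scatter in real compilations).

Descriptors are sampled **independently** — no covariance between size,
lipophilicity and charge, and no real structures — so passing the closure
tests (RMSE → 0 at zero noise; recovered RMSE tracks injected noise within
10% at n = 500) demonstrates internal consistency of the
generate → predict → curate → score pipeline, *not* predictive accuracy on
real chemicals. The published dataset-level statistics require the original
per-chemical descriptor table, which this package does not ship; the test
suite instead pins the model to its closed-form constants (φ ≈ 682,
h_lateral ≈ 24 μm, κ to 3 s.f.), to hand-derived reference values for every
individual resistance, and to the published pathway totals of the three
lateral-dominant chemicals, which must recombine into the published
log P_app via the parallel-conductance sum.

Problem sizes in the default test run (n ≤ 1000 synthetic chemicals,
200-sample property sweeps) keep the whole suite around a few seconds while
still giving the Monte-Carlo noise-recovery check ~1% sampling error.

## Known limitations

- No pKa/microspecies prediction: speciation fractions are inputs.
- No estimation of K_hexw, K_lipw, D_aq, D_hex from structure; all are
  consumed as descriptor columns.
- The UWL is solute-size independent and shared across parallel pathways.
- The secondary pore population is neither size- nor charge-selective, as
  the pore model is written.
- D_lateral has no mechanistic submodel; the lateral route exists mainly to
  show it rarely matters.
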