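# Methods

## Model

`actocap` simulates dendritic actin network growth at a membrane as a system
of consecutive elementary reactions between five actors: polymerization-
competent G-actin (profilin-loaded; pointed-end dynamics and spontaneous
bulk nucleation are suppressed by profilin and therefore absent from the
model), membrane-tethered VCA, the Arp2/3 complex, free barbed ends B, and
capping protein CP.

    r1  VCA + G        → VCA·G                 k_bind_VG [µM⁻¹s⁻¹]
    r2  VCA·G + Arp    → Arp* + VCA_spent + G  k_act     [µM⁻¹s⁻¹]
    r3  Arp*           → B                     k_seed · s(G) (de novo)
    r4  Arp* + B       → 2B                    k_branch · s(G)
    r5  B: G → P                               k_elong (G − c_crit) per end
    r6  B + CP         → B_capped              k_cap     [µM⁻¹s⁻¹]
    r7  VCA_spent      → VCA                   k_regen   [s⁻¹]

Membrane species (the VCA states, Arp*, B, B_capped) are areal densities in
µm⁻²; bulk pools (G, polymerized actin P, inactive Arp2/3, free CP) are
concentrations in µM. The two are coupled by the vesicle surface-to-volume
ratio (1 µm⁻² ≡ A/(V·602.2) µM) and, for reactions between two membrane
species (branching), by a reaction-shell thickness h that converts the 3D
rate constant into a 2D one: k₂D = k₃D/(602.2·h). Confinement in a thin
shell concentrates the reactants, which is why membrane-localized branching
can ignite while solution branching stays subcritical.

Two refinements of the literal reaction list:

* **s(G) = (G−c_crit)₊/(K_nuc + (G−c_crit)₊)** gates both nucleation
  channels (r3, r4) on monomer availability: a seed or a branch incorporates
  a first subunit, so nucleation must stop when the pool reaches the
  critical concentration. Without this gate, branching would keep
  converting Arp* into (non-growing) ends after monomer exhaustion, which
  both violates mass-action common sense and freezes spurious spatial
  patterns into starved domains.
* **eta_seed_membrane** scales k_seed for membrane-tethered Arp*
  (default 10⁻⁵). De novo nucleation by activated Arp2/3 without a mother
  filament is inefficient, and a VCA-tethered, membrane-oriented complex is
  further constrained; in solution the same pathway is the productive one
  (it is what starts pyrene-assay polymerization). Mechanistically this is
  one rate constant observed in two environments. It is also structurally
  necessary: with full-strength membrane seeding, the spatially uniform
  Arp* ramp self-ignites the entire membrane nearly simultaneously and no
  CP-dependent radial pattern can form.

On activation (r2) the VCA-bound monomer is released back to the pool, so
the actin conservation law is exactly A_tot = G + P + conv·VCA·G. The other
invariants are CP_tot = CP_free + conv·B_capped (capping is stoichiometric),
VCA_tot = VCA_free + VCA·G + VCA_spent, and Arp_tot = Arp_inactive +
conv·(Arp* + B + B_capped) — every end carries the Arp2/3 that made it.

### Dynamical regimes

Activation is slow (k_act·Arp ≈ 6×10⁻⁴ s⁻¹ per VCA·G), so Arp* accumulates
as a quasi-uniform stock. Branching is autocatalytic: once k₂D·s(G)·Arp*
exceeds k_cap·CP, any barbed ends present amplify exponentially, burning the
stock in a burst; capping then relaxes B toward the activation-limited level
J/(k_cap·CP). This produces the four growth regimes (seeding, initial rapid
growth, transient, steady state), the CP-ordered steady states (B_ss
decreasing, unconsumed Arp* increasing with CP), and — under finite pools —
a transient barbed-end maximum above the final level, most pronounced at
high CP where the ignition threshold is higher and the accumulated stock
larger.

A deliberate consequence of slow activation: total end creation over a run
stays comparable to the CP budget (CP_tot in areal equivalents is only
120–360 µm⁻² at 40–120 nM against an Arp2/3 pool of ~900 µm⁻²), which is
what keeps the peak barbed-end density below the ~450 µm⁻² ceiling of this
low-VCA-density regime. Fast activation would inevitably convert the whole
Arp2/3 pool into ends, overwhelm the CP budget, and break both the density
ceiling and the transient-overshoot phenomenology.

## Spatial model

One actin domain is resolved on a radially symmetric annular finite-volume
grid (default r_max = 5 µm, 128 cells, half-open cells, no-flux boundaries);
the six membrane fields react locally and diffuse laterally; the bulk pools
are well-stirred and global (3D diffusion treated as fast). Barbed ends
random-walk with D_B = alpha_spread · v_pol · ell_step, proportional to the
local polymerization speed v_pol = k_elong(G−c_crit)δ, with step length
ell_step of order a filament length. The initial state is uniform
membrane-loaded VCA plus a seeded disc of barbed ends (20 µm⁻² within
0.2 µm) representing the first nucleation site. Method of lines with a
sparse-Jacobian BDF integrator; global conservation is checked to 1e-5
relative at every output time and self-convergence under grid refinement
(128→256 cells) is below 1%.

The CP-dependent patterns emerge as follows:

* **40 nM** — low ignition threshold, weak capping: the domain ignites
  early, the growth front crosses the patch quickly, and capping-limited
  relaxation equalizes every radius; the profile is flat well within 40 s.
* **80 nM** — the front moves into territory whose Arp* stock has kept
  accumulating (nothing consumed it there), so the rim burns a larger
  stock than the centre did, while the centre has already relaxed to the
  low sustained level: a propagating rim wave, i.e. a double-peaked radial
  profile. The pattern is a transient of the growth process; once the wave
  has crossed and the stock is spent, sustained activation flattens the
  profile. The canonical pattern run therefore ends at 25 s, during
  spreading, and classifies its final profile (rim/centre ratio threshold
  1.5; calibrated ratios 1.17 / 1.95 / 0.21 at 40 / 80 / 120 nM).
* **120 nM** — nucleation at many sites partitions the pools:
  `domain_competition` divides the depleting pools (actin, Arp2/3) by the
  domain count (default 6 at ≥100 nM). CP is deliberately not divided: it
  is an intensive concentration common to every domain, and dividing it
  would weaken capping exactly where it must be strongest. The starved
  domain barely grows (s(G) small, v_pol small), stays confined and flat.

## Morphology mapping

In the tension-dominated, low-density regime the membrane load F_mem per
area is shared by the local ends, giving the ratchet law
v(B) = v_free·exp(−F_mem δ/(B k_BT)) with v(0)=0, strictly increasing in B
and saturating at v_free. Classification is deterministic: concave if the
rim grows >1.5× faster than the centre, else protrusion if the mean speed
exceeds 10% of the unloaded speed at the reference 3 µM pool, else flat.
The speed threshold is referenced to the 3 µM v_free (not the run's own
depleted v_free) so that starved domains are called flat. F_mem = 15 pN/µm²
spans v from ~0 to ~89 nm/s over B ∈ (0, 450] µm⁻².

## Bulk (pyrene-like) assay

Solution mode runs the same network with every species a bulk concentration
(conv = 1, full-strength seeding) and reports the polymerized fraction
P(t)/A_tot — a linear stand-in for pyrene fluorescence, with optional
seeded Gaussian observation noise. The lag time uses the tangent method:
Savitzky–Golay smoothing, tangent at the maximal slope, intersection with
f = 0 (exact on a logistic: t_lag = t0 − 2/k). The lag is governed by the
time for the Arp* stock to carry branching past the capping threshold
k_cap·CP, hence increases nearly linearly with CP while the maximal rate
decreases — the observed supplementary-assay trend.

## Calibration (frozen defaults)

Fixed from standard actin biochemistry: k_elong = 11.6 µM⁻¹s⁻¹,
k_cap = 3 µM⁻¹s⁻¹, c_crit = 0.1 µM, δ = 2.7 nm, k_BT = 4.116 pN·nm (25 °C).
The free constants were calibrated once against three anchors — bulk lag
1.5 ± 0.3 min at 20 nM CP, flat 40 nM radial profile by 40 s, peak density
≤ 450 µm⁻² — plus the qualitative regime structure (overshoot at high CP,
flat/double/flat patterns), and then frozen:

| parameter | default | role |
|---|---|---|
| k_bind_VG | 1.0 µM⁻¹s⁻¹ | VCA·G loading, effectively instantaneous |
| k_act | 2×10⁻³ µM⁻¹s⁻¹ | slow activation; sets the Arp* supply J |
| k_seed | 2×10⁻⁴ s⁻¹ | solution seeding; sets bulk take-off |
| k_branch | 10 µM⁻¹s⁻¹ | autocatalysis; with k_cap·CP sets lag & threshold |
| k_regen | 10⁻⁴ s⁻¹ | slow VCA recycling; sets late steady levels |
| shell h | 0.08 µm | membrane branching enhancement (k₂D = k₃D/602.2h) |
| eta_seed_membrane | 10⁻⁵ | membrane de novo seeding suppression |
| K_nuc_G | 0.3 µM | monomer gating of nucleation |
| alpha_spread, ell_step | 0.45, 0.3 µm | barbed-end walk, D_B ≈ 0.012 µm²/s |
| D_VCA, D_Arp* | 0.5, 0.2 µm²/s | lateral membrane mobilities |
| N_domains (≥100 nM) | 6 | pool partition at high CP |
| F_mem | 15 pN/µm² | membrane load per area |

With these defaults the package computes: bulk lag 1.63 min at 20 nM CP;
40 nM flatness at 26 s; maximal barbed-end density ~25 µm⁻² across all
default runs (well under the 450 µm⁻² ceiling); steady-state B of
0.65/0.32/0.22 µm⁻² and Arp* of 0.64/1.28/1.91 µm⁻² at 40/80/120 nM.

## Synthetic vesicle ensembles

The generator emulates the experimental variability structure: radii uniform
in 10–25 µm; encapsulated CP multiplied by lognormal noise (σ = 0.15);
nucleation-seed counts Poisson with mean λ(CP) = max(0.2, −1.3 + 0.06·CP/nM)
(≈1 at 40 nM, ≈6 at 120 nM — nucleation at more sites as CP rises). Labels
are exclusive per vesicle: CP ≥ 150 nM → volume-spanning network
(seeding outcompetes membrane growth); ≥6 seeds → closed cortex of packed
domains; 0 seeds → homogeneous cortex; otherwise the domain model is run
with the vesicle's pools shared across its seeds and the ratchet classifier
applied. A surrogate mode precomputes labels on a (CP, seed-count) grid for
large ensembles. Fractions are reported with Wilson intervals.

What the generator does **not** emulate: myosin-driven contraction and
fission, encapsulation artifacts, membrane mechanics, or the paper-level
vesicle percentages (which depend on those unmodelled factors). A green
ensemble test therefore establishes the qualitative ordering (protrusions
most frequent at 40 nM; protrusion-labelled vesicles have fewer seeds), not
quantitative fractions.

## Numerical choices

* Well-mixed: LSODA, rtol 1e-8 / atol 1e-10; conservation enforced to 1e-6
  relative (zero-total laws judged against 1% of the system scale).
  Species are clamped at zero inside rate laws so solver-scale negative
  excursions cannot feed back; net elongation is signed (depolymerization
  above c_crit in reverse) but cannot draw on an empty polymer pool.
* Steady states: long relaxation (20× the slowest timescale) followed by a
  Newton polish in which the redundant VCA balance is replaced by the VCA
  conservation law (the unpolished Jacobian is singular). P and B_capped
  are cumulative counters, excluded from the fixed-point criterion.
* Phase detection: seeding ends when B exceeds 1% of its maximum, initial
  growth at max dB/dt, transient when |dB/dt| falls below 1% of the peak
  rate; boundaries are clipped to keep the ordering invariant for curves
  (e.g. pure saturations) whose maximal slope precedes the seed threshold.
* Spatial: BDF with analytic Jacobian sparsity (local 6×6 blocks +
  diffusion tridiagonals + dense bulk coupling), rtol 1e-6 / atol 1e-9.
* Flatness: CV over the full disc out to the 5%-of-peak support radius
  (interior holes count — a hollow ring is never flat), outermost 10%
  excluded, support required beyond half the patch radius.
* Stochastic oracle: Gillespie direct method on molecule counts; the ODE is
  its exact mean-field limit by construction. At small copy numbers the
  polymerized fraction acquires a real O(1/N) bias once monomer depletion
  correlates with end-count fluctuations; oracle comparisons therefore use
  horizons on which the pool stays far from depletion.

## Known limitations

* The rim pattern at 80 nM is transient (by design and by the model's
  logic); the package classifies patterns at the 25-s spreading snapshot.
  A model with local activator exhaustion (e.g. spatially resolved bulk
  diffusion) might sustain it longer.
* Bulk G is well-stirred; monomer gradients along the membrane are not
  represented, so steering effects of local depletion are out of reach.
* No filament-level structure (lengths, 70° branch angles, orientation),
  no membrane mechanics: morphology calls are kinetic classifications, not
  computed curvatures.
* The seven-reaction network is a reconstruction from the described
  biochemistry; all non-textbook rate constants are calibrated effective
  parameters, not measurements.
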