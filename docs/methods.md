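# Methods

## The physical problem

Photolyases repair UV-damaged DNA using light energy captured by an FAD
cofactor, which must be in its fully reduced FADH⁻ state to be
catalytically active. Isolated enzymes usually carry oxidized flavin
(FAD_ox), which is re-reduced photochemically: the excited flavin abstracts
an electron from a chain of tryptophan (and auxiliary tyrosine) residues,
producing a flavin-anion / protein-radical pair whose fate — deprotonation,
charge recombination, scavenging, protonation of FAD˙⁻ to FADH˙ — is
followed by transient absorption (ΔA) spectroscopy from picoseconds to
seconds. `photokin` implements the complete quantitative analysis chain
for such data on a class II CPD photolyase: a first-order kinetic network
of the photocycle, Beer–Lambert synthesis of multi-wavelength ΔA traces
under three instrument regimes, global multiexponential fitting with
shared lifetimes, decomposition of amplitude spectra onto radical-pair
difference spectra, and relative-actinometry quantum yields.

## Kinetic model

The photocycle is a linear network, dp/dt = K·p, solved exactly through the
eigendecomposition of the rate matrix (a scaling-and-squaring matrix
exponential is the fallback for defective matrices). The wild-type preset
encodes:

* an excited/formation state that branches 65:35 into the primary
  FAD˙⁻ Trp388H˙⁺ pair versus direct decay, with a lumped hopping time of
  2 ps — hole migration along the Trp381–Trp360–Trp388 triad is not
  resolved by any of the instrument regimes (each hop is bounded above by
  ~100 ps, homolog per-step transfers are 0.8–30 ps), so the lumped step
  is made delta-like relative to the 200 ps response; any other value can
  be supplied via `tau_hop`;
* deprotonation of the distal TrpH˙⁺ (85 %) in competition with pair
  recombination (15 %), realizing the observed 350 ps phase; the intrinsic
  channel constants follow as 350 ps/0.85 ≈ 0.4 ns and 350 ps/0.15 ≈ 2.3 ns;
* effective 300 μs FAD˙⁻Trp˙ recombination in parallel with 1 ms oxidation
  of the auxiliary Tyr345 (the observed fast phase is their parallel
  combination, ≈ 231 μs), followed by 1.1 ms FAD˙⁻Tyr˙ recombination.
  The thermal Trp˙ ⇌ TrpH˙⁺ reprotonation equilibrium behind the tyrosine
  oxidation is represented only through these effective constants; the
  microscopic equilibrium is not modelled.

Mutant/condition presets: `WT_D2O` (fast phase slowed to 800 ps, KIE 2.3),
`W388F` (1.2 ns pair recombination vs 10–20 ns side electron transfer from
a tyrosine, 2.7 ms tyrosyl-pair recombination; the primary-pair formation
yield 0.54 is fixed once by dividing the 4 % end yield by the branching
fraction at the 15 ns default), `E387Q` (static 10:1 two-subpopulation
model of the biphasic 400 ps / 3 ns TrpH˙⁺ decay), `Y345F` (no tyrosine
channel; the printed 250 μs decay is stored directly rather than the
300 μs value implied by removing the tyrosine path from the wild-type
scheme — the two differ by ~20 %, a discrepancy the source data leave
unresolved), and `WT_cysteine(c)` (scavenging of Trp˙/Tyr˙ at
k₂·c with k₂ = 1×10⁵ M⁻¹ s⁻¹ — a free proportionality chosen at the
typical order of thiol–radical reactions, as only the acceleration is
documented — followed by FAD˙⁻ protonation at 630 ms, with a 15 %
fast-protonating subpopulation at 2.2 ms modelled as static heterogeneity).

Internal time unit is the SI second; configs and CLI accept/print
ps/ns/μs/ms/s.

## Spectra

Species spectra (FAD_ox, FAD˙⁻, FADH˙, TrpH˙⁺, Trp˙, Tyr˙, e⁻_aq, and the
Ru(bpy)₃²⁺ actinometry reference) are Gaussian-band stand-ins on a 1 nm
grid (340–740 nm), corrected by an exact linear solve of narrow Gaussian
bumps so that every quantitatively known ε value ("anchor") is honoured to
machine precision — e.g. ε₄₅₇ = 4740 (FAD˙⁻, taken from the insect
cryptochrome spectrum since the in-protein spectrum is unavailable — a
known accuracy caveat recorded in the table metadata), 940 (Trp˙), 9205
(FAD_ox), 150 (Tyr˙), ε₄₇₀ = 9460/10128 (FAD_ox/Ru), ε_max = 11300
(FAD_ox, 445 nm) and ≈18000 (e⁻_aq, 720 nm). Every number used by the
quantitative analysis flows through anchors; the band shapes between
anchors are qualitative (the reference curves exist only as figures) and
are declared non-authoritative. FAD_ox is rolled off to exactly zero above
505 nm. A weak FAD˙⁻ red tail (>550 nm), the tentative explanation for
small residual red signals, can be switched on
(`default_registry(fad_anion_red_tail=True)`); default off.

Difference spectra are exact signed sums of species tables; the
partial-photoreduction unmixer recovers an unknown component as
(mixture − f·known)/(1 − f) with negative clipping reported.

## Synthetic data

`generate_dataset` composes ΔA(λ, t) = c·d·Σ_s p_s(t)·Δε_s(λ) from the
scheme's exact multi-exponential solution, convolves each component
analytically with a Gaussian instrument response (the overflow-safe erfcx
form of exp⊗Gaussian), and adds i.i.d. Gaussian noise. Regime defaults:
200 ps / 5 ns / 30 μs response FWHM for the ps–ns, ns–μs and ms–s setups;
log-spaced grids of 10 ps–20 ns, 1 ns–80 μs, and 10 μs to five times the
scheme's slowest time constant; default pair concentration 6.5 μM over a
1 cm probe path (giving the published ~0.02 bleach at 457 nm). "1 % noise"
means σ = 0.01 × peak |ΔA| of the clean trace set. The hydrated-electron
artifact adds an e⁻_aq component at a given fraction of the radical-pair
*concentration* (the "x %" notation is ambiguous between concentration and
amplitude conventions; the concentration convention is chosen and can be
overridden by scaling the fraction) decaying with τ = 300 ns, a
representative lifetime in air-saturated protein solution — long enough to
contaminate ps–ns UV-excited data, short enough to be absent past the
response of the ms–s setup.

What the generator does *not* emulate: excitation-energy→population
conversion (pair concentration is specified directly), fluorescence and
coherent artifacts around t = 0, detector bandwidth beyond the Gaussian
response, probe-light actinic effects, correlated/1-f noise. Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated noise model, not robustness to every artifact of real traces.

## Global fitting

Shared lifetimes across wavelengths, per-wavelength amplitudes and
optional offsets, unweighted least squares. The amplitudes are linear
given the lifetimes, so the fit uses variable projection: Levenberg–
Marquardt iterates on log τ only, with amplitudes projected out exactly at
each step. Initialization is a deterministic multi-start (log-spaced τ
grid over the data span, best candidates refined, plus two seeded jitter
starts); components are reported in ascending τ. Wavelength columns are
internally sorted into canonical order so results are bitwise invariant
under input permutations. With an IRF FWHM the basis is the convolved
exponential (and a convolved step for the offset); without one, plain
exponentials are fitted and points before 1.5× the recorded response FWHM
are excluded, matching the practice of fitting post-response windows and
extrapolating amplitudes to t → 0 (the t → 0 spectrum is the sum of
component amplitudes, offsets excluded; a per-component spectrum is also
available). τ standard errors come from the variable-projection Jacobian
(approximate: amplitude uncertainty is conditioned on τ). Non-convergence
and degenerate (constant) data are reported through flags, never raised.
Model comparison reports the RMSD ratio; the verdict is "substantial" only
when the richer model improves RMSD by more than 5 % (default).

Noiseless ms-regime data are exactly in the fitted model class and are
recovered to 1e-6 relative. On ps/ns data the unresolved 2 ps formation
step is not in a monoexponential model class; the induced bias is ~3 %,
far inside the 10 % recovery tolerance at 1 % noise.

## Quantum yields

Relative actinometry against the Ru(bpy)₃²⁺ ³MLCT reference (Φ = 1):

    Φ = Φ_ref · [ΔA_s/(Δε_s·f_s)] / [ΔA_ref/(Δε_ref·f_ref)],
    f = 1 − 10^(−ε₄₇₀·c·d)

with d = 0.2 cm the excitation path (sample and reference share the probe
geometry, so probe-path factors cancel). The formula is validated by
reproducing both published yields from the printed inputs: 3.668 % → 3.7 %
(W388F) exactly at the printed precision, and 55.51 % vs 55.4 % (WT) — the
printed ΔA inputs carry two significant figures (±0.7 points on Φ), so the
0.1-point difference reflects rounding of the published inputs, not the
formula. Yields outside [0, 1.05] trigger a plausibility warning.
Amplitude-spectrum decomposition is linear least squares onto candidate
difference spectra (optionally with an e⁻_aq column), unconstrained by
default because amplitude spectra are signed, with a non-negativity option
(NNLS) for concentration-scale work and a collinearity warning from the
design-matrix SVD.

## Numerical choices and degenerate inputs

* Eigen-solution validated by reconstruction; matrix-exponential fallback.
* Populations clipped of ±1e-13 algebraic excursions; conservation holds
  to 1e-9 on all presets.
* exp⊗Gaussian evaluated as ½·erfcx((kσ − t/σ)/√2)·e^(−t²/2σ²), switching
  to the pure-exponential tail form where erfcx would overflow
  (argument < −25); the two branches agree to 1e-10 at the seam.
* Component ordering ascending in τ; ties broken by the stable sort.
* Anchor corrections use σ = 8 nm Gaussians solved exactly at the anchor
  wavelengths; unsatisfiable (negative-ε) anchors raise with the anchor
  named.
* TSV formats round-trip bit-exactly (`%.17g` writing,
  `float_precision="round_trip"` parsing).
* One run seed fans out to per-stage seeds via SHA-256 of "seed/stage"
  (mod 2³¹), so any stage can be reproduced in isolation.

## Problem sizes

Synthetic datasets use 200–300 time points per trace and 3–7 wavelengths
— matching the information content of the published figures while keeping
every fit in the sub-second range; recovery tolerances are quoted at these
sizes.

## Known limitations

* Spectral stand-ins are qualitative between anchors; decomposition
  rankings on synthetic data exercise the logic, not the true band shapes.
* No target analysis (direct rate-matrix fitting) — the pipeline is
  simulate → exponential fit → assign, as in the original analysis.
* No Marcus-theory rates, temperature/pH dependence, or explicit
  water-cluster proton-transfer modelling; the Grotthuss-type deprotonation
  pathway enters only through its observed rate and isotope effect.
* The cysteine-scavenging proportionality and the exact composition of the
  partial-photoreduction mixture behind the FADH˙ spectrum construction
  are free parameters of the emulation.
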