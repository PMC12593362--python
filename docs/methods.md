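# Methods

`synsplice` implements the quantitative machinery for studying how the
monomer conformation of α-synuclein (αSyn) splice variants relates to
their amyloid-formation kinetics.  The SNCA gene's cassette exons 3
(canonical residues 41–54) and 5 (residues 103–130) can be skipped,
producing αSynΔ3 (126 aa), αSynΔ5 (112 aa) and αSynΔ3Δ5 (98 aa)
alongside the 140-residue full-length protein.  Exon 5 carries ten of
the acidic C-terminal domain's negative charges, so its loss reshapes
the long-range electrostatics of the monomer; the package quantifies
the consequences on both sides — fibril-formation kinetics (ThT
fluorescence, seeded assays, pelleting, Taylor dispersion) and monomer
conformational ensembles (coarse-grained simulation) — and correlates
them.

## Sequence frame

All variants are generated by deleting exon-encoded segments from an
embedded canonical 140-residue sequence; every variant carries a
strictly increasing map from its own positions to canonical numbering,
and all reported residue indices are canonical (1–140).  Cross-variant
residue-pair analyses use only pairs whose members are present in every
variant **and** lie in the same contiguous common block (1–40, 55–102,
131–140 for the four isoforms): a pair straddling a potentially
spliced-out region changes meaning between variants and is masked.
This yields C(40,2)+C(48,2)+C(10,2) = 1953 pairs for the four-variant
set.  Extinction coefficients use the Pace rule (1490·nTyr + 5500·nTrp
+ 125·n_cystine M⁻¹cm⁻¹), which gives 5960 for the exon-5-containing
and 4470 for the exon-5-deleted variants (4 vs 3 tyrosines, no
tryptophan or cysteine).

## ThT kinetics

Normalised fibril-mass curves are fitted with the empirical
growth model

    y(t) = 1 − [1 + λ²/(2κ²θ)·e^{κt}]^{−θ},   0 ≤ θ ≤ 3,

where λ (h⁻¹) aggregates the primary pathway (primary nucleation +
elongation), κ (h⁻¹) the secondary pathway (secondary processes +
elongation), and θ is a shape parameter fitted once per replicate group
(per variant and buffer series) while λ and κ are per-replicate.  Only
data up to each trace's maximum are fitted, which protects the fit from
plateau-phase signal loss (flocculation, prominent for the
exon-5-deleted variants).  The optimiser is trust-region-reflective
bound-constrained least squares with a small multistart over λ
(10⁻³–10⁻¹ h⁻¹); κ is initialised from the steepest slope of the
log-signal, which approximates the exponential-growth rate.  T50 is the
time of the *first sample* at or above half-maximal signal — no
interpolation — and the concentration dependence T50 = a·c^γ is fitted
by nonlinear least squares with the log–log slope reported as a
cross-check.  Pelleting densitometry reduces to
100·(1 − D_sol/D_whole), clipped to [0, 100] with a warning.

## Ionic-strength models of the secondary pathway

Buffer recipes reduce to ionic strength I = ½Σcᵢzᵢ² with phosphate
speciated between H₂PO₄⁻/HPO₄²⁻ by Henderson–Hasselbalch on pKa2 and
Na⁺ fixed by electroneutrality.  pKa2 = 7.0 was chosen because it
reproduces the 49 mM convention for 20 mM sodium phosphate at pH 7.4
to the nearest mM; thermodynamic pKa2 ≈ 7.2 with activity corrections
lands in the same place, but the speciation here is deliberately the
simplest model consistent with that anchor.

Two Debye–Hückel-motivated single-process models describe κ(I):

* Free Energy Barrier (FEB): κ = κ_sat·(κ0/κ_sat)^(2^(−I/I_mid)) —
  ions screen an unfavourable electrostatic term in the barrier for
  templated conversion, so κ saturates at high I;
* Brønsted–Bjerrum (BB): κ = κ0·2^(I/I₂) — ions stabilise a
  pre-nucleation intermediate, with no saturation.

Fits are Levenberg–Marquardt least squares; model selection uses
AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1) (Gaussian-residual form).
A deliberate design point: with a single mean κ per ionic strength
(n = 6) the small-sample AICc penalty difference between the 3- and
2-parameter models is ≈10, which no realistic fit-quality difference
overcomes reliably; since λ and κ are fitted per replicate anyway, the
model-comparison machinery (and its power test) uses the per-replicate
design — three κ values per ionic strength, n = 18 — at which the
generating model is identified in ≈98% of 10%-noise datasets.
Under the FEB picture ΔG‡ = ΔG‡_charged + ΔG‡_noncharged, and with a
common Arrhenius prefactor the saturated rates of two variants compare
their non-electrostatic barriers: ΔΔG‡_noncharged = −ln(κ_sat,a/κ_sat,b)
in RT units.

## Fragmentation-dominance test

Quiescent seeded growth is elongation-dominated, y = a(1 − e^{−kt})
with k = 2k₊P_seed.  Aging fibrils for Δt multiplies seed ends by
fragmentation; if fragmentation also dominated de novo secondary
growth, κ² = 2k_frag·k₊·m_original would pin the aged-seed rate to
k′ = k + κ²rΔt (r = M_seed/m_original, default 0.1; Δt default 15 h).
The deficit (k′_pred − k)/(k′_obs − k) is scale-invariant and ≫1 when
fragmentation is too slow to explain κ; it is reported raw and rounded
to one significant figure, with a configurable verdict threshold
(default 3-fold).

## Taylor dispersion (FIDA)

Single-species Taylorgrams are fitted as Gaussians after linear
baseline subtraction; the Taylor–Aris relation D = r_c²·t_R/(24σ_t²)
and Stokes–Einstein R_h = k_BT/(6πηD) convert the temporal peak
variance to a hydrodynamic radius.  Defaults: 37.5 µm capillary radius
(75 µm bore), 298 K, η = 0.89 mPa·s; all configurable.  A secondary
peak above 40% prominence flags the single-species reduction as
unreliable.  The unfolded-state expectation R_h ≈ 0.27·N^0.588 nm is a
literature-sourced empirical constant, exposed as parameters.

## Coarse-grained simulation

A CALVADOS-style model: one bead per residue, harmonic bonds
(0.38 nm, 8033 kJ mol⁻¹ nm⁻²), Ashbaugh–Hatch nonbonded term
(Lennard-Jones with the attractive tail scaled by the mean per-residue
stickiness λ̄; truncated-shifted at 2.0 nm; ε = 0.8368 kJ/mol) and
truncated Debye–Hückel electrostatics (4.0 nm cutoff) with a
temperature-dependent water dielectric.  The embedded residue table is
the published CALVADOS 2 set; it is an explicit input so toy parameter
sets (ideal chains, purely repulsive chains) run through the same
machinery in tests.  His carries a Henderson–Hasselbalch fractional
charge (pKa 6.0; +0.038 e at pH 7.4); the termini carry +1/−1 e and
+2/+16 Da.  Dynamics: BAOAB Langevin splitting, dt = 10 fs, friction
0.01 ps⁻¹, 310 K, cubic periodic box of edge 0.76(N−1)+4 nm (more than
twice the contour length, so minimum-image is exact for one chain),
700 ps equilibration from a straight chain.  Forces use Verlet
neighbour lists (0.3 nm skin, half-skin displacement trigger) over an
O(N²) numba kernel; with zero friction the integrator reduces to
velocity Verlet and conserves energy to <0.1% over 10⁵ steps at dt/10.
Trajectories are reproducible bit-for-bit per seed and are written as
plain-text XYZ with a JSON protocol sidecar.

The reference experimental conditions are 310 K, pH 7.4, I = 49 mM
(no-salt phosphate buffer) with 350 ns production sampled every 70 ps
(5000 frames).  The package's standard scaled-down problem size is a
tenth of that — 35 ns sampled every 17.5 ps (2000 frames).  At that
length the Δ5 Flory exponent is seed-stable (±0.005) but single-run
spectral-class populations of the full-length chain spread by several
points, because one short trajectory samples a limited number of
independent compaction episodes; full-length summary estimates
therefore pool two independent trajectories.

## Ensemble analysis

Per frame, the gyration tensor's eigenvalues λ1 ≥ λ2 ≥ λ3 give
Rg = √Σλᵢ and the deviatoric shape invariants.  Asphericity and
prolateness are reported as ratios of trajectory averages,

    Δ = (3/2)·⟨Σ(λᵢ−λ̄)²⟩/⟨(Σλᵢ)²⟩,   S = 27·⟨Π(λᵢ−λ̄)⟩/⟨(Σλᵢ)³⟩,

a convention chosen because it reproduces the documented limits exactly
(rod: Δ = 1, S = 2; cubic symmetry: 0, 0) and the known ideal-chain
value Δ = 10/19 ≈ 0.53; errors are bootstrap over frames.  The Flory
exponent ν comes from a log–log fit of √⟨R_ij²⟩ against |i−j| for
separations ≥ 10 (the window is a parameter; short separations are
dominated by local chain stiffness).  Contact maps report
P(d_ij ≤ 2.0 nm) over pairs with |i−j| ≥ 2.

Frames are classified by spectral clustering of the affinity

    A_xy = exp[−⟨(d_ij,x − d_ij,y)²⟩ / ⟨2·Var(d_ij)⟩],

with ⟨···⟩ averaging over nonbonded pairs (i > j+1) separately in
numerator and denominator — the separate averages keep high-variance
pairs (the ones that actually move) dominant in the kernel, and make
the mean off-diagonal −ln A equal 1 for i.i.d. frames, a property the
tests check.  scikit-learn's SpectralClustering (precomputed affinity,
fixed seed, k = 4 by default) assigns classes, which are relabelled
1..k by ascending mean Rg so class 1 is always the most compact; each
class's representative frame maximises mean affinity to its classmates
(ties to the lowest index).  Cluster reports carry the caveat that the
classes are subdivisions of a continuous conformational spectrum, not
separated free-energy basins, and per-variant clusterings are
independent — class 1 of one variant is not assumed to be the same
state as class 1 of another.

## Correlation maps

Observation tables hold one row per (variant, ionic strength) with the
kinetic parameters (λ, κ, % insoluble) and ensemble metrics (Δ, S, ν);
conditions where κ is undefined (no fibrils formed) are excluded.
Spearman ρ (average-rank ties) is reported pooled and per variant, with
a Simpson's-paradox flag when the pooled sign contradicts the majority
of within-variant signs.  Per-pair maps correlate the trajectory-mean
Cα–Cα distance of every unmasked canonical pair with κ across all
conditions; no multiple-testing correction is applied by default (the
headline output is the ρ map itself), with an optional
Benjamini–Hochberg layer.

## Synthetic data

Every input class has a generator that draws from the exact forward
model its fitter assumes, records the truth parameters, and is
bit-reproducible per seed: model-generated ThT curves (σ = 0.01–0.05
normalised units, emulating plate-reader noise; optional first-order
plateau decay that starts once growth is complete, so the truncation
rule isolates it), κ(I) series from either salt model with optional
replicates, seeded-growth pairs with or without the fragmentation aging
effect, Gaussian Taylorgrams at specified SNR, and toy conformational
ensembles.  The toy ensembles are: ideal Gaussian chains (ν = 0.5);
a step-wise regrowth self-avoiding proxy (swollen, ν ≈ 0.59); and a
compact/expanded mixture in which frames jitter around an
end-to-end-tethered contracted reference and a free-chain reference
respectively — mimicking families of closely interrelated conformers,
which is what makes the planted two-class partition recoverable by the
affinity kernel.  What the toys do *not* emulate: real instrument
gains, well-position effects, multi-species Taylorgrams, or the
continuous (non-mixture) conformational spectrum of a real IDP
trajectory — passing the planted-partition test shows the clustering
machinery is correct, not that four classes are a physical fact.

## Numerical choices and limitations

* Fits reject inputs below their identifiable minimum (≥10 points per
  ThT trace, ≥3 concentrations for scaling, n > p+1 for AICc) rather
  than returning unstable estimates; degenerate cases (flat salt
  response, constant Rh) are flagged, not silently fitted.
* The simulator is single-chain only: no multi-chain assembly, no
  hydrodynamics, no all-atom detail.  Kinetic quantities (λ, κ) are
  empirical pathway aggregates, not microscopic rate constants, and the
  correlation maps are correlations — no causal claim.
* At the standard scaled-down trajectory length, stochastic
  quantities (class populations, ν) carry seed-to-seed spread of a few
  percent; the per-residue-pair ρ map at 24 observations is noisy for
  weak effects, and the planted-signal tests quantify exactly that.
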