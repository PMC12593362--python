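# synsplice

Amyloid-formation kinetics and monomer conformation of α-synuclein
(αSyn) splice variants.

The SNCA gene can skip cassette exon 3 (residues 41–54) and/or exon 5
(residues 103–130), producing the isoforms αSynΔ3, αSynΔ5 and
αSynΔ3Δ5 alongside the canonical 140-residue protein.  Exon 5 carries
ten negative charges of the acidic C-terminal domain, so splicing
rewires the monomer's long-range electrostatics — and with it the
protein's amyloid behaviour.  `synsplice` is a toolkit for researchers
quantifying that link: it fits plate-reader aggregation kinetics,
models their ionic-strength dependence, discriminates secondary
nucleation from fragmentation, reduces Taylor dispersion data to
hydrodynamic radii, simulates single-chain coarse-grained
conformational ensembles, classifies conformers, and correlates
conformation with kinetics.  Every input class has a synthetic
generator with recorded ground truth, so the full pipeline is testable
end to end without instrument data.

## The models at the core

**Fibril-mass growth.**  Normalised ThT fluorescence is fitted with

    y(t) = 1 − [1 + λ²/(2κ²θ)·e^{κt}]^{−θ},   0 ≤ θ ≤ 3,

giving per-replicate rates of the primary (λ) and secondary (κ)
pathways and a group-shared shape θ.  T50 is the first sample crossing
half-maximum, and T50 = a·c^γ gives the concentration-scaling exponent.

**Ionic-strength response of κ.**  Two Debye–Hückel-motivated models
are fitted and compared by AICc: the saturating "Free Energy Barrier"
form κ = κ_sat·(κ0/κ_sat)^(2^(−I/I_mid)), and the unbounded
"Brønsted–Bjerrum" form κ = κ0·2^(I/I₂).  Saturated rates compare
non-electrostatic barrier components between variants via
ΔΔG‡ = −ln(κ_sat,a/κ_sat,b) (RT units).

**Fragmentation-dominance test.**  Quiescent seeded growth follows
y = a(1 − e^{−kt}); if fragmentation dominated de novo assembly, seeds
aged Δt longer would elongate at k′ = k + κ²rΔt.  The deficit
(k′_pred − k)/(k′_obs − k) ≫ 1 rules fragmentation out.

**Conformational ensembles.**  A CALVADOS-style coarse-grained model
(one bead per residue, Ashbaugh–Hatch + screened electrostatics,
BAOAB Langevin dynamics at 310 K) generates monomer ensembles whose
compaction is summarised by Rg, the Flory exponent ν
(√⟨R_ij²⟩ ∝ |i−j|^ν), asphericity Δ and prolateness S.  Frames are
clustered with a Gaussian kernel of inter-residue distance deviations,
A_xy = exp[−⟨Δd_ij²⟩/⟨2·Var(d_ij)⟩], and Spearman analyses link the
ensemble metrics and per-residue-pair distances to the fitted kinetics.

## Worked example

The headline fragmentation-dominance test, with reference seeded-growth rates: a fresh-seed
elongation rate k = 0.036 h⁻¹, an observed aged-seed rate
k′ = 0.072 h⁻¹, and a de novo secondary rate κ = 2.170 h⁻¹ with seeds
aged Δt = 15 h at dilution r = 0.1:

```
$ synsplice frag-test --k 0.036 --k-obs 0.072 --kappa 2.170
{
 "k_per_h": 0.036,
 "kappa_per_h": 2.17,
 "r": 0.1,
 "dt_h": 15.0,
 "k_obs_prime_per_h": 0.072,
 "k_pred_prime_per_h": 7.09935,
 "deficit": 196.2041666666667,
 "deficit_1sf": 200.0,
 "verdict": "secondary-nucleation-dominated"
}
```

If fragmentation drove the secondary pathway, aging should have raised
the seeded rate to 7.1 h⁻¹; the observed rise was ~200-fold smaller, so
secondary nucleation dominates.

Sequence bookkeeping for the four isoforms:

```python
>>> from synsplice import sequences
>>> vs = sequences.splice_isoforms()
>>> print(sequences.properties_table(vs.values()).to_string())
         length  n_negative  n_positive  n_his  net_charge_formal  epsilon_280
variant
FL          140          24          15      1                 -9         5960
d3          126          23          13      0                -10         5960
d5          112          14          15      1                  1         4470
d3d5         98          13          13      0                  0         4470
>>> len(sequences.common_pair_mask(vs.values()))   # cross-variant pair mask
1953
>>> from synsplice import salt_models as sm
>>> round(sm.ionic_strength(sm.BufferRecipe.make(pH=7.4, sodium_phosphate=20)), 1)
48.6
```

Deleting exon 5 removes ten negatives (net charge −9 → +1) and one
tyrosine (ε₂₈₀ 5960 → 4470 M⁻¹cm⁻¹); the no-salt phosphate buffer sits
at ≈49 mM ionic strength.

Simulating and analysing an ensemble:

```
$ synsplice simulate --variant d5 --ionic-strength-mM 49 --production-ns 35 --seed 1
$ synsplice analyze-ensemble d5_I49mM.xyz --k 4
```

writes per-frame Rg/Δ/S, a 2 nm contact map and a cluster report with
class populations and representative frames.  Multi-stage runs are
driven by `synsplice run config.yaml` and emit a manifest with content
digests so identical configs reproduce identical outputs.

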