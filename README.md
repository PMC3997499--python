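# gbscan

**MM-GB/SA hot-spot analysis of protein dimer interfaces**, built around the
computational strategy that located the druggable hot-spot cluster in the
C-terminal dimerization interface of human Hsp90: decompose the effective
energy of dimerization residue by residue over a conformational ensemble,
call residues with ΔG < −2 kcal mol⁻¹ hot spots, confirm them by in-silico
alanine scanning, and contrast them with a surface-burial baseline and with
"cold-spot" interface residues that contribute nothing.  The package also
implements the assay-side computations used to test such predictions:
melting-temperature extraction from thermal-shift (Thermofluor) curves, SEC
calibration-curve molecular weights, and sequence-derived properties
(computed MW, A280 extinction coefficients, pairwise identity/similarity).

It is aimed at structural bioinformaticians who want a transparent,
dependency-light, fully testable implementation of the end-point method —
not at people running production MD (there is no MD engine here; ensembles
arrive as multi-MODEL PDB files or from the bundled synthetic generators).

## The model in brief

For a dimer AB evaluated on identical complex coordinates
(single-trajectory scheme),

```
ΔG_eff = E_elec(A↔B) + E_vdw(A↔B)
         + [G_GB(AB) − G_GB(A) − G_GB(B)]
         + γ [SASA(AB) − SASA(A) − SASA(B)]
```

with gas-phase terms over all cross-partner pairs (no cutoff), polar
solvation from the generalized Born model (HCT pairwise descreening with
OBC-II rescaling, mbondi2 intrinsic radii, ε_in = 1, ε_out = 80, 100 mM
salt) and a nonpolar term γ·SASA with γ = 0.0072 kcal mol⁻¹ Å⁻².
Configurational entropy is not estimated.  Every term splits into self and
half/half pair shares, so per-residue contributions ΔG_r sum to ΔG_eff
*exactly* on every frame; ensemble means and SEMs are reported per residue.
A residue is **hot** when mean ΔG_r < −2 kcal mol⁻¹ (strict), **cold** when
it sits at the interface (relative burial ≥ 0.05) yet |ΔG_r| ≤ 1 kcal mol⁻¹.
The alanine scan truncates one side chain at a time at Cβ on the fixed
ensemble and reports ΔΔG = ΔG_eff(mutant) − ΔG_eff(wild type), positive =
destabilizing.  See `docs/methods.md` for every constant and convention.

## Worked example

An engineered test case: an antiparallel poly-alanine helix dimer carrying
one buried tryptophan contact per chain — a caricature of a hydrophobic
interface hot spot — jittered into an 8-frame pseudo-ensemble:

```python
from gbscan import (assign_parameters, decompose_per_residue, aggregate_ensemble,
                    classify_spots, relative_burial, SpotThresholds,
                    jitter_ensemble, alanine_scan)
from gbscan.synth import sticky_helix_dimer

structure, partition, anchor = sticky_helix_dimer()          # anchor == ("A", 6)
system = assign_parameters(jitter_ensemble(structure, 0.15, 8, seed=42),
                           partition=partition)
table = decompose_per_residue(system)
report = classify_spots(aggregate_ensemble(table), SpotThresholds(),
                        relative_burial(system, frames=[0]))
print(report.table.sort_values("dg_mean").head(3).to_string(index=False))
print(alanine_scan(system, [anchor], frames=[0]).table.to_string(index=False))
```

prints

```
chain  resnum resname   dg_mean   dg_sem  rel_burial spot_class
    A       6     TRP -2.569989 0.158046    0.382042        hot
    B       8     ALA -1.359788 0.094998    0.518818    neutral
    B       9     ALA -1.306170 0.285199    0.785428    neutral
chain  resnum resname  ddg_mean  ddg_sem  n_frames
    A       6     TRP  4.533513      NaN         1
```

The engineered tryptophan is recovered as the only hot spot (mean
contribution −2.6 kcal mol⁻¹, SEM 0.16 over 8 frames, 38% of its surface
buried by the partner), the surrounding alanines stay above the −2
threshold, and truncating the tryptophan to alanine costs 4.5 kcal mol⁻¹ of
binding — the two computational routes agree on where the interface energy
lives.  On the assay side:

```python
from gbscan import synth_melting_curve, tm_from_derivative
wt  = tm_from_derivative(synth_melting_curve(73.0, slope=2.0, noise_sigma=0.02, seed=1))
mut = tm_from_derivative(synth_melting_curve(60.0, slope=2.0, noise_sigma=0.02, seed=2))
print(f"Tm(wt) = {wt.tm:.1f} C, Tm(mutant) = {mut.tm:.1f} C, dTm = {mut.tm-wt.tm:+.1f} C")
```

```
Tm(wt) = 73.4 C, Tm(mutant) = 59.5 C, dTm = -13.8 C
```

recovering, from noisy synthetic fluorescence, the ~13 °C destabilization
that distinguishes a hot-spot triple mutant from the wild-type domain in a
real thermal-shift experiment.

There is also a CLI (`gbscan scan / alascan / burial / tm / sec / seqprops /
align / synth ...`) for file-based workflows; `gbscan --help` lists the
subcommands.

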