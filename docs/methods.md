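# Methods

`gbscan` estimates which residues of a protein-protein interface dominate
binding, using the MM-GB/SA end-point decomposition that identified the
hot-spot cluster in the C-terminal dimerization interface of human Hsp90,
and implements the assay-side computations (thermal-shift Tm, SEC
calibration, sequence properties) used to test such predictions in the wet
lab.  This note records the model, its assumptions, the defaults and the
design decisions.

## Effective binding energy

For a dimer with partners A and B evaluated on one set of complex
coordinates (the *single-trajectory* scheme),

    dG_eff = E_elec(A<->B) + E_vdw(A<->B)
             + [G_GB(AB) - G_GB(A) - G_GB(B)]
             + gamma * [SASA(AB) - SASA(A) - SASA(B)]

Intramolecular gas-phase terms are identical in complex and monomers and
cancel exactly, so they are never computed.  Configurational entropy is
deliberately not estimated.  Units are kcal/mol, Angstrom and elementary
charges throughout; the electrostatic constant is 332.0637 kcal A mol^-1 e^-2.

* **Gas phase.**  All cross-partner atom pairs, no cutoff.  Coulomb with a
  solute dielectric of 1; Lennard-Jones with Lorentz-Berthelot combination
  (`rmin = rmin_half_i + rmin_half_j`, `eps = sqrt(eps_i eps_j)`).  Because
  only inter-molecular pairs occur, no 1-4 scaling is needed.
* **Polar solvation.**  Generalized Born.  Effective radii come from the
  analytic pairwise-descreening (HCT) integral — validated in the test
  suite against numeric quadrature of the defining volume integral,
  including the overlapping and engulfed sphere branches — with the OBC-II
  tanh rescaling (alpha, beta, gamma = 1.0, 0.8, 4.85; radius offset
  0.09 A).  Intrinsic radii follow the mbondi2 convention (C 1.70, N 1.55,
  O 1.50, S 1.80, H 1.20, H-on-N 1.30 A); descreening scale factors are the
  standard element-wise set (H 0.85, C 0.72, N 0.79, O 0.85, S 0.96).  The
  energy uses the Still interpolation `f_GB = sqrt(r^2 + R_i R_j
  exp(-r^2/(4 R_i R_j)))` (diagonal `f = R_i`) with the dielectric factor
  `1/eps_in - exp(-kappa f)/eps_out`, eps_in 1, eps_out 80.  Salt enters
  through `kappa = sqrt(0.10806 * I[mol/L])` per Angstrom at 298.15 K,
  I = 0.100 M by default.  Some GB implementations scale kappa by 0.73 to
  compensate for the exclusion of ions from the solute interior; the
  unscaled form is the default here and `GBOptions.kappa_scale` makes the
  choice explicit.
* **Nonpolar solvation.**  `gamma * SASA` with gamma = 0.0072
  kcal mol^-1 A^-2.  SASA is computed by Shrake-Rupley sphere sampling
  with a deterministic generalized-spiral point set (960 points by
  default; no RNG anywhere in the geometry path).  Atom radii are the
  intrinsic GB radii plus the 1.4 A probe; hydrogens are included with
  their table radii.  Each atom's point set is oriented in a local frame
  built from its two nearest overlapping neighbours, which makes the
  sampled areas *exactly* invariant under rigid transforms of the system
  (and exactly symmetric for symmetric dimers); for a single neighbour
  the burial is axially symmetric and the azimuthal freedom of the frame
  has no effect.  The quadrature error of the area itself is ~1/n_points
  (about 1% at 960 points against the analytic sphere).

## Per-residue decomposition

Every energy term above is a sum of self terms and symmetric pair terms.
Self terms are attributed to their atom; every pair term is split half/half
between its two atoms; atom shares are summed per residue.  Cross-partner
gas terms touch a residue only through the pair ledger; GB shares are
complex-minus-monomer differences on the same coordinates (all pairs
contribute, because binding changes every Born radius); SASA shares
likewise.  The residue contributions therefore sum to dG_eff *identically*
on every frame — the test suite asserts agreement to 1e-6 kcal/mol and the
acceptance script reports the realized maximum error (~1e-12, pure float
accumulation).

Over an ensemble the per-residue mean and the standard error of the mean
(sample SD / sqrt(n_frames)) are reported; SEM is flagged undefined for a
single frame.

## Hot spots, cold spots, alanine scanning

* **Hot spot**: ensemble-mean dG_r strictly below -2 kcal/mol (the
  threshold that defined the Hsp90 CTD hot-spot cluster; configurable).
* **Interface membership**: residue-wise relative burial
  `rb = (SASA_monomer - SASA_complex)/SASA_monomer >= 0.05` (the paper-style
  relative-SASA baseline gives no numeric rule; 0.05 flags any residue
  that loses a twentieth of its accessible surface).  Residues with
  monomer SASA below 1 A^2 have undefined burial.
* **Cold spot**: interface residue with |mean dG_r| <= 1 kcal/mol that is
  not hot — an operational rule reproducing the qualitative choice of
  marginal interface residues as negative controls.  Classification is
  row-local by construction.
* **Alanine scan**: for each position and frame, side-chain atoms beyond
  C-beta are removed (C-beta and backbone untouched, no re-minimization,
  the single-trajectory philosophy), the alanine methyl is rebuilt at
  ideal geometry, the system is re-parameterized and the *full* effective
  energy recomputed — no ledger shortcuts, so the scan itself can serve as
  an oracle.  Reported as `ddG = dG_eff(mutant) - dG_eff(wild type)`;
  positive ddG destabilizes binding.  Gly (no C-beta) and Pro (backbone
  ring) are excluded, the standard convention.

## Force-field tables and structure preparation

Per-atom charges for the 20 standard residues are the published Amber
fixed-charge protein set (the ff94/ff99 charges that ff99SB inherits
unchanged); each residue's charges sum exactly to its formal integer
charge, which the loader re-validates at 1e-3 e.  LJ parameters follow the
Amber vdW types.  Protonation defaults for the assay's pH optimum (7.5):
His neutral in the N-epsilon tautomer, Asp/Glu deprotonated, Lys/Arg
protonated, Cys reduced.  Termini are detected from chain ends: the
N-terminus is protonated (H1/H2/H3 at +0.26 e each, remainder on N); the
C-terminus becomes a carboxylate when an OXT atom is present (O = OXT =
-0.80 e, remainder on C), otherwise the interior charge set is kept so
that arbitrary PDB files without OXT remain readable.  These terminal
charges are a documented exact-integer adjustment rule rather than a
separately fitted terminal set — termini never sit in the synthetic
interfaces this package analyses, so the simplification does not touch the
reported energetics.

Missing hydrogens are built from the ideal residue geometry of the
chemical component dictionary (bundled with biotite) by local-frame
superposition; backbone amide protons are constructed in the peptide plane
anti to the preceding carbonyl.  Waters and counterions are always
stripped before energetics; for altlocs the highest-occupancy conformer is
kept (ties to file order).  Multi-MODEL PDB is the only ensemble
interchange format; atom serials beyond 99999 wrap deterministically.

## Synthetic data: what it emulates, what it does not

The generators exist so every pipeline stage is testable at desk scale
without MD or downloads:

* **Ideal helices / dimers** — backbone chained at phi/psi = -57/-47
  (omega 180), one fixed template rotamer per residue type, optional exact
  C2 symmetry (chain B the image of chain A under a two-fold rotation
  through the helix mid-plane).  The C2 mode turns the observation that
  interface profiles are "almost identical for the two monomers" into an
  exact, machine-testable property.
* **Sticky preset** — a poly-alanine pair with one bulky Trp per chain;
  both helices are spun on a deterministic 10-degree grid to the lowest
  cross-chain gas-phase energy, packing the two side chains into one
  dominant buried hydrophobic contact (mirroring the hydrophobic character
  of the real hot-spot cluster).  A solvent-exposed Arg-Glu bridge was
  evaluated as the anchor first and rejected: in this GB model its Coulomb
  attraction (about -37 kcal/mol gas phase in the best grid geometry) is
  cancelled almost exactly by the desolvation penalty (about +40), a
  physically faithful outcome that makes an isolated charge pair unusable
  as a designed hot spot.
* **Pseudo-ensembles** — i.i.d. Gaussian coordinate jitter (default sigma
  0.15 A, frame 0 unperturbed).  They emulate the *bookkeeping* of an MD
  snapshot set — frame averaging, SEMs, conservation — not its physics: no
  correlated motions, no relaxation, no Boltzmann weighting.  Passing
  tests on jittered ensembles therefore validates the estimator machinery,
  not any conformational claim about real proteins.
* **Melting curves** — Boltzmann sigmoid `F = F_min + (F_max - F_min)/(1 +
  exp((Tm - T)/s))` plus additive Gaussian noise and an optional linear
  post-transition decay (dye loss on aggregation); default range 25-95 C,
  0.5 C steps, the plate-reader convention.
* **SEC standards** — `log10(MW) = a Ve + b` with the six printed
  calibration proteins (14, 29, 66, 150, 200, 443 kDa) and Gaussian
  elution noise.

All generators are deterministic under a fixed seed.

## Assay analytics

* **Tm (derivative)** — midpoint of thermal unfolding taken as the maximum
  of the smoothed dF/dT (centered moving average, default window 5, applied
  to both the trace and its finite difference), restricted to rising
  transitions above 3x the median absolute derivative; the grid peak is
  refined by a 5-point quadratic fit.  On the reference synthetic noise
  level (2% of amplitude) the estimator calibrates to |bias| < 0.2 C and
  RMSE < 0.5 C over 100 seeds, and the estimate is exactly equivariant
  under temperature shifts.
* **Tm (sigmoid fit)** — Boltzmann least squares over the pre-aggregation
  region (up to the fluorescence maximum), initialized from the derivative
  estimate; agrees with the derivative to 0.3 C on smooth data.
* **SEC** — ordinary least squares of log10(MW) on Ve; a non-negative
  slope (larger proteins eluting later) is reported as a warning, since it
  contradicts size-exclusion behaviour; predictions outside the standards'
  range carry an extrapolation flag.
* **Sequence properties** — average-mass MW (residue masses + one water)
  and the A280 extinction coefficient 5500 nW + 1490 nY (+125 per cystine
  pair on request), the ProtParam conventions.  Identity/similarity come
  from a global affine-gap pairwise alignment (BLOSUM62, open 10, extend
  0.5) rather than a progressive multiple alignment; identity counts
  identical columns over columns with residues on both sides (gap columns
  excluded), similarity additionally counts positive-scoring substitutions.
  Because tool conventions differ, comparisons against published
  percentages are tolerance-based (+-2 points).  The computation is made
  order-independent by canonicalizing the argument order.

## Bundled reference sequences

`data/sequences.fasta` carries the Hsp90-alpha full-length sequence and the
two template CTD fragments (yeast Hsp82 540-677, E. coli HtpG 510-624) so
the sequence-level analyses run offline.  The human entry is corroborated
by many independent facts recoverable from the mutagenesis literature on
this domain (primer-encoded wild-type codons around the interface,
mutant-vs-wild-type mass and extinction differences); the bacterial
fragment has fewer such anchors and its transcription fidelity is the
weakest link of the sequence bundle (see Limitations).

## Problem sizes

Default test and reproduction workloads are desk-scale by design: dimers
of 8-30 residues per chain, ensembles of 3-20 frames, 960-point SASA
spheres, 100-seed estimator calibrations.  At these sizes the full test
suite and the reproduction script each run in minutes on one core.

## Known limitations

* Pseudo-ensembles are not dynamics; nothing here reproduces observables
  that depend on real conformational sampling (the full hot-spot set of a
  real 100-ns trajectory, for example, is explicitly out of reach).
* The GB model is a single dielectric-boundary approximation: no
  Poisson-Boltzmann reference, no explicit ions, no entropy.
* SASA is sampled, not analytic: per-atom areas carry ~1% quadrature
  error (the decomposition conservation is exact regardless, because
  complex and monomer terms use the same sampled areas).
* Terminal residue charges are a documented simplification (above).
* The E. coli HtpG fragment in the sequence bundle reproduces published
  identity/similarity percentages only within ~5/9 points; the yeast and
  human entries reproduce their published anchors within the stated
  tolerances.
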