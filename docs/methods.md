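# Methods

## The model

Chitosan is a linear (1→4)-linked copolymer of N-acetyl-glucosamine
(GlcNAc) and glucosamine (GlcN); GlcN is a weak base that is neutral
(GlcNH2) or protonated (GlcNH3+) depending on pH and its electrostatic
environment.  `chitosim` implements a coarse-grained model in which

* each monomer is a rigid body (ideal ⁴C₁ pyranose chair) carrying one
  interaction site at the ring's geometric center;
* the only degrees of freedom are the glycosidic dihedrals (φ, ψ) of
  each link, governed by a two-dimensional free-energy map G(φ, ψ)
  (k_BT units, periodic on [0, 2π)²) specific to the ordered pair of
  monomer states flanking the link — nine maps in total;
* non-adjacent sites repel sterically through a purely repulsive
  cut-and-shifted Lennard-Jones potential,
  U = 4ε[(σ/r)¹² − (σ/r)⁶ + ¼] for r ≤ 2^{1/6}σ, else 0;
* non-adjacent charged sites interact through the Debye-Hückel
  potential U^DH = z_a z_b λ_B e^{−κr}/r (k_BT), with Bjerrum length
  λ_B = e²/(4πε₀ε_r k_BT) (0.714 nm in water at 298 K) and inverse
  screening length κ = (8π λ_B N_A c_eff)^{1/2};
* protonation states are sampled in a semi-grand-canonical ensemble:
  the titration free energy is F_prot = Σ_i μ_i z_i + Σ_{pairs} U^DH,
  with μ_i = ln(10)(pH − pK_i), the pair sum running over all charged
  pairs *including* nearest neighbours (whose conformational
  electrostatics are otherwise folded into the maps).

Monte Carlo sampling alternates **pivot moves** (redraw one link's
(φ, ψ) uniformly from the region of its map below a cutoff — 7 k_BT by
default — and rigidly rotate the downstream segment; accept with
min(1, e^{−ΔE}), ΔE = ΔE_map + ΔE_LJ + ΔE_DH) with **titration moves**
(flip one titratable site's charge; accept with min(1, e^{−ΔF})).  One
MC step is one pivot move plus N_t titration attempts.  Because pivot
proposals are uniform over a fixed allowed set containing the current
point, the chain samples the Boltzmann distribution truncated at the
cutoff; the truncated weight is negligible (< 10⁻³ for the 7 k_BT
cutoff).

**Map swapping.**  When a titration move changes a monomer's charge,
the maps of its (up to) two adjacent links are replaced by the maps of
the new link types.  The map-energy change of those links is *not*
included in the titration acceptance by default, mirroring the original
protocol; as a consequence the joint (conformation, charge) stationary
law is not exactly a Gibbs measure of a single Hamiltonian when maps
differ across charge states.  The flag
`ForceFieldParams.include_bonded_in_titration` adds the bonded term and
restores exact detailed balance; the full-enumeration ensemble test
uses it.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| σ_LJ | 0.65 | nm | sphere surface ≈ monomer molecular surface; `sigma_from_msa` derives σ from an area |
| ε_LJ | 0.6276 | kJ/mol | carbon LJ well depth; results insensitive (repulsive-only) |
| pK_i | 6.6 | — | intrinsic dissociation constant of GlcN |
| map cutoff | 7 | k_BT | pivot-proposal restriction |
| T | 298 | K | enters λ_B and the kJ/mol→k_BT conversion (R·T = 2.478 kJ/mol) |
| ε_r | 78.5 | — | water at 298 K |
| c_eff | c_s + 10^(−pH) | mol/L | strong-acid proton contribution; switchable |
| titration attempts/step | N_t | — | one sweep of the titratable sites per pivot |

The degree of dissociation α is reported as the *neutral* fraction of
titratable sites (α = 0 fully charged, α = 1 fully neutral).

## Geometry

The paper-level model fixes all bonds and angles; the concrete internal
coordinates are this package's own idealized construction
(`chitosim.geometry`): a chair ring with uniform endocyclic bond length
0.1513 nm and 111° angles, equatorial glycosidic substituents at C1 and
C4 (109.5°), C1–O 0.1414 nm, O–C4′ 0.1426 nm and a 116° C1–O–C4′
valence angle.  Dihedrals follow the heavy-atom convention
φ = O5–C1–O–C4′, ψ = C1–O–C4′–C5′.  The virtual-bond length between
successive ring centers is *derived* from forward reconstruction — it
comes out ≈ 0.45 nm at the main map minimum — and every analysis uses
the measured value, never a hard-coded one.  Pivot updates compose a
rigid rotation onto the downstream frames; the rotation is projected
back onto SO(3) each move, keeping 10⁵-move trajectories within
~10⁻¹¹ nm of a from-scratch rebuild.

## The synthetic map library

The numeric metadynamics maps are distributed as supplementary data of
the source study and are not bundled here; the package instead ships a
generator (`MapLibrary.synthetic`) that reproduces their published
feature statistics.  Each link map is built from two basins on a
14 k_BT background: the main minimum at the published (φ, ψ) position
and a secondary basin at (φ, ψ − π) — the anti-ψ conformer, the
conventional second basin of (1→4) glycosidic maps — ΔG₂ above it,
with each basin a narrow Gaussian core plus a broad shoulder 6 k_BT up.
The two widths are calibrated per link (by root finding on the
generated grid) so that the <1 k_BT and ≤12 k_BT accessible-area
fractions match the published per-link values exactly; minimum
positions and ΔG₂ match by construction.

What this stand-in does *not* fix is the detailed basin anatomy: the
true maps' secondary-minimum locations, basin anisotropy and minor
tertiary minima are not published as numbers.  Chain stiffness is
sensitive to exactly these features, so map-derived dynamical
quantities agree with the published ones only approximately: the
stiffness *ordering* of the nine links and the stiff-map persistence
lengths (≈14 and ≈19 nm) are reproduced within ~10 %, while the most
flexible maps come out ~20–30 % stiffer than published and
consequently the alternating-pattern stiffness and the
characteristic-ratio plateau are overestimated by similar margins.
Passing feature-level tests therefore validates the machinery and the
calibration, not the unpublished fine structure of the real maps.
Loading the real supplementary maps through `load_map`/`from_manifest`
replaces the stand-in entirely.

## Estimators

* **R_G** — root mean squared site distance from the centroid,
  unweighted.
* **C_k** — bond-vector correlation ⟨b_i·b_{i+n}⟩/⟨|b|²⟩ over all
  origins and frames; L_P from the slope of ln C_k vs n·l on the
  largest contiguous window with C_k ∈ [0.05, 0.75], which skips the
  short-scale helical oscillation and the noisy tail.  L_P,0 comes from
  a matched run with electrostatics disabled; L_P,e = L_P − L_P,0.
* **Benoit-Doty inversion** — solves
  3R_G²/L = L_P(1 − 3x + 6x² − 6x³(1 − e^{−1/x})), x = L_P/L, by
  bracketing root finding.  For L_P ≫ L the bracket cancels
  catastrophically in floating point, so the stiff branch evaluates the
  equivalent series Σ_{m≥4} 6(−1)^m x^{3−m}/m! instead.  The long-chain
  approximation 3R_G²/L is reported alongside.
* **Odijk-Houwaart iteration** — alternates the Benoit-Doty inversion
  with the electrostatic excluded-volume parameter
  z_el = (27L/2π)^{1/2} κ⁻¹ L_P^{−3/2} and expansion factor
  α_el² = 0.541 + 0.459(1 + 6.04 z_el)^{0.46}, updating
  R_G,0 = R_G/α_el until relative convergence 10⁻⁶ (the printed
  coefficients sum to 1, so α_el(0) = 1 exactly).  The OSF form
  L_P,e = λ_B/(4κ²A²) (A = mean contour spacing of charges) is used for
  the electrostatic component: the literal printed expression
  λ_Bκ⁻²/4 is dimensionally a volume, and OSF is its canonical
  referent.  The perturbation-theory factor
  α_R² = 1 + 1.33z − 2.075z² + 6.459z³ is provided for
  characteristic-ratio de-expansion.
* **C_n** — ⟨R²(n)⟩/(n l²) averaged over *all* internal sub-chains
  (not only the chain ends), the mean-square reading; the printed
  ⟨R_ee⟩/nl² is dimensionally inconsistent otherwise.
* **Henderson-Hasselbalch fit** — linear fit of pH against
  log₁₀(α/(1−α)) restricted to |log₁₀(α/(1−α))| < 0.5, yielding pK_app
  (intercept) and the slope factor n; pK_app is also reported as the
  interpolated pH at α = ½.

## Numerical conventions

* Maps are cell-centered grids (default 200×200, the metadynamics grid
  resolution), normalized so min G = 0 exactly; continuous energies by
  periodic bilinear interpolation (ghost-padded); file loaders accept
  3-column triples or dense matrices, shift [−π, π) input to [0, 2π),
  and convert kJ/mol to k_BT at 298 K when declared.
* Local minima are strict 8-neighbour minima with separable quadratic
  sub-bin refinement; two minima are *distinct* when the watershed
  saddle between them (union-find over energy-sorted bins) exceeds the
  median inter-bin energy difference, which suppresses grid-noise
  duplicates.  ΔG₂ is the gap to the second distinct minimum.
* The restricted-region sampler draws an allowed bin uniformly and
  jitters uniformly within it; a jittered point's interpolated energy
  can exceed the cutoff by at most the local inter-cell variation.
* Initial state: every link at its map's global minimum; all titratable
  sites charged when pH < pK_i, neutral otherwise.  Default burn-in
  discards 20 % of logged records; a stationarity screen requires the
  first and last thirds of retained R_G to agree within two combined
  standard errors, and per-link allowed-bin coverage can be tracked.
* One seeded `numpy` generator drives everything, consumed in a fixed
  order per step: pivot link choice, proposal bin, two jitters,
  acceptance uniform; then per titration attempt: site choice,
  acceptance uniform.  Identical seeds give byte-identical logs.
* Incremental energy caches (map, LJ, DH) are updated from accepted
  moves only and verified against a fresh evaluation every 10⁴ steps
  (tolerance 10⁻⁶ k_BT), together with the map-key/monomer-state
  consistency invariant.

## Problem sizes in the shipped studies

The test-suite and the acceptance script run desk-scale versions of the
published studies: DP = 200 homopolymer chains (6×10⁴ steps) for
per-map intrinsic persistence lengths, DP = 400 (1.2×10⁵ steps) for the
characteristic-ratio plateau, DP = 50–200 for the chain-size scan,
DP = 120 (2×10⁴ steps) for the map-swapping comparison, and DP = 80 for
titration curves.  These sizes give ~5 % statistical precision on R_G
and 10–15 % on persistence-length fits.  The ensemble-correctness
oracle uses DP = 3 with 10×10 piecewise-constant maps so the joint
(bin, bin, charge) distribution can be enumerated exactly; its two
charge-state maps share an identical cutoff-allowed region by
construction so pivot proposals remain reversible across charge flips.

## Known limitations

* Single chain in implicit solvent: no aggregation, hydrogen bonding,
  attractive dispersion, explicit ions or Manning condensation; the
  model is meaningful only where chitosan is soluble (sufficiently
  charged chains).
* The idealized geometry yields a virtual bond of ≈0.45 nm versus
  ≈0.52 nm for real pyranose stacking; lengths reported in nm are
  correspondingly compressed relative to experiment at equal DP.
* The synthetic maps reproduce published *feature statistics*, not the
  full free-energy topology (see above).
* pK_i is constant; the coupling between solubility and protonation
  that matters near complete neutralization is outside the model.
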