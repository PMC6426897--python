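# Methods

## The model

`cgdock` implements a structure-based (Gō-type) coarse-grained model for
protein–peptide docking driven by screened electrostatics, together with the
interface-similarity analysis used to judge docked poses against an
experimental reference interface.

**Representation.** Each residue contributes a bead at the Cα position and,
for non-glycine residues, a second bead at the Cβ position. Charged residues
(K, R, H: +1; D, E: −1) carry their charge on the Cβ bead. Histidine is
treated as +1 by convention of the charged-residue set used here, despite its
ambiguous physiological pKa. Termini are modeled as uncharged, consistent
with acetyl/amide capping of the designed peptides; the caps themselves are
not beads.

**Potential.** Four terms, in reduced units with the Gō well depth
ε_go = 1 as the energy unit, lengths in Å, unit masses:

- *Bonded*: harmonic springs `k (r − r0)²` on consecutive Cα–Cα pairs and
  intra-residue Cα–Cβ pairs, with r0 from the source structure and
  k = 50 ε_go/Å² (stiff enough to fix local geometry, soft enough for a
  0.01 timestep).
- *Gō contacts*: for every intramolecular residue pair with any heavy-atom
  distance ≤ 4.5 Å and sequence separation ≥ 3 (both configurable), a
  12-10 Lennard-Jones well `ε_go [5(r0/r)¹² − 6(r0/r)¹⁰]` on the Cα–Cα and
  (where both exist) Cβ–Cβ bead pairs, with r0 the bead distance in the
  source structure. The native geometry is therefore the exact minimum of
  the Gō + bonded terms (verified to gradient < 1e-6). A 12-6 form is
  available by configuration. Attractive interactions exist only within a
  molecule: receptor and peptide cohere internally but do not attract each
  other through this term.
- *Excluded volume*: a truncated-and-shifted repulsive core
  `ε_rep [(σ/r)¹² − 1]` for r < σ = 3.8 Å on all non-bonded, non-contact
  pairs. Intramolecular pairs whose native separation exceeds 12 Å are
  pruned from this list — the Gō web keeps them out of core range while the
  molecule is folded, so the term cannot fire; this is purely a performance
  measure and is configurable.
- *Electrostatics*: Debye–Hückel screened Coulomb
  `U = C q_i q_j exp(−r/λ_D) / r` between charged Cβ beads of *different*
  molecules. This is the only attractive protein–peptide interaction: the
  docking search tests whether charge complementarity alone suffices for
  site-specific binding. λ_D = 3.04/√I Å at 298 K; the default ionic
  strength 10 mM gives λ_D ≈ 30.4 Å (weak screening). Because CG bead
  separations exceed their all-atom counterparts, nominal 10 mM screens like
  roughly 30 mM; this is noted, not corrected for.

**The electrostatic-to-Gō weight.** No absolute energy scale exists for the
CG model, so the coupling C is the single calibration scalar. The default,
C = 332.0637/ε_r ≈ 4.15 ε_go·Å at ε_r = 80, reads the aqueous Coulomb
constant (kcal·mol⁻¹·Å·e⁻²) in units of ε_go ≈ 1 kcal/mol. On the synthetic
patch system this produces a bound native pose ≈ 7 ε_go below the unbound
state — strongly bound at the default temperature, while both molecules
fluctuate around their native structures.

## Docking protocol

The default `DockingProtocol` reproduces the published sampling recipe: the
peptide is placed at 10 positions distributed around the receptor with the
distance from the receptor surface (nearest bead) to the peptide geometric
center at 35 Å, 10 replicas per position, 10⁷ Langevin steps per replica,
frames saved every 1000 steps, and only the last 2000 saved frames per
replica analysed — 2 × 10⁵ kept conformations in total. Placement
directions follow a Fibonacci spiral on the sphere (near-maximal pairwise
angular separation), rigidly rotated by the seeded RNG; peptide orientation
at each start is random.

Unspecified simulation parameters are calibration choices, exposed in the
protocol/config:

- *Integrator*: BAOAB-splitting Langevin, timestep 0.01 (bond-stiffness
  limited; halve it above kT ≈ 1), friction γ = 0.2 (low friction speeds the
  diffusive search; the BAOAB thermostat holds mean kinetic energy per
  degree of freedom within 5% of kT/2 regardless).
- *Temperature*: "relatively low" is quantified as kT = 0.5 ε_go
  (ε_go/kT = 2), the folded-but-fluctuating regime.
- *Confinement*: a soft harmonic spherical wall at 2× the placement distance
  around the receptor centroid prevents escape to infinity while preserving
  an unbound ensemble; finite campaigns do not converge without some
  confinement.
- *Flexibility*: both molecules remain flexible under their Gō + bonded
  terms; there is no rigid-body shortcut. An internal-RMSD guard (default
  5 Å after superposition) flags replicas that drift from their native
  folds.
- *Reproducibility*: each replica owns an RNG stream seeded from
  (master seed, position index, replica index), so campaign results are
  bit-reproducible and independent of execution order.

## The similarity statistic D

Docked conformations are compared with the reference interface through the
table of interfacial Cβ–Cβ distances:

    D = (1 / (N_protein · N_peptide)) Σ_i Σ_j (r_ij − r_ij⁰)

with i over the protein interface residues, j over the peptide interface
residues, and r⁰ from the reference structure. For the pyrin-domain target
the defaults are Asp6, Leu9, Asp10, Glu13, Asp48, Leu50, Asp51, Asp54
(protein side, author numbering) and Lys6, Lys7, Lys9, Ile10, Lys11
(peptide side, 15-mer numbering) — 40 reference pairs. Residue j is matched
to reference residue j in order (directional matching; no
best-of-both-orientations). Splitting the peptide list at its midpoint
({6,7} | {9,10,11} by default) and applying the same formula per half gives
D1 and D2.

Two properties worth noting:

- D is *signed* as written; poses whose distances systematically undershoot
  the reference give D < 0. The native-like classifier therefore requires
  `max(D1, D2) ≤ τ` **and** `D ≥ −τ`, the lower guard rejecting
  steric-overlap poses. τ defaults to 3 Å; the cutoff behind the published
  28%/38% comparison was never printed, so `tau_scan` reports the fraction
  across a τ grid rather than asserting those two numbers.
- The aggregate D depends only on the sums Σ r_ij and Σ r⁰_ij and is
  therefore invariant under reversal of the peptide residue order; the
  direction sensitivity the statistic is meant to carry lives in D1/D2,
  whose group membership follows the residue order. The test suite pins
  both facts.

The (D1, D2) free-energy landscape is `F = −kT ln(P/P_max)` over a 2-D
histogram of the kept frames, with kT the simulation temperature, the most
populated bin at F = 0 and unoccupied bins masked.

## Interface analysis

- *SASA*: internal Shrake–Rupley with deterministic golden-spiral sphere
  points (960 by default; total area changes < 0.5% on doubling),
  element-keyed united-atom-style radii (C 1.70, N 1.55, O 1.52, S 1.80 Å,
  …) and a 1.4 Å probe.
- *Buried area*: per side, `SASA(part alone) − SASA(part in complex)`;
  total, the sum of the sides (equal to `SASA(A)+SASA(B)−SASA(AB)`).
  Published interface sizes of ~900 Å² (whole type-I interface) and ~700 Å²
  (helix-2 contribution) are conventionally quoted per side, so the report
  exposes both conventions. Interface residues bury > 0.1 Å² and are
  classed D/E negative, K/R/H positive, A/V/L/I/M/F/W/P hydrophobic, else
  other.
- *Probe grids*: probe atoms of an externally aligned trajectory are binned
  into 1 Å³ cells. The bulk threshold is the maximum count among cells
  farther than 8 Å from every receptor atom, and hotspot cells reach a
  multiple (default 5×) of it — the benzene-mapping post-processing
  convention. The probe *simulation* itself is out of scope; any aligned
  trajectory (including the synthetic density-map sampler) can be analysed.

## Peptide designs

The registry ships the ten design rows: two helix-2 templates
(TAEELKKFKLKLLSV, residues 16–30 of the adaptor pyrin domain;
VDLKKFKMHLEDY, residues 20–32 of the NLRP3 pyrin domain), their i,i+7
stapled variants ('*' marks the staple positions, 5/12 on 15-mers, 3/10 on
13-mers) and the mutational series. Mutation sets were inferred by
row-by-row comparison against the templates (the published table marks
mutations typographically, which plain-text extraction loses); every row is
reconstructed by `template → staple → mutations` in the tests. Stapled
positions enter the CG model as alanine-like beads plus one soft harmonic
restraint (k = 10 ε_go/Å²) between the two staple Cβ beads at their model
distance — the model has no hydrocarbon-linker beads, and the restraint
preserves the staple's rigidifying role. Staple chemistry and termini caps
are metadata. 13-mer positions map to 15-mer numbering via +2, so interface
residue lists quoted in long numbering resolve for both lengths.

## The synthetic world

`make_patch_system` builds a three-helix-bundle receptor (60 residues,
ideal helix geometry: 1.5 Å rise, 100°/residue, Cα radius 2.3 Å, Cβ 1.53 Å
radially outward) with a contiguous anionic stripe of 6 glutamates on the
bundle-averted face of one helix, and a 13-residue peptide helix with 4
lysines on one face, posed natively with its cationic face against the
patch (charge pairs within 12 Å) plus a decoy pose on the patch-free far
side. The counts (60, 13, 6, 4) mirror the scale of the real problem: a
~90-residue receptor domain truncated to its binding region, a 13-mer
peptide with 4–5 cationic residues against a ~6-residue anionic surface.
The seed perturbs coordinates by 0.05 Å jitter only, so systems are
reproducible. A charge-scrambled control peptide (same composition, lysines
at seeded random positions) mirrors the design comparison in which
misplaced charge degrades native-like binding.

Because the synthetic scaffolds carry only Cα/Cβ pseudo-atoms, the
all-heavy-atom 4.5 Å contact default yields too sparse a native web to hold
the bundle together; the synthetic builders therefore use an 8 Å cutoff,
which restores inter-helix contacts and internal rigidity (receptor RMSD
≈ 2 Å at kT = 0.5). The 4.5 Å default stands for atomic structures.

What a green synthetic test establishes: that sampling, scoring and
bookkeeping behave as specified in a world with the assumed structure
(localized anionic patch, cationic helix, known native pose). It does not
establish all-atom realism, real-sequence specificity, or any experimental
affinity.

## Numerical choices and degenerate inputs

- Trajectories round-trip through a plain-text columnar format at 1e-4 Å
  precision (declared bound 1e-3 Å).
- Missing Cβ on a non-glycine residue is reconstructed from ideal backbone
  geometry with a warning; missing Cα is an error.
- Altloc atoms keep the highest-occupancy conformer.
- Zero-frame campaigns, empty contact lists, all-zero probe densities,
  coincident charged beads and overlapping interface selections raise
  explicit errors or return well-defined empty results (tested).
- Landscape ties: equally populated maximal bins all receive F = 0.

## Known limitations

- The published 28%/38% native-like percentages are not asserted anywhere:
  their cutoff τ and the CG calibration behind them are unknown; only the
  ordering (correctly charged > mischarged) is tested, on the synthetic
  world, and `tau_scan` provides the reporting tool for real receptors.
- Real-receptor workflows (e.g. the type-I dimer of the pyrin-domain
  filament, or the CARD-domain negative control) require the user to supply
  the PDB files; no network fetching is built in.
- MM/GBSA binding energies, all-atom refinement, Poisson–Boltzmann surface
  maps and probe-mapping *simulations* are out of scope; the per-residue
  energy decomposition offered here is the CG-level Debye–Hückel share
  (half of each pair term to each partner residue), not an all-atom
  free-energy decomposition.
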