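# Methods

## Tripartite decomposition

A PROTAC is partitioned into E3 ligand, linker and POI ligand by matching a
library of E3-core substructure patterns (SMARTS; shipped defaults cover
glutarimide–phthalimide/isoindolinone cereblon cores in N- and O-linked
variants and the hydroxyproline/tert-leucine/methylthiazolyl-benzyl VHL
core). A usable match must touch the rest of the molecule through exactly one
bond, at the pattern's marked exit-vector atom when one is marked (SMARTS
atom map 1). Two atom-disjoint matches raise an ambiguity error and require a
user override; overlapping matches resolve to the largest core.

The POI ligand is not matched against a library: it is delineated as the
fused ring system topologically farthest from the E3 exit vector, together
with every atom attached beyond it; the linker is whatever remains between
the two anchors. This handles linkers that themselves contain pass-through
rings (piperazine, triazole), but it assumes the POI ligand (a) contains at
least one ring and (b) attaches to the linker through a ring atom, and it
assigns acyclic atoms between the linker and a multi-ring-system POI to the
linker. The synthetic fragment library respects these assumptions; for
real-world inputs that violate them the decomposition table should be
reviewed (the anchors and per-atom domain labels are exposed for that
purpose).

Fragments are hydrogen-capped at the cut bonds: each cut bond contributes
one explicit hydrogen to the atom it left behind, which keeps aromatic
nitrogens kekulizable. Capping makes fragment descriptors well defined but
not strictly additive; `mw_cap_correction` (2 × 1.008 Da per cut bond) and
`tpsa_cap_correction` (per-atom TPSA-contribution difference at the boundary
atoms, exact because TPSA contributions are local) restore additivity to the
tested 0.01 Da / 0.1 Å² tolerances.

## 2D descriptors and linker motifs

Descriptors are the standard RDKit set computed on the unprotonated input
form: average-mass MW, atom-contribution cLogP (minor non-additivity across
fragments accepted), TPSA, Lipinski N/O hydrogen-bond counts (N–H/O–H
donors; N and O acceptors — recorded because H-bond counts are
convention-dependent), and strict rotatable bonds.

Monoisotopic [M+H]⁺ masses use a hand-tabulated most-abundant-isotope table
and add one proton (1.00727646677 Da = H atom minus the electron). The value
is an analytical-chemistry identity check, so it is computed from the
elemental formula alone, never from a parsed structure.

Linker motif counting operates on the hydrogen-capped linker fragment.
Because capping turns the two attachment CH₂ units into CH₃, a "chain
carbon" is any non-ring sp³ carbon with 2–3 hydrogens and at most two heavy
neighbours; the alkyl run is the longest simple path through chain carbons.
PEG monomers are counted as the maximum set of pairwise atom-disjoint
O–CH₂–CH₂ triples, which is invariant to SMILES atom order and equals
"maximal non-overlapping repeats walked from the anchor" on an unbranched
chain; terminal partial repeats are not counted. Methyl branches on a chain
are counted as chain units (a deliberate simplification; real PROTAC linkers
are rarely methylated). Linker classes resolve mixed motifs with the fixed
precedence EMPTY > RINGS_ONLY > PEG_LONG (≥3 monomers, with or without
rings) > PEG_SHORT > ALKYL (run ≥ 3, no PEG) > RINGS_PLUS_SHORT_CHAINS >
OTHER.

## Contraction metrics

The 2D reference geometry is a deterministic depiction (CoordGen) with
hydrogens placed, rescaled so the mean heavy-atom bond length is 1.5 Å —
depiction coordinates carry no physical unit, and the rescaling makes the
2D/3D ratios of the contraction metrics reproducible and dimensionless.
d_max,2D is the exact sum of the three segments E3-COM→E3-anchor,
anchor→anchor, POI-anchor→POI-COM. Molecule contraction is
100 · d(E3 COM, POI COM)₃D / d_max,2D; linker contraction is
100 · d(anchor, anchor)₃D / d_linker,2D and is undefined (NotApplicable) for
an empty linker. Contraction centres of mass include hydrogens and are
mass-weighted by default (a flag excludes hydrogens); orientation centres of
mass exclude hydrogens (below). Values above 115% are flagged as 2D-depiction
distortion rather than clamped.

## Surface areas and polarity shielding

Exposed areas use deterministic Shrake–Rupley sphere sampling: a
golden-spiral lattice of 960 points per atom (configurable), Bondi van der
Waals radii, probe 1.4 Å for the solvent-accessible variant and 0 for the
van der Waals variant. PSA is the summed exposed area of polar atoms — N, O
and hydrogens bonded to them; sulfur is excluded by default and the polar
element set is configurable. Lattice sampling converges to well under 1% of
an independent Monte Carlo point-sampling oracle on small configurations
(tested at 2%). Polarity shielding per ensemble is
hidden = PSA_max − PSA_min and range fraction = 100 · hidden / PSA_max, with
minimum-PSA bins at 100/150/200 Å².

## Free-energy profiles

Profiles are G(z) in kJ/mol on strictly increasing z (Å from the bilayer
core at z = 0), default temperature 310 K, R = 8.314 J/(mol·K). The working
grid is uniform and symmetric, default ±35 Å at 1 Å slices (≈0.1 nm). The
bulk-water reference is the mean of G over |z| ≥ 30 Å (configurable), set to
zero.

Boltzmann combination of N conformer profiles uses the per-slice partition
sum with a uniform prior, G_ens = −RT ln[(1/N) Σ exp(−Gᵢ/RT)], evaluated via
log-sum-exp; it satisfies min Gᵢ ≤ G_ens ≤ min Gᵢ + RT ln N and returns
per-slice weights summing to one. A per-slice arithmetic mean is available
separately (`average_profiles`) for snapshot averaging (mean) and
across-compound summaries (median).

Barrier extraction searches the interface region 5 Å ≤ |z| ≤ 30 Å for the
global minimum (the two leaflet minima reduce to the deeper one); G at the
core is read at z = 0 exactly. Barriers: depth = −G_min (= barrier back to
water, since water is the zero reference), barrier to core = G_core − G_min,
dominant = the larger. If no sub-zero minimum exists the depth is 0 and
z_min is undefined. A short Savitzky–Golay smoother (quadratic, window 5
slices, disabled with window 1) suppresses per-slice noise before the
extremum search; it is exact on locally quadratic wells, so it introduces no
bias at the well widths the generator produces (≥3 Å) while roughly halving
the noise on the extracted values. Occupancy ratios are exp(−ΔG/RT); 53.5
kJ/mol at 310 K gives 9.7·10⁻¹⁰, i.e. below 0.001 ppm.

Profile clustering is complete-linkage agglomerative clustering (scipy) on
the raw G(z) vectors with Euclidean distance; labels are renumbered by first
occurrence so the partition is order-independent. The regression helper is
ordinary least squares with R². Permeability classes use half-open bins with
boundary values assigned upward; the default cutoffs 1·10⁻⁶ and 10·10⁻⁶ cm/s
are package defaults, not literature-prescribed values.

## Orientation groups

With the linker centre of mass translated to the origin (hydrogens excluded
from all orientation COMs), the three angles are (1) membrane normal ↔
linker→E3 vector, (2) normal ↔ linker→POI vector, (3) between the two domain
vectors, each via arccos of normalised dot products. The membrane normal is
+z, pointing toward the water side the molecule approached from. Sections
are [0,60), [60,120), [120,180] (180° closed into section 2, so the three
sections cover without double counting); the group index is 9·s₁ + 3·s₂ +
s₃ ∈ [0,26]. Note that the spherical triangle inequality makes some section
triples (e.g. both domains within 60° of −z but ≥120° apart) geometrically
unreachable; all 27 indices remain representable and the classifier is
surjective over arbitrary angle triples. Schematic labels follow a fixed
table: (0,2,·) extended POI-in, (2,0,·) extended E3-in, (1,1,·) flat,
(0,0,·)/(2,2,·) bent with both domains out/in, anything else "other".

## Assay reduction

Dialysis: fu = C_buffer/C_homogenate and Cb/Cu = (C_hom − C_buf)/C_buf, with
buffer readings below the LLOQ imputed at LLOQ/2 and flagged; C_buf = C_hom
is flagged degenerate (log ratio undefined). Mass balance is
100 · recovered amount / nominal amount over both chambers (defaults 0.2 and
0.35 mL).

Transport: the cumulative receiver amount is corrected for
withdrawn-and-replaced samples, Q(t_k) = C_R(t_k)·V_R + Σ_{j<k} C_R(t_j)·V_w
(V_R = 0.8 mL, V_w = 0.1 mL defaults); Papp = slope/(A·D) with the slope by
least squares over all receiver points (the origin included by default) and
A = 0.33 cm². D is the initial donor concentration by default — the raw-data
convention — with a time-averaged-donor mode for simulation round trips: the
10 µL donor samples each remove 5% of the donor mass, so against a forward
simulation the initial-donor convention is ~4% biased by design while the
time-averaged donor recovers a known Papp within 1% under sink conditions.
Recovery(%) over 0–120 min is
100 · (CR₁₂₀·V_R + CR₄₅·0.1 + CD₄₅·0.01 + CD₁₂₀·V_D)/(D₀·V_D), volumes in
mL, with the sampling volumes configurable. The forward simulator defines D₀
as the donor concentration after the time-zero sample and books exactly the
amounts this equation accounts for (constant chamber volumes), under which
the identity recovery = 100% holds to rounding on conservation-constructed
inputs.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) with a counter-based
Philox stream, and every dataset carries its ground truth.

- **Structures** are assembled from real E3 cores (three cereblon variants,
  one VHL core), parametric alkyl(n)/PEG(n) and ring-containing linkers, and
  small single-ring-system POI ligands of graded lipophilicity. They are
  chemically valid but far smaller and simpler than marketed degrader
  warheads; they exercise the decomposition and motif logic, not the
  descriptor distributions of real PROTAC space.
- **Conformer ensembles** are geometric constructions, not force-field
  samples: rigid E3/POI bodies (lifted from the 2D depiction) hinged at the
  anchors so the prescribed molecule/linker contraction is realised exactly,
  with seeded rigid jitter that cannot move the realised values, and
  relative energies from a truncated exponential (mean 5 kJ/mol, window
  21 kJ/mol, minimum shifted to 0). Passing tests therefore verify the
  measurement mathematics, not conformational sampling.
- **Profiles** are two symmetric interface Gaussian wells (depth, position,
  width) plus a core Gaussian barrier plus i.i.d. Gaussian noise; ground
  truth is extracted from the noise-free form on a 0.001 Å grid with the
  same bulk-water referencing as the analysis, and includes the profile's
  maximum interface-region |dG/dz| so recovery can be judged against
  max(2σ, grid spacing × slope bound) — the noise floor or the
  discretization bound, whichever dominates. Real COSMOmic profiles are
  asymmetric between leaflets and have correlated, depth-dependent errors;
  none of that is emulated.
- **Assays** forward-simulate the two-compartment transport system exactly
  (piecewise-linear ODE solution between sampling events) at standard assay
  conditions (0.1 µM dialysis, 10 µM donor, 0.2/0.8 mL chambers, 0.33 cm²),
  with multiplicative lognormal noise. Nonspecific binding, efflux and
  monolayer variability are not modelled.
- **Orientation states** are rejection-sampled pairs of uniform random unit
  vectors, so every generated state is geometrically consistent; the target
  group distribution must be over feasible groups.

Problem sizes used by the test suite and the acceptance script — 56-compound
cohorts, 200 noisy profiles, 20 surface-area configurations at 960 lattice /
6000 oracle points — were chosen as the smallest sizes at which the binomial
noise on the reported rates is comfortably below the tolerances being
checked.

## Known limitations

- POI delineation is heuristic (see above); a POI library with marked
  attachment points is the extension path for ambiguous real-world inputs.
- Conformational sampling, membrane MD and COSMO solvation are out of scope;
  profiles and ensembles come from files or the generators.
- No stereochemistry enumeration, tautomers or ionization-state prediction;
  descriptors are computed on the input (unprotonated) species.
- Barrier extraction reads G_core at z = 0 exactly and reports the literal
  minimum-to-extremum differences; it does not integrate a permeation model
  (inhomogeneous solubility–diffusion) over the profile.
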