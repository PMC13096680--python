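# Methods

## Scope and model form

The package estimates the lateral (radial) cohesive energy per
tropocollagen (TC) molecule in a fibril as the sum of five mechanism
energies, each computed as

    E_mechanism = (number of interactions) × (energy per interaction) / (divisors)

where divisors account for limited solvent/neighbour accessibility and
for double counting of contacts shared between two molecules. No atomic
coordinates are used anywhere: all counts are statistical expectations
over the residue composition of the molecule, and all per-interaction
energies are literature-calibrated constants modulated by hydration.
Axial (longitudinal) interactions, D-period gap/overlap structure,
cross-links and tissue-scale mechanics are out of scope.

Two built-in scenarios parameterise the model: `typeI` at 1.6 g water/g
dry collagen and `typeII` at 2.39 g/g. Everything that differs between
them is an explicit scenario field.

## Composition statistics

A TC molecule is three α-chains; residue counts are summed over chains
with a multiplicity field (type I is α1×2 + α2×1, type II α1×3).
Side-chain element counts are full amino-acid formulas minus the
repeating backbone unit C₂H₄NO₂ (glycine retains one side-chain
hydrogen; arginine yields C₄H₁₀N₃). Charged residues are Asp, Glu, Lys,
Arg. CH₂/CH₃ groups are counted only on predominantly aliphatic side
chains (Ala 1, Val 2, Leu/Ile/Pro/Met/Arg 3, Lys 4, Hyp 2, Hyl 3);
α-C–H groups and methylenes belonging to polar or aromatic side chains
are excluded as weak hydrophobic contributors. Hydroxyproline and
hydroxylysine carry internal codes `O` and `J`; database sequences
encode them as P/K, and the fixtures follow that convention.

## Hydration and geometry

Hydration C (g/g) converts to weight fraction C/(1+C) and, with phase
densities, to the water volume fraction φ_w = (C/ρ_w)/(C/ρ_w + 1/ρ_c).
The collagen density ρ_c = 1.35 g/cm³ is a calibration: it is the single
value for which both 1.6 and 2.39 g/g reproduce the adopted volume
fractions of 68.4% and 76.3%; it is exposed in every scenario.

Swelling is anisotropic: the triple-helix core diameter (10 Å) and axial
length are conserved, so added water inflates only the lateral cell
area. The lattice constant therefore scales as the square root of the
specific volume, taking 16.52 Å at 1.6 g/g to 19.1 Å at 2.39 g/g. The
radial gap is lattice minus core; its ratio between the two states
(9.1/6.52 ≈ 1.40) is the swelling factor applied to intermolecular
distances outside the core.

The effective dielectric uses the Maxwell Garnett mixture (protein host
ε_p = 4, water inclusions ε_w = 78), which is exact in the pure-phase
limits and strictly increasing in φ_w; it gives ≈21.2 (type I) and ≈27
(type II).

## The five mechanisms

**Direct hydrogen bonds.** Of N = 5,017 hydrogen-bonding sites per TC,
water occupies the Hill fraction θ(C) = Cⁿ/(K_dⁿ + Cⁿ) with n = 1 (no
cooperativity); the remainder form collagen–collagen bonds. K_d is
fitted from the type I anchor (392 direct bonds at 1.6 g/g), giving
K_d ≈ 0.136 and 269 bonds at 2.39 g/g. Per-bond energies are constants:
2.64 kcal/mol (type I) and 1.58 kcal/mol (type II). A linear
interpolation helper between the dry (4.79) and highly hydrated (1.58 at
6.6 g/g) limits is provided but is *not* used for the headline numbers:
no obvious interpolation coordinate (g/g, weight or volume fraction)
reproduces 2.64, so the adopted values are treated as calibrated
constants and the helper as exploratory. An independent calorimetric
conversion (17.74 J/g × 300 kDa) lands at ≈1,270 kcal/mol, the same
scale as the 392 × 2.64 ≈ 1,035 kcal/mol model value.

**Water-mediated bridges.** One bridge per Gly-X-Y triplet (1,078 /
1,216 per TC). A single-water bridge spans 4.92 Å donor-to-acceptor and
carries 0.46 kcal/mol; in the wetter fibril an extra water layer turns
single into double bridges (span 7.72 Å), attenuated by the
dipole–dipole decay (4.92/7.72)³ ≈ 0.26 to ≈0.12 kcal/mol. Each bridge
is shared by the two molecules it connects, hence a sharing divisor of
2 — this divisor is required for internal consistency with the explicit
double-counting correction used by the hydrophobic mechanism, and is the
only reading under which the per-type totals (248 / 72 kcal/mol) follow
from the stated counts and energies. The alternative "uniform swelling"
treatment — bridges keep their type but their path lengthens by the
radial gap increase (2.58 Å, one water diameter) — lands within
7 kcal/mol of the transformation treatment on the type II fixture and is
kept as a comparison utility.

**Van der Waals.** Accessible side-chain atoms (half of the total, by
triple-helix symmetry) interact with unordered-pair probabilities f_X²
(self) and 2 f_X f_Y (cross), which normalise to one; expected counts
are probabilities times the accessible total. Each element maps to a
representative protein force-field class (aliphatic sp³ C, carbonyl/
carboxyl O, amide N, aliphatic H, thioether S) with Lorentz–Berthelot
mixing; type I contacts sit at the LJ minimum (−ε per pair) and swollen
fibrils attenuate every pair by the same factor |E(s·r_min)|/ε. Because
a class-level parameterisation cannot settle the absolute scale (the
statistical estimate gives ≈249 kcal/mol for type I), the per-type
totals used in the assembled decomposition (414 / 125 kcal/mol) are
calibrated model constants, pinned in the scenarios and removable via
`vdw_total_pinned=None`. The pair *statistics* (probabilities, the 238
expected C–O contacts, the attenuation law) are fully computed and
tested.

**Hydrophobic.** Burying a CH₂/CH₃ group displaces structured water
worth 0.057 kcal/mol of entropy per molecule (1.1 kcal/mol per group at
19.2 waters/residue). Displaced-water counts are adopted per-type
constants (16.5 / 19.2); they are not proportional to bulk hydration, so
a mass-balance convention is included only for sensitivity studies. The
total divides by 2 (half the side chains face the helix interior) and by
2 again (shared contacts): 4,152 × 1.1 / 4 ≈ 1,142 kcal/mol for type II.

**Salt bridges.** With charged-residue fraction P, the chance that a
charged side chain finds an opposite charge among the n residues it can
face across the gap is 1 − (1−P)ⁿ, with n = 9 (type I) and 7 (type II);
the geometric rule behind n is not reconstructible from published
intermediates, so the windows are configured constants. Bridges are
shared (divisor 2) and the expectation is kept unrounded internally
(207.5 × 3.0 ≈ 622 kcal/mol). The per-pair energy is 3.0 kcal/mol at
type I hydration, scaled by ε_I/ε_II for other states (≈2.35 kcal/mol
for type II). Like-charge repulsion and long-range electrostatics are
neglected.

## Numerical conventions

Interaction counts that are physically integral (hydrogen bonds,
bridges, contact counts) use round-half-up before display; statistical
expectations (salt bridges, pair counts within the energy sum) stay
unrounded inside energy products. Totals are assembled from unrounded
components and rounded only for display, so the assembled totals
(3,046 / 2,206 kcal/mol) may differ by ~1–2 kcal/mol from sums of
rounded components. Reports serialize deterministically (fixed mechanism
order, no timestamps). Below the reference hydration the swelling factor
would drop under 1; dispersion contacts are then clamped at the LJ
minimum, since flexible side chains can always relax to contact.

## Synthetic data

The sequence generator emits strict Gly-X-Y chains with X/Y drawn
independently from configurable frequency tables under a seeded
generator; it emulates composition statistics only — no helical
register, no D-period, no real-sequence motifs — so tests based on it
validate the statistical pipeline, not residue-level structure. The
frozen per-TC fixture tables are synthetic summaries constructed by
constrained integer search (`scripts/build_fixture_tables.py`) to
satisfy all published composition statistics simultaneously (type I:
3,233 residues, 1,078 triplets, 522 charged, 165 Arg, side-chain C/O
frequencies 29.22%/3.95%, 3,073 CH₂/CH₃ groups, 238 expected C–O
contacts; type II: 3,648 residues, 1,216 triplets, 551 charged, 1,683
hydrophobic residues, 4,152 CH₂/CH₃ groups), with a weak prior pulling
the mix toward typical collagen composition. They are not real chain
compositions and cannot be audited residue-by-residue.

## Known limitations

- Absolute dispersion totals rest on calibrated constants (above); only
  their statistics are predictive.
- The 2.64 kcal/mol type I bond energy and the 16.5/19.2 displaced-water
  counts are adopted constants whose derivations are not reproduced.
- The uniform-hydration, average-geometry assumptions ignore local
  variation (gap vs overlap zones, cross-link heterogeneity,
  glycosylation).
- The bead-spring reference (6.72 kcal/mol × 218 beads × 6 neighbours ×
  F_gap/2 ≈ 3,911 kcal/mol) uses a gap-zone discount F_gap = 0.89 that
  is itself calibrated to the published result; it is a scale check,
  not an independent validation.
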