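# collagen-cohesion

Mesoscale energy decomposition of the lateral cohesion between
tropocollagen (TC) molecules in type I (tendon-like) and type II
(cartilage-like) collagen fibrils.

Collagen fibrils are held together radially by a balance of weak
interactions whose strengths shift with water content. This package
implements a statistical (coordinate-free) model that decomposes the
cohesive energy per TC molecule into five mechanisms and quantifies how
hydration — 1.6 g H₂O/g dry collagen in type I versus 2.39 g/g in
type II — modulates each one:

| mechanism | count model | energy model |
|---|---|---|
| direct hydrogen bonds | Hill competition with water, θ(C) = Cⁿ/(K_dⁿ + Cⁿ) over N = 5,017 sites | 2.64 / 1.58 kcal/mol per bond (hydration-dependent) |
| water-mediated bridges | one bridge per Gly-X-Y triplet | 0.46 kcal/mol single bridge; double bridges attenuated by (r₁/r₂)³ |
| van der Waals | pair probabilities P(X−Y) = 2 f_X f_Y over accessible side-chain atoms | Lennard-Jones wells with Lorentz–Berthelot mixing, swelling-attenuated |
| hydrophobic | CH₂/CH₃ group census of nonpolar side chains | 0.057 kcal/mol per displaced water × waters displaced per residue |
| salt bridges | P_coul = 1 − (1−P)ⁿ over n facing residues | 3.0 kcal/mol scaled by ε_I/ε_II (Maxwell Garnett effective medium) |

It is aimed at researchers building coarse-grained models of collagenous
tissues (tendon, bone, cartilage) who need per-mechanism cohesive energy
parameters rather than a single averaged intermolecular potential.

## Worked example

```python
from collagen_cohesion import run_scenario, scenario

for label in ("typeI", "typeII"):
    r = run_scenario(scenario(label))
    d = r.decomposition
    print(label, round(d.total_kcal_mol), {m: c.total_display for m, c in d.components.items()})
```

prints

```
typeI 3046 {'hbond': 1035, 'water_bridge': 248, 'vdw': 414, 'hydrophobic': 726, 'coulomb': 622}
typeII 2206 {'hbond': 425, 'water_bridge': 72, 'vdw': 125, 'hydrophobic': 1142, 'coulomb': 442}
```

Read: a type I TC molecule is bound to its neighbours by ≈3,046 kcal/mol,
dominated by direct hydrogen bonding (34%); the wetter type II fibril
loses ≈27% of that cohesion and flips to hydrophobic dominance (52%),
because water outcompetes direct hydrogen bonds, stretches dispersion
contacts, and screens salt bridges, while boosting the entropic gain of
burying CH₂/CH₃ groups.

Input compositions can come from FASTA chains
(`composition.read_fasta`), per-TC residue tables
(`composition.read_composition_tsv`), or the built-in synthetic fixtures
(`synthetic.fixture_profiles`); every scenario constant can be overridden
(`scenario("typeI", hydration_gg=2.0)`) or stored as YAML.

## Analysis scripts

The numbered scripts under `analysis/` walk through the study and write
their tables to `results/`:

1. `01_composition_profiles.py` — residue/atom statistics of both fixtures
2. `02_hydration_geometry.py` — weight/volume fractions, lattice spacing, swelling, dielectrics
3. `03_energy_components.py` — per-mechanism counts and energies, plus diagnostics
4. `04_decomposition.py` — assembled decompositions, cross-type comparison, bead-spring reference
5. `05_hydration_sweep.py` — cohesion versus hydration from 1.0 to 3.0 g/g

`scripts/build_fixture_tables.py` documents and re-verifies the
constrained construction of the synthetic composition fixtures.

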