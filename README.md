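# pedivis

Pedigree visualization and relatedness analysis for family data that has
outgrown hand drawing: multi-generational human pedigrees in behavior
genetics and genetic epidemiology, breeding pedigrees, and any study where
families run to hundreds or thousands of members, contain consanguineous
loops, remarriages, or twins, and need to be inspected, published, or
explored interactively.

The package is organised as a pipeline of small, separately usable stages:

1. **Data standardisation** (`pedivis.ped_model`, `pedivis.io`) — read
   pedigree CSV or PLINK `.fam` tables, normalise sex and missing-parent
   codes, validate structure (self-parenting, sex-inconsistent parents,
   dangling ids, ancestry cycles, twin-group consistency), pad single
   parents with placeholder co-parents, label families as connected
   components, and extract matrilines/patrilines.
2. **Coordinate calculation** (`pedivis.layout`) — a layered layout:
   longest-path generation leveling with spouse equalization, barycenter
   crossing-minimisation sweeps, duplicate symbols for individuals whose
   multiple matings cannot all be adjacent, and a bottom-up pass centering
   each couple over its children. Coordinates are abstract (one unit = one
   symbol slot; y = generation, increasing downward).
3. **Connection mapping** (`pedivis.connections`) — typed segments
   (spouse, drop, sibship bar, child stub, twin tie) computed from the
   layout tables, with quadratic-Bezier arcs replacing segments that would
   cut through unrelated symbols.
4. **Rendering** (`pedivis.render`, `pedivis.config`) — a static
   matplotlib figure and a self-contained interactive HTML document
   (hover tooltips, wheel zoom, drag pan) built from one shared draw list,
   steered by a schema of 176 documented aesthetic and layout parameters.
5. **Relatedness** (`pedivis.relatedness`, `pedivis.analysis`) — kinship
   coefficients by the classical recursion
   `phi(i,i) = (1 + phi(m_i, f_i))/2`,
   `phi(i,j) = (phi(m_i, j) + phi(f_i, j))/2`
   evaluated parents-first (founders non-inbred and unrelated), the
   additive matrix `A = 2 phi`, the 0/1 mitochondrial (matrilineal) matrix,
   relative highlighting, clustered relatedness heatmaps, and phenotypic
   correlation as a function of relatedness with Fisher-z confidence
   intervals.
6. **Synthetic data** (`pedivis.synth`) — a seeded forward-in-time
   pedigree generator and an additive polygenic phenotype simulator with
   chosen heritability, plus small hand-curated fixture pedigrees.

## Worked example

```python
import pedivis as pv

ped = pv.fixture("cousin_marriage")      # 10 people; X and Y are first cousins
print("valid:", pv.validate(ped).isValid)

a = pv.additive_matrix(ped)
print("additive(X, Y)  =", a.loc("X", "Y"))
print("additive(Z, Z)  =", a.loc("Z", "Z"))

layout = pv.compute_layout(pv.assign_families(ped))
for n in sorted(layout.nodes, key=lambda n: (n.y, n.x)):
    print(f"{n.personID:>3}  gen={n.generation}  x={n.x:.1f}")
print("crossings:", layout.crossingCount)
```

prints

```
valid: True
additive(X, Y)  = 0.125
additive(Z, Z)  = 1.0625
 G1  gen=0  x=0.5
 G2  gen=0  x=1.5
 P1  gen=1  x=0.0
 S1  gen=1  x=1.0
 P2  gen=1  x=2.0
 S2  gen=1  x=3.0
  W  gen=2  x=0.0
  X  gen=2  x=1.0
  Y  gen=2  x=2.0
  Z  gen=3  x=0.0
crossings: 2
```

`additive(X, Y) = 0.125` is the textbook first-cousin coefficient, and
`additive(Z, Z) = 1.0625 = 1 + 1/16` shows that Z, the child of that cousin
marriage, carries inbreeding coefficient F = 1/16. The layout block is the
drawing plan: grandparents centred over their children, each person one
slot apart, the consanguineous loop closed without duplicate symbols.

Figures come from the same objects:

```python
fig = pv.plot_static(ped)                       # matplotlib Figure
widget = pv.plot_interactive(ped)               # self-contained HTML
widget.save("family.html")
```

## Command line

Every stage is also a subcommand (`pedivis --help`):

```
pedivis simulate --generations 6 --founding-couples 3 --seed 42 --out synth.csv
pedivis validate synth.csv
pedivis layout synth.csv --out layout.csv
pedivis connections synth.csv --out segments.csv
pedivis relatedness synth.csv --kind additive --out matrix.csv
pedivis heatmap matrix.csv --cluster --out heat.png
pedivis pbd synth.csv --phenotype trait --summary pbd.csv
pedivis plot synth.csv --out fig.png --set symbols.size=0.4
pedivis plot synth.csv --interactive --out fig.html
```

Exit codes are 0 (success), 1 (validation failure), 2 (usage error), and
every written artifact gets a `.manifest.json` recording the command,
configuration overrides, input checksum, version and seed.

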