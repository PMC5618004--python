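# pentaweb

Steady-state theory, Lotka–Volterra simulation and community-fingerprint
statistics for the *pentagon* microbial food web — the five-compartment
trophic module of free phosphate (P), autotrophic flagellates (A),
heterotrophic prokaryotes (B), heterotrophic nanoflagellates (H) and
ciliates (C), closed from above by copepod predation.

The package is aimed at microbial ecologists studying how the predator
chain sets the growth-limitation regime of heterotrophic prokaryotes in
nutrient-enrichment mesocosms, and how that regime propagates into the
responsiveness of bacterial and viral communities to labile organic-carbon
additions.

## The model

Under steady state ("growth = loss") with linear functional responses, the
pentagon collapses to closed forms in ciliate biomass *C* (nmol-P L⁻¹):

```
B  = α_C C / (Y_H α_H)          prokaryote biomass
P  = (α_C / α_A) C              free phosphate
μ  = α_B P                      prokaryote growth rate
```

Bacterial carbon demand (BCD) is production over yield, capped by the
labile-DOC supply rate ψ:

```
BCD = min( k C²,  ψ ),    k = α_B α_C² / (Y_BC Y_H α_H α_A)
```

Below the crossover `C* = sqrt(ψ/k)` the prokaryotes are
mineral-nutrient-limited (**MNL**) and indifferent to added glucose; above
it they are organic-carbon-limited (**OCL**) and highly responsive.  A Q10
factor rescales the rate constants away from the 17 °C reference, and the
conversion factor σ (nmol-P per ciliate cell, derived from a 20 μm
spherical cell at 0.13 pg-C μm⁻³ and molar C:P = 106) maps microscope
counts (cells mL⁻¹) onto biomass.

Around this core the package provides:

* `pentaweb.dynamics` — an explicit ODE reconstruction of the pentagon
  (bilinear grazing, Liebig minimum of P- and C-limited growth, copepod
  closure, impulse glucose dosing) whose steady states reproduce the
  closed forms;
* `pentaweb.fingerprints` — Jaccard distances, Kruskal nonmetric MDS
  (SMACOF + monotone regression), symmetric Procrustes superposition with
  a permutation test (protest), the repeated-NMDS coupling ensemble,
  one-factor PERMANOVA, Pearson tests and the virus-to-prokaryote ratio;
* `pentaweb.synth` — generators for the two mesocosm designs, ODE-driven
  abundance/virus-count tables, paired host/virus band matrices with
  tunable coupling, and the inverse fit of (k, ψ) from (C, BCD) data;
* `pentaweb.io` / the `pentaweb` CLI — TSV/YAML round-trip I/O and run
  manifests.

## Worked example

```sh
pentaweb steady-state --params examples/params.yaml --ciliates 1,7
```

```
C	B	P	mu	bcd	regime
1.0	1.1111111111111112	0.0125	0.001	0.18518518518518517	MNL
7.0	7.777777777777779	0.08750000000000001	0.007000000000000001	3.0	OCL
```

At 1 nmol-P L⁻¹ of ciliates (≈ 2.3 cells mL⁻¹) the prokaryotes sit deep in
the MNL regime: carbon demand (0.185 nmol-C L⁻¹ h⁻¹) is far below the
supply ψ = 3.  At 7 nmol-P L⁻¹ (≈ 16 cells mL⁻¹), demand has crossed the
supply ceiling and growth is carbon-limited — this tank would respond
strongly to a glucose pulse.  The same contrast emerges dynamically:

```python
import pentaweb as pw
from pentaweb import synth

params = pw.example_parameters()
design = synth.generate_design("PAME-I")
for regime in ("high", "low"):
    table = synth.simulate_experiment(design, params, regime, noise_cv=0.0, seed=0)
    prok = table[(table.variable == "prokaryotes") & (table.day == 12)]
    b0 = prok[prok.glucose_x == 0.0].value.mean()
    b3 = prok[prok.glucose_x == 3.0].value.mean()
    print(regime, f"{100 * (b3 - b0) / b0:.1f}% response to 3x glucose")
```

```
high 161.6% response to 3x glucose
low 0.0% response to 3x glucose
```

On the fingerprint side, perfectly coupled host/virus band matrices give a
median Procrustes correlation of 1.0 with 100% of ensemble repetitions
significant, while independent matrices are called significant at the
nominal 5% rate (see `pentaweb stats couple --help`).

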