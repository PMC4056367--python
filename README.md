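# focal — forced coupling analysis for metabolic models

`focal` designs experiments for testing genome-scale metabolic models. Given a
constraint-based model and a reaction of interest, it searches for a **coupling
condition** — a minimal-media composition plus a small set of gene deletions —
under which flux through the chosen reaction becomes *required* for flux
through an experimentally measurable reaction (typically biomass production).
Growing the proposed mutant on the proposed medium then tests whether the
chosen reaction really occurs: if the model says the reaction is conditionally
essential and the strain grows (and a further deletion of the chosen reaction
abolishes growth), the network connection is supported; disagreements point at
missing isozymes, wrong gene–protein–reaction (GPR) rules, or regulation.

The same machinery designs strains with engineered phenotypes, e.g. mutants
that *must* co-utilize two carbon sources to grow — a strong selection for
substrate co-utilization in adaptive evolution.

Intended users: systems-biology and metabolic-engineering groups working with
COBRA-style models (SBML/FBC, COBRA JSON) who want model-testing experiments
or co-utilization strain designs without exhaustively simulating every
media × knockout combination.

## The optimization problem

All fluxes are first made nonnegative by splitting each reversible reaction
into forward and reverse components, and normalized by the measured flux,

$$\hat v_j = v_j \cdot t, \qquad t = 1 / v_{\text{measured}},$$

so that flux ratios become linear. The **inner problem** is the flux-coupling
LP: minimize $\hat v_{\text{chosen,for}} + \hat v_{\text{chosen,rev}}$ subject
to steady-state mass balance over unblocked reactions, uptake caps
$\hat v_{x,\text{rev}} \le t \cdot v_x^{\text{MaxUptake}}$ for exchanges, the
selected measured component pinned to 1, zero flux through deleted reactions,
and zero uptake through unselected media exchanges. A positive minimum
certifies $v_{\text{measured}} \rightarrow v_{\text{chosen}}$.

The **outer problem** picks the binary decisions — measured flux $c$, media
composition $h_x$ with type assignments $m_{x,k}$ over four component sets
(carbon, nitrogen, electron acceptor, additional), and gene knockouts
$ko_g$ mapped to reaction states $a_j$ through the GPR rules — to maximize

$$\big(r_{\text{obj}}(\Delta_{\max}+1) - 1\big)
  \;-\; \alpha \sum_g (1-ko_g) \;-\; \beta \sum_x m_{x,\text{additional}},$$

where $r_{\text{obj}} = 1$ is allowed only when the inner minimum clears an
acceptance margin $\varepsilon$. Per-type media caps ($\text{maxMedia}_k$),
deletion limits $\Delta_{\min} \le \sum_g (1-ko_g) \le \Delta_{\max}$ and an
optional one-type-per-exchange rule complete the outer constraints.

The bi-level program is solved as a **single-level MILP** by adding the inner
LP's dual constraints and a strong-duality equality; binary-controlled bounds
are handled OptKnock-style with products of dual variables and outer binaries
linearized exactly by McCormick envelopes. Alternative conditions are
enumerated with integer cuts that exclude each found solution and its
supersets. Every coupled answer is re-verified by independent FBA and
flux-ratio LPs before being returned. Defaults: $\alpha = 1$, $\beta = 0.25$,
$\Delta_{\max} = 5$, $\varepsilon = 10^{-5}$.

## Worked example

The bundled example network has two substrates: A feeds biomass component F
through an upper pathway (v1 → v2 → v4) and a lower pathway (v3 → v8), G
feeds component H (v10 → v7/v9). In the wild type v2 is dispensable; `focal`
finds the condition that makes it essential:

```python
from focal import *
from focal.model_core import fwd
from focal import flux_analysis as fa
from focal.synthetic_fixtures import make_example_network, example_media_sets

model = make_example_network()
sets = example_media_sets()
split = split_reversible(model)
split = split.with_blocked(fa.find_blocked_reactions(split, fa.all_nutrient_context(sets)))

problem = CouplingProblem(split=split, chosen=["v2"],
                          coupling_set=[fwd("vbio")], media_sets=sets)
sol = solve_focal(problem)
print(sol.to_json())
report = verify_solution(problem, sol)
print(f"growth under condition: {report.growth:.1f}")
print(f"v2 essential: {report.essential['v2']}, min ratio: {report.min_ratios['v2']:.3f}")
```

prints

```
{
  "status": "coupled",
  "measured": "vbio:fwd",
  "media": [
    {
      "exchange": "EX_A",
      "type": "carbon"
    }
  ],
  "knockouts": [
    "gv8"
  ],
  "inner_objective": 1.0,
  "outer_objective": 4.0
}
growth under condition: 5.0
v2 essential: True, min ratio: 1.000
```

Read this as: grow a Δgv8 mutant on A as the sole carbon source. Under that
condition every unit of biomass flux forces one unit of v2 flux (minimum flux
ratio 1.0), the strain still grows (biomass flux 5.0 at an uptake cap of 10),
and additionally deleting v2 is lethal — so a growth assay on this mutant and
medium directly tests whether v2 occurs. The outer objective 4.0 is the
coupling reward (Δmax + 1) − 1 = 5 minus one deletion penalty.

The same interface designs co-utilizing strains: with `chosen=["v1", "v10"]`
and two carbon sources allowed, `design_coutilization` returns the double
deletion {gv3, gv8} on media {A, G} — a mutant that grows on both substrates
together (biomass flux 10.0) but on neither alone (0.0).

A CLI mirrors the library:

```bash
focal couple    --model example.tsv --media media.tsv --chosen v2
focal coutilize --model example.tsv --media media.tsv --chosen v1,v10 --max-carbon 2
focal couple-all --model example.tsv --media media.tsv --out outcomes.tsv
focal verify    --model example.tsv --media media.tsv --chosen v2 --solution sol.json
```

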