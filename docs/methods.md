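# Methods

## Model representation and preprocessing

A model is a stoichiometric matrix $S_{ij}$ over metabolites $i \in M$ and
reactions $j \in R$, a reversibility flag per reaction, boolean GPR rules over
genes $G$, and a distinguished biomass reaction. Exchange reactions are
auto-detected as single-metabolite boundary reactions (the biomass demand is
excluded even when it drains one precursor) and normalized to the
*export-positive* orientation: the forward component secretes, the reverse
component takes the nutrient up. Uptake magnitudes are deliberately **not**
taken from input files — reversibility is the only bound information retained;
uptake caps come from the media configuration. Models with forced nonzero
fluxes (e.g. ATP maintenance lower bounds) are therefore relaxed on loading;
this is a known limitation for genome-scale work and can be compensated by
adding the forced reaction to the chosen set of interest or pre-fixing the
model.

Every reversible reaction is split into forward and reverse components with
negated stoichiometry, so all component fluxes are nonnegative — the
precondition for the flux-ratio normalization. Blocked reactions (zero flux in
flux variability analysis when every selectable exchange is open at maximum
uptake) are recorded on the split model and excluded from all balances.

Media are organized into four component types — carbon, nitrogen, electron
acceptor, additional — via a membership table over exchanges, with a per-type
selection cap `maxMedia` (default 1; 2 for carbon in co-utilization designs),
a `Minimal` set of always-open exchanges that are never decision variables,
and a per-exchange maximum uptake rate in mmol·gDW⁻¹·h⁻¹ (fixture default 10).
An exchange may be listed under several types; by default an optional rule
restricts each selected exchange to a single type assignment (toggle
`no_multi_type`). An FBA screening mode drops membership entries whose
exchange cannot support growth as the sole member of its type.

## The flux-ratio inner problem

Coupling between a chosen reaction and a measured flux is quantified in the
normalized space $\hat v_j = v_j t$, $t = 1/v_{\text{measured}}$: minimize
$\hat v_{\text{chosen,for}} + \hat v_{\text{chosen,rev}}$ subject to

* mass balance over unblocked components,
* $\hat v_{x,\text{rev}} \le t\, v_x^{\text{MaxUptake}}$ for exchanges,
* the selected measured component equal to 1,
* zero flux for GPR-disabled reactions and unselected non-Minimal exchanges.

A positive minimum means flux through the measured reaction is impossible
without flux through the chosen one. The general pairwise classifier also
calls a pair coupled when the *maximum* ratio is finite (the contrapositive
direction); the coupling-design acceptance uses only the minimum.

Numerical bounds: normalized fluxes are capped at $U_v = 10^3$ and $t$ at
$U_t = 10^3$ (configurable). The $t$ cap means conditions are only considered
growth-supporting when the measured flux can reach $1/U_t = 10^{-3}$ of the
normalization unit under the given uptake caps; with fixture uptakes of 10
this is far below any real optimum and never binds. The in-silico growth
threshold for essentiality checks is $10^{-6}$ (configurable) — the
literature reports only experimental OD thresholds, so this is a project
choice well below any meaningful growth rate and above solver noise.

## Single-level reformulation

The bi-level search (outer binaries, inner LP minimum) is collapsed into one
MILP: the inner primal constraints, the inner dual constraints, and a
strong-duality equality are all imposed simultaneously, so any feasible point
has the inner problem at its exact minimum for the chosen binaries. The
published single-level form of this algorithm is only available in a
supplement we do not use; the dual here is derived directly from the primal
above, with binary-controlled bounds handled as in OptKnock: the binary
multiplies the bound on the primal side, and the dual-variable × binary
products that then appear in the strong-duality row are linearized with
McCormick envelopes. The linearization is exact provided the dual variables
entering products stay below an explicit cap $D = 10^3$; the cap can in
principle truncate the dual (which would make the MILP miss couplings, never
fabricate them), so the equivalence suite below checks against exhaustive
search, and a strong-duality test re-solves primal and dual in isolation at
every coupled optimum (gap ≤ 10⁻⁶ required).

Acceptance couples the binary $r_{\text{obj}}$ to the inner optimum via
$r_{\text{obj}} \le \hat v_{\text{chosen,for}} + \hat v_{\text{chosen,rev}}
+ 1 - \varepsilon$ with $\varepsilon = 10^{-5}$ by default ($10^{-4}$ is the
suggested preset for badly scaled models). GPR rules are encoded exactly with
one auxiliary binary per AND/OR node so the reaction state equals the rule's
truth value under the knockout assignment; orphan reactions are permanently
active. The outer objective rewards coupling with $\Delta_{\max}+1$ and
penalizes deletions ($\alpha = 1$) and additional nutrients ($\beta = 0.25$);
validation requires $\alpha\Delta_{\max} + \beta\,n_{\text{additional}} <
\Delta_{\max}+1$ so that penalties can never outweigh the coupling reward and
any coupled solution beats the uncoupled baseline of −1.

Degenerate and failure cases: a chosen reaction in the blocked set
short-circuits to status `blocked` without building the MILP; an infeasible
MILP (no admissible condition sustains any measured flux) reports
`infeasible`; binary assignments under which the inner LP is infeasible (the
condition kills the measured flux) are simply pruned by the solver, which
realizes the "treat as not coupled" convention.

### Solver hygiene

MILPs are solved with HiGHS through scipy. Big-M rows amplify the solver's
integer feasibility slack — a binary at $1 - 10^{-8}$ can fake exactly
$\varepsilon$ of strong-duality slack — so HiGHS runs with tightened
tolerances (`mip_feasibility_tolerance` $10^{-9}$), **and** every coupled
incumbent is re-verified with independent LPs (growth under the condition,
lethality of the additional chosen-reaction deletion, minimum ratio at or
above $\varepsilon$). A spurious incumbent triggers a no-good cut on its exact
outer binary assignment and a re-solve, so correctness never rests on solver
tolerances; unverifiable couplings are never returned silently. Variable
ordering is deterministic (model order, sorted gene/exchange ids) and HiGHS
is deterministic given a fixed model, so runs are reproducible.

### Search policy

The reference implementation used CPLEX incumbent callbacks; here the policy
is a generic time budget (default 300 s per problem, configurable — the
original genome-scale runs used hours). An optional staged pass solves a
reduced-media problem first (budgeted by `incumbent_extension`, default 30 s)
before the full media set, mirroring the reduced-set-first strategy used at
genome scale. scipy's HiGHS interface exposes only a global time limit, so
the incumbent-extension idea is realized as the staged pass budget. A
time-limited solve that produced a verified coupled incumbent is returned
with a note that optimality was not proven.

### Alternatives and co-utilization

Integer cuts $\sum_{g \in \text{OldKO}} (1 - ko_g) + \sum_{x \in
\text{OldMedia}} h_x \le |\text{OldKO}| + |\text{OldMedia}| - 1$ forbid a
previous solution and its supersets; variants omit the knockout or media term.
Enumeration iterates cuts until the problem turns uncoupled or a cap is hit.

Co-utilization designs instantiate **one inner primal/dual copy and one
acceptance constraint per chosen reaction**, all sharing the outer binaries:
the returned condition makes each chosen reaction *individually* essential.
(Minimizing the sum of chosen fluxes instead would allow one reaction to
carry the whole minimum; the per-reaction form is the faithful reading of
"multiple reactions are required".)

## Exhaustive oracle

`brute_force_coupling_search` enumerates every media assignment respecting
the per-type caps and every knockout set up to $\Delta_{\max}$, in ascending
penalty order (ties broken lexicographically), testing coupling with the same
inner LP; the first coupled condition is therefore an outer optimum. A guard
refuses instances beyond $10^6$ combinations. Its independence from the MILP
lies in the search itself — no duality, no big-M, no integrality — which is
exactly what the MILP can get wrong; the equivalence suite compares verdicts
and outer objectives on every (network, chosen reaction) pair of a seeded
20-network suite (8–12 reactions, 2–3 media candidates, $\Delta_{\max} = 2$ —
sizes chosen to keep exhaustive enumeration itself tractable).
`brute_force_enumerate` mirrors integer-cut semantics (descending objective,
superset filtering) for the enumeration-completeness check.

## Synthetic fixtures

`make_example_network` ships the two-substrate illustrative network. Its
published stoichiometry is not available, so the fixture is specified
*behaviourally* — (i) v2 dispensable in the wild type on {A, G}; (ii) v2
conditionally essential on A with v8 deleted; (iii) Δv3Δv8 forces
co-utilization of A and G; (iv) v4 coupled to v2 — and the shipped wiring
(A → upper v1/v2/v4 and lower v3/v8 routes to component F; G → v10/v7/v9 to
component H; v5/v6 a futile pair) was chosen so that, additionally, the
single-coupling and co-utilization optima are *unique*: {Δgv8, A} and
{Δgv3, Δgv8, {A, G}} respectively. That uniqueness is what lets regression
tests assert exact answers rather than membership in a tie set.

`make_random_network` builds seeded viable networks: a guaranteed
substrate-to-biomass backbone, extra exchanges entering at random metabolites,
and random internal conversions (reversible with a configurable fraction);
GPRs are one gene per reaction by default (so deletion counts equal reaction
knockouts, simplifying oracle comparisons) or random isozyme OR-pairs. The
generator emulates small bacterial central-metabolism topologies — branching,
redundancy, reversibility — but not genome-scale features (compartments,
cofactor coupling, complex GPRs, forced maintenance fluxes), so passing the
randomized suites demonstrates algorithmic correctness, not genome-scale
performance or biological accuracy.

## Reporting

Outcome tables are summarized into category counts/percentages, deletion
histograms and per-subsystem breakdowns. The deletion-distance analysis
builds a reaction graph (edges between reactions sharing a non-currency
metabolite; the directed variant links producers to consumers, reversible
reactions both ways; the default currency list covers protons, water,
ATP/ADP/AMP, NAD(P)(H), CoA, CO₂, O₂, NH₄, Pi, PPi and is user-replaceable
since the published choice is not available). Observed distances are directed
shortest paths from each deleted reaction to its chosen reaction, restricted
to single-deletion outcomes by default (averaging over multi-deletion sets is
an option); the baseline resamples deleted reactions uniformly (seeded), and
a one-tailed Welch t-test (the published analysis states only "one-tailed
t-test"; Welch avoids the equal-variance assumption) asks whether observed
distances are smaller. Unreachable pairs are excluded and counted.

## Problem sizes and defaults used in the shipped checks

The test and acceptance suites run the example network (13 reactions) with
$\Delta_{\max} = 5$ and twenty seeded random networks of 8–12 reactions with
$\Delta_{\max} = 2$ and 2–3 carbon candidates; these sizes keep the
exhaustive oracle exact and the whole verification loop comfortably fast
while exercising every constraint family of the MILP. Genome-scale models are
supported through the same interfaces (SBML/FBC, COBRA JSON) with the staged
time-budget policy, but no genome-scale result is asserted by the shipped
checks.

## Known limitations

* Input flux bounds beyond reversibility are not retained (see above).
* Regulatory constraints and gene-level (rather than reaction-level) coupling
  are out of scope.
* The dual-variable cap $D$ and big-M caps $U_v$, $U_t$ are finite; grossly
  rescaled models should raise them (and $\varepsilon$) together.
* The pairwise classifier implements only the coupled/uncoupled rule used by
  the design algorithm, not the full flux-coupling taxonomy.
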