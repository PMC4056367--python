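"""LP-level analyses on split metabolic models.

Flux balance analysis, flux variability, blocked-reaction detection, pairwise
flux-ratio coupling in the normalized (Burgard-style) space, conditional
essentiality, and an exhaustive search over media/knockout conditions that
serves as the independent oracle for the bi-level MILP.

The flux-ratio LPs work on *normalized* fluxes: every component flux is scaled
by ``t = 1 / v_measured`` so the measured component is pinned at 1 and uptake
caps become ``v̂_rev <= t * MaxUptake``.  Minimum flux ratio > 0 certifies that
flux through the measured reaction requires flux through the chosen one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from ._solver import INF, LinearProgram, SolveStatus
from .model_core import (
    MediaComponentSets,
    MetabolicModel,
    SplitModel,
    fwd,
    rev,
)

__all__ = [
    "FLUX_CAP",
    "GROWTH_THRESHOLD",
    "NORM_FLUX_CAP",
    "T_CAP",
    "FluxSolution",
    "MeasuredInfeasible",
    "MediaContext",
    "all_nutrient_context",
    "brute_force_coupling_search",
    "brute_force_enumerate",
    "classify_pair",
    "enumerate_conditions",
    "fba",
    "find_blocked_reactions",
    "flux_variability",
    "is_conditionally_essential",
    "max_flux_ratio",
    "media_context",
    "min_flux_ratio",
]

# default caps; unnormalized internal fluxes and normalized (t-scaled) fluxes
FLUX_CAP = 1000.0
NORM_FLUX_CAP = 1000.0  # big-M cap on v̂ components
T_CAP = 1000.0  # cap on the normalization variable t
GROWTH_THRESHOLD = 1e-6
UNBOUNDED_PROBE = 1e6


class MeasuredInfeasible(RuntimeError):
    """The measured component cannot carry flux under the given context."""


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    t: float | None = None


@dataclass(frozen=True)
class MediaContext:
    """Open exchanges (with uptake caps) plus gene knockouts.

    Minimal exchanges are expected to be part of ``open_exchanges``; use
    :func:`media_context` to build contexts from :class:`MediaComponentSets`.
    """

    open_exchanges: dict[str, float]
    knockouts: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "open_exchanges", dict(self.open_exchanges))
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))

    def disabled_reactions(self, model: MetabolicModel) -> frozenset[str]:
        return model.disabled_reactions(self.knockouts)


def media_context(
    sets: MediaComponentSets,
    selected: set[str] | frozenset[str] = frozenset(),
    knockouts: set[str] | frozenset[str] = frozenset(),
) -> MediaContext:
    """Context with the Minimal set always open plus the selected exchanges."""
    unknown = set(selected) - sets.selectable
    if unknown:
        raise ValueError(f"selected exchanges not in media sets: {sorted(unknown)}")
    open_exch = {x: sets.max_uptake[x] for x in sets.minimal}
    open_exch.update({x: sets.max_uptake[x] for x in selected})
    return MediaContext(open_exchanges=open_exch, knockouts=frozenset(knockouts))


def all_nutrient_context(sets: MediaComponentSets) -> MediaContext:
    """All selectable exchanges open at maximum uptake (blocked-reaction setting)."""
    return media_context(sets, selected=sets.selectable)


# ---------------------------------------------------------------------------
# Unnormalized LPs: FBA / FVA / blocked reactions
# ---------------------------------------------------------------------------


def _flux_lp(
    split: SplitModel,
    ctx: MediaContext,
    extra_disabled: frozenset[str] = frozenset(),
    flux_cap: float = FLUX_CAP,
) -> LinearProgram:
    model = split.parent
    exchanges = set(model.exchanges)
    disabled = ctx.disabled_reactions(model) | extra_disabled
    lp = LinearProgram("fba")
    for comp in split.unblocked_components:
        rxn, sign = split.origin(comp)
        if rxn in disabled:
            ub = 0.0
        elif rxn in exchanges and sign < 0:  # uptake side of an exchange
            ub = ctx.open_exchanges.get(rxn, 0.0)
        else:
            ub = flux_cap
        lp.add_var(comp, lb=0.0, ub=ub)
    balance: dict[str, dict[str, float]] = {}
    for comp in split.unblocked_components:
        for met, coef in split.component_column(comp).items():
            balance.setdefault(met, {})[comp] = coef
    for met, coeffs in balance.items():
        lp.add_constr(coeffs, "==", 0.0, tag="balance", name=f"mb[{met}]")
    return lp


def fba(
    split: SplitModel,
    ctx: MediaContext,
    objective_component: str,
    extra_disabled: frozenset[str] = frozenset(),
) -> FluxSolution:
    """Maximize one component flux subject to balance, media and knockouts."""
    lp = _flux_lp(split, ctx, extra_disabled)
    lp.sense = "max"
    lp.set_objective_coeff(objective_component, 1.0)
    res = lp.solve()
    if res.status is SolveStatus.INFEASIBLE:
        return FluxSolution("infeasible", None)
    if res.status is SolveStatus.UNBOUNDED:
        return FluxSolution("unbounded", None)
    return FluxSolution("optimal", res.objective, res.values)


def flux_variability(
    split: SplitModel,
    ctx: MediaContext,
    components: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-component (min, max) flux over the feasible region of the context."""
    lp = _flux_lp(split, ctx)
    comps = components if components is not None else split.unblocked_components
    out: dict[str, tuple[float, float]] = {}
    for comp in comps:
        lo_hi = []
        for sense in ("min", "max"):
            lp.sense = sense
            for other in lp.variables:
                lp.set_objective_coeff(other, 1.0 if other == comp else 0.0)
            res = lp.solve()
            if not res.ok:
                raise RuntimeError(
                    f"FVA {sense} of {comp!r} failed ({res.status.value}) under context "
                    f"open={sorted(ctx.open_exchanges)} ko={sorted(ctx.knockouts)}"
                )
            lo_hi.append(res.objective)
        out[comp] = (lo_hi[0], lo_hi[1])
    return out


def find_blocked_reactions(
    split: SplitModel,
    all_nutrients: MediaContext,
    tol: float = 1e-6,
) -> frozenset[str]:
    """Reactions whose every component is stuck at zero flux even when every
    selectable nutrient is provided at maximum uptake."""
    fva = flux_variability(split, all_nutrients)
    blocked = set()
    for rxn in split.unblocked_reactions:
        if all(abs(fva[c][0]) <= tol and abs(fva[c][1]) <= tol for c in split.components_of(rxn)):
            blocked.add(rxn)
    return frozenset(blocked)


# ---------------------------------------------------------------------------
# Normalized flux-ratio LPs
# ---------------------------------------------------------------------------


def _ratio_lp(
    split: SplitModel,
    measured_component: str,
    ctx: MediaContext,
    extra_disabled: frozenset[str] = frozenset(),
    capped: bool = True,
    norm_cap: float = NORM_FLUX_CAP,
    t_cap: float = T_CAP,
) -> LinearProgram:
    """The inner flux-coupling LP with the measured component normalized to 1."""
    model = split.parent
    exchanges = set(model.exchanges)
    disabled = ctx.disabled_reactions(model) | extra_disabled
    comps = split.unblocked_components
    if measured_component not in comps:
        raise MeasuredInfeasible(f"measured component {measured_component!r} not in model")
    lp = LinearProgram("ratio")
    cap = norm_cap if capped else INF
    for comp in comps:
        rxn, sign = split.origin(comp)
        lp.add_var(comp, lb=0.0, ub=0.0 if rxn in disabled else cap)
    lp.add_var("t", lb=0.0, ub=t_cap if capped else INF)
    balance: dict[str, dict[str, float]] = {}
    for comp in comps:
        for met, coef in split.component_column(comp).items():
            balance.setdefault(met, {})[comp] = coef
    for met, coeffs in balance.items():
        lp.add_constr(coeffs, "==", 0.0, tag="balance", name=f"mb[{met}]")
    for comp in comps:
        rxn, sign = split.origin(comp)
        if rxn in exchanges and sign < 0:
            if rxn in ctx.open_exchanges:
                lp.add_constr(
                    {comp: 1.0, "t": -ctx.open_exchanges[rxn]},
                    "<=",
                    0.0,
                    tag="uptake",
                    name=f"up[{rxn}]",
                )
            else:
                lp.set_bounds(comp, ub=0.0)
    lp.add_constr({measured_component: 1.0}, "==", 1.0, tag="measured", name="meas")
    return lp


def _chosen_objective(split: SplitModel, chosen: str) -> dict[str, float]:
    return {c: 1.0 for c in split.components_of(chosen)}


def min_flux_ratio(
    split: SplitModel,
    chosen: str,
    measured_component: str,
    ctx: MediaContext,
    extra_disabled: frozenset[str] = frozenset(),
) -> float:
    """Minimum of (v̂_chosen,for + v̂_chosen,rev) with the measured flux at 1.

    A positive value certifies v_measured -> v_chosen.  Raises
    :class:`MeasuredInfeasible` when the measured component cannot carry flux
    under the context.
    """
    lp = _ratio_lp(split, measured_component, ctx, extra_disabled)
    for comp, coef in _chosen_objective(split, chosen).items():
        lp.set_objective_coeff(comp, coef)
    res = lp.solve()
    if res.status is SolveStatus.INFEASIBLE:
        raise MeasuredInfeasible(
            f"measured component {measured_component!r} infeasible under context"
        )
    if not res.ok:
        raise RuntimeError(f"ratio LP failed: {res.status.value}")
    return max(0.0, res.objective)


def max_flux_ratio(
    split: SplitModel,
    chosen: str,
    measured_component: str,
    ctx: MediaContext,
    extra_disabled: frozenset[str] = frozenset(),
) -> float:
    """Maximum normalized chosen flux; ``inf`` when the LP is unbounded."""
    lp = _ratio_lp(split, measured_component, ctx, extra_disabled, capped=False)
    lp.sense = "max"
    for comp, coef in _chosen_objective(split, chosen).items():
        lp.set_objective_coeff(comp, coef)
    res = lp.solve()
    if res.status is SolveStatus.INFEASIBLE:
        raise MeasuredInfeasible(
            f"measured component {measured_component!r} infeasible under context"
        )
    if res.status is SolveStatus.UNBOUNDED:
        return math.inf
    if res.ok:
        return res.objective
    # some solver paths report unboundedness unreliably: re-solve with a large
    # artificial cap and treat a solution at the cap as unbounded
    lp2 = _ratio_lp(
        split, measured_component, ctx, extra_disabled, capped=True,
        norm_cap=UNBOUNDED_PROBE, t_cap=UNBOUNDED_PROBE,
    )
    lp2.sense = "max"
    for comp, coef in _chosen_objective(split, chosen).items():
        lp2.set_objective_coeff(comp, coef)
    res2 = lp2.solve()
    if not res2.ok:
        raise RuntimeError(f"ratio LP failed: {res.status.value} / {res2.status.value}")
    return math.inf if res2.objective >= 0.99 * UNBOUNDED_PROBE else res2.objective


def classify_pair(
    split: SplitModel,
    chosen: str,
    measured_component: str,
    ctx: MediaContext,
    eps: float = 1e-5,
) -> str:
    """``coupled`` if the minimum flux ratio is positive or the maximum flux
    ratio is finite; ``uncoupled`` otherwise."""
    lo = min_flux_ratio(split, chosen, measured_component, ctx)
    if lo >= eps:
        return "coupled"
    hi = max_flux_ratio(split, chosen, measured_component, ctx)
    return "coupled" if math.isfinite(hi) else "uncoupled"


def is_conditionally_essential(
    split: SplitModel,
    ctx: MediaContext,
    chosen: str,
    measured_component: str,
    threshold: float = GROWTH_THRESHOLD,
) -> bool:
    """Growth (measured flux) occurs under the context but vanishes when the
    chosen reaction is additionally eliminated."""
    base = fba(split, ctx, measured_component)
    if base.status != "optimal" or base.objective <= threshold:
        return False
    knocked = fba(split, ctx, measured_component, extra_disabled=frozenset({chosen}))
    return knocked.status != "optimal" or knocked.objective <= threshold


# ---------------------------------------------------------------------------
# Exhaustive coupling-condition search (oracle for the MILP)
# ---------------------------------------------------------------------------


def _media_assignments(sets: MediaComponentSets, no_multi_type: bool = True):
    """All media selections respecting the per-type caps.

    Yields frozensets of (exchange, type) pairs; with ``no_multi_type`` an
    exchange may appear under at most one type (the optional overlap rule).
    """
    per_type_choices = []
    for k in sorted({k for _, k in sets.membership}):
        members = sorted(sets.members(k))
        opts = []
        for n in range(0, min(sets.max_per_type[k], len(members)) + 1):
            opts.extend(itertools.combinations(members, n))
        per_type_choices.append([(k, combo) for combo in opts])
    if not per_type_choices:
        yield frozenset()
        return
    for combo in itertools.product(*per_type_choices):
        assignment = frozenset((x, k) for k, xs in combo for x in xs)
        if no_multi_type:
            xs = [x for x, _ in assignment]
            if len(xs) != len(set(xs)):
                continue
        yield assignment


def enumerate_conditions(
    model: MetabolicModel,
    media_sets: MediaComponentSets,
    dmin: int,
    dmax: int,
    alpha: float,
    beta: float,
    no_multi_type: bool = True,
    guard: int = 10**6,
):
    """All (media assignment, knockout set) conditions ordered by ascending
    outer-objective penalty, ties broken lexicographically."""
    assignments = list(_media_assignments(media_sets, no_multi_type))
    genes = sorted(model.genes)
    n_ko = sum(math.comb(len(genes), d) for d in range(dmin, dmax + 1))
    if n_ko * max(1, len(assignments)) > guard:
        raise RuntimeError(
            f"exhaustive search refused: {n_ko * len(assignments)} combinations exceed guard {guard}"
        )
    combos = []
    for assignment in assignments:
        n_add = sum(1 for _, k in assignment if k == "additional")
        for d in range(dmin, dmax + 1):
            for kos in itertools.combinations(genes, d):
                penalty = alpha * d + beta * n_add
                combos.append((penalty, sorted(x for x, _ in assignment), sorted(kos), assignment))
    combos.sort(key=lambda c: (c[0], c[1], c[2]))
    for penalty, _, kos, assignment in combos:
        yield penalty, assignment, frozenset(kos)


def _check_condition(
    split: SplitModel,
    chosen: list[str],
    coupling_set: list[str],
    media_sets: MediaComponentSets,
    assignment: frozenset[tuple[str, str]],
    kos: frozenset[str],
    eps: float,
):
    """First measured component coupled to *every* chosen reaction, plus the
    worst (smallest) inner objective across the chosen set; None if none."""
    ctx = media_context(media_sets, {x for x, _ in assignment}, kos)
    for measured in coupling_set:
        try:
            ratios = [min_flux_ratio(split, r, measured, ctx) for r in chosen]
        except MeasuredInfeasible:
            continue
        if all(v >= eps for v in ratios):
            return measured, min(ratios), ctx
    return None


def brute_force_coupling_search(
    split: SplitModel,
    chosen: str | list[str],
    media_sets: MediaComponentSets,
    coupling_set: list[str],
    dmax: int,
    dmin: int = 0,
    alpha: float = 1.0,
    beta: float = 0.25,
    eps: float = 1e-5,
    no_multi_type: bool = True,
    guard: int = 10**6,
):
    """Enumerate every admissible media/knockout condition and return the one
    maximizing the outer objective, or ``None`` when no coupling exists.

    Conditions are visited in ascending penalty order, so the first coupled
    condition found is an optimum of the outer objective.
    """
    from .focal_milp import CouplingSolution  # deferred to avoid an import cycle

    chosen_list = [chosen] if isinstance(chosen, str) else list(chosen)
    model = split.parent
    for penalty, assignment, kos in enumerate_conditions(
        model, media_sets, dmin, dmax, alpha, beta, no_multi_type, guard
    ):
        hit = _check_condition(split, chosen_list, coupling_set, media_sets, assignment, kos, eps)
        if hit is None:
            continue
        measured, inner, ctx = hit
        outer = (dmax + 1) - 1 - penalty
        return CouplingSolution(
            status="coupled",
            r_obj=1,
            measured=measured,
            media=dict(sorted(assignment)),
            knockouts=kos,
            reaction_states={
                r: r not in ctx.disabled_reactions(model) for r in model.reaction_ids
            },
            inner_objective=inner,
            outer_objective=outer,
        )
    return None


def brute_force_enumerate(
    split: SplitModel,
    chosen: str | list[str],
    media_sets: MediaComponentSets,
    coupling_set: list[str],
    dmax: int,
    dmin: int = 0,
    alpha: float = 1.0,
    beta: float = 0.25,
    eps: float = 1e-5,
    no_multi_type: bool = True,
    guard: int = 10**6,
    max_solutions: int | None = None,
):
    """All maximal coupling conditions in integer-cut order.

    Mirrors iterated integer cuts: conditions are visited by descending outer
    objective and a condition is kept only if its (knockouts ∪ media) support
    is not a superset of an already kept condition's support.
    """
    from .focal_milp import CouplingSolution

    chosen_list = [chosen] if isinstance(chosen, str) else list(chosen)
    model = split.parent
    kept: list[CouplingSolution] = []
    for penalty, assignment, kos in enumerate_conditions(
        model, media_sets, dmin, dmax, alpha, beta, no_multi_type, guard
    ):
        media = {x for x, _ in assignment}
        if any(
            set(prev.knockouts) <= set(kos) and set(prev.media) <= media for prev in kept
        ):
            continue
        hit = _check_condition(split, chosen_list, coupling_set, media_sets, assignment, kos, eps)
        if hit is None:
            continue
        measured, inner, ctx = hit
        kept.append(
            CouplingSolution(
                status="coupled",
                r_obj=1,
                measured=measured,
                media=dict(sorted(assignment)),
                knockouts=kos,
                reaction_states={
                    r: r not in ctx.disabled_reactions(model) for r in model.reaction_ids
                },
                inner_objective=inner,
                outer_objective=(dmax + 1) - 1 - penalty,
            )
        )
        if max_solutions is not None and len(kept) >= max_solutions:
            break
    return kept
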