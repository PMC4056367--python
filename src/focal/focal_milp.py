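"""Forced-coupling MILP: find media and gene deletions that make a chosen
reaction essential for a measurable flux.

The bi-level program has an outer search over binary decisions (measured-flux
selection ``c``, media ``h``/``m``, gene knockouts ``ko``, reaction states
``a``) and an inner LP that drives the normalized chosen flux to its minimum
given those decisions.  Coupling is accepted (``r_obj = 1``) when that minimum
stays at or above a margin ``eps``.

The inner LP is replaced by the conjunction of its primal constraints, its
dual constraints and a strong-duality equality, yielding a single-level MILP.
Binary-controlled bounds are handled OptKnock-style: the binary multiplies the
bound on the primal side, and the resulting dual-variable × binary products in
the strong-duality row are linearized exactly with McCormick envelopes (the
dual variables involved carry an explicit cap).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from ._solver import INF, LinearProgram, SolveStatus, dual_of
from .model_core import (
    MEDIA_TYPES,
    MediaComponentSets,
    SplitModel,
    fwd,
)
from . import flux_analysis as fa
from .flux_analysis import (
    GROWTH_THRESHOLD,
    MediaContext,
    MeasuredInfeasible,
    media_context,
)

__all__ = [
    "CouplingProblem",
    "CouplingSolution",
    "FocalProblemError",
    "MilpArtifact",
    "SearchPolicy",
    "VerificationFailure",
    "VerificationReport",
    "add_integer_cut",
    "build_focal_milp",
    "build_inner_primal",
    "couple_all_reactions",
    "design_coutilization",
    "dualize_inner",
    "enumerate_alternatives",
    "solve_focal",
    "verify_solution",
]


class FocalProblemError(ValueError):
    """The coupling problem violates a structural invariant."""


class VerificationFailure(RuntimeError):
    """A solution reported as coupled failed independent LP verification."""


@dataclass
class SearchPolicy:
    """Time-budget policy for the MILP search.

    ``incumbent_extension`` doubles as the budget of the staged reduced-media
    pass; the solver backend exposes a global time limit only.
    """

    total_time_budget: float = 300.0
    incumbent_extension: float = 30.0
    staged_media: bool = False
    reduced_media_set: tuple[str, ...] = ()

    def __post_init__(self):
        if self.total_time_budget <= 0 or self.incumbent_extension <= 0:
            raise FocalProblemError("search budgets must be positive")


@dataclass
class CouplingProblem:
    """A forced-coupling instance: what to couple, to what, under which rules."""

    split: SplitModel
    chosen: list[str]
    coupling_set: list[str]  # candidate measured *components* (direction-resolved)
    media_sets: MediaComponentSets
    dmin: int = 0
    dmax: int = 5
    alpha: float = 1.0
    beta: float = 0.25
    eps: float = 1e-5
    policy: SearchPolicy = field(default_factory=SearchPolicy)
    no_multi_type: bool = True  # optional rule: an exchange gets at most one type
    norm_cap: float = fa.NORM_FLUX_CAP  # big-M cap on normalized fluxes
    t_cap: float = fa.T_CAP
    dual_cap: float = 1000.0  # cap on dual variables entering binary products
    growth_threshold: float = GROWTH_THRESHOLD

    def __post_init__(self):
        if isinstance(self.chosen, str):
            self.chosen = [self.chosen]
        self.validate()

    def validate(self) -> None:
        model = self.split.parent
        genes = model.genes
        if not (0 <= self.dmin <= self.dmax <= len(genes)):
            raise FocalProblemError(
                f"need 0 <= dmin <= dmax <= |G|, got {self.dmin}, {self.dmax}, |G|={len(genes)}"
            )
        if self.eps <= 0:
            raise FocalProblemError("eps must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise FocalProblemError("penalties must be nonnegative")
        n_add = min(
            self.media_sets.max_per_type["additional"],
            len(self.media_sets.members("additional")),
        )
        if self.alpha * self.dmax + self.beta * n_add >= self.dmax + 1:
            raise FocalProblemError(
                "maximum combined penalties must stay below the coupling reward "
                f"(alpha*dmax + beta*n_additional = {self.alpha * self.dmax + self.beta * n_add} "
                f">= dmax + 1 = {self.dmax + 1})"
            )
        for r in self.chosen:
            if r not in model.reaction_ids:
                raise FocalProblemError(f"chosen reaction {r!r} not in model")
        overlap = self.media_sets.selectable & self.media_sets.minimal
        if overlap:
            raise FocalProblemError(
                f"exchanges cannot be both selectable and Minimal: {sorted(overlap)}"
            )
        for comp in self.coupling_set:
            self.split.origin(comp)  # raises KeyError on malformed ids

    @property
    def measured_big_m(self) -> float:
        return self.norm_cap + 1.0


@dataclass
class CouplingSolution:
    status: str  # coupled | uncoupled | infeasible | timeout | blocked
    r_obj: int = 0
    measured: str | None = None  # selected measured component (c_j,for / c_j,rev)
    media: dict[str, str] = field(default_factory=dict)  # exchange -> media type
    knockouts: frozenset[str] = frozenset()  # genes with ko_g = 0
    reaction_states: dict[str, bool] = field(default_factory=dict)  # a_j
    inner_objective: float | None = None  # min over chosen of v̂_for + v̂_rev
    inner_objectives: dict[str, float] = field(default_factory=dict)
    outer_objective: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)  # normalized witness (+ t)
    note: str = ""

    @property
    def deletion_count(self) -> int:
        return len(self.knockouts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "measured": self.measured,
                "media": [{"exchange": x, "type": k} for x, k in sorted(self.media.items())],
                "knockouts": sorted(self.knockouts),
                "inner_objective": self.inner_objective,
                "outer_objective": self.outer_objective,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CouplingSolution":
        d = json.loads(text)
        return cls(
            status=d["status"],
            r_obj=1 if d["status"] == "coupled" else 0,
            measured=d.get("measured"),
            media={e["exchange"]: e["type"] for e in d.get("media", [])},
            knockouts=frozenset(d.get("knockouts", [])),
            inner_objective=d.get("inner_objective"),
            outer_objective=d.get("outer_objective"),
        )


# ---------------------------------------------------------------------------
# Inner primal and its dual (nested, binaries fixed)
# ---------------------------------------------------------------------------


def _active_components(split: SplitModel, media_sets: MediaComponentSets) -> list[str]:
    """Unblocked components minus uptake sides of exchanges that can never open."""
    model = split.parent
    exchanges = set(model.exchanges)
    openable = media_sets.selectable | media_sets.minimal
    out = []
    for comp in split.unblocked_components:
        rxn, sign = split.origin(comp)
        if rxn in exchanges and sign < 0 and rxn not in openable:
            continue
        out.append(comp)
    return out


def build_inner_primal(
    problem: CouplingProblem,
    chosen: str,
    measured: str | None = None,
    knockouts: frozenset[str] = frozenset(),
    media_selected: frozenset[str] = frozenset(),
) -> LinearProgram:
    """The inner LP for one chosen reaction with all binaries fixed.

    Minimizes ``v̂_chosen,for + v̂_chosen,rev`` subject to mass balance over
    unblocked components, t-scaled uptake caps, the measured component pinned
    to 1, deletion zeroing and unselected-media zeroing.  Every bound is an
    explicit constraint so the program is in the standard form
    ``min c'x, Ax {<=,=} b, x >= 0`` expected by :func:`dualize_inner`.
    """
    split, sets = problem.split, problem.media_sets
    model = split.parent
    measured = measured or problem.coupling_set[0]
    exchanges = set(model.exchanges)
    disabled = model.disabled_reactions(knockouts)
    comps = _active_components(split, sets)
    if measured not in comps:
        raise MeasuredInfeasible(f"measured component {measured!r} cannot carry flux")
    M_c, U_v, U_t = problem.measured_big_m, problem.norm_cap, problem.t_cap

    lp = LinearProgram(f"inner[{chosen}]")
    for comp in comps:
        lp.add_var(comp, lb=0.0, ub=INF)
    lp.add_var("t", lb=0.0, ub=INF)
    for comp in split.components_of(chosen):
        if comp in comps:
            lp.set_objective_coeff(comp, 1.0)

    balance: dict[str, dict[str, float]] = {}
    for comp in comps:
        for met, coef in split.component_column(comp).items():
            balance.setdefault(met, {})[comp] = coef
    for met, coeffs in sorted(balance.items()):
        lp.add_constr(coeffs, "==", 0.0, tag="Eq7", name=f"mb[{met}]")
    for comp in comps:
        rxn, sign = split.origin(comp)
        if rxn in exchanges and sign < 0:
            lp.add_constr(
                {comp: 1.0, "t": -sets.max_uptake[rxn]}, "<=", 0.0, tag="Eq8", name=f"up[{rxn}]"
            )
    # measured selection with c fixed: c=1 for `measured`, 0 elsewhere
    for comp in problem.coupling_set:
        if comp not in comps:
            continue
        c_val = 1.0 if comp == measured else 0.0
        lp.add_constr(
            {comp: -1.0}, "<=", M_c - 1.0 - M_c * c_val, tag="Eq11", name=f"mlo[{comp}]"
        )
        lp.add_constr(
            {comp: 1.0}, "<=", 1.0 + M_c - M_c * c_val, tag="Eq12", name=f"mhi[{comp}]"
        )
    for comp in comps:
        rxn, sign = split.origin(comp)
        a_val = 0.0 if rxn in disabled else 1.0
        lp.add_constr({comp: 1.0}, "<=", U_v * a_val, tag="Eq14", name=f"del[{comp}]")
        if rxn in exchanges and sign < 0 and rxn in (sets.selectable - sets.minimal):
            h_val = 1.0 if rxn in media_selected else 0.0
            lp.add_constr({comp: 1.0}, "<=", U_v * h_val, tag="Eq15", name=f"med[{rxn}]")
    lp.add_constr({"t": 1.0}, "<=", U_t, tag="tcap", name="tcap")
    return lp


def dualize_inner(lp: LinearProgram) -> LinearProgram:
    """LP dual of an inner primal (strong duality holds whenever the primal is
    feasible, since the primal is bounded below by zero)."""
    return dual_of(lp)


# ---------------------------------------------------------------------------
# Single-level MILP
# ---------------------------------------------------------------------------


@dataclass
class MilpArtifact:
    """Assembled single-level MILP plus the bookkeeping needed to read answers
    back out of a solver point."""

    problem: CouplingProblem
    lp: LinearProgram
    obj_constant: float
    active_components: list[str]
    copies: list[str]  # one prefix per chosen reaction (inner-problem copy)

    def primal_objective_vars(self, copy: str, chosen: str) -> list[str]:
        return [
            f"{copy}.v[{c}]"
            for c in self.problem.split.components_of(chosen)
            if c in self.active_components
        ]


def _mccormick(lp: LinearProgram, z: str, w: str, b: str, cap: float, tag: str) -> None:
    """z = w * b for w in [0, cap] and binary b."""
    lp.add_var(z, lb=0.0, ub=cap)
    lp.add_constr({z: 1.0, b: -cap}, "<=", 0.0, tag=tag, name=f"{z}.ub1")
    lp.add_constr({z: 1.0, w: -1.0}, "<=", 0.0, tag=tag, name=f"{z}.ub2")
    lp.add_constr({z: -1.0, w: 1.0, b: cap}, "<=", cap, tag=tag, name=f"{z}.lb")


def _encode_gpr(lp: LinearProgram, rxn: str, expr, a_var: str) -> None:
    """Exact MILP encoding of a monotone AND/OR tree: a_j equals the truth
    value of the GPR under the ko assignment."""
    counter = [0]

    def encode(node) -> tuple[str, float]:
        # returns (variable name, coefficient-offset) representing the node value;
        # leaves map straight to ko variables
        if node[0] == "gene":
            return f"ko[{node[1]}]", 0.0
        counter[0] += 1
        y = lp.add_binary(f"gpr[{rxn}.{counter[0]}]")
        children = [encode(c) for c in node[1]]
        n = len(children)
        if node[0] == "and":
            for child, _ in children:
                lp.add_constr({y: 1.0, child: -1.0}, "<=", 0.0, tag="Eq21", name=f"{y}.le")
            coeffs = {y: 1.0}
            for child, _ in children:
                coeffs[child] = coeffs.get(child, 0.0) - 1.0
            lp.add_constr(coeffs, ">=", -(n - 1.0), tag="Eq21", name=f"{y}.ge")
        else:  # or
            for child, _ in children:
                lp.add_constr({y: 1.0, child: -1.0}, ">=", 0.0, tag="Eq21", name=f"{y}.ge")
            coeffs = {y: 1.0}
            for child, _ in children:
                coeffs[child] = coeffs.get(child, 0.0) - 1.0
            lp.add_constr(coeffs, "<=", 0.0, tag="Eq21", name=f"{y}.le")
        return y, 0.0

    root_var, _ = encode(expr.root)
    lp.add_constr({a_var: 1.0, root_var: -1.0}, "==", 0.0, tag="Eq21", name=f"a[{rxn}].root")


def build_focal_milp(problem: CouplingProblem) -> MilpArtifact:
    """Assemble the single-level MILP: outer objective and rules, one primal +
    dual inner copy per chosen reaction, strong duality, and the acceptance
    margin linking the inner optimum to ``r_obj``."""
    split, sets = problem.split, problem.media_sets
    model = split.parent
    exchanges = set(model.exchanges)
    genes = sorted(model.genes)
    comps = _active_components(split, sets)
    comp_set = set(comps)
    coupling = [c for c in problem.coupling_set if c in comp_set]
    if not coupling:
        raise FocalProblemError("no coupling-set component can carry flux in this model")
    M_c, U_v, U_t, D = problem.measured_big_m, problem.norm_cap, problem.t_cap, problem.dual_cap
    selectable_media = sorted(sets.selectable - sets.minimal)

    lp = LinearProgram("focal", sense="max")

    # ---- outer binaries and objective (Eq5) ------------------------------
    lp.add_binary("r_obj", obj=problem.dmax + 1.0)
    for g in genes:
        lp.add_binary(f"ko[{g}]", obj=problem.alpha)  # -alpha * (1 - ko) up to a constant
    obj_constant = -1.0 - problem.alpha * len(genes)
    for x in selectable_media:
        lp.add_binary(f"h[{x}]")
    for x, k in sorted(sets.membership):
        lp.add_binary(f"m[{x},{k}]", obj=-problem.beta if k == "additional" else 0.0)
    for comp in coupling:
        lp.add_binary(f"c[{comp}]")

    # reaction states a_j: fixed at 1 for orphans, GPR-driven otherwise
    orphan: dict[str, bool] = {}
    for rxn in model.reaction_ids:
        expr = model.gpr.get(rxn)
        orphan[rxn] = expr is None or expr.is_empty()
        if not orphan[rxn]:
            lp.add_binary(f"a[{rxn}]")
            _encode_gpr(lp, rxn, expr, f"a[{rxn}]")

    # ---- outer rules -----------------------------------------------------
    lp.add_constr({f"c[{c}]": 1.0 for c in coupling}, "==", 1.0, tag="Eq13", name="pick_meas")
    for x in selectable_media:
        lp.add_constr(
            {f"m[{x},{k}]": 1.0 for k in sets.types_of(x)} | {f"h[{x}]": -1.0},
            ">=",
            0.0,
            tag="Eq17",
            name=f"type_if_open[{x}]",
        )
        for k in sets.types_of(x):
            lp.add_constr(
                {f"m[{x},{k}]": 1.0, f"h[{x}]": -1.0}, "<=", 0.0, tag="Eq18",
                name=f"open_if_typed[{x},{k}]",
            )
        if problem.no_multi_type:
            lp.add_constr(
                {f"m[{x},{k}]": 1.0 for k in sets.types_of(x)}, "<=", 1.0, tag="Eq19",
                name=f"one_type[{x}]",
            )
    for k in MEDIA_TYPES:
        members = sorted(sets.members(k))
        if members:
            lp.add_constr(
                {f"m[{x},{k}]": 1.0 for x in members}, "<=", float(sets.max_per_type[k]),
                tag="Eq20", name=f"max_media[{k}]",
            )
    ko_sum = {f"ko[{g}]": 1.0 for g in genes}
    if genes:
        lp.add_constr(ko_sum, ">=", len(genes) - problem.dmax, tag="Eq22", name="dmax")
        lp.add_constr(ko_sum, "<=", len(genes) - problem.dmin, tag="Eq22", name="dmin")

    # ---- one primal + dual inner copy per chosen reaction ---------------
    copies = []
    for idx, chosen in enumerate(problem.chosen):
        p = f"i{idx}"
        copies.append(p)
        chosen_comps = [c for c in split.components_of(chosen) if c in comp_set]
        if not chosen_comps:
            raise FocalProblemError(f"chosen reaction {chosen!r} has no active component")

        # primal variables
        for comp in comps:
            lp.add_var(f"{p}.v[{comp}]", lb=0.0, ub=U_v)
        lp.add_var(f"{p}.t", lb=0.0, ub=U_t)

        # Eq7 balance
        balance: dict[str, dict[str, float]] = {}
        for comp in comps:
            for met, coef in split.component_column(comp).items():
                balance.setdefault(met, {})[f"{p}.v[{comp}]"] = coef
        for met, coeffs in sorted(balance.items()):
            lp.add_constr(coeffs, "==", 0.0, tag="Eq7", name=f"{p}.mb[{met}]")

        uptake_exchanges = []
        for comp in comps:
            rxn, sign = split.origin(comp)
            if rxn in exchanges and sign < 0:
                uptake_exchanges.append((rxn, comp))
                lp.add_constr(
                    {f"{p}.v[{comp}]": 1.0, f"{p}.t": -sets.max_uptake[rxn]},
                    "<=", 0.0, tag="Eq8", name=f"{p}.up[{rxn}]",
                )
        # Eq11/12: v pinned to 1 when its c is picked, free otherwise
        for comp in coupling:
            lp.add_constr(
                {f"{p}.v[{comp}]": -1.0, f"c[{comp}]": M_c}, "<=", M_c - 1.0,
                tag="Eq11", name=f"{p}.mlo[{comp}]",
            )
            lp.add_constr(
                {f"{p}.v[{comp}]": 1.0, f"c[{comp}]": M_c}, "<=", M_c + 1.0,
                tag="Eq12", name=f"{p}.mhi[{comp}]",
            )
        # Eq14 deletions, Eq15 media
        media_rows = []
        for comp in comps:
            rxn, sign = split.origin(comp)
            if orphan[rxn]:
                lp.add_constr(
                    {f"{p}.v[{comp}]": 1.0}, "<=", U_v, tag="Eq14", name=f"{p}.del[{comp}]"
                )
            else:
                lp.add_constr(
                    {f"{p}.v[{comp}]": 1.0, f"a[{rxn}]": -U_v}, "<=", 0.0,
                    tag="Eq14", name=f"{p}.del[{comp}]",
                )
            if rxn in exchanges and sign < 0 and rxn in selectable_media:
                media_rows.append((rxn, comp))
                lp.add_constr(
                    {f"{p}.v[{comp}]": 1.0, f"h[{rxn}]": -U_v}, "<=", 0.0,
                    tag="Eq15", name=f"{p}.med[{rxn}]",
                )

        # ---- dual variables ---------------------------------------------
        for met in sorted(balance):
            lp.add_var(f"{p}.lam[{met}]", lb=-INF, ub=INF)
        for rxn, comp in uptake_exchanges:
            lp.add_var(f"{p}.mu[{rxn}]", lb=0.0, ub=INF)
        for comp in coupling:
            lp.add_var(f"{p}.glo[{comp}]", lb=0.0, ub=D)
            lp.add_var(f"{p}.ghi[{comp}]", lb=0.0, ub=D)
        for comp in comps:
            lp.add_var(f"{p}.dl[{comp}]", lb=0.0, ub=D)
        for rxn, comp in media_rows:
            lp.add_var(f"{p}.eta[{rxn}]", lb=0.0, ub=D)
        lp.add_var(f"{p}.tau", lb=0.0, ub=INF)

        # ---- dual feasibility (one row per primal variable) -------------
        uptake_of = {comp: rxn for rxn, comp in uptake_exchanges}
        media_of = {comp: rxn for rxn, comp in media_rows}
        coupling_set_ = set(coupling)
        for comp in comps:
            coeffs: dict[str, float] = {}
            for met, coef in split.component_column(comp).items():
                coeffs[f"{p}.lam[{met}]"] = coef
            coeffs[f"{p}.dl[{comp}]"] = 1.0
            if comp in uptake_of:
                coeffs[f"{p}.mu[{uptake_of[comp]}]"] = 1.0
            if comp in media_of:
                coeffs[f"{p}.eta[{media_of[comp]}]"] = 1.0
            if comp in coupling_set_:
                coeffs[f"{p}.glo[{comp}]"] = -1.0
                coeffs[f"{p}.ghi[{comp}]"] = coeffs.get(f"{p}.ghi[{comp}]", 0.0) + 1.0
            rhs = -1.0 if comp in chosen_comps else 0.0
            lp.add_constr(coeffs, ">=", rhs, tag="dual", name=f"{p}.df[{comp}]")
        t_coeffs = {f"{p}.mu[{rxn}]": -sets.max_uptake[rxn] for rxn, _ in uptake_exchanges}
        t_coeffs[f"{p}.tau"] = 1.0
        lp.add_constr(t_coeffs, ">=", 0.0, tag="dual", name=f"{p}.df[t]")

        # ---- linearized dual-binary products -----------------------------
        for comp in coupling:
            _mccormick(lp, f"{p}.zlo[{comp}]", f"{p}.glo[{comp}]", f"c[{comp}]", D, "linearization")
            _mccormick(lp, f"{p}.zhi[{comp}]", f"{p}.ghi[{comp}]", f"c[{comp}]", D, "linearization")
        for comp in comps:
            rxn, _ = split.origin(comp)
            if not orphan[rxn]:
                _mccormick(
                    lp, f"{p}.zdl[{comp}]", f"{p}.dl[{comp}]", f"a[{rxn}]", D, "linearization"
                )
        for rxn, comp in media_rows:
            _mccormick(lp, f"{p}.zeta[{rxn}]", f"{p}.eta[{rxn}]", f"h[{rxn}]", D, "linearization")

        # ---- strong duality: primal objective == dual objective ----------
        sd: dict[str, float] = {}
        for c_ in chosen_comps:
            sd[f"{p}.v[{c_}]"] = 1.0
        for comp in coupling:
            sd[f"{p}.glo[{comp}]"] = sd.get(f"{p}.glo[{comp}]", 0.0) + (M_c - 1.0)
            sd[f"{p}.zlo[{comp}]"] = -M_c
            sd[f"{p}.ghi[{comp}]"] = sd.get(f"{p}.ghi[{comp}]", 0.0) + (M_c + 1.0)
            sd[f"{p}.zhi[{comp}]"] = -M_c
        for comp in comps:
            rxn, _ = split.origin(comp)
            if orphan[rxn]:
                sd[f"{p}.dl[{comp}]"] = sd.get(f"{p}.dl[{comp}]", 0.0) + U_v
            else:
                sd[f"{p}.zdl[{comp}]"] = U_v
        for rxn, comp in media_rows:
            sd[f"{p}.zeta[{rxn}]"] = U_v
        sd[f"{p}.tau"] = U_t
        lp.add_constr(sd, "==", 0.0, tag="strong_duality", name=f"{p}.sd")

        # ---- acceptance margin (Eq16): r_obj <= inner + 1 - eps ----------
        acc = {f"{p}.v[{c_}]": -1.0 for c_ in chosen_comps}
        acc["r_obj"] = 1.0
        lp.add_constr(acc, "<=", 1.0 - problem.eps, tag="Eq16", name=f"{p}.accept")

    return MilpArtifact(problem, lp, obj_constant, comps, copies)


def add_integer_cut(
    milp: MilpArtifact,
    prior: CouplingSolution,
    mode: str = "full",
) -> MilpArtifact:
    """Forbid a prior solution and its supersets.

    ``sum_{g in OldKO} (1 - ko_g) + sum_{x in OldMedia} h_x <= |OldKO| + |OldMedia| - 1``;
    ``knockouts_only`` / ``media_only`` drop the other term.
    """
    if prior.status != "coupled":
        raise FocalProblemError("integer cuts require a coupled prior solution")
    if mode not in ("full", "knockouts_only", "media_only"):
        raise ValueError(f"unknown cut mode {mode!r}")
    old_ko = sorted(prior.knockouts) if mode != "media_only" else []
    old_media = sorted(prior.media) if mode != "knockouts_only" else []
    coeffs: dict[str, float] = {}
    for g in old_ko:
        coeffs[f"ko[{g}]"] = -1.0
    for x in old_media:
        coeffs[f"h[{x}]"] = 1.0
    rhs = len(old_media) - 1.0  # |OldKO| moved to the left via (1 - ko)
    n_cuts = sum(1 for c in milp.lp.constraints if c.tag == "cut")
    milp.lp.add_constr(coeffs, "<=", rhs, tag="cut", name=f"cut{n_cuts}")
    return milp


# ---------------------------------------------------------------------------
# Solving and extraction
# ---------------------------------------------------------------------------


def _extract_solution(milp: MilpArtifact, values: dict[str, float]) -> CouplingSolution:
    problem = milp.problem
    split, sets = problem.split, problem.media_sets
    model = split.parent

    def on(name: str) -> bool:
        return values.get(name, 0.0) > 0.5

    r_obj = 1 if on("r_obj") else 0
    knockouts = frozenset(g for g in model.genes if not on(f"ko[{g}]"))
    media: dict[str, str] = {}
    for x, k in sorted(sets.membership):
        if on(f"m[{x},{k}]"):
            media[x] = k
    measured = None
    for comp in problem.coupling_set:
        if on(f"c[{comp}]"):
            measured = comp
            break
    states = {}
    for rxn in model.reaction_ids:
        expr = model.gpr.get(rxn)
        if expr is None or expr.is_empty():
            states[rxn] = True
        else:
            states[rxn] = on(f"a[{rxn}]")
    inner_objs = {}
    for p, chosen in zip(milp.copies, problem.chosen):
        inner_objs[chosen] = sum(values[v] for v in milp.primal_objective_vars(p, chosen))
    outer = (
        r_obj * (problem.dmax + 1.0)
        - 1.0
        - problem.alpha * len(knockouts)
        - problem.beta * sum(1 for k in media.values() if k == "additional")
    )
    p0 = milp.copies[0]
    fluxes = {
        comp: values[f"{p0}.v[{comp}]"] for comp in milp.active_components
    }
    fluxes["t"] = values[f"{p0}.t"]
    return CouplingSolution(
        status="coupled" if r_obj else "uncoupled",
        r_obj=r_obj,
        measured=measured,
        media=media,
        knockouts=knockouts,
        reaction_states=states,
        inner_objective=min(inner_objs.values()),
        inner_objectives=inner_objs,
        outer_objective=outer,
        fluxes=fluxes,
    )


def _nogood_cut(milp: MilpArtifact, values: dict[str, float]) -> None:
    """Exclude one exact outer binary assignment (numerical-repair cut).

    Big-M rows can amplify the solver's integrality slack into a spurious
    acceptance; excluding the offending assignment and re-solving restores
    correctness without relying on solver tolerances.
    """
    problem = milp.problem
    names = [f"ko[{g}]" for g in sorted(problem.split.parent.genes)]
    names += [f"h[{x}]" for x in sorted(problem.media_sets.selectable - problem.media_sets.minimal)]
    names += [f"c[{comp}]" for comp in problem.coupling_set if milp.lp.has_var(f"c[{comp}]")]
    coeffs: dict[str, float] = {}
    ones = 0
    for name in names:
        if values.get(name, 0.0) > 0.5:
            coeffs[name] = -1.0
            ones += 1
        else:
            coeffs[name] = 1.0
    n_cuts = sum(1 for c in milp.lp.constraints if c.tag == "cut")
    milp.lp.add_constr(coeffs, ">=", 1.0 - ones, tag="cut", name=f"nogood{n_cuts}")


def _solve_artifact(
    milp: MilpArtifact, time_limit: float | None, verify: bool = True, max_repairs: int = 10
) -> CouplingSolution:
    for _ in range(max_repairs + 1):
        res = milp.lp.solve(time_limit=time_limit)
        if res.status is SolveStatus.INFEASIBLE:
            return CouplingSolution(
                status="infeasible", note="no admissible condition sustains any measured flux"
            )
        if res.values == {} or res.status in (SolveStatus.UNBOUNDED, SolveStatus.ERROR):
            return CouplingSolution(status="timeout", note=f"solver status {res.status.value}")
        sol = _extract_solution(milp, res.values)
        if res.status is SolveStatus.TIME_LIMIT:
            if sol.status != "coupled":
                return CouplingSolution(
                    status="timeout", note="time limit without coupled incumbent"
                )
            sol.note = "incumbent at time limit (optimality not proven)"
        if sol.status != "coupled" or not verify:
            return sol
        report = verify_solution(milp.problem, sol)
        if report.is_valid:
            return sol
        _nogood_cut(milp, res.values)  # spurious acceptance: exclude and retry
    raise VerificationFailure(
        f"solver kept returning unverifiable couplings after {max_repairs} repair cuts"
    )


def solve_focal(problem: CouplingProblem) -> CouplingSolution:
    """Solve one forced-coupling instance under the problem's search policy.

    A chosen reaction in the blocked set short-circuits to status ``blocked``.
    With a staged policy, a reduced-media pass runs first under the incumbent
    budget; the full-media pass consumes the remaining total budget.
    """
    for r in problem.chosen:
        if r in problem.split.blocked:
            return CouplingSolution(status="blocked", note=f"chosen reaction {r!r} is blocked")
    policy = problem.policy
    if policy.staged_media and policy.reduced_media_set:
        reduced = problem.media_sets.restrict(set(policy.reduced_media_set))
        if reduced.membership:
            staged_problem = replace(problem, media_sets=reduced)
            try:
                sol = _solve_artifact(
                    build_focal_milp(staged_problem), policy.incumbent_extension
                )
                if sol.status == "coupled":
                    return sol
            except FocalProblemError:
                pass  # reduced set may lack any usable coupling component
    return _solve_artifact(build_focal_milp(problem), policy.total_time_budget)


def enumerate_alternatives(
    problem: CouplingProblem, max_solutions: int
) -> list[CouplingSolution]:
    """Distinct coupling conditions by iterated integer cuts, best first.

    Stops at ``max_solutions`` or when the cut problem turns uncoupled or
    infeasible.  The staged media policy is bypassed: alternatives are
    meaningful only against the full media set.
    """
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    for r in problem.chosen:
        if r in problem.split.blocked:
            return []
    milp = build_focal_milp(problem)
    out: list[CouplingSolution] = []
    while len(out) < max_solutions:
        sol = _solve_artifact(milp, problem.policy.total_time_budget)
        if sol.status != "coupled":
            break
        out.append(sol)
        add_integer_cut(milp, sol, mode="full")
    return out


def design_coutilization(problem: CouplingProblem) -> CouplingSolution:
    """One condition under which every chosen reaction is individually coupled
    to the measured flux (one inner problem and one acceptance per chosen,
    sharing the outer binaries)."""
    if len(problem.chosen) < 2:
        raise FocalProblemError("co-utilization design needs at least two chosen reactions")
    return solve_focal(problem)


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


@dataclass
class VerificationReport:
    growth: float
    growth_ok: bool
    essential: dict[str, bool]
    min_ratios: dict[str, float]
    excluded: str = ""

    @property
    def is_valid(self) -> bool:
        return self.growth_ok and all(self.essential.values()) and not self.excluded


def verify_solution(problem: CouplingProblem, solution: CouplingSolution) -> VerificationReport:
    """Independent LP check of a coupled solution: growth occurs under the
    condition, vanishes when each chosen reaction is additionally disabled,
    and each chosen min flux ratio clears the acceptance margin."""
    if solution.status != "coupled":
        raise FocalProblemError("verify_solution expects a coupled solution")
    split, sets = problem.split, problem.media_sets
    ctx = media_context(sets, set(solution.media), solution.knockouts)
    measured = solution.measured or problem.coupling_set[0]
    base = fa.fba(split, ctx, measured)
    growth = base.objective if base.status == "optimal" else 0.0
    growth_ok = base.status == "optimal" and growth > problem.growth_threshold
    essential: dict[str, bool] = {}
    ratios: dict[str, float] = {}
    for r in problem.chosen:
        knocked = fa.fba(split, ctx, measured, extra_disabled=frozenset({r}))
        dead = knocked.status != "optimal" or knocked.objective <= problem.growth_threshold
        try:
            ratio = fa.min_flux_ratio(split, r, measured, ctx)
        except MeasuredInfeasible:
            ratio = math.nan
        essential[r] = growth_ok and dead and ratio >= problem.eps
        ratios[r] = ratio
    return VerificationReport(
        growth=growth, growth_ok=growth_ok, essential=essential, min_ratios=ratios
    )


# ---------------------------------------------------------------------------
# Batch coupling
# ---------------------------------------------------------------------------


def couple_all_reactions(
    split: SplitModel,
    media_sets: MediaComponentSets,
    coupling_set: list[str] | None = None,
    fallback_coupling_set: list[str] | None = None,
    fallback_dmax: int | None = None,
    **problem_kwargs,
):
    """Run the forced-coupling search for every reaction in the model.

    Returns a list of :class:`focal.reporting.CouplingOutcome`.  Reactions in
    the blocked set are categorized without solving; per-reaction failures are
    recorded and the batch continues.  When a fallback coupling set or raised
    deletion limit is given, uncoupled reactions get a second pass.
    """
    from .reporting import CouplingOutcome  # downstream module

    model = split.parent
    coupling_set = coupling_set or [fwd(model.biomass_id)]
    outcomes = []
    for rxn in model.reaction_ids:
        if rxn in split.blocked:
            outcomes.append(
                CouplingOutcome(
                    reaction=rxn, category="blocked",
                    subsystem=model.subsystems.get(rxn, ""),
                )
            )
            continue
        try:
            problem = CouplingProblem(
                split=split, chosen=[rxn], coupling_set=list(coupling_set),
                media_sets=media_sets, **problem_kwargs,
            )
            sol = solve_focal(problem)
            if sol.status != "coupled" and (fallback_coupling_set or fallback_dmax):
                retry = CouplingProblem(
                    split=split, chosen=[rxn],
                    coupling_set=list(fallback_coupling_set or coupling_set),
                    media_sets=media_sets,
                    **{**problem_kwargs, **({"dmax": fallback_dmax} if fallback_dmax else {})},
                )
                sol2 = solve_focal(retry)
                if sol2.status == "coupled":
                    sol = sol2
        except (FocalProblemError, VerificationFailure, RuntimeError) as exc:
            outcomes.append(
                CouplingOutcome(
                    reaction=rxn, category="uncoupled", reason=f"error: {exc}",
                    subsystem=model.subsystems.get(rxn, ""),
                )
            )
            continue
        if sol.status == "coupled":
            outcomes.append(
                CouplingOutcome(
                    reaction=rxn, category="coupled", deletion_count=sol.deletion_count,
                    subsystem=model.subsystems.get(rxn, ""), condition=sol,
                )
            )
        else:
            outcomes.append(
                CouplingOutcome(
                    reaction=rxn, category="uncoupled", reason=sol.status,
                    subsystem=model.subsystems.get(rxn, ""),
                )
            )
    return outcomes
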