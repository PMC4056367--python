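"""Deterministic fixture generators: the worked example network and seeded
random viable networks, so every analysis has a download-free test surface.

The example network is a two-substrate toy: carbon source A feeds an upper
pathway (v1, v2, v4) and a lower pathway (v3, v8) to biomass component F,
carbon source G feeds component H through v10, v7, v9, and a futile pair
(v5/v6) recycles an intermediate.  Its defining behaviour:

* wild type on {A, G}: v2 is not required for biomass (the lower pathway and
  the G branch cover both components);
* on A alone with v8 deleted: v2 becomes essential for growth;
* with v3 and v8 deleted on {A, G}: growth needs both transporters (v1 and
  v10) — a substrate co-utilization phenotype;
* v4 is coupled to v2 in the wild type (its sole substrate comes from v2).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model_core import (
    GprExpression,
    MediaComponentSets,
    MetabolicModel,
    parse_gpr,
)

__all__ = [
    "FixtureSpec",
    "GenerationError",
    "example_media_sets",
    "make_example_network",
    "make_random_network",
    "media_sets_for",
    "write_fixture",
]


class GenerationError(ValueError):
    """A fixture spec that cannot host a viable network."""


# ---------------------------------------------------------------------------
# Worked example network
# ---------------------------------------------------------------------------

_EXAMPLE_REACTIONS = [
    # id, equation, reversible, gpr
    ("EX_A", "A_ex ->", True, ""),
    ("EX_G", "G_ex ->", True, ""),
    ("v1", "A_ex -> A", False, "gv1"),
    ("v2", "A -> B", False, "gv2"),
    ("v3", "A -> C", False, "gv3"),
    ("v4", "B -> F", False, "gv4"),
    ("v5", "B -> E", False, "gv5"),
    ("v6", "E -> B", False, "gv6"),
    ("v7", "G -> C", False, "gv7"),
    ("v8", "C -> F", False, "gv8"),
    ("v9", "C -> H", False, "gv9"),
    ("v10", "G_ex -> G", False, "gv10"),
    ("vbio", "F + H ->", False, ""),
]


def _model_from_rows(rows, biomass_id: str) -> MetabolicModel:
    from .model_core import _parse_equation  # shared equation grammar

    stoich: dict[tuple[str, str], float] = {}
    mets: list[str] = []
    seen: set[str] = set()
    reversible: dict[str, bool] = {}
    gpr: dict[str, GprExpression] = {}
    reactions: list[str] = []
    for rid, eq, rev_flag, gpr_text in rows:
        coeffs, eq_rev = _parse_equation(eq, rid)
        reactions.append(rid)
        reversible[rid] = rev_flag or eq_rev
        gpr[rid] = parse_gpr(gpr_text)
        for m, c in coeffs.items():
            stoich[(m, rid)] = c
            if m not in seen:
                seen.add(m)
                mets.append(m)
    genes = sorted({g for e in gpr.values() for g in e.genes()})
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=reactions,
        stoichiometry=stoich,
        reversible=reversible,
        gpr=gpr,
        genes=genes,
        biomass_id=biomass_id,
    )


def make_example_network() -> MetabolicModel:
    """The illustrative two-substrate network (v1–v10 plus vbio).

    One gene per internal reaction; exchange and biomass pseudo-reactions are
    orphans.  See the module docstring for the behavioural contract.
    """
    return _model_from_rows(_EXAMPLE_REACTIONS, biomass_id="vbio")


def example_media_sets(max_carbon: int = 1, max_uptake: float = 10.0) -> MediaComponentSets:
    """Carbon candidates {EX_A, EX_G}, other types empty, no Minimal set."""
    return MediaComponentSets(
        membership=frozenset({("EX_A", "carbon"), ("EX_G", "carbon")}),
        max_per_type={"carbon": max_carbon},
        minimal=frozenset(),
        max_uptake={"EX_A": max_uptake, "EX_G": max_uptake},
    )


def media_sets_for(
    model: MetabolicModel,
    max_uptake: float = 10.0,
    max_carbon: int = 1,
) -> MediaComponentSets:
    """All exchanges of a model as selectable carbon candidates."""
    return MediaComponentSets(
        membership=frozenset((x, "carbon") for x in model.exchanges),
        max_per_type={"carbon": max_carbon},
        minimal=frozenset(),
        max_uptake={x: max_uptake for x in model.exchanges},
    )


# ---------------------------------------------------------------------------
# Random viable networks
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    n_metabolites: int = 8
    n_reactions: int = 10
    n_exchanges: int = 2
    reversibility_fraction: float = 0.15
    gpr_scheme: str = "one_gene_per_reaction"  # or "random_isozymes"
    seed: int = 0

    def __post_init__(self):
        if self.gpr_scheme not in ("one_gene_per_reaction", "random_isozymes"):
            raise GenerationError(f"unknown gpr scheme {self.gpr_scheme!r}")


def make_random_network(spec: FixtureSpec) -> MetabolicModel:
    """Seeded random network with a guaranteed substrate-to-biomass backbone.

    The first exchange feeds a linear chain ending in the biomass precursor;
    the other exchanges enter at random internal metabolites; the remaining
    reaction budget is spent on random conversions between internal
    metabolites.  Every generated network supports positive biomass flux when
    all exchanges are open (checked).
    """
    if spec.n_exchanges < 1:
        raise GenerationError("need at least one exchange")
    if spec.n_metabolites < 3:
        raise GenerationError("need at least three internal metabolites")
    rng = random.Random(spec.seed)

    chain_len = 2
    fixed = 2 * spec.n_exchanges + chain_len + 1  # exchanges + transporters + chain + biomass
    if fixed > spec.n_reactions:
        chain_len = 1
        fixed = 2 * spec.n_exchanges + chain_len + 1
    if fixed > spec.n_reactions:
        raise GenerationError(
            f"spec cannot host a viable path: {spec.n_reactions} reactions < {fixed} required"
        )
    n_extras = spec.n_reactions - fixed

    internal = [f"M{i + 1}" for i in range(spec.n_metabolites)]
    rows: list[tuple[str, str, bool, str]] = []
    gene_counter = [0]

    def next_gene() -> str:
        gene_counter[0] += 1
        return f"g{gene_counter[0]}"

    def gpr_for() -> str:
        if spec.gpr_scheme == "random_isozymes" and rng.random() < 0.3:
            return f"{next_gene()} or {next_gene()}"
        return next_gene()

    # exchanges and transporters
    for i in range(spec.n_exchanges):
        ext = f"X{i + 1}_ex"
        rows.append((f"EX_X{i + 1}", f"{ext} ->", True, ""))
        target = internal[0] if i == 0 else rng.choice(internal[:-1])
        rows.append((f"T{i + 1}", f"{ext} -> {target}", False, gpr_for()))

    # backbone chain M1 -> ... -> precursor
    chain = [internal[0]] + [internal[min(i + 1, len(internal) - 1)] for i in range(chain_len)]
    for i in range(chain_len):
        rows.append((f"B{i + 1}", f"{chain[i]} -> {chain[i + 1]}", False, gpr_for()))
    precursor = chain[-1]
    rows.append(("BIOMASS", f"{precursor} ->", False, ""))

    # random extra conversions
    for i in range(n_extras):
        sub = rng.choice(internal)
        prod = rng.choice([m for m in internal if m != sub])
        reversible = rng.random() < spec.reversibility_fraction
        rows.append((f"R{i + 1}", f"{sub} -> {prod}", reversible, gpr_for()))

    model = _model_from_rows(rows, biomass_id="BIOMASS")

    from . import flux_analysis as fa
    from .model_core import fwd, split_reversible

    sets = media_sets_for(model)
    sol = fa.fba(split_reversible(model), fa.all_nutrient_context(sets), fwd(model.biomass_id))
    if sol.status != "optimal" or sol.objective <= fa.GROWTH_THRESHOLD:
        raise GenerationError(f"generated network is not viable (seed {spec.seed})")
    return model


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _format_equation(model: MetabolicModel, rxn: str) -> str:
    subs, prods = [], []
    for met, coef in sorted(model.column(rxn).items()):
        term = met if abs(coef) == 1 else f"{abs(coef):g} {met}"
        (subs if coef < 0 else prods).append(term)
    return f"{' + '.join(subs)} -> {' + '.join(prods)}".strip()


def to_cobra(model: MetabolicModel):
    """A cobrapy model mirroring this one (bounds encode reversibility only)."""
    import cobra

    cmodel = cobra.Model("focal_fixture")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolite_ids}
    for rid in model.reaction_ids:
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = -1000.0 if model.reversible[rid] else 0.0
        rxn.upper_bound = 1000.0
        cmodel.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in model.column(rid).items()})
        gpr = model.gpr.get(rid)
        if gpr is not None and not gpr.is_empty():
            rxn.gene_reaction_rule = gpr.to_string()
    cmodel.objective = model.biomass_id
    return cmodel


def write_fixture(model: MetabolicModel, path, format: str) -> None:
    """Write a model as project TSV, COBRA JSON or SBML (round-trips through
    :func:`focal.model_core.load_model`)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"#!biomass {model.biomass_id}\n")
            fh.write("id\tequation\treversible\tgpr\n")
            for rid in model.reaction_ids:
                gpr = model.gpr.get(rid)
                fh.write(
                    f"{rid}\t{_format_equation(model, rid)}\t"
                    f"{1 if model.reversible[rid] else 0}\t"
                    f"{'' if gpr is None else gpr.to_string()}\n"
                )
        return
    import cobra.io

    cmodel = to_cobra(model)
    if format == "cobra_json":
        cobra.io.save_json_model(cmodel, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(cmodel, str(path))
    else:
        raise ValueError(f"unknown fixture format {format!r}")
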