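"""The single-level reformulation: duality, solving, cuts, co-utilization,
verification, batch coupling, and equivalence against the exhaustive oracle."""

import math

import numpy as np
import pytest

from focal import flux_analysis as fa
from focal import focal_milp as fm
from focal._solver import LinearProgram, SolveStatus, dual_of
from focal.model_core import fwd, load_model, split_reversible
from focal.synthetic_fixtures import (
    FixtureSpec,
    make_random_network,
    media_sets_for,
)

VBIO = fwd("vbio")


def make_problem(split, sets, chosen, **kw):
    biomass = split.parent.biomass_id
    kw.setdefault("coupling_set", [fwd(biomass)])
    return fm.CouplingProblem(split=split, chosen=chosen, media_sets=sets, **kw)


# ---------------------------------------------------------------------------
# duality
# ---------------------------------------------------------------------------


def test_textbook_dual():
    lp = LinearProgram("toy")
    lp.add_var("x", obj=1.0)
    lp.add_constr({"x": 1.0}, ">=", 3.0, tag="c")
    dual = fm.dualize_inner(lp)
    assert lp.solve().objective == pytest.approx(3.0)
    assert dual.solve().objective == pytest.approx(3.0)


def test_random_lp_strong_duality():
    """Dual optimum equals primal optimum whenever the primal is solvable."""
    rng = np.random.default_rng(11)
    solved = 0
    for k in range(50):
        lp = LinearProgram(f"r{k}")
        n, m = int(rng.integers(2, 6)), int(rng.integers(1, 5))
        for j in range(n):
            lp.add_var(f"x{j}", obj=float(rng.normal()))
        for i in range(m):
            lp.add_constr(
                {f"x{j}": float(rng.normal()) for j in range(n)},
                ["<=", ">=", "=="][int(rng.integers(0, 3))],
                float(rng.normal()),
                tag="c",
            )
        primal = lp.solve()
        if not primal.ok:
            continue
        dual = dual_of(lp).solve()
        assert dual.ok
        assert dual.objective == pytest.approx(primal.objective, abs=1e-6)
        solved += 1
    assert solved >= 10  # the suite actually exercised strong duality


def test_inner_primal_fixture_conditions(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    # media {A}, all genes present: the lower pathway still makes F -> min 0
    lp = problem and fm.build_inner_primal(problem, "v2", media_selected=frozenset({"EX_A"}))
    res = lp.solve()
    assert res.ok and res.objective == pytest.approx(0.0, abs=1e-9)
    # same but v8 deleted: upper pathway forced -> positive minimum
    lp2 = fm.build_inner_primal(
        problem, "v2", knockouts=frozenset({"gv8"}), media_selected=frozenset({"EX_A"})
    )
    res2 = lp2.solve()
    assert res2.ok and res2.objective == pytest.approx(1.0)
    # dual of the coupled condition agrees (nested strong duality)
    dres = fm.dualize_inner(lp2).solve()
    assert dres.objective == pytest.approx(res2.objective, abs=1e-6)


def test_inner_primal_infeasible_when_measured_killed(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"], coupling_set=[fwd("v4")])
    # deleting the measured reaction's gene contradicts "measured = 1"
    lp = fm.build_inner_primal(
        problem, "v2", measured=fwd("v4"), knockouts=frozenset({"gv4"}),
        media_selected=frozenset({"EX_A"}),
    )
    assert lp.solve().status is SolveStatus.INFEASIBLE


# ---------------------------------------------------------------------------
# solve_focal on the example network
# ---------------------------------------------------------------------------


def test_focal_recovers_the_single_deletion_condition(example_split, example_sets):
    sol = fm.solve_focal(make_problem(example_split, example_sets, ["v2"]))
    assert sol.status == "coupled"
    assert sol.knockouts == {"gv8"}
    assert sol.media == {"EX_A": "carbon"}
    assert sol.measured == VBIO
    assert sol.inner_objective >= 1e-5
    assert sol.outer_objective == pytest.approx(4.0)  # (5+1)-1 - one deletion
    assert not sol.reaction_states["v8"] and sol.reaction_states["v2"]


def test_focal_self_coupling_needs_no_deletions(example_split, example_sets):
    sol = fm.solve_focal(make_problem(example_split, example_sets, ["vbio"]))
    assert sol.status == "coupled"
    assert sol.knockouts == frozenset()
    assert sol.outer_objective == pytest.approx(5.0)


def test_focal_v3_couples_via_media_alone(example_split, example_sets):
    # H can only come from C; on A-only media C comes only through v3
    sol = fm.solve_focal(make_problem(example_split, example_sets, ["v3"]))
    assert sol.status == "coupled"
    assert sol.knockouts == frozenset()
    assert sol.media == {"EX_A": "carbon"}
    oracle = fa.brute_force_coupling_search(
        example_split, "v3", example_sets, [VBIO], dmax=5
    )
    assert oracle.outer_objective == pytest.approx(sol.outer_objective)


def test_blocked_chosen_short_circuits(tmp_path, example_sets):
    tsv = (
        "#!biomass BIO\n"
        "EX_A\tA_ex ->\t1\t\n"
        "T\tA_ex -> A\t0\tgT\n"
        "DEAD\tA -> X\t0\tgD\n"
        "BIO\tA ->\t0\t\n"
    )
    path = tmp_path / "dead.tsv"
    path.write_text(tsv)
    model = load_model(path, "tsv")
    sets = media_sets_for(model)
    split = split_reversible(model)
    split = split.with_blocked(fa.find_blocked_reactions(split, fa.all_nutrient_context(sets)))
    assert "DEAD" in split.blocked
    sol = fm.solve_focal(make_problem(split, sets, ["DEAD"], dmax=2))
    assert sol.status == "blocked"


def test_penalty_dominance_is_validated(example_split, example_sets):
    with pytest.raises(fm.FocalProblemError, match="penalt"):
        make_problem(example_split, example_sets, ["v2"], alpha=2.0)


def test_every_milp_constraint_is_tagged(example_split, example_sets):
    art = fm.build_focal_milp(make_problem(example_split, example_sets, ["v2"]))
    allowed = {f"Eq{i}" for i in range(5, 23)} | {
        "dual", "linearization", "strong_duality", "cut", "tcap",
    }
    assert art.lp.constraint_tags() <= allowed


def test_staged_policy_still_finds_the_solution(example_split, example_sets):
    policy = fm.SearchPolicy(staged_media=True, reduced_media_set=("EX_A",))
    sol = fm.solve_focal(make_problem(example_split, example_sets, ["v2"], policy=policy))
    assert sol.status == "coupled" and sol.knockouts == {"gv8"}


# ---------------------------------------------------------------------------
# integer cuts and enumeration
# ---------------------------------------------------------------------------


def test_integer_cut_excludes_prior_solution(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    art = fm.build_focal_milp(problem)
    first = fm._solve_artifact(art, None)
    assert first.status == "coupled"
    fm.add_integer_cut(art, first)
    second = fm._solve_artifact(art, None)
    if second.status == "coupled":  # must differ and not be a superset
        assert not (
            set(first.knockouts) <= set(second.knockouts)
            and set(first.media) <= set(second.media)
        )
    else:
        assert second.status in ("uncoupled", "infeasible")


def test_integer_cut_requires_coupled_prior(example_split, example_sets):
    art = fm.build_focal_milp(make_problem(example_split, example_sets, ["v2"]))
    with pytest.raises(fm.FocalProblemError):
        fm.add_integer_cut(art, fm.CouplingSolution(status="uncoupled"))


def test_degenerate_media_only_cut_bans_the_exchange(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    art = fm.build_focal_milp(problem)
    prior = fm.CouplingSolution(
        status="coupled", r_obj=1, media={"EX_A": "carbon"}, knockouts=frozenset()
    )
    fm.add_integer_cut(art, prior, mode="media_only")
    cut = [c for c in art.lp.constraints if c.tag == "cut"][0]
    assert cut.rhs == pytest.approx(0.0)  # h_EX_A <= 0
    sol = fm._solve_artifact(art, None)
    assert sol.status != "coupled" or "EX_A" not in sol.media


def test_enumeration_cap_one_equals_solve(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    single = fm.solve_focal(problem)
    alts = fm.enumerate_alternatives(problem, 1)
    assert len(alts) == 1
    assert alts[0].knockouts == single.knockouts
    assert alts[0].media == single.media


def test_enumeration_matches_exhaustive_search(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    alts = fm.enumerate_alternatives(problem, 10)
    oracle = fa.brute_force_enumerate(example_split, "v2", example_sets, [VBIO], dmax=5)
    ours = {(frozenset(a.knockouts), frozenset(a.media)) for a in alts}
    theirs = {(frozenset(a.knockouts), frozenset(a.media)) for a in oracle}
    assert ours == theirs


# ---------------------------------------------------------------------------
# co-utilization
# ---------------------------------------------------------------------------


def test_coutilization_design(example_split, example_sets_two_carbon):
    problem = make_problem(example_split, example_sets_two_carbon, ["v1", "v10"])
    sol = fm.design_coutilization(problem)
    assert sol.status == "coupled"
    assert sol.knockouts == {"gv3", "gv8"}
    assert set(sol.media) == {"EX_A", "EX_G"}
    assert all(v >= problem.eps for v in sol.inner_objectives.values())
    # FBA triple check: no growth on either sugar alone, growth on both
    for selected, grows in (({"EX_A"}, False), ({"EX_G"}, False), ({"EX_A", "EX_G"}, True)):
        ctx = fa.media_context(example_sets_two_carbon, selected, sol.knockouts)
        growth = fa.fba(example_split, ctx, VBIO).objective
        assert (growth > 1e-6) is grows


def test_coutilization_duplicate_chosen_is_trivial(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["vbio", "vbio"])
    sol = fm.design_coutilization(problem)
    assert sol.status == "coupled"
    assert sol.knockouts == frozenset()


def test_coutilization_needs_two_chosen(example_split, example_sets):
    with pytest.raises(fm.FocalProblemError):
        fm.design_coutilization(make_problem(example_split, example_sets, ["v1"]))


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def test_verify_accepts_the_real_condition(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    sol = fm.solve_focal(problem)
    report = fm.verify_solution(problem, sol)
    assert report.is_valid
    assert report.min_ratios["v2"] >= problem.eps


def test_verify_rejects_bogus_condition(example_split, example_sets):
    problem = make_problem(example_split, example_sets, ["v2"])
    bogus = fm.CouplingSolution(
        status="coupled", r_obj=1, measured=VBIO,
        media={"EX_A": "carbon"}, knockouts=frozenset(),  # wild type: v2 not needed
    )
    report = fm.verify_solution(problem, bogus)
    assert not report.is_valid
    assert report.growth_ok  # it grows, but the chosen reaction is dispensable
    assert not report.essential["v2"]


# ---------------------------------------------------------------------------
# batch coupling
# ---------------------------------------------------------------------------


def test_couple_all_on_example_network(example_split, example_sets):
    outcomes = fm.couple_all_reactions(example_split, example_sets)
    by_rxn = {o.reaction: o for o in outcomes}
    assert set(by_rxn) == set(example_split.parent.reaction_ids)
    assert by_rxn["v2"].category == "coupled"
    assert by_rxn["v2"].deletion_count == 1
    assert by_rxn["v2"].condition.knockouts == {"gv8"}
    # the futile pair can never be made essential
    assert by_rxn["v5"].category == "uncoupled"
    assert by_rxn["v6"].category == "uncoupled"
    assert by_rxn["vbio"].category == "coupled"
    # oracle agrees on every verdict
    for rxn, o in by_rxn.items():
        oracle = fa.brute_force_coupling_search(
            example_split, rxn, example_sets, [VBIO], dmax=5
        )
        assert (o.category == "coupled") == (oracle is not None)


# ---------------------------------------------------------------------------
# randomized oracle equivalence and invariants
# ---------------------------------------------------------------------------


def _random_suite(n_networks, dmax=2, seed0=1000):
    for i in range(n_networks):
        spec = FixtureSpec(
            n_metabolites=6,
            n_reactions=8 + (i % 5),
            n_exchanges=2 + (i % 2),
            reversibility_fraction=0.2,
            seed=seed0 + i,
        )
        model = make_random_network(spec)
        sets = media_sets_for(model)
        split = split_reversible(model)
        split = split.with_blocked(
            fa.find_blocked_reactions(split, fa.all_nutrient_context(sets))
        )
        yield split, sets, dmax


def test_oracle_equivalence_on_random_networks():
    """solve_focal and the exhaustive search agree on couplability and outer
    objective for every (network, chosen reaction) pair."""
    for split, sets, dmax in _random_suite(6):
        coupling = [fwd(split.parent.biomass_id)]
        for rxn in split.unblocked_reactions:
            sol = fm.solve_focal(make_problem(split, sets, [rxn], dmax=dmax))
            oracle = fa.brute_force_coupling_search(split, rxn, sets, coupling, dmax=dmax)
            assert (sol.status == "coupled") == (oracle is not None), (
                f"verdict mismatch for {rxn} (seed net)"
            )
            if oracle is not None:
                assert sol.outer_objective == pytest.approx(
                    oracle.outer_objective, abs=1e-4
                )
                # soundness: emitted couplings verify independently
                report = fm.verify_solution(make_problem(split, sets, [rxn], dmax=dmax), sol)
                assert report.is_valid


def test_strong_duality_at_coupled_optima(example_split, example_sets):
    """Nested primal and dual inner objectives agree within 1e-6 at every
    coupled optimum found on the example network."""
    problem = make_problem(example_split, example_sets, ["v2"])
    for rxn in ("v1", "v2", "v3", "vbio"):
        sol = fm.solve_focal(make_problem(example_split, example_sets, [rxn]))
        if sol.status != "coupled":
            continue
        inner = fm.build_inner_primal(
            problem, rxn, measured=sol.measured,
            knockouts=sol.knockouts, media_selected=frozenset(sol.media),
        )
        p = inner.solve()
        d = fm.dualize_inner(inner).solve()
        assert p.ok and d.ok
        assert abs(p.objective - d.objective) <= 1e-6
        assert sol.inner_objective == pytest.approx(p.objective, abs=1e-5)


def test_epsilon_monotonicity(example_split, example_sets):
    """A condition accepted at eps is accepted at any smaller eps' > 0."""
    sol = fm.solve_focal(make_problem(example_split, example_sets, ["v2"], eps=1e-4))
    assert sol.status == "coupled"
    for eps in (1e-5, 1e-7):
        again = fm.solve_focal(make_problem(example_split, example_sets, ["v2"], eps=eps))
        assert again.status == "coupled"
        assert again.inner_objective >= eps


def test_objective_dominance(example_split, example_sets):
    """Any coupled solution scores above the uncoupled baseline of -1."""
    for rxn in ("v1", "v2", "v3", "v4"):
        sol = fm.solve_focal(make_problem(example_split, example_sets, [rxn]))
        if sol.status == "coupled":
            assert sol.outer_objective > -1.0
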