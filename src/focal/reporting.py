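"""Batch statistics and network analyses over forced-coupling outcomes.

Category breakdowns (blocked / coupled / uncoupled), deletion-count
histograms, per-subsystem distributions, and the deleted-reaction-to-chosen
shortest-path analysis with a resampled random baseline and a one-tailed
Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model_core import MetabolicModel

__all__ = [
    "DEFAULT_CURRENCY_METABOLITES",
    "CouplingOutcome",
    "build_reaction_graph",
    "categorize",
    "deletion_distance_stats",
    "outcomes_to_frame",
]

# common cofactor/carrier metabolites excluded from graph edges by default;
# matching is by exact id, callers with compartment suffixes pass their own list
DEFAULT_CURRENCY_METABOLITES = (
    "h", "h2o", "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
    "co2", "pi", "ppi", "coa", "o2", "nh4",
)


@dataclass
class CouplingOutcome:
    reaction: str
    category: str  # blocked | coupled | uncoupled
    deletion_count: int | None = None
    subsystem: str = ""
    condition: object | None = None  # CouplingSolution for coupled reactions
    reason: str = ""

    def __post_init__(self):
        if self.category not in ("blocked", "coupled", "uncoupled"):
            raise ValueError(f"unknown category {self.category!r}")
        if (self.deletion_count is not None) != (self.category == "coupled"):
            raise ValueError("deletion_count must be present exactly for coupled outcomes")


def outcomes_to_frame(outcomes: list[CouplingOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reaction": [o.reaction for o in outcomes],
            "category": [o.category for o in outcomes],
            "deletion_count": [o.deletion_count for o in outcomes],
            "subsystem": [o.subsystem for o in outcomes],
            "reason": [o.reason for o in outcomes],
        }
    )


def categorize(outcomes: list[CouplingOutcome]) -> dict:
    """Counts and percentages by category, a deletion-count histogram over the
    coupled reactions, and a per-subsystem breakdown."""
    ids = [o.reaction for o in outcomes]
    if len(ids) != len(set(ids)):
        dupes = sorted({r for r in ids if ids.count(r) > 1})
        raise ValueError(f"duplicate reaction ids in outcomes: {dupes}")
    n = len(outcomes)
    counts = {k: 0 for k in ("blocked", "coupled", "uncoupled")}
    histogram: dict[int, int] = {}
    for o in outcomes:
        counts[o.category] += 1
        if o.category == "coupled":
            histogram[o.deletion_count] = histogram.get(o.deletion_count, 0) + 1
    percentages = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    frame = outcomes_to_frame(outcomes)
    if n:
        by_subsystem = (
            frame.groupby(["subsystem", "category"]).size().unstack(fill_value=0)
        )
    else:
        by_subsystem = pd.DataFrame()
    return {
        "n": n,
        "counts": counts,
        "percentages": percentages,
        "deletion_histogram": dict(sorted(histogram.items())),
        "by_subsystem": by_subsystem,
    }


def build_reaction_graph(
    model: MetabolicModel,
    directed: bool,
    exclude_currency: tuple[str, ...] = DEFAULT_CURRENCY_METABOLITES,
) -> nx.Graph:
    """Reaction graph: nodes are reactions, edges connect reactions sharing a
    non-currency metabolite; in the directed variant an edge j -> j' exists
    when a product of j is a substrate of j' (reversible reactions contribute
    both orientations)."""
    currency = set(exclude_currency)
    graph = nx.DiGraph() if directed else nx.Graph()
    graph.add_nodes_from(model.reaction_ids)
    touched: dict[str, list[tuple[str, float]]] = {}
    for (met, rxn), coef in model.stoichiometry.items():
        if met in currency or not coef:
            continue
        touched.setdefault(met, []).append((rxn, coef))
    for met, entries in touched.items():
        if directed:
            producers = {r for r, c in entries if c > 0 or model.reversible[r]}
            consumers = {r for r, c in entries if c < 0 or model.reversible[r]}
            for a in producers:
                for b in consumers:
                    if a != b:
                        graph.add_edge(a, b)
        else:
            rxns = sorted({r for r, _ in entries})
            for i, a in enumerate(rxns):
                for b in rxns[i + 1:]:
                    graph.add_edge(a, b)
    return graph


def _deleted_reactions(outcome: CouplingOutcome) -> list[str]:
    sol = outcome.condition
    if sol is None:
        return []
    return sorted(r for r, active in sol.reaction_states.items() if not active)


def deletion_distance_stats(
    outcomes: list[CouplingOutcome],
    graph: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    multi_deletion: str = "skip",
) -> dict:
    """Are the deleted reactions closer to their chosen reaction than chance?

    Observed distances are directed shortest paths from each deleted reaction
    to the chosen reaction, over coupled outcomes with a single deleted
    reaction (``multi_deletion='mean'`` averages over multi-deletion sets
    instead of skipping them).  The baseline resamples deleted reactions
    uniformly from the graph, ``n_random`` draws per observation.  A
    one-tailed Welch t-test asks whether observed < random.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    observed: list[float] = []
    anchors: list[str] = []
    n_unreachable = 0

    def distance(src: str, dst: str) -> float | None:
        try:
            return float(nx.shortest_path_length(graph, src, dst))
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None

    for o in outcomes:
        if o.category != "coupled":
            continue
        deleted = _deleted_reactions(o)
        if not deleted:
            continue
        if len(deleted) > 1:
            if multi_deletion == "skip":
                continue
            ds = [distance(d, o.reaction) for d in deleted]
            ds = [d for d in ds if d is not None]
            if not ds:
                n_unreachable += 1
                continue
            observed.append(float(np.mean(ds)))
            anchors.append(o.reaction)
        else:
            d = distance(deleted[0], o.reaction)
            if d is None:
                n_unreachable += 1
                continue
            observed.append(d)
            anchors.append(o.reaction)

    random_distances: list[float] = []
    for chosen in anchors:
        for pick in rng.choice(len(nodes), size=n_random):
            d = distance(nodes[pick], chosen)
            if d is not None:
                random_distances.append(d)

    if not observed or not random_distances:
        return {
            "mean_observed": float("nan"),
            "mean_random": float("nan"),
            "t_statistic": float("nan"),
            "p_value": float("nan"),
            "n_observed": len(observed),
            "n_random": len(random_distances),
            "n_unreachable": n_unreachable,
        }
    t_stat, p_value = stats.ttest_ind(
        observed, random_distances, equal_var=False, alternative="less"
    )
    return {
        "mean_observed": float(np.mean(observed)),
        "mean_random": float(np.mean(random_distances)),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "n_observed": len(observed),
        "n_random": len(random_distances),
        "n_unreachable": n_unreachable,
    }
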