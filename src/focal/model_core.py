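"""Metabolic model representation and preprocessing.

Holds the stoichiometric model (metabolites, reactions, reversibility,
gene-protein-reaction rules, exchange reactions), the irreversible split used
by all flux-ratio computations, and the minimal-media component sets (carbon /
nitrogen / electron-acceptor / additional nutrient candidates with per-exchange
maximum uptake rates).

Conventions
-----------
* Exchange reactions are stored in the *export-positive* orientation: the
  single metabolite they touch carries a negative coefficient, so nutrient
  uptake is the reverse component of the split reaction.
* Reversibility is the only bound information retained from input files;
  uptake magnitudes come from the media configuration, internal fluxes are
  capped by the analysis layer.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GprExpression",
    "GprParseError",
    "MediaComponentSets",
    "MetabolicModel",
    "ModelValidationError",
    "ParseError",
    "SplitModel",
    "MEDIA_TYPES",
    "build_media_sets",
    "fwd",
    "rev",
    "load_model",
    "parse_gpr",
    "read_media_tsv",
    "split_reversible",
    "write_media_tsv",
]

MEDIA_TYPES = ("carbon", "nitrogen", "electron_acceptor", "additional")


class ParseError(ValueError):
    """A model file could not be parsed; the message names the offending element."""


class ModelValidationError(ValueError):
    """A structurally invalid model (dangling references, bad exchange, ...)."""


class GprParseError(ParseError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-\[\]]+)")


@dataclass(frozen=True)
class GprExpression:
    """Boolean AND/OR tree over gene identifiers.

    ``root`` is ``None`` for an orphan reaction (no gene association), or a
    nested tuple ``("gene", gid)`` / ``("and", children)`` / ``("or", children)``.
    An orphan always evaluates active and can never be disabled by knockouts.
    """

    root: tuple | None = None

    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            kind = node[0]
            if kind == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self.root)
        return frozenset(out)

    def evaluate(self, knockouts: set[str] | frozenset[str]) -> bool:
        """Is the reaction active when the genes in ``knockouts`` are deleted?"""

        def walk(node) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in knockouts
            if kind == "and":
                return all(walk(c) for c in node[1])
            return any(walk(c) for c in node[1])

        if self.root is None:
            return True
        return walk(self.root)

    def to_string(self) -> str:
        def fmt(node) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            sep = f" {kind} "
            return "(" + sep.join(fmt(c) for c in node[1]) + ")"

        return "" if self.root is None else fmt(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str) -> GprExpression:
    """Parse a COBRA-style GPR string (case-insensitive ``and``/``or``).

    The grammar is monotone boolean: gene ids, AND, OR and parentheses; OR
    binds loosest.  An empty/blank string yields the orphan expression.
    """
    if text is None or not text.strip():
        return GprExpression(None)

    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GprParseError(f"unknown token {stripped[0]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def parse_or():
        nonlocal idx
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return ("or", tuple(children))

    def parse_and():
        nonlocal idx
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return ("and", tuple(children))

    def parse_atom():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", len(text))
        tok_pos = tokens[idx][1]
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses", tok_pos)
            idx += 1
            return node
        if tok == ")":
            raise GprParseError("unbalanced parentheses", tok_pos)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"misplaced operator {tok!r}", tok_pos)
        idx += 1
        return ("gene", tok)

    root = parse_or()
    if idx != len(tokens):
        raise GprParseError(f"trailing token {tokens[idx][0]!r}", tokens[idx][1])
    return GprExpression(root)


# ---------------------------------------------------------------------------
# MetabolicModel
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: dict[tuple[str, str], float]
    reversible: dict[str, bool]
    gpr: dict[str, GprExpression]
    genes: list[str]
    biomass_id: str
    subsystems: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        mets = set(self.metabolite_ids)
        rxns = set(self.reaction_ids)
        for (met, rxn), coef in self.stoichiometry.items():
            if met not in mets:
                raise ModelValidationError(f"reaction {rxn!r} references undeclared metabolite {met!r}")
            if rxn not in rxns:
                raise ModelValidationError(f"stoichiometry references undeclared reaction {rxn!r}")
            if not math.isfinite(coef):
                raise ModelValidationError(f"non-finite coefficient for ({met!r}, {rxn!r})")
        if self.biomass_id not in rxns:
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} not in model")
        declared = set(self.genes)
        for rxn in self.reaction_ids:
            expr = self.gpr.get(rxn, GprExpression(None))
            missing = expr.genes() - declared
            if missing:
                raise ModelValidationError(
                    f"GPR of {rxn!r} references undeclared gene(s) {sorted(missing)}"
                )
        for x in self.exchanges:
            if sum(1 for (m, r), c in self.stoichiometry.items() if r == x and c) != 1:
                raise ModelValidationError(f"exchange {x!r} must touch exactly one metabolite")

    # -- derived views -----------------------------------------------------
    @property
    def exchanges(self) -> list[str]:
        """Reactions exchanging exactly one metabolite with the environment.

        The biomass reaction is excluded even when it drains a single
        precursor: it is a demand, not a boundary exchange.
        """
        counts: dict[str, int] = {}
        for (met, rxn), coef in self.stoichiometry.items():
            if coef:
                counts[rxn] = counts.get(rxn, 0) + 1
        return [
            r for r in self.reaction_ids
            if counts.get(r, 0) == 1 and r != self.biomass_id
        ]

    def exchange_metabolite(self, exch: str) -> str:
        for (met, rxn), coef in self.stoichiometry.items():
            if rxn == exch and coef:
                return met
        raise KeyError(exch)

    def reactions_of_gene(self, gene: str) -> list[str]:
        return [r for r in self.reaction_ids if gene in self.gpr.get(r, GprExpression()).genes()]

    def disabled_reactions(self, knockouts: set[str] | frozenset[str]) -> frozenset[str]:
        """Reactions whose GPR is inactive under the given gene deletions."""
        ko = set(knockouts)
        unknown = ko - set(self.genes)
        if unknown:
            raise ModelValidationError(f"unknown gene(s) in knockout set: {sorted(unknown)}")
        return frozenset(
            r
            for r in self.reaction_ids
            if not self.gpr.get(r, GprExpression()).evaluate(ko)
        )

    def column(self, rxn: str) -> dict[str, float]:
        return {m: c for (m, r), c in self.stoichiometry.items() if r == rxn and c}


# ---------------------------------------------------------------------------
# Irreversible split
# ---------------------------------------------------------------------------


def fwd(rxn: str) -> str:
    return f"{rxn}:fwd"


def rev(rxn: str) -> str:
    return f"{rxn}:rev"


@dataclass
class SplitModel:
    """Irreversible expansion of a model: one forward component per reaction,
    plus a reverse component (negated stoichiometry) for each reversible one.

    ``blocked`` lists original reactions excluded from the balance; only the
    components of unblocked reactions enter any LP built on this model.
    """

    parent: MetabolicModel
    blocked: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.blocked - set(self.parent.reaction_ids)
        if unknown:
            raise ModelValidationError(f"blocked set references unknown reactions {sorted(unknown)}")

    # -- component bookkeeping --------------------------------------------
    def components_of(self, rxn: str) -> tuple[str, ...]:
        if self.parent.reversible[rxn]:
            return (fwd(rxn), rev(rxn))
        return (fwd(rxn),)

    @property
    def component_ids(self) -> list[str]:
        out = []
        for r in self.parent.reaction_ids:
            out.extend(self.components_of(r))
        return out

    @property
    def unblocked_reactions(self) -> list[str]:
        return [r for r in self.parent.reaction_ids if r not in self.blocked]

    @property
    def unblocked_components(self) -> list[str]:
        out = []
        for r in self.unblocked_reactions:
            out.extend(self.components_of(r))
        return out

    def origin(self, component: str) -> tuple[str, int]:
        """Original reaction and direction sign (+1 forward, -1 reverse)."""
        if component.endswith(":fwd"):
            return component[:-4], +1
        if component.endswith(":rev"):
            return component[:-4], -1
        raise KeyError(component)

    def component_column(self, component: str) -> dict[str, float]:
        rxn, sign = self.origin(component)
        return {m: sign * c for m, c in self.parent.column(rxn).items()}

    def net_flux(self, component_fluxes: dict[str, float], rxn: str) -> float:
        v = component_fluxes.get(fwd(rxn), 0.0)
        if self.parent.reversible[rxn]:
            v -= component_fluxes.get(rev(rxn), 0.0)
        return v

    def with_blocked(self, blocked: set[str] | frozenset[str]) -> "SplitModel":
        return SplitModel(self.parent, frozenset(blocked))


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Decompose every reversible reaction into forward and reverse components.

    Component count is ``|R| + |R_reversible|`` and every component flux is
    bounded below by zero; no blocked set is attached yet (see
    :func:`focal.flux_analysis.find_blocked_reactions`).
    """
    for r in model.reaction_ids:
        if r.endswith(":fwd") or r.endswith(":rev"):
            raise ModelValidationError(
                f"reaction id {r!r} collides with split-component naming"
            )
    return SplitModel(model)


# ---------------------------------------------------------------------------
# Media component sets
# ---------------------------------------------------------------------------


@dataclass
class MediaComponentSets:
    """Membership of exchange reactions in the four media component types.

    ``membership`` holds the (exchange, type) pairs eligible for selection,
    ``max_per_type`` the per-type selection cap (``maxMedia``), ``minimal``
    the always-open exchanges that are never decision variables, and
    ``max_uptake`` the per-exchange uptake cap in mmol·gDW⁻¹·h⁻¹.
    """

    membership: frozenset[tuple[str, str]]
    max_per_type: dict[str, int]
    minimal: frozenset[str]
    max_uptake: dict[str, float]

    def __post_init__(self) -> None:
        for x, k in self.membership:
            if k not in MEDIA_TYPES:
                raise ModelValidationError(f"unknown media type {k!r} for exchange {x!r}")
        for k in MEDIA_TYPES:
            self.max_per_type.setdefault(k, 1)
            if self.max_per_type[k] < 1:
                raise ModelValidationError(f"max_per_type[{k!r}] must be >= 1")
        for x in self.selectable | self.minimal:
            if self.max_uptake.get(x, 0.0) <= 0.0:
                raise ModelValidationError(f"exchange {x!r} needs a positive max uptake")

    @property
    def selectable(self) -> frozenset[str]:
        return frozenset(x for x, _ in self.membership)

    def types_of(self, exch: str) -> tuple[str, ...]:
        return tuple(k for k in MEDIA_TYPES if (exch, k) in self.membership)

    def members(self, media_type: str) -> frozenset[str]:
        return frozenset(x for x, k in self.membership if k == media_type)

    def restrict(self, exchanges: set[str] | frozenset[str]) -> "MediaComponentSets":
        """Sets limited to the given selectable exchanges (staged search)."""
        keep = frozenset(exchanges)
        return MediaComponentSets(
            membership=frozenset((x, k) for x, k in self.membership if x in keep),
            max_per_type=dict(self.max_per_type),
            minimal=self.minimal,
            max_uptake=dict(self.max_uptake),
        )


def read_media_tsv(path) -> list[dict]:
    """Rows of the media config TSV: exchange_id, type, max_uptake, in_minimal."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "exchange_id":  # header
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 tab-separated columns")
            exch, mtype, uptake, in_min = parts
            rows.append(
                {
                    "exchange_id": exch,
                    "type": mtype if mtype not in ("", "-") else None,
                    "max_uptake": float(uptake),
                    "in_minimal": in_min.strip().lower() in ("1", "true", "yes"),
                }
            )
    return rows


def write_media_tsv(path, sets: MediaComponentSets) -> None:
    with open(path, "w") as fh:
        fh.write("exchange_id\ttype\tmax_uptake\tin_minimal\n")
        for x, k in sorted(sets.membership):
            fh.write(f"{x}\t{k}\t{sets.max_uptake[x]:g}\t0\n")
        for x in sorted(sets.minimal):
            fh.write(f"{x}\t-\t{sets.max_uptake[x]:g}\t1\n")


def build_media_sets(
    model: MetabolicModel,
    config,
    classify_by_fba: bool = False,
    max_per_type: dict[str, int] | None = None,
    growth_threshold: float = 1e-6,
) -> MediaComponentSets:
    """Assemble :class:`MediaComponentSets` from a media config TSV.

    With ``classify_by_fba`` every candidate membership is screened by flux
    balance analysis: the exchange is opened as the sole member of its type
    (all other selectable exchanges closed, Minimal open) and dropped from
    that type if maximal biomass flux stays at or below ``growth_threshold``.
    """
    rows = config if isinstance(config, list) else read_media_tsv(config)
    exch_set = set(model.exchanges)
    membership: set[tuple[str, str]] = set()
    minimal: set[str] = set()
    max_uptake: dict[str, float] = {}
    for row in rows:
        x = row["exchange_id"]
        if x not in exch_set:
            raise ModelValidationError(f"media config names non-exchange reaction {x!r}")
        max_uptake[x] = row["max_uptake"]
        if row["in_minimal"]:
            minimal.add(x)
        elif row["type"] is not None:
            if row["type"] not in MEDIA_TYPES:
                raise ModelValidationError(f"unknown media type {row['type']!r}")
            membership.add((x, row["type"]))

    sets = MediaComponentSets(
        membership=frozenset(membership),
        max_per_type=dict(max_per_type or {}),
        minimal=frozenset(minimal),
        max_uptake=max_uptake,
    )
    if not classify_by_fba:
        return sets

    from . import flux_analysis  # deferred: flux_analysis imports this module

    split = split_reversible(model)
    keep: set[tuple[str, str]] = set()
    for x, k in sorted(sets.membership):
        ctx = flux_analysis.MediaContext(
            open_exchanges={x: sets.max_uptake[x], **{m: sets.max_uptake[m] for m in sets.minimal}},
            knockouts=frozenset(),
        )
        sol = flux_analysis.fba(split, ctx, fwd(model.biomass_id))
        if sol.status == "optimal" and sol.objective > growth_threshold:
            keep.add((x, k))
    return replace(sets, membership=frozenset(keep))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def _parse_equation(eq: str, rxn: str) -> tuple[dict[str, float], bool]:
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ParseError(f"reaction {rxn!r}: no arrow in equation {eq!r}")
    left, right = eq.split(arrow, 1)
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ParseError(f"reaction {rxn!r}: empty term in equation {eq!r}")
            bits = term.split()
            if len(bits) == 1:
                coef, met = 1.0, bits[0]
            elif len(bits) == 2:
                try:
                    coef = float(bits[0])
                except ValueError as exc:
                    raise ParseError(f"reaction {rxn!r}: bad coefficient {bits[0]!r}") from exc
                met = bits[1]
            else:
                raise ParseError(f"reaction {rxn!r}: malformed term {term!r}")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {m: c for m, c in coeffs.items() if c}, arrow in ("<->", "<=>")


def _load_tsv(path) -> MetabolicModel:
    stoich: dict[tuple[str, str], float] = {}
    reactions: list[str] = []
    reversible: dict[str, bool] = {}
    gpr: dict[str, GprExpression] = {}
    mets: list[str] = []
    seen_mets: set[str] = set()
    biomass_id: str | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("#!biomass"):
                biomass_id = line.split(None, 1)[1].strip()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "id":
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 tab-separated columns, got {len(parts)}")
            rid, eq, rev_flag, gpr_text = parts
            if rid in reversible:
                raise ParseError(f"{path}:{ln}: duplicate reaction id {rid!r}")
            coeffs, eq_rev = _parse_equation(eq, rid)
            reactions.append(rid)
            reversible[rid] = eq_rev or rev_flag.strip().lower() in ("1", "true", "yes")
            gpr[rid] = parse_gpr(gpr_text)
            for m, c in coeffs.items():
                stoich[(m, rid)] = c
                if m not in seen_mets:
                    seen_mets.add(m)
                    mets.append(m)
    if biomass_id is None:
        candidates = [r for r in reactions if "bio" in r.lower()]
        if len(candidates) != 1:
            raise ParseError(f"{path}: no '#!biomass <id>' directive and no unique *bio* reaction")
        biomass_id = candidates[0]
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


def _from_cobra(cmodel) -> MetabolicModel:
    """Convert a cobrapy model, normalizing exchanges to export-positive."""
    stoich: dict[tuple[str, str], float] = {}
    reversible: dict[str, bool] = {}
    gpr: dict[str, GprExpression] = {}
    subsystems: dict[str, str] = {}
    reactions = [r.id for r in cmodel.reactions]
    mets = [m.id for m in cmodel.metabolites]
    for rxn in cmodel.reactions:
        coeffs = {m.id: float(c) for m, c in rxn.metabolites.items() if c}
        can_fwd = rxn.upper_bound > 0
        can_back = rxn.lower_bound < 0
        flip = False
        if len(coeffs) == 1:  # exchange: force export-positive orientation
            if next(iter(coeffs.values())) > 0:
                flip = True
        elif not can_fwd and can_back:
            flip = True
        if flip:
            coeffs = {m: -c for m, c in coeffs.items()}
            can_fwd, can_back = can_back, can_fwd
        for m, c in coeffs.items():
            stoich[(m, rxn.id)] = c
        reversible[rxn.id] = bool(can_back)
        gpr[rxn.id] = parse_gpr(rxn.gene_reaction_rule or "")
        if getattr(rxn, "subsystem", None):
            subsystems[rxn.id] = rxn.subsystem
    biomass = None
    for rxn in cmodel.reactions:
        if rxn.objective_coefficient:
            biomass = rxn.id
            break
    if biomass is None:
        candidates = [r for r in reactions if "biomass" in r.lower() or "bio" in r.lower()]
        if not candidates:
            raise ParseError("model declares no objective and no *biomass* reaction")
        biomass = candidates[0]
    genes = sorted({g for e in gpr.values() for g in e.genes()})
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=reactions,
        stoichiometry=stoich,
        reversible=reversible,
        gpr=gpr,
        genes=genes,
        biomass_id=biomass,
        subsystems=subsystems,
    )


def load_model(path, format: str) -> MetabolicModel:
    """Load a metabolic model from ``sbml``, ``cobra_json`` or ``tsv``.

    Exchange reactions are auto-detected as the single-metabolite boundary
    reactions and normalized to the export-positive orientation.
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "cobra_json":
        import cobra.io

        try:
            cmodel = cobra.io.load_json_model(str(path))
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            raise ParseError(f"failed to parse COBRA JSON {path}: {exc}") from exc
        return _from_cobra(cmodel)
    if format == "sbml":
        import cobra.io

        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises a mix of exception types here
            raise ParseError(f"failed to parse SBML {path}: {exc}") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unknown model format {format!r}")
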