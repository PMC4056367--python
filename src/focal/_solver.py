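"""Thin LP/MILP layer over scipy's HiGHS interfaces.

All linear and mixed-integer programs in the package are assembled through
:class:`LinearProgram`, a small incremental model builder that keeps variables
and constraints addressable by name and tag.  Continuous problems are solved
with :func:`scipy.optimize.linprog`, problems with integer variables with
:func:`scipy.optimize.milp` (both HiGHS).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["LinearProgram", "SolveResult", "SolveStatus", "dual_of"]

INF = float("inf")


class SolveStatus(enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    TIME_LIMIT = "time_limit"
    ERROR = "error"


@dataclass
class SolveResult:
    status: SolveStatus
    objective: float | None
    values: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status is SolveStatus.OPTIMAL

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class _Constraint:
    coeffs: dict[int, float]
    sense: str  # "<=", ">=", "=="
    rhs: float
    tag: str
    name: str


class LinearProgram:
    """Incremental LP/MILP model with named variables and tagged constraints."""

    def __init__(self, name: str = "", sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        self.name = name
        self.sense = sense
        self._var_names: list[str] = []
        self._var_index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._obj: dict[int, float] = {}
        self._constraints: list[_Constraint] = []

    # -- variables ---------------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = INF,
        obj: float = 0.0,
        integer: bool = False,
    ) -> str:
        if name in self._var_index:
            raise ValueError(f"duplicate variable {name!r}")
        self._var_index[name] = len(self._var_names)
        self._var_names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        if obj:
            self._obj[self._var_index[name]] = obj
        return name

    def add_binary(self, name: str, obj: float = 0.0) -> str:
        return self.add_var(name, lb=0.0, ub=1.0, obj=obj, integer=True)

    def has_var(self, name: str) -> bool:
        return name in self._var_index

    @property
    def variables(self) -> list[str]:
        return list(self._var_names)

    def set_bounds(self, name: str, lb: float | None = None, ub: float | None = None) -> None:
        i = self._var_index[name]
        if lb is not None:
            self._lb[i] = lb
        if ub is not None:
            self._ub[i] = ub

    def bounds_of(self, name: str) -> tuple[float, float]:
        i = self._var_index[name]
        return self._lb[i], self._ub[i]

    def set_objective_coeff(self, name: str, coeff: float) -> None:
        self._obj[self._var_index[name]] = coeff

    def objective_coeff(self, name: str) -> float:
        return self._obj.get(self._var_index[name], 0.0)

    # -- constraints -------------------------------------------------------
    def add_constr(
        self,
        coeffs: dict[str, float],
        sense: str,
        rhs: float,
        tag: str,
        name: str | None = None,
    ) -> None:
        if sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {sense!r}")
        idx: dict[int, float] = {}
        for var, coef in coeffs.items():
            if coef == 0.0:
                continue
            idx[self._var_index[var]] = idx.get(self._var_index[var], 0.0) + coef
        self._constraints.append(
            _Constraint(idx, sense, rhs, tag, name or f"c{len(self._constraints)}")
        )

    @property
    def constraints(self) -> list[_Constraint]:
        return list(self._constraints)

    def constraint_tags(self) -> set[str]:
        return {c.tag for c in self._constraints}

    # -- assembly & solve --------------------------------------------------
    def _matrix(self) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
        n, m = len(self._var_names), len(self._constraints)
        rows, cols, data = [], [], []
        lower = np.empty(m)
        upper = np.empty(m)
        for r, con in enumerate(self._constraints):
            for c, v in con.coeffs.items():
                rows.append(r)
                cols.append(c)
                data.append(v)
            if con.sense == "<=":
                lower[r], upper[r] = -np.inf, con.rhs
            elif con.sense == ">=":
                lower[r], upper[r] = con.rhs, np.inf
            else:
                lower[r] = upper[r] = con.rhs
        A = sp.csr_matrix((data, (rows, cols)), shape=(m, n))
        return A, lower, upper

    def solve(self, time_limit: float | None = None) -> SolveResult:
        n = len(self._var_names)
        c = np.zeros(n)
        for i, v in self._obj.items():
            c[i] = v
        sign = 1.0 if self.sense == "min" else -1.0
        lb = np.array(self._lb, dtype=float)
        ub = np.array(self._ub, dtype=float)
        A, lower, upper = self._matrix()
        if any(self._integer):
            integrality = np.array(self._integer, dtype=int)
            # big-M rows amplify integrality slack, so run HiGHS tighter than
            # its defaults; the options pass through scipy verbatim
            options = {
                "mip_feasibility_tolerance": 1e-9,
                "primal_feasibility_tolerance": 1e-8,
                "dual_feasibility_tolerance": 1e-8,
            }
            if time_limit is not None:
                options["time_limit"] = float(time_limit)
            cons = LinearConstraint(A, lower, upper) if A.shape[0] else ()
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="Unrecognized options")
                res = milp(
                    c=sign * c,
                    constraints=cons,
                    integrality=integrality,
                    bounds=Bounds(lb, ub),
                    options=options,
                )
            status = {
                0: SolveStatus.OPTIMAL,
                1: SolveStatus.TIME_LIMIT,
                2: SolveStatus.INFEASIBLE,
                3: SolveStatus.UNBOUNDED,
            }.get(res.status, SolveStatus.ERROR)
            # a time-limited run that still produced an incumbent is usable
            if status is SolveStatus.TIME_LIMIT and res.x is not None:
                pass
        else:
            # split the interval constraints back into <= / >= / == blocks
            a_ub_rows, b_ub, a_eq_rows, b_eq = [], [], [], []
            for r in range(A.shape[0]):
                row = A.getrow(r)
                if lower[r] == upper[r]:
                    a_eq_rows.append(row)
                    b_eq.append(lower[r])
                else:
                    if np.isfinite(upper[r]):
                        a_ub_rows.append(row)
                        b_ub.append(upper[r])
                    if np.isfinite(lower[r]):
                        a_ub_rows.append(-row)
                        b_ub.append(-lower[r])
            kwargs = {}
            if a_ub_rows:
                kwargs["A_ub"] = sp.vstack(a_ub_rows)
                kwargs["b_ub"] = np.array(b_ub)
            if a_eq_rows:
                kwargs["A_eq"] = sp.vstack(a_eq_rows)
                kwargs["b_eq"] = np.array(b_eq)
            res = linprog(
                sign * c,
                bounds=np.column_stack([lb, ub]),
                method="highs",
                options={"time_limit": time_limit} if time_limit else None,
                **kwargs,
            )
            status = {
                0: SolveStatus.OPTIMAL,
                1: SolveStatus.TIME_LIMIT,
                2: SolveStatus.INFEASIBLE,
                3: SolveStatus.UNBOUNDED,
            }.get(res.status, SolveStatus.ERROR)
        if res.x is None:
            return SolveResult(status, None, {})
        values = {name: float(res.x[i]) for i, name in enumerate(self._var_names)}
        objective = float(sign * res.fun) if res.fun is not None else None
        return SolveResult(status, objective, values)


def dual_of(lp: LinearProgram) -> LinearProgram:
    """Construct the LP dual of a continuous program in standard form.

    Requires a minimization with every variable bounded as ``x >= 0`` with no
    finite upper bound (fold caps into explicit constraints first).  For
    ``min c'x  s.t.  a_r'x {<=,>=,==} b_r, x >= 0`` the dual is
    ``max b'y  s.t.  A'y <= c`` with ``y_r <= 0`` on <=-rows, ``y_r >= 0`` on
    >=-rows and free on equalities.
    """
    if lp.sense != "min":
        raise ValueError("dual_of expects a minimization")
    if any(lp._integer):
        raise ValueError("dual_of expects a continuous LP")
    for i, name in enumerate(lp._var_names):
        if lp._lb[i] != 0.0 or np.isfinite(lp._ub[i]):
            raise ValueError(f"variable {name!r} not in standard form (x >= 0)")
    dual = LinearProgram(name=f"dual({lp.name})", sense="max")
    for r, con in enumerate(lp._constraints):
        yname = f"y[{con.name}]"
        if con.sense == "<=":
            dual.add_var(yname, lb=-INF, ub=0.0, obj=con.rhs)
        elif con.sense == ">=":
            dual.add_var(yname, lb=0.0, ub=INF, obj=con.rhs)
        else:
            dual.add_var(yname, lb=-INF, ub=INF, obj=con.rhs)
    # one dual constraint per primal variable: sum_r a_{r,i} y_r <= c_i
    cols: dict[int, dict[str, float]] = {i: {} for i in range(len(lp._var_names))}
    for r, con in enumerate(lp._constraints):
        for i, coef in con.coeffs.items():
            cols[i][f"y[{con.name}]"] = coef
    for i, name in enumerate(lp._var_names):
        dual.add_constr(cols[i], "<=", lp._obj.get(i, 0.0), tag="dual", name=f"d[{name}]")
    return dual
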