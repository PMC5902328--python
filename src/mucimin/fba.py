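"""Flux balance analysis over a :class:`~mucimin.model.MetabolicModel`.

The steady-state assumption S·v = 0 (production of every intracellular
metabolite equals consumption) plus per-reaction bounds define a polytope
of feasible flux vectors; FBA maximises (or minimises) the flux of an
objective reaction over that polytope by linear programming, and FVA
reports the attainable [min, max] flux of every reaction while the
objective is held at (a fraction of) its optimum.

Only the objective value and the FVA ranges are contracts: the flux
vector returned for a degenerate optimum is one optimal vertex chosen by
the solver, not a canonical one. All quantities are in the model's
arbitrary units (a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

#: infinity-norm tolerance on S·v for a solution reported as optimal
STEADY_STATE_TOL = 1e-6
#: slack subtracted from the fixed objective in FVA to avoid spurious
#: infeasibility at the vertex
FVA_SLACK = 1e-9

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


class InfeasibleError(RuntimeError):
    """Raised where downstream analysis requires an optimal base solution."""


@dataclass
class FBAResult:
    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float

    def __post_init__(self) -> None:
        if self.min_flux > self.max_flux + 1e-6:
            raise ValueError(
                f"{self.reaction_id}: min_flux {self.min_flux} > max_flux {self.max_flux}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_flux + self.max_flux)


def _lp(
    S: sparse.csc_matrix,
    c: np.ndarray,
    bounds: list[tuple[float, float]],
    A_ub: sparse.csr_matrix | None = None,
    b_ub: np.ndarray | None = None,
):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )


def _status_of(res) -> str:
    if res.status == 0:
        return STATUS_OPTIMAL
    if res.status == 2:
        return STATUS_INFEASIBLE
    if res.status == 3:
        return STATUS_UNBOUNDED
    raise SolverError(f"LP solver failed: {res.message}")


def optimize(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FBAResult:
    """Solve max/min of one reaction's flux at steady state.

    Returns an :class:`FBAResult` whose status is reported honestly;
    a numerically failed solve raises :class:`SolverError` rather than
    returning a silent zero.
    """
    objective_id = objective_id or model.objective_id
    if objective_id not in model.reactions_by_id:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    c = np.zeros(n)
    c[idx[objective_id]] = -1.0 if direction == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = _lp(S, c, bounds)
    status = _status_of(res)
    if status != STATUS_OPTIMAL:
        return FBAResult(status=status, objective_value=float("nan"))
    v = np.asarray(res.x)
    residual = np.abs(S @ v).max() if n else 0.0
    if residual > STEADY_STATE_TOL:
        raise SolverError(f"steady-state residual {residual:.3g} exceeds tolerance")
    fluxes = {r.id: float(v[j]) for r, j in zip(model.reactions, idx.values())}
    return FBAResult(
        status=STATUS_OPTIMAL,
        objective_value=float(v[idx[objective_id]]),
        fluxes=fluxes,
    )


def flux_variability(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction_of_optimum: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> list[FluxRange]:
    """Per-reaction [min, max] flux with the objective fixed near its optimum.

    The objective is constrained to ``fraction_of_optimum * optimum`` minus a
    tiny slack (two-sided inequality written as one >= constraint, since the
    objective can only be pushed down by the sub-problems when maximised).
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    objective_id = objective_id or model.objective_id
    base = optimize(model, objective_id, "max")
    if not base.optimal:
        raise InfeasibleError(
            f"FVA undefined: base problem is {base.status} for {objective_id!r}"
        )
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    # objective >= fraction * optimum - slack   <=>   -v_obj <= -(target)
    target = fraction_of_optimum * base.objective_value - FVA_SLACK
    row = np.zeros(n)
    row[idx[objective_id]] = -1.0
    A_ub = sparse.csr_matrix(row.reshape(1, -1))
    b_ub = np.array([-target])
    wanted = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    out = []
    for rid in wanted:
        if rid not in idx:
            raise KeyError(f"no reaction {rid!r} in model")
        c = np.zeros(n)
        c[idx[rid]] = 1.0
        lo = _lp(S, c, bounds, A_ub, b_ub)
        hi = _lp(S, -c, bounds, A_ub, b_ub)
        if _status_of(lo) != STATUS_OPTIMAL or _status_of(hi) != STATUS_OPTIMAL:
            raise SolverError(f"FVA sub-problem for {rid!r} did not solve")
        vmin, vmax = float(lo.x[idx[rid]]), float(hi.x[idx[rid]])
        if vmin > vmax:  # numerical jitter at a unique vertex
            vmin = vmax = 0.5 * (vmin + vmax)
        out.append(FluxRange(rid, vmin, vmax))
    return out


def knockout(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Copy of the model with one reaction's flux forced to zero."""
    if reaction_id not in model.reactions_by_id:
        raise KeyError(f"no reaction {reaction_id!r} in model")
    return model.with_reaction_bounds(reaction_id, 0.0, 0.0)


# -- serialisation ----------------------------------------------------------

def result_to_tsv(result: FBAResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# status\t{result.status}\n")
        fh.write(f"# objective_value\t{result.objective_value:.12g}\n")
        fh.write("reaction_id\tflux\n")
        for rid, v in result.fluxes.items():
            fh.write(f"{rid}\t{v:.12g}\n")


def ranges_to_tsv(ranges: Sequence[FluxRange], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tmin_flux\tmax_flux\n")
        for fr in ranges:
            fh.write(f"{fr.reaction_id}\t{fr.min_flux:.12g}\t{fr.max_flux:.12g}\n")
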