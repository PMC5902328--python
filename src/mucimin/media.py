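"""Medium recipes as exchange-reaction bounds, and growth across media.

A medium is a list of components, each tagged with a bound category:

* ``secretion_only`` - present in the simulation only as a product
  (uptake stays closed, secretion open);
* ``non_limiting`` - abundant mineral/base components, uptake opened to
  the conventional -1000 a.u.;
* ``limited_uptake`` - components with a declared maximal uptake (the
  L-threonine supplementation convention, bound 1 a.u.);
* ``sugar`` - carbon sources sharing a total sugar budget equally
  (equimolar convention for mixtures), default budget 10 a.u., the top
  of the conventional 0-10 uptake scan range.

Applying a medium first closes every exchange uptake, then opens the
listed components; secretion stays allowed (upper bound 1000 a.u.) on
every exchange, so fermentation products can always leave. A component
with no matching exchange reaction is a structured "no transport route"
outcome - biologically, a compound the organism has no annotated way to
import (the GlcN case).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fba import FluxRange, InfeasibleError, flux_variability, optimize
from .model import DEFAULT_BOUND, MetabolicModel, Reaction

CATEGORIES = ("secretion_only", "non_limiting", "limited_uptake", "sugar")

#: objective value above which a prediction counts as growth (a.u.);
#: far below any reported growing optimum (~0.1 a.u.)
GROWTH_THRESHOLD = 1e-6

DEFAULT_SUGAR_BUDGET = 10.0
NON_LIMITING_BOUND = DEFAULT_BOUND


class MediumError(ValueError):
    pass


class MissingExchangeError(MediumError):
    """A medium component has no exchange reaction in the model."""

    def __init__(self, metabolite_ids: Sequence[str]):
        self.metabolite_ids = tuple(metabolite_ids)
        super().__init__(
            "no exchange reaction for medium component(s): "
            + ", ".join(self.metabolite_ids)
        )


@dataclass(frozen=True)
class MediumComponent:
    metabolite_id: str
    category: str
    uptake_bound: float | None = None  # a.u., for limited_uptake

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise MediumError(f"unknown component category {self.category!r}")
        if self.category == "limited_uptake":
            if self.uptake_bound is None or self.uptake_bound < 0:
                raise MediumError(
                    f"{self.metabolite_id}: limited_uptake needs a bound >= 0"
                )
        if self.uptake_bound is not None and self.uptake_bound < 0:
            raise MediumError(f"{self.metabolite_id}: uptake_bound must be >= 0")


@dataclass(frozen=True)
class MediumSpec:
    name: str
    components: tuple[MediumComponent, ...]
    sugar_budget: float = DEFAULT_SUGAR_BUDGET

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.sugar_budget < 0:
            raise MediumError("sugar_budget must be >= 0")

    @property
    def sugar_ids(self) -> tuple[str, ...]:
        return tuple(c.metabolite_id for c in self.components if c.category == "sugar")

    def without(self, metabolite_id: str) -> "MediumSpec":
        kept = tuple(c for c in self.components if c.metabolite_id != metabolite_id)
        if len(kept) == len(self.components):
            raise MediumError(f"{metabolite_id!r} is not a component of {self.name!r}")
        return replace(self, name=f"{self.name}-{metabolite_id}", components=kept)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "sugar_budget": self.sugar_budget,
                    "components": [
                        {"metabolite": c.metabolite_id, "category": c.category,
                         "bound": c.uptake_bound}
                        for c in self.components
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "MediumSpec":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            name=raw["name"],
            components=tuple(
                MediumComponent(c["metabolite"], c["category"], c.get("bound"))
                for c in raw["components"]
            ),
            sugar_budget=float(raw.get("sugar_budget", DEFAULT_SUGAR_BUDGET)),
        )


@dataclass(frozen=True)
class GrowthPrediction:
    medium: str
    grows: bool
    mu_au: float  # FBA optimum, a.u.
    missing_exchanges: tuple[str, ...] = ()  # components with no import route

    @property
    def no_route(self) -> bool:
        return bool(self.missing_exchanges)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Copy of the model with exchange bounds implementing the medium.

    All uptake is closed first; listed components are then opened per
    their category. Secretion (upper bound 1000) remains allowed on every
    exchange.
    """
    missing = [
        c.metabolite_id for c in medium.components
        if model.exchange_for(c.metabolite_id) is None
    ]
    if missing:
        raise MissingExchangeError(missing)

    sugars = medium.sugar_ids
    share = medium.sugar_budget / len(sugars) if sugars else 0.0

    new = model.copy()
    exchange_ids = set(new.exchange_ids())
    lb_for: dict[str, float] = {}
    for c in medium.components:
        rid = model.exchange_for(c.metabolite_id)
        if c.category == "non_limiting":
            lb_for[rid] = -NON_LIMITING_BOUND
        elif c.category == "limited_uptake":
            lb_for[rid] = -float(c.uptake_bound)
        elif c.category == "sugar":
            lb_for[rid] = -share
        else:  # secretion_only
            lb_for[rid] = 0.0
    for i, r in enumerate(new.reactions):
        if r.id in exchange_ids:
            new.reactions[i] = replace(
                r, lower_bound=lb_for.get(r.id, 0.0), upper_bound=DEFAULT_BOUND
            )
    return new


def predict_growth(
    model: MetabolicModel,
    medium: MediumSpec,
    objective_id: str | None = None,
    threshold: float = GROWTH_THRESHOLD,
    on_missing: str = "raise",
) -> GrowthPrediction:
    """FBA growth optimum on a medium, thresholded into a yes/no call.

    ``on_missing='flag'`` turns components with no import route into a
    structured outcome instead of an exception: the unusable components
    are dropped (flagged in ``missing_exchanges``) and the rest of the
    medium is simulated, the way a compound the organism cannot import
    simply goes unused in a culture. A medium whose only carbon source
    is unusable therefore comes out as no growth.
    """
    missing: tuple[str, ...] = ()
    try:
        constrained = apply_medium(model, medium)
    except MissingExchangeError as exc:
        if on_missing != "flag":
            raise
        missing = exc.metabolite_ids
        usable = tuple(
            c for c in medium.components if c.metabolite_id not in missing
        )
        # unusable sugars still occupy their equimolar share of the budget
        n_sugar = len(medium.sugar_ids)
        n_usable = sum(1 for c in usable if c.category == "sugar")
        budget = (
            medium.sugar_budget * n_usable / n_sugar if n_sugar else
            medium.sugar_budget
        )
        reduced = replace(medium, components=usable, sugar_budget=budget)
        constrained = apply_medium(model, reduced)
    res = optimize(constrained, objective_id or model.objective_id, "max")
    mu = (res.objective_value + 0.0) if res.optimal else 0.0  # +0.0 folds -0.0
    return GrowthPrediction(
        medium=medium.name, grows=mu > threshold, mu_au=mu,
        missing_exchanges=missing,
    )


def growth_table(
    models: Sequence[MetabolicModel],
    media: Sequence[MediumSpec],
    threshold: float = GROWTH_THRESHOLD,
) -> pd.DataFrame:
    """Growth predictions for every (model version, medium) pair.

    One row per medium; per version a y/n column, an a.u. column and a
    no-route marker column (components the version cannot import).
    """
    rows = []
    for medium in media:
        row: dict[str, object] = {"medium": medium.name}
        for model in models:
            tag = model.version_tag or "model"
            pred = predict_growth(model, medium, threshold=threshold,
                                  on_missing="flag")
            row[f"{tag} (y/n)"] = "y" if pred.grows else "n"
            row[f"{tag} (au)"] = pred.mu_au
            row[f"{tag} no_route"] = ";".join(pred.missing_exchanges)
        rows.append(row)
    columns = ["medium"]
    for model in models:
        tag = model.version_tag or "model"
        columns += [f"{tag} (y/n)", f"{tag} (au)", f"{tag} no_route"]
    return pd.DataFrame(rows, columns=columns)


def essentiality_scan(
    model: MetabolicModel,
    medium: MediumSpec,
    objective_id: str | None = None,
    threshold: float = GROWTH_THRESHOLD,
) -> dict[str, dict]:
    """Leave-one-out essentiality of every medium component.

    A component is essential when omitting it (only it) drops the growth
    optimum below the threshold. Undefined when the base medium itself
    does not support growth.
    """
    base = predict_growth(model, medium, objective_id, threshold)
    if not base.grows:
        raise InfeasibleError(
            f"essentiality scan undefined: no growth on base medium {medium.name!r}"
        )
    out = {}
    for comp in medium.components:
        reduced = medium.without(comp.metabolite_id)
        pred = predict_growth(model, reduced, objective_id, threshold,
                              on_missing="flag")
        out[comp.metabolite_id] = {
            "essential": not pred.grows,
            "mu_without": pred.mu_au,
            "mu_base": base.mu_au,
        }
    return out


def uptake_scan(
    model: MetabolicModel,
    medium: MediumSpec,
    sugar_id: str,
    grid: Sequence[float],
    objective_id: str | None = None,
) -> list[tuple[float, float]]:
    """Growth optimum as a function of one sugar's uptake bound.

    The medium is applied as usual, then the chosen sugar's uptake bound
    is swept over the grid (replacing its budget share).
    """
    grid = [float(g) for g in grid]
    if any(g < 0 for g in grid):
        raise MediumError("uptake bounds must be >= 0")
    if sugar_id not in medium.sugar_ids:
        raise MediumError(f"{sugar_id!r} is not a sugar component of {medium.name!r}")
    constrained = apply_medium(model, medium)
    rid = model.exchange_for(sugar_id)
    out = []
    for bound in grid:
        m = constrained.with_reaction_bounds(rid, -bound, DEFAULT_BOUND)
        res = optimize(m, objective_id or model.objective_id, "max")
        out.append((bound, (res.objective_value + 0.0) if res.optimal else 0.0))
    return out


def compare_flux_distributions(
    model: MetabolicModel,
    media: Sequence[MediumSpec],
    objective_id: str | None = None,
    rel_tol: float = 0.1,
    abs_tol: float = 1e-6,
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction flux comparison across media at maximal growth.

    For each medium the FVA range at fraction 1.0 of the optimum is
    computed and summarised by its midpoint. Per reaction, each medium's
    midpoint is classified against the across-media mean midpoint:
    ``higher``/``lower`` when it deviates by more than ``rel_tol`` of the
    largest midpoint magnitude (and more than ``abs_tol``), ``similar``
    otherwise - so reactions with zero flux everywhere are similar.
    """
    if not media:
        raise MediumError("need at least one medium")
    per_medium: dict[str, dict[str, FluxRange]] = {}
    for medium in media:
        constrained = apply_medium(model, medium)
        ranges = flux_variability(
            constrained, objective_id or model.objective_id,
            fraction_of_optimum=1.0, reactions=reactions,
        )
        per_medium[medium.name] = {fr.reaction_id: fr for fr in ranges}
    rids = (list(reactions) if reactions is not None
            else [r.id for r in model.reactions])
    rows = []
    for rid in rids:
        mids = {name: per_medium[name][rid].midpoint for name in per_medium}
        mean_mid = float(np.mean(list(mids.values())))
        scale = max(abs(v) for v in mids.values())
        tol = max(rel_tol * scale, abs_tol)
        row: dict[str, object] = {"reaction_id": rid}
        for name, fr in ((n, per_medium[n][rid]) for n in per_medium):
            mid = fr.midpoint
            if mid - mean_mid > tol:
                cls = "higher"
            elif mean_mid - mid > tol:
                cls = "lower"
            else:
                cls = "similar"
            row[f"{name} min"] = fr.min_flux
            row[f"{name} max"] = fr.max_flux
            row[f"{name} mid"] = mid
            row[f"{name} class"] = cls
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_markdown(df: pd.DataFrame, float_fmt: str = "%.3f") -> str:
    """Render a growth/flux table as a GitHub-style markdown table."""
    def fmt(v):
        if isinstance(v, float):
            return float_fmt % v
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
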