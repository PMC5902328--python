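"""Synthetic fixtures: toy metabolic networks and simulated experiments.

Every generator here is a pure function of its parameters and a seed, so
the whole analysis is reproducible without any external download.

The centrepiece is ``amino_sugar_core``, a ~30-reaction abstraction of
the A. muciniphila amino-sugar node: sugars enter as glucose, fructose,
GlcNAc, GalNAc (and optionally GlcN), are funnelled to fructose-6-
phosphate, and are fermented to acetate and propionate under a redox
coupling, while biomass formation drains UDP-GlcNAc, L-threonine and
ATP. The network reproduces the organism's defining phenotype: without
the GlmS amination (Fru6P + glutamine -> GlcN6P + glutamate) there is no
route from plain hexoses to the amino-sugar pool, so glucose alone
cannot support growth, whereas GlcNAc feeds the pool directly through
its phosphorylation "shortcut" and GalNAc through the reversible
UDP-GlcNAc 4-epimerase. GlcN can only be used when a hypothetical
transporter is switched on - by default the metabolite has no exchange
at all, mirroring the missing annotation.

Stoichiometric coefficients are fixture constants (the biology fixes the
topology, not the numbers); they are chosen so that a sugar mixture
yields a higher growth optimum than GlcNAc alone and GlcNAc and GalNAc
yield similar optima, and they are all overridable through
``ToyModelSpec.yields``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .growth import GrowthCurve, MetaboliteTimeSeries
from .kinetics import AssaySeries
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction


@dataclass(frozen=True)
class SimConfig:
    """Seeded configuration shared by the stochastic generators."""

    seed: int = 0
    noise_cv: float = 0.0  # coefficient of variation of the noise
    n_replicates: int = 3
    grid: tuple[float, ...] | None = None  # sampling grid (h), generator default if None


@dataclass(frozen=True)
class ToyModelSpec:
    kind: str = "amino_sugar_core"  # chain | parallel | bottleneck | amino_sugar_core
    with_glms: bool = False
    with_glcn_transporter: bool = False
    yields: Mapping[str, float] = field(default_factory=dict)


#: default fixture coefficients of the amino-sugar core
CORE_YIELDS = {
    "glycolysis_atp": 2.0,  # ATP per Fru6P through lumped glycolysis
    "glycolysis_nadh": 1.0,  # redox produced per Fru6P (re-oxidised by the propionate branch)
    "ack_atp": 1.0,  # ATP per acetyl-CoA converted to acetate
    "prop_atp": 1.0,  # ATP per Fru6P through the propionate branch
    "hexose_kinase_atp": 1.0,  # ATP cost of activating glucose/fructose
    "amino_kinase_atp": 1.5,  # ATP cost of activating GlcNAc/GalNAc (uptake + phosphorylation)
    "glcn_kinase_atp": 1.0,  # ATP cost of the hypothetical GlcN kinase
    "uap_atp": 1.0,  # ATP cost of UDP-GlcNAc synthesis
    "biomass_udp_glcnac": 0.05,  # UDP-GlcNAc per unit biomass flux
    "biomass_thr": 0.05,  # L-threonine per unit biomass flux
    "biomass_atp": 1.0,  # ATP per unit biomass flux
}

BIOMASS_ID = "BIOMASS"
GLMS_ID = "R_GLMS"
EPIMERASE_ID = "R_EPIM"
NAGB_ID = "R_NAGB"
DEACETYLASE_ID = "R_DEAC"


def make_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    if spec.kind == "chain":
        return _chain()
    if spec.kind == "parallel":
        return _parallel()
    if spec.kind == "bottleneck":
        return _bottleneck()
    if spec.kind == "amino_sugar_core":
        return _amino_sugar_core(spec)
    raise ValueError(f"unknown toy model kind {spec.kind!r}")


def _chain() -> MetabolicModel:
    """Single path uptake -> transport -> biomass; optimum = uptake bound."""
    mets = [
        Metabolite("a_e", compartment="extracellular"),
        Metabolite("a_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, lower_bound=-10.0, upper_bound=DEFAULT_BOUND),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}),
        Reaction(BIOMASS_ID, {"a_c": -1.0}),
    ]
    return MetabolicModel(mets, rxns, objective_id=BIOMASS_ID, version_tag="toy_chain")


def _parallel() -> MetabolicModel:
    """Two redundant transport routes of capacity 10 each behind one uptake."""
    mets = [
        Metabolite("a_e", compartment="extracellular"),
        Metabolite("a_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, lower_bound=-10.0, upper_bound=DEFAULT_BOUND),
        Reaction("T_route1", {"a_e": -1.0, "a_c": 1.0}, upper_bound=10.0),
        Reaction("T_route2", {"a_e": -1.0, "a_c": 1.0}, upper_bound=10.0),
        Reaction(BIOMASS_ID, {"a_c": -1.0}),
    ]
    return MetabolicModel(mets, rxns, objective_id=BIOMASS_ID, version_tag="toy_parallel")


def _bottleneck() -> MetabolicModel:
    """Chain with an internal conversion capped at 7: optimum saturates there."""
    mets = [
        Metabolite("a_e", compartment="extracellular"),
        Metabolite("a_c", compartment="cytosol"),
        Metabolite("b_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, lower_bound=-10.0, upper_bound=DEFAULT_BOUND),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}),
        Reaction("R_conv", {"a_c": -1.0, "b_c": 1.0}, upper_bound=7.0),
        Reaction(BIOMASS_ID, {"b_c": -1.0}),
    ]
    return MetabolicModel(
        mets, rxns, objective_id=BIOMASS_ID, version_tag="toy_bottleneck"
    )


def _amino_sugar_core(spec: ToyModelSpec) -> MetabolicModel:
    y = dict(CORE_YIELDS)
    y.update(spec.yields)

    ext = ["glc", "fru", "glcnac", "galnac", "thr", "gln", "ac", "prop", "nh4",
           "glu", "h2o"]
    cyt = ["glc", "fru", "glcnac", "galnac", "thr", "gln", "glu", "fru6p",
           "glcn6p", "glcnac6p", "udp_glcnac", "udp_galnac", "accoa", "atp",
           "nadh", "ac", "prop", "nh4"]
    if spec.with_glcn_transporter:
        ext.append("glcn")
        cyt.append("glcn")

    mets = [Metabolite(f"{m}_e", compartment="extracellular") for m in ext]
    mets += [Metabolite(f"{m}_c", compartment="cytosol") for m in cyt]

    rxns: list[Reaction] = []

    def ex(met: str) -> None:
        rxns.append(
            Reaction(f"EX_{met}", {f"{met}_e": -1.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, name=f"{met} exchange")
        )

    def rxn(rid, stoich, lb=0.0, ub=DEFAULT_BOUND, name="", ann=()):
        rxns.append(Reaction(rid, stoich, name=name, lower_bound=lb,
                             upper_bound=ub, annotation=ann))

    for m in ext:
        ex(m)

    # transport (uptake direction for substrates, secretion for products)
    for m in ("glc", "fru", "glcnac", "galnac", "thr", "gln"):
        rxn(f"T_{m}", {f"{m}_e": -1.0, f"{m}_c": 1.0})
    for m in ("ac", "prop", "nh4", "glu"):
        rxn(f"T_{m}", {f"{m}_c": -1.0, f"{m}_e": 1.0})
    if spec.with_glcn_transporter:
        rxn("T_glcn", {"glcn_e": -1.0, "glcn_c": 1.0},
            name="hypothetical GlcN transporter")

    hk = y["hexose_kinase_atp"]
    ak = y["amino_kinase_atp"]
    rxn("R_HEX", {"glc_c": -1.0, "atp_c": -hk, "fru6p_c": 1.0},
        name="hexokinase + isomerase (lumped)")
    rxn("R_FRK", {"fru_c": -1.0, "atp_c": -hk, "fru6p_c": 1.0},
        name="fructokinase (lumped)")
    rxn("R_NAGK", {"glcnac_c": -1.0, "atp_c": -ak, "glcnac6p_c": 1.0},
        name="GlcNAc kinase (Akkermansia GlcNAc shortcut)")
    rxn("R_GALNK", {"galnac_c": -1.0, "atp_c": -ak, "udp_galnac_c": 1.0},
        name="GalNAc kinase + uridylyltransferase (lumped)")
    if spec.with_glcn_transporter:
        rxn("R_GLCNK", {"glcn_c": -1.0, "atp_c": -y["glcn_kinase_atp"],
                        "glcn6p_c": 1.0}, name="GlcN kinase")

    # amino-sugar node
    rxn(NAGB_ID, {"glcn6p_c": -1.0, "fru6p_c": 1.0, "nh4_c": 1.0},
        name="GlcN6P deaminase (NagB), deaminating only", ann=("EC 3.5.99.6",))
    rxn(DEACETYLASE_ID, {"glcnac6p_c": -1.0, "glcn6p_c": 1.0, "ac_c": 1.0},
        name="GlcNAc6P deacetylase", ann=("EC 3.5.1.25",))
    rxn("R_ACTRF", {"glcn6p_c": -1.0, "accoa_c": -1.0, "glcnac6p_c": 1.0},
        name="GlcN6P N-acetyltransferase")
    rxn("R_UAP", {"glcnac6p_c": -1.0, "atp_c": -y["uap_atp"], "udp_glcnac_c": 1.0},
        name="UDP-GlcNAc synthesis (lumped)")
    rxn("R_UAP_R", {"udp_glcnac_c": -1.0, "glcnac6p_c": 1.0},
        name="UDP-GlcNAc catabolic return (lumped)")
    rxn(EPIMERASE_ID, {"udp_glcnac_c": -1.0, "udp_galnac_c": 1.0},
        lb=-DEFAULT_BOUND, name="UDP-GlcNAc 4-epimerase (reversible)",
        ann=("EC 5.1.3.7",))
    if spec.with_glms:
        rxn(GLMS_ID, {"fru6p_c": -1.0, "gln_c": -1.0, "glcn6p_c": 1.0,
                      "glu_c": 1.0},
            name="GlcN6P synthase (GlmS)", ann=("EC 2.6.1.16",))

    # fermentation with a redox coupling between the two acid branches
    rxn("R_GLYC", {"fru6p_c": -1.0, "accoa_c": 1.0,
                   "atp_c": y["glycolysis_atp"], "nadh_c": y["glycolysis_nadh"]},
        name="glycolysis + pyruvate oxidation (lumped)")
    rxn("R_ACK", {"accoa_c": -1.0, "ac_c": 1.0, "atp_c": y["ack_atp"]},
        name="acetate kinase")
    rxn("R_PROPF", {"fru6p_c": -1.0, "nadh_c": -y["glycolysis_nadh"],
                    "prop_c": 1.0, "atp_c": y["prop_atp"]},
        name="propionate branch (succinate route, lumped)")
    rxn("R_ATPM", {"atp_c": -1.0}, name="ATP maintenance sink")
    rxn(BIOMASS_ID,
        {"udp_glcnac_c": -y["biomass_udp_glcnac"], "thr_c": -y["biomass_thr"],
         "atp_c": -y["biomass_atp"]},
        name="biomass (UDP-GlcNAc + L-threonine + ATP)")

    tag = "core_v1" if spec.with_glms else "core_v2"
    if spec.with_glcn_transporter:
        tag += "+glcnT"
    return MetabolicModel(mets, rxns, objective_id=BIOMASS_ID, version_tag=tag)


def make_random_network(seed: int) -> MetabolicModel:
    """Small random network with finite bounds, for solver cross-checks.

    All bounds are finite so the LP is never unbounded; with probability
    ~0.3 one reaction is forced to carry flux, which may make the problem
    infeasible - both outcomes must be reproduced by any correct solver.
    """
    rng = np.random.default_rng(seed)
    n_met = int(rng.integers(2, 7))
    n_rxn = int(rng.integers(4, 13))
    mets = [Metabolite(f"m{i}_c", compartment="cytosol") for i in range(n_met)]
    rxns = []
    for j in range(n_rxn):
        k = int(rng.integers(1, min(3, n_met) + 1))
        chosen = rng.choice(n_met, size=k, replace=False)
        stoich = {}
        for m in chosen:
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            stoich[f"m{m}_c"] = coef
        cap = float(rng.uniform(1.0, 10.0))
        lb = -cap if rng.random() < 0.5 else 0.0
        rxns.append(Reaction(f"r{j}", stoich, lower_bound=lb, upper_bound=cap))
    if rng.random() < 0.3:
        j = int(rng.integers(0, n_rxn))
        rxns[j] = Reaction(
            rxns[j].id, rxns[j].stoichiometry, lower_bound=0.5,
            upper_bound=max(rxns[j].upper_bound, 0.5),
        )
    objective = rxns[-1].id
    return MetabolicModel(mets, rxns, objective_id=objective,
                          version_tag=f"random_{seed}")


# ---------------------------------------------------------------------------
# experiment simulators
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))


def simulate_growth_curve(
    mu: float,
    od0: float = 0.02,
    cap_od: float = 0.5,
    config: SimConfig = SimConfig(),
    condition: str = "",
) -> list[GrowthCurve]:
    """Replicate OD600 curves: logistic-capped exponential + multiplicative noise.

    OD(t) = cap*od0*e^(mu t) / (cap - od0 + od0*e^(mu t)); mu = 0 gives a
    flat curve at od0 carrying noise only.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not 0 < od0 < cap_od:
        raise ValueError("need 0 < od0 < cap_od")
    t = np.asarray(config.grid if config.grid is not None
                   else np.arange(0.0, 60.0 + 1e-9, 2.0), dtype=float)
    rng = np.random.default_rng(config.seed)
    growth = np.exp(mu * t)
    clean = cap_od * od0 * growth / (cap_od - od0 + od0 * growth)
    out = []
    for rep in range(config.n_replicates):
        noisy = clean * _lognormal_factors(rng, config.noise_cv, clean.shape)
        out.append(GrowthCurve(times=t, od600=noisy, replicate_id=rep,
                               condition=condition))
    return out


def simulate_fermentation(
    sugars: Mapping[str, float],
    acid_yields: Mapping[str, tuple[float, float]],
    consumption_rates: Mapping[str, float],
    config: SimConfig = SimConfig(),
    condition: str = "",
) -> MetaboliteTimeSeries:
    """Fermentation time series with fixed acetate/propionate yield stoichiometry.

    Each sugar decays linearly at its consumption rate until exhausted;
    the acids accumulate as yield x sugar consumed. Noise is additive
    Gaussian with SD = noise_cv x the largest initial sugar concentration,
    floored at zero (HPLC-style measurement error).
    """
    for name, c0 in sugars.items():
        if c0 < 0:
            raise ValueError(f"initial concentration of {name!r} must be >= 0")
        if consumption_rates.get(name, 0.0) < 0:
            raise ValueError(f"consumption rate of {name!r} must be >= 0")
    t = np.asarray(config.grid if config.grid is not None
                   else np.arange(0.0, 48.0 + 1e-9, 4.0), dtype=float)
    rng = np.random.default_rng(config.seed)
    conc: dict[str, np.ndarray] = {}
    acetate = np.zeros_like(t)
    propionate = np.zeros_like(t)
    for name, c0 in sugars.items():
        rate = consumption_rates.get(name, 0.0)
        remaining = np.maximum(c0 - rate * t, 0.0)
        consumed = c0 - remaining
        y_ac, y_prop = acid_yields.get(name, (0.0, 0.0))
        if y_ac < 0 or y_prop < 0:
            raise ValueError(f"yields of {name!r} must be >= 0")
        acetate = acetate + y_ac * consumed
        propionate = propionate + y_prop * consumed
        conc[name] = remaining
    conc["acetate"] = acetate
    conc["propionate"] = propionate
    if config.noise_cv > 0:
        sd = config.noise_cv * (max(sugars.values()) if sugars else 1.0)
        conc = {
            k: np.maximum(v + rng.normal(0.0, sd, size=v.shape), 0.0)
            for k, v in conc.items()
        }
    return MetaboliteTimeSeries(times=t, concentrations=conc, condition=condition)


def simulate_assay(
    Km: float,
    Vmax: float,
    concentrations: Sequence[float] | None = None,
    config: SimConfig = SimConfig(),
    substrate_id: str = "S",
    activator_conc: float = 0.0,
) -> list[AssaySeries]:
    """Replicate Michaelis-Menten initial-rate series with multiplicative noise.

    Default concentrations: 8 points log-spaced over 0.1x-10x Km. Noise is
    mean-one log-normal with CV ``config.noise_cv`` (positivity-preserving,
    so the reciprocal transform stays defined).
    """
    if Km <= 0 or Vmax <= 0:
        raise ValueError("Km and Vmax must be > 0")
    conc = np.asarray(
        concentrations if concentrations is not None
        else np.geomspace(0.1 * Km, 10.0 * Km, 8),
        dtype=float,
    )
    rng = np.random.default_rng(config.seed)
    clean = Vmax * conc / (Km + conc)
    out = []
    for rep in range(config.n_replicates):
        rates = clean * _lognormal_factors(rng, config.noise_cv, clean.shape)
        out.append(
            AssaySeries(substrate_id=substrate_id, concentrations=conc,
                        rates=rates, replicate_id=rep,
                        activator_conc=activator_conc)
        )
    return out
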