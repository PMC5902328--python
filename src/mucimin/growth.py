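"""Growth-curve and fermentation time-series analysis.

Specific growth rates mu (1/h) are estimated as the slope of ln(OD600)
against time over an automatically selected exponential window. Window
candidates are confined to the early phase of the curve - points whose
OD is within ``window_fold`` (default 3x) of the starting OD - because
on a saturating culture every later segment of
ln(OD) is already bent towards stationary phase and systematically
understates mu. Within that segment the estimator takes the longest run
of >= 4 consecutive points whose log-linear fit reaches R^2 >= 0.98,
rises by at least one doubling (which screens out chance alignments of
flat noise), and has positive slope. When no window qualifies - slow but
genuine growth that never doubles, buried in measurement noise - a
fallback fit over the whole retained curve is accepted if its slope is
positive and statistically significant (one-sided p < 1e-3); otherwise
the replicate is flagged no-growth with mu = 0, matching how flat curves
are tabulated as 0.000. A condition is called no-growth when fewer than
half of its replicates show growth.

Short-chain fatty-acid (SCFA) production and sugar consumption are read
endpoint-to-endpoint from concentration time series, the same way molar
product ratios like 1.5:1-2:1 are quoted from fermentation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class GrowthDataError(ValueError):
    pass


@dataclass
class GrowthCurve:
    times: np.ndarray  # h, strictly increasing
    od600: np.ndarray  # dimensionless, >= 0
    replicate_id: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise GrowthDataError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise GrowthDataError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise GrowthDataError("od600 must be non-negative")


@dataclass(frozen=True)
class GrowthRateConfig:
    """Tunable parameters of the exponential-window estimator."""

    detection_floor: float = 0.01  # OD units below which points are noise
    blank: float = 0.0  # subtracted before the log transform
    min_points: int = 4
    r_squared_min: float = 0.98
    window_fold: float = 3.0  # window confined to OD <= fold x starting OD
    min_rise: float = math.log(2.0)  # ln-OD rise a window must span
    saturation_ratio: float = 2.0  # OD max/start ratio implying a stationary phase
    slow_growth_p: float = 1e-3  # one-sided slope test for the fallback


@dataclass
class RateEstimate:
    mu: float  # 1/h, pooled mean across replicates
    window: tuple[float, float]  # (t_start, t_end) h, union over replicates
    r_squared: float  # mean over replicates with a fitted window
    sd: float  # across-replicate SD of mu
    n_replicates: int = 1
    no_growth: bool = False
    slow_growth: bool = False  # fallback path was used for >=1 replicate
    replicate_mu: tuple[float, ...] = ()


@dataclass
class MetaboliteTimeSeries:
    times: np.ndarray  # h
    concentrations: dict[str, np.ndarray]  # analyte -> mM
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise GrowthDataError("times must be strictly increasing")
        conc = {}
        for k, v in self.concentrations.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.times.shape:
                raise GrowthDataError(f"analyte {k!r}: length mismatch")
            if np.any(v < 0):
                raise GrowthDataError(f"analyte {k!r}: negative concentration")
            conc[k] = v
        self.concentrations = conc


@dataclass(frozen=True)
class ScfaRatio:
    acetate_produced: float  # mM
    propionate_produced: float  # mM
    ratio: float | None  # acetate/propionate; None when undefined

    @property
    def defined(self) -> bool:
        return self.ratio is not None


# ---------------------------------------------------------------------------
# growth rate
# ---------------------------------------------------------------------------

def _fit_replicate(
    curve: GrowthCurve, cfg: GrowthRateConfig
) -> tuple[float, tuple[float, float] | None, float, bool, bool]:
    """Return (mu, window, r2, no_growth, slow_growth) for one curve."""
    od = curve.od600 - cfg.blank
    keep = od >= cfg.detection_floor
    t, od = curve.times[keep], od[keep]
    if len(t) < cfg.min_points:
        return 0.0, None, float("nan"), True, False
    if od.max() >= cfg.saturation_ratio * od[0]:
        # the curve saturates: drop everything past the peak (stationary/decline)
        peak = int(np.argmax(od))
        t, od = t[: peak + 1], od[: peak + 1]
    y = np.log(od)
    n = len(t)

    # exponential-phase candidates: the early, low-OD segment of the rise
    win_ok = od <= cfg.window_fold * od[0]
    idx = np.nonzero(win_ok)[0]
    best: tuple[int, float, float, int, int] | None = None  # (len, r2, slope, i, j)
    for pos, i in enumerate(idx):
        for j in idx[pos:]:
            if j - i + 1 < cfg.min_points or not np.all(win_ok[i : j + 1]):
                continue
            if y[j] - y[i] < cfg.min_rise:
                continue
            fit = stats.linregress(t[i : j + 1], y[i : j + 1])
            r2 = fit.rvalue**2
            if r2 < cfg.r_squared_min or fit.slope <= 0:
                continue
            cand = (j - i + 1, r2, fit.slope, i, j)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is not None:
        _, r2, slope, i, j = best
        return slope, (float(t[i]), float(t[j])), float(r2), False, False

    # fallback: shallow exponential growth that never doubles cannot clear
    # the window gates; accept the whole-curve slope when it is unambiguously
    # positive
    if n > 2:
        fit = stats.linregress(t, y)
        if fit.slope > 0 and fit.stderr > 0:
            p_one_sided = stats.t.sf(fit.slope / fit.stderr, df=n - 2)
            if p_one_sided < cfg.slow_growth_p:
                return (fit.slope, (float(t[0]), float(t[-1])),
                        float(fit.rvalue**2), False, True)
    return 0.0, None, float("nan"), True, False


def estimate_growth_rate(
    curves: Sequence[GrowthCurve], config: GrowthRateConfig | None = None
) -> RateEstimate:
    """Pooled specific growth rate over replicate OD600 curves.

    Each replicate is fitted independently; the pooled mu is the mean
    and ``sd`` the across-replicate standard deviation. A no-growth
    result (mu = 0, flag set) is returned when fewer than half of the
    replicates show a credible exponential phase - growth that is not
    reproducible across replicates is not called.
    """
    if not curves:
        raise GrowthDataError("no growth curves supplied")
    cfg = config or GrowthRateConfig()
    for c in curves:
        if len(c.times) < cfg.min_points:
            raise GrowthDataError(
                f"replicate {c.replicate_id}: need >= {cfg.min_points} points"
            )
    mus, windows, r2s = [], [], []
    n_growing = 0
    slow = False
    for c in curves:
        mu, window, r2, ng, sl = _fit_replicate(c, cfg)
        mus.append(mu)
        if not ng:
            n_growing += 1
            windows.append(window)
            r2s.append(r2)
        slow = slow or sl
    mus_arr = np.asarray(mus)
    sd = float(np.std(mus_arr, ddof=1)) if len(mus_arr) > 1 else 0.0
    if n_growing < 0.5 * len(curves):
        t0 = min(float(c.times[0]) for c in curves)
        t1 = max(float(c.times[-1]) for c in curves)
        return RateEstimate(
            mu=0.0, window=(t0, t1), r_squared=float("nan"), sd=sd,
            n_replicates=len(curves), no_growth=True, replicate_mu=tuple(mus),
        )
    window = (
        min(w[0] for w in windows),
        max(w[1] for w in windows),
    )
    return RateEstimate(
        mu=float(np.mean(mus_arr)),
        window=window,
        r_squared=float(np.mean(r2s)),
        sd=sd,
        n_replicates=len(curves),
        no_growth=False,
        slow_growth=slow,
        replicate_mu=tuple(mus),
    )


# ---------------------------------------------------------------------------
# SCFA and consumption
# ---------------------------------------------------------------------------

def scfa_ratio(ts: MetaboliteTimeSeries) -> ScfaRatio:
    """Acetate:propionate molar production ratio, endpoint-to-endpoint.

    Production of each acid is final minus initial concentration, floored
    at zero. When no propionate is produced the ratio is undefined
    (``ratio is None``) - the analogue of fermentations where no SCFA
    production is observed at all.
    """
    for analyte in ("acetate", "propionate"):
        if analyte not in ts.concentrations:
            raise GrowthDataError(f"series lacks analyte {analyte!r}")
    ac = ts.concentrations["acetate"]
    prop = ts.concentrations["propionate"]
    ac_prod = max(float(ac[-1] - ac[0]), 0.0)
    prop_prod = max(float(prop[-1] - prop[0]), 0.0)
    if prop_prod <= 1e-9:
        return ScfaRatio(ac_prod, prop_prod, None)
    return ScfaRatio(ac_prod, prop_prod, ac_prod / prop_prod)


@dataclass(frozen=True)
class ConsumptionRate:
    analyte: str
    rate: float  # mM/h, positive = consumed
    rate_se: float
    ci_low: float
    ci_high: float
    n_points: int


def consumption_rate(
    ts: MetaboliteTimeSeries, analyte: str, depletion_fraction: float = 0.05
) -> ConsumptionRate:
    """Linear consumption rate over the depletion phase of one analyte.

    The phase runs from t0 until the concentration first drops below
    ``depletion_fraction`` of its initial value (points beyond are in the
    exhausted regime and would flatten the slope).
    """
    if analyte not in ts.concentrations:
        raise GrowthDataError(f"series lacks analyte {analyte!r}")
    conc = ts.concentrations[analyte]
    if len(conc) < 3:
        raise GrowthDataError("need >=3 time points")
    c0 = conc[0]
    if c0 <= 0:
        keep = np.ones(len(conc), dtype=bool)
    else:
        below = np.nonzero(conc < depletion_fraction * c0)[0]
        cutoff = below[0] + 1 if len(below) else len(conc)
        keep = np.arange(len(conc)) < max(cutoff, 3)
    fit = stats.linregress(ts.times[keep], conc[keep])
    rate = -fit.slope
    se = fit.stderr
    # t-based 95% CI: depletion phases are short, so the normal quantile
    # would badly understate the uncertainty of the slope
    df = max(int(keep.sum()) - 2, 1)
    half = stats.t.ppf(0.975, df) * se
    return ConsumptionRate(
        analyte=analyte,
        rate=float(rate),
        rate_se=float(se),
        ci_low=float(rate - half),
        ci_high=float(rate + half),
        n_points=int(keep.sum()),
    )


def consumption_rates(
    ts: MetaboliteTimeSeries,
    analytes: Sequence[str],
    compare: tuple[str, str] | None = None,
) -> dict:
    """Consumption rates per analyte, optionally with an equality call.

    Two sugars are declared consumed at equal rates when their slope 95%
    confidence intervals overlap.
    """
    rates = {a: consumption_rate(ts, a) for a in analytes}
    out: dict = {"rates": rates}
    if compare is not None:
        a, b = (rates[c] for c in compare)
        equal = a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
        out["equal_rates"] = bool(equal)
        out["compared"] = compare
    return out


# ---------------------------------------------------------------------------
# CSV interchange (long format)
# ---------------------------------------------------------------------------

def read_growth_csv(path: str) -> dict[str, list[GrowthCurve]]:
    """Read curves from CSV columns condition, replicate, time_h, od600."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, list[GrowthCurve]] = {}
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.setdefault(str(cond), []).append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                replicate_id=int(rep),
                condition=str(cond),
            )
        )
    return out


def write_growth_csv(curves: Sequence[GrowthCurve], path: str) -> None:
    import pandas as pd

    rows = [
        {"condition": c.condition, "replicate": c.replicate_id,
         "time_h": t, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od600)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_hplc_csv(path: str) -> dict[str, MetaboliteTimeSeries]:
    """Read time series from CSV columns condition, time_h, analyte, conc_mM."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for cond, grp in df.groupby("condition", sort=True):
        wide = grp.pivot_table(index="time_h", columns="analyte",
                               values="conc_mM").sort_index()
        out[str(cond)] = MetaboliteTimeSeries(
            times=wide.index.to_numpy(),
            concentrations={str(a): wide[a].to_numpy() for a in wide.columns},
            condition=str(cond),
        )
    return out


def write_hplc_csv(series: Sequence[MetaboliteTimeSeries], path: str) -> None:
    import pandas as pd

    rows = [
        {"condition": ts.condition, "time_h": t, "analyte": analyte,
         "conc_mM": c}
        for ts in series
        for analyte, conc in ts.concentrations.items()
        for t, c in zip(ts.times, conc)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
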