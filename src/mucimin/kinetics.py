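"""Michaelis-Menten parameter estimation from initial-rate enzyme assays.

The primary estimator mirrors classical bench practice: each replicate's
initial rates are transformed to a double-reciprocal (Lineweaver-Burk)
plot, 1/v is regressed on 1/[S] by unweighted ordinary least squares, and
Km = slope/intercept, Vmax = 1/intercept. Replicates are fitted
separately and pooled (mean across replicates, SE = SD/sqrt(n)) so that
the pooled estimate carries a spread comparable to a "mean +/- SD, n"
table entry. The reciprocal transform is statistically fragile - it
amplifies noise at low rates - so an independent nonlinear least-squares
fit of v = Vmax*[S]/(Km+[S]) is provided as a cross-check, and activator
effects are judged by a Welch two-sample t-test on replicate-level Km
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats


class KineticsError(ValueError):
    pass


@dataclass
class AssaySeries:
    """One replicate's initial-rate series for a single substrate."""

    substrate_id: str
    concentrations: np.ndarray  # mM, strictly increasing
    rates: np.ndarray  # initial rates (assay units / min)
    replicate_id: int = 0
    activator_conc: float = 0.0  # mM GlcNAc6P

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise KineticsError("concentrations and rates must have equal length")
        if np.any(self.concentrations <= 0):
            raise KineticsError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise KineticsError("concentrations must be strictly increasing")
        if np.any(self.rates < 0):
            raise KineticsError("rates must be non-negative")


@dataclass
class KineticFit:
    Km: float  # mM
    Vmax: float
    Km_se: float
    Vmax_se: float
    n_replicates: int
    method: str
    replicate_Km: tuple[float, ...] = ()
    replicate_Vmax: tuple[float, ...] = ()
    valid: bool = True
    poor_fit: bool = False


@dataclass(frozen=True)
class KmComparison:
    substrate_id: str
    Km_a: float
    Km_b: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise KineticsError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def no_influence(self) -> bool:
        """True when the activator condition is indistinguishable (p > 0.05)."""
        return self.p_value > 0.05


def _check_series(series: Sequence[AssaySeries], allow_zero_rates: bool) -> None:
    if not series:
        raise KineticsError("no assay series supplied")
    for s in series:
        if len(np.unique(s.concentrations)) < 3:
            raise KineticsError(
                f"replicate {s.replicate_id}: need >=3 distinct concentrations"
            )
        if not allow_zero_rates and np.any(s.rates == 0):
            raise KineticsError(
                f"replicate {s.replicate_id}: zero rate makes the reciprocal "
                "transform undefined"
            )


def _pool(kms, vmaxes, method, valid=True, poor=False) -> KineticFit:
    kms = np.asarray(kms, dtype=float)
    vmaxes = np.asarray(vmaxes, dtype=float)
    n = len(kms)
    km_se = float(np.std(kms, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    vm_se = float(np.std(vmaxes, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return KineticFit(
        Km=float(np.mean(kms)),
        Vmax=float(np.mean(vmaxes)),
        Km_se=km_se,
        Vmax_se=vm_se,
        n_replicates=n,
        method=method,
        replicate_Km=tuple(kms),
        replicate_Vmax=tuple(vmaxes),
        valid=valid,
        poor_fit=poor,
    )


def fit_lineweaver_burk(series: Sequence[AssaySeries]) -> KineticFit:
    """Double-reciprocal (Lineweaver-Burk) estimate pooled over replicates.

    A non-positive intercept on any replicate (which would imply
    Vmax <= 0) marks the pooled fit invalid rather than raising.
    """
    _check_series(series, allow_zero_rates=False)
    kms, vmaxes = [], []
    valid = True
    for s in series:
        x = 1.0 / s.concentrations
        y = 1.0 / s.rates
        fit = stats.linregress(x, y)
        if fit.intercept <= 0:
            valid = False
            kms.append(float("nan"))
            vmaxes.append(float("nan"))
            continue
        kms.append(fit.slope / fit.intercept)
        vmaxes.append(1.0 / fit.intercept)
    return _pool(kms, vmaxes, "lineweaver_burk", valid=valid)


def _mm(conc, vmax, km):
    return vmax * conc / (km + conc)


def fit_michaelis_nonlinear(series: Sequence[AssaySeries]) -> KineticFit:
    """Nonlinear least-squares fit of the Michaelis-Menten curve.

    Used as the statistically robust cross-check of the double-reciprocal
    estimator; zero rates are permitted. Fits whose R^2 against the MM
    curve falls below 0.8 are flagged ``poor_fit`` (model mismatch, e.g.
    monotone-decreasing rates).
    """
    _check_series(series, allow_zero_rates=True)
    kms, vmaxes = [], []
    poor = False
    for s in series:
        vmax0 = float(np.max(s.rates)) or 1.0
        half = 0.5 * vmax0
        km0 = float(s.concentrations[np.argmin(np.abs(s.rates - half))]) or 1.0
        try:
            popt, _ = optimize.curve_fit(
                _mm, s.concentrations, s.rates, p0=(vmax0, km0),
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as exc:
            raise KineticsError(f"nonlinear fit did not converge: {exc}") from exc
        pred = _mm(s.concentrations, *popt)
        ss_res = float(np.sum((s.rates - pred) ** 2))
        ss_tot = float(np.sum((s.rates - np.mean(s.rates)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if r2 < 0.8:
            poor = True
        vmaxes.append(popt[0])
        kms.append(popt[1])
    return _pool(kms, vmaxes, "michaelis_nonlinear", poor=poor)


def compare_km(
    kms_a: Sequence[float],
    kms_b: Sequence[float],
    substrate_id: str = "",
) -> KmComparison:
    """Welch two-sample t-test on replicate-level Km estimates."""
    a = np.asarray(kms_a, dtype=float)
    b = np.asarray(kms_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise KineticsError("need >=2 replicate Km estimates per condition")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: the t statistic is 0/0
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return KmComparison(
        substrate_id=substrate_id,
        Km_a=float(np.mean(a)),
        Km_b=float(np.mean(b)),
        p_value=p,
    )


def activity_above_blank(
    rates: Sequence[float], blank_rates: Sequence[float], alpha: float = 0.05
) -> tuple[bool, float]:
    """One-sided Welch test: are assay rates above the no-enzyme control?

    Encodes the "no activity" call for substrate pairs the enzyme cannot
    turn over (e.g. Fru6P + glutamine): activity is declared only when the
    mean rate is significantly above blank.
    """
    res = stats.ttest_ind(
        np.asarray(rates, float), np.asarray(blank_rates, float),
        equal_var=False, alternative="greater",
    )
    p = float(res.pvalue)
    return p < alpha, p


# ---------------------------------------------------------------------------
# CSV interchange (long format)
# ---------------------------------------------------------------------------

def read_assay_csv(path: str) -> dict[tuple[str, float], list[AssaySeries]]:
    """Read assays from CSV columns replicate, substrate, conc_mM, rate, activator_mM.

    Returns series grouped by (substrate, activator concentration).
    """
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[tuple[str, float], list[AssaySeries]] = {}
    keys = ["substrate", "activator_mM", "replicate"]
    for (sub, act, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("conc_mM")
        out.setdefault((str(sub), float(act)), []).append(
            AssaySeries(
                substrate_id=str(sub),
                concentrations=grp["conc_mM"].to_numpy(),
                rates=grp["rate"].to_numpy(),
                replicate_id=int(rep),
                activator_conc=float(act),
            )
        )
    return out


def write_assay_csv(series: Sequence[AssaySeries], path: str) -> None:
    import pandas as pd

    rows = [
        {"replicate": s.replicate_id, "substrate": s.substrate_id,
         "conc_mM": c, "rate": r, "activator_mM": s.activator_conc}
        for s in series
        for c, r in zip(s.concentrations, s.rates)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
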