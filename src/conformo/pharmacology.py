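"""Dose-response, competition-binding and kinetic fits, plus the
proliferation factor.

All concentration-response fits use the three-parameter logistic (3PL) with
unit Hill slope,

    Y(c) = basal + (emax - basal) / (1 + 10**(-(pEC50 + log10 c))),

so Y(EC50) is halfway between basal and emax and pEC50 = -log10 EC50 (molar).
Competition binding fits a descending displacement curve for IC50 and
converts it to an affinity constant with the Cheng-Prusoff relation
Ki = IC50 / (1 + [L]/KD), where [L] and KD are the concentration and
affinity of the labelled ("hot") tracer. Tracer kinetics are fit with an
association-then-dissociation model, giving KD = koff/kon with
kon = (kobs - koff)/[L]. The proliferation factor pIC50 x span condenses
anti-proliferative potency and efficacy into one number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

NORMALIZATION_REFERENCES = ("NECA", "forskolin_100uM", "CGS21680", "DMSO_1pct")


@dataclass
class AssayTable:
    """Tidy assay data with a normalisation reference.

    data columns: compound_id, cell_context, conc_M, response_pct, replicate.
    """

    data: pd.DataFrame
    normalization_reference: str = "CGS21680"

    def __post_init__(self):
        required = {"compound_id", "cell_context", "conc_M", "response_pct", "replicate"}
        if not required <= set(self.data.columns):
            raise ValueError(f"assay table must have columns {sorted(required)}")
        if self.normalization_reference not in NORMALIZATION_REFERENCES:
            raise ValueError(f"normalization_reference must be one of {NORMALIZATION_REFERENCES}")
        if (self.data["conc_M"] <= 0).any():
            raise ValueError("concentrations must be positive (molar)")
        if (self.data["replicate"] < 1).any():
            raise ValueError("replicate indices start at 1")


@dataclass
class DoseResponseFit:
    basal: float
    emax: float
    pec50: float
    se_pec50: float
    converged: bool
    n_concentrations: int

    @property
    def range(self) -> float:
        return self.emax - self.basal


@dataclass
class CompetitionFit:
    hot_kd: float  # M
    hot_conc: float  # M
    ic50: float  # M
    pki: float
    full_displacement: bool
    top: float
    bottom: float
    converged: bool


@dataclass
class KineticFit:
    kobs: float  # 1/min
    koff: float  # 1/min
    kon: float  # 1/(M min)
    kd: float  # M
    beq: float
    injection_time: float  # min
    converged: bool


@dataclass
class ProliferationResult:
    pic50: float
    span: float
    proliferation_factor: float
    anti_proliferative: bool


@dataclass
class PotencyCorrelation:
    r: float
    ci_low: float
    ci_high: float
    n_used: int
    n_dropped: int


def _collapse_replicates(conc: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame({"c": conc, "r": resp}).groupby("c", sort=True).mean().reset_index()
    return df["c"].to_numpy(), df["r"].to_numpy()


def logistic_3pl(conc_M: np.ndarray, basal: float, emax: float, pec50: float) -> np.ndarray:
    x = np.log10(conc_M)
    return basal + (emax - basal) / (1.0 + 10.0 ** (-(pec50 + x)))


def fit_3pl(
    table: AssayTable | pd.DataFrame,
    basal_fixed: float | None = None,
    max_fixed: float | None = None,
) -> DoseResponseFit:
    """Least-squares 3PL fit with unit Hill slope.

    Replicates are averaged per concentration before fitting (uniform
    weights). pEC50 is bounded to the tested concentration window +/- 1 log.
    basal and/or emax can be held fixed (e.g. proliferation fits constrain
    basal to 100 % and emax to the assay's maximal-inhibition floor).
    """
    df = table.data if isinstance(table, AssayTable) else table
    conc, resp = _collapse_replicates(
        df["conc_M"].to_numpy(dtype=float), df["response_pct"].to_numpy(dtype=float)
    )
    if conc.size < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {conc.size}")
    n_free = 3 - (basal_fixed is not None) - (max_fixed is not None)
    if conc.size < n_free:
        raise ValueError("fewer points than free parameters")
    logc = np.log10(conc)
    pec50_lo, pec50_hi = -logc.max() - 1.0, -logc.min() + 1.0
    lo, hi = float(resp.min()), float(resp.max())
    span_guess = hi - lo if hi > lo else 1.0
    increasing = resp[np.argsort(logc)][-1] >= resp[np.argsort(logc)][0]

    p0 = {
        "basal": basal_fixed if basal_fixed is not None else (lo if increasing else hi),
        "emax": max_fixed if max_fixed is not None else (hi if increasing else lo),
        "pec50": float(np.clip(-np.median(logc), pec50_lo, pec50_hi)),
    }
    free = [name for name, fixed in (("basal", basal_fixed), ("emax", max_fixed)) if fixed is None]
    free.append("pec50")
    bounds_map = {
        "basal": (lo - 2 * span_guess, hi + 2 * span_guess),
        "emax": (lo - 2 * span_guess, hi + 2 * span_guess),
        "pec50": (pec50_lo, pec50_hi),
    }

    def model(c, *params):
        kw = dict(p0)
        kw.update(dict(zip(free, params)))
        return logistic_3pl(c, kw["basal"], kw["emax"], kw["pec50"])

    try:
        popt, pcov = optimize.curve_fit(
            model,
            conc,
            resp,
            p0=[p0[name] for name in free],
            bounds=(
                [bounds_map[name][0] for name in free],
                [bounds_map[name][1] for name in free],
            ),
            maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan, False, conc.size)
    fitted = dict(p0)
    fitted.update(dict(zip(free, popt)))
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    se = dict(zip(free, perr))
    return DoseResponseFit(
        basal=float(fitted["basal"]),
        emax=float(fitted["emax"]),
        pec50=float(fitted["pec50"]),
        se_pec50=float(se["pec50"]),
        converged=converged,
        n_concentrations=int(conc.size),
    )


def delta_table(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> dict[str, float]:
    """Differences a - b in pEC50 and range, with SE propagated in quadrature."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("delta_table requires two converged fits")
    return {
        "delta_pec50": fit_a.pec50 - fit_b.pec50,
        "se_delta_pec50": math.sqrt(fit_a.se_pec50**2 + fit_b.se_pec50**2),
        "delta_range": fit_a.range - fit_b.range,
    }


def cheng_prusoff_ki(ic50_M: float, hot_conc_M: float, hot_kd_M: float) -> float:
    """Ki = IC50 / (1 + [L]/KD)."""
    if ic50_M <= 0 or hot_kd_M <= 0 or hot_conc_M < 0:
        raise ValueError("IC50 and KD must be positive, [L] non-negative")
    return ic50_M / (1.0 + hot_conc_M / hot_kd_M)


def fit_competition(
    table: AssayTable | pd.DataFrame,
    hot_kd: float = 65e-9,
    hot_conc: float = 300e-9,
    displacement_floor: float = 0.20,
) -> CompetitionFit:
    """One-site competition fit: descending unit-slope curve, then Cheng-Prusoff.

    ``full_displacement`` is False when the fitted lower plateau sits above
    ``displacement_floor`` of the fitted assay window (bottom > floor * top),
    flagging partial displacers.
    """
    df = table.data if isinstance(table, AssayTable) else table
    conc, resp = _collapse_replicates(
        df["conc_M"].to_numpy(dtype=float), df["response_pct"].to_numpy(dtype=float)
    )
    logc = np.log10(conc)
    if logc.max() - logc.min() < 3.0:
        raise ValueError("competition data must span >= 3 log units of concentration")

    def model(c, top, bottom, log_ic50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (np.log10(c) - log_ic50))

    p0 = [float(resp.max()), float(resp.min()), float(np.median(logc))]
    try:
        popt, _ = optimize.curve_fit(
            model, conc, resp, p0=p0,
            bounds=([-np.inf, -np.inf, logc.min() - 2], [np.inf, np.inf, logc.max() + 2]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return CompetitionFit(hot_kd, hot_conc, math.nan, math.nan, False, math.nan, math.nan, False)
    top, bottom, log_ic50 = popt
    ic50 = 10.0 ** log_ic50
    ki = cheng_prusoff_ki(ic50, hot_conc, hot_kd)
    window = top
    full = bool(bottom <= displacement_floor * window)
    return CompetitionFit(
        hot_kd=hot_kd,
        hot_conc=hot_conc,
        ic50=float(ic50),
        pki=float(-math.log10(ki)),
        full_displacement=full,
        top=float(top),
        bottom=float(bottom),
        converged=converged,
    )


def association_dissociation(t: np.ndarray, beq: float, kobs: float, koff: float, injection_time: float) -> np.ndarray:
    """Tracer signal: mono-exponential association, then decay after injection."""
    t = np.asarray(t, dtype=float)
    b_inj = beq * (1.0 - np.exp(-kobs * injection_time))
    assoc = beq * (1.0 - np.exp(-kobs * t))
    dissoc = b_inj * np.exp(-koff * (t - injection_time))
    return np.where(t <= injection_time, assoc, dissoc)


def fit_association_dissociation(
    times_min: Sequence[float],
    signal: Sequence[float],
    injection_time: float,
    hot_conc: float = 40e-9,
) -> KineticFit:
    """Fit the association-then-dissociation trace of the labelled tracer.

    kon = (kobs - koff) / [hot]; KD = koff / kon. A fit with kobs <= koff is
    unphysical (it implies a negative association rate) and raises.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    n_before = int(np.sum(t <= injection_time))
    n_after = t.size - n_before
    if n_before < 5 or n_after < 5:
        raise ValueError("need >= 5 points on each side of the injection time")

    def model(tt, beq, kobs, koff):
        return association_dissociation(tt, beq, kobs, koff, injection_time)

    beq0 = float(np.max(np.abs(y))) or 1.0
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[beq0, 0.2, 0.05],
            bounds=([0, 1e-6, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return KineticFit(math.nan, math.nan, math.nan, math.nan, math.nan, injection_time, False)
    beq, kobs, koff = popt
    if kobs <= koff:
        raise ValueError(f"unphysical fit: kobs ({kobs:.4g}) <= koff ({koff:.4g})")
    kon = (kobs - koff) / hot_conc
    return KineticFit(
        kobs=float(kobs),
        koff=float(koff),
        kon=float(kon),
        kd=float(koff / kon),
        beq=float(beq),
        injection_time=float(injection_time),
        converged=converged,
    )


def proliferation_factor(pic50: float, span: float) -> ProliferationResult:
    """pIC50 x span; non-anti-proliferative compounds (span < 0) get factor 0."""
    if span < 0:
        return ProliferationResult(pic50, span, 0.0, False)
    return ProliferationResult(pic50, span, float(pic50 * span), True)


def potency_correlation(pairs: Sequence[tuple[float, float]]) -> PotencyCorrelation:
    """Pearson r between cAMP pEC50 and proliferation pIC50, Fisher-z 95 % CI.

    Pairs with a missing (NaN) member are dropped and counted.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    keep = np.all(np.isfinite(arr), axis=1)
    n_dropped = int((~keep).sum())
    arr = arr[keep]
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 complete pairs")
    res = stats.pearsonr(arr[:, 0], arr[:, 1])
    ci = res.confidence_interval(confidence_level=0.95)
    return PotencyCorrelation(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_used=int(arr.shape[0]),
        n_dropped=n_dropped,
    )
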