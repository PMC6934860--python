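"""MTS dose-response analysis: viability, 4PL fits, IC50 comparison.

Viability is the blank-corrected A490-A650 signal of a treated well as
a percentage of the untreated control.  The dose-response model is the
four-parameter logistic

    V(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

fitted by least squares on a log-concentration grid with multi-start
initialisation of log IC50.  The reported IC50 is the 4PL inflection
concentration (a *relative* IC50, not the absolute-50% crossing).  A
profile-likelihood confidence interval for IC50 is computed by
re-optimising the remaining parameters along a log-IC50 grid and
thresholding the residual sum of squares with the F(1, n-p) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class InvalidPlateError(ValueError):
    pass


def four_pl(conc, top, bottom, ic50, hill):
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


# ---------------------------------------------------------------------------
# absorbance -> viability
# ---------------------------------------------------------------------------

def viability_from_absorbance(a490_t, a650_t, a490_ctrl, a650_ctrl,
                              a490_blank, a650_blank) -> float:
    """Percent viability of a treated well.

    100 * ((A490_t - A650_t) - blank) / ((A490_ctrl - A650_ctrl) - blank),
    where blank is the mean corrected blank absorbance; scalar or
    array-like control/blank readings are averaged.
    """
    blank = float(np.mean(np.asarray(a490_blank, float) - np.asarray(a650_blank, float)))
    ctrl = float(np.mean(np.asarray(a490_ctrl, float) - np.asarray(a650_ctrl, float))) - blank
    if ctrl <= 0:
        raise InvalidPlateError("control-minus-blank corrected signal must be > 0")
    treated = np.asarray(a490_t, float) - np.asarray(a650_t, float) - blank
    out = 100.0 * treated / ctrl
    return float(out) if np.ndim(out) == 0 else out


def plate_to_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Tidy well table -> per-well viability table.

    Expects columns well, drug, conc_uM, mode, replicate, role
    (treated/control/blank), a490, a650.
    """
    required = {"drug", "conc_uM", "mode", "replicate", "role", "a490", "a650"}
    missing = required - set(plate.columns)
    if missing:
        raise InvalidPlateError(f"plate table missing columns: {sorted(missing)}")
    ctrl = plate[plate.role == "control"]
    blank = plate[plate.role == "blank"]
    treated = plate[plate.role == "treated"]
    if ctrl.empty or blank.empty or treated.empty:
        raise InvalidPlateError("plate needs treated, control and blank wells")
    v = viability_from_absorbance(
        treated.a490.to_numpy(), treated.a650.to_numpy(),
        ctrl.a490.to_numpy(), ctrl.a650.to_numpy(),
        blank.a490.to_numpy(), blank.a650.to_numpy(),
    )
    out = treated[["drug", "conc_uM", "mode", "replicate"]].copy()
    out["viability_pct"] = v
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    drug: str = ""
    culture_mode: str = ""
    top: float = float("nan")
    bottom: float = float("nan")
    hill: float = float("nan")
    ic50: float = float("nan")
    residual_sd: float = float("nan")
    converged: bool = False
    ci_ic50: tuple[float, float] = (float("nan"), float("nan"))
    n_points: int = 0

    def as_dict(self) -> dict:
        return {
            "drug": self.drug, "culture_mode": self.culture_mode,
            "top": self.top, "bottom": self.bottom, "hill": self.hill,
            "ic50": self.ic50, "residual_sd": self.residual_sd,
            "converged": self.converged,
            "ci_ic50": [self.ci_ic50[0], self.ci_ic50[1]],
            "n_points": self.n_points,
        }


def _fit_params(conc, viab, log_ic50_starts):
    """Least-squares 4PL in (top, bottom, log10 ic50, hill); best of
    the supplied log-IC50 starts."""
    logc = np.log10(conc)

    def resid(theta):
        top, bottom, lic, hill = theta
        return four_pl(conc, top, bottom, 10.0**lic, hill) - viab

    best = None
    vmax, vmin = float(np.max(viab)), float(np.min(viab))
    for lic0 in log_ic50_starts:
        theta0 = np.array([vmax, vmin, lic0, 1.0])
        try:
            sol = optimize.least_squares(
                resid, theta0,
                bounds=([-np.inf, -np.inf, logc.min() - 3, 0.05],
                        [np.inf, np.inf, logc.max() + 3, 20.0]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_dose_response(viability: pd.DataFrame, ci_level: float = 0.90,
                      min_dynamic_range_frac: float = 0.10) -> DoseResponseFit:
    """Fit the 4PL to a per-well viability table.

    Needs >= 4 distinct concentrations.  A flat response (observed
    dynamic range below ``min_dynamic_range_frac`` of the top) is not
    fitted: the fit is returned with converged=False and IC50 undefined.
    """
    conc = viability["conc_uM"].to_numpy(float)
    viab = viability["viability_pct"].to_numpy(float)
    drug = str(viability["drug"].iloc[0]) if "drug" in viability else ""
    mode = str(viability["mode"].iloc[0]) if "mode" in viability else ""
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    fit = DoseResponseFit(drug=drug, culture_mode=mode, n_points=len(conc))

    vmax = float(np.max(viab))
    if vmax <= 0 or (vmax - float(np.min(viab))) < min_dynamic_range_frac * vmax:
        return fit  # flat response; converged stays False

    logc = np.log10(conc)
    starts = np.linspace(logc.min(), logc.max(), 5)
    sol = _fit_params(conc, viab, starts)
    if sol is None or not sol.success and sol.cost > 1e12:
        return fit

    top, bottom, lic, hill = sol.x
    if bottom > top:  # canonical orientation: force descending curve
        top, bottom, hill = bottom, top, -hill
    n, p = len(conc), 4
    ssr = 2.0 * sol.cost
    fit.top, fit.bottom, fit.hill, fit.ic50 = top, bottom, hill, 10.0**lic
    fit.residual_sd = float(np.sqrt(ssr / max(n - p, 1)))
    fit.converged = bool(hill > 0 and np.isfinite(fit.ic50))
    if fit.converged and n > p:
        fit.ci_ic50 = _profile_ci_ic50(conc, viab, sol.x, ssr, ci_level)
    elif fit.converged:
        fit.ci_ic50 = (fit.ic50, fit.ic50)
    return fit


def _profile_ssr(conc, viab, lic, theta_init):
    """Min SSR with log-ic50 fixed."""
    def resid(th3):
        top, bottom, hill = th3
        return four_pl(conc, top, bottom, 10.0**lic, hill) - viab

    sol = optimize.least_squares(
        resid, theta_init, bounds=([-np.inf, -np.inf, 0.05], [np.inf, np.inf, 20.0]),
        method="trf", xtol=1e-10, ftol=1e-10,
    )
    return 2.0 * sol.cost


def _profile_ci_ic50(conc, viab, theta_hat, ssr_min, level) -> tuple[float, float]:
    n, p = len(conc), 4
    fq = stats.f.ppf(level, 1, n - p)
    thresh = ssr_min * (1.0 + fq / (n - p))
    lic_hat = theta_hat[2]
    th3 = np.array([theta_hat[0], theta_hat[1], theta_hat[3]])
    logc = np.log10(conc)

    def excess(lic):
        return _profile_ssr(conc, viab, lic, th3) - thresh

    lo_bound, hi_bound = logc.min() - 3, logc.max() + 3

    def bracket(direction):
        step = 0.05
        prev = lic_hat
        while True:
            cand = prev + direction * step
            if cand < lo_bound or cand > hi_bound:
                return None  # CI open on this side within the search range
            if excess(cand) > 0:
                return (min(prev, cand), max(prev, cand))
            prev = cand
            step *= 1.6

    out = []
    for direction, bound in ((-1, lo_bound), (+1, hi_bound)):
        br = bracket(direction)
        if br is None:
            out.append(10.0**bound)
            continue
        try:
            root = optimize.brentq(excess, br[0], br[1], xtol=1e-6)
        except ValueError:
            root = br[0] if direction < 0 else br[1]
        out.append(10.0**root)
    return (float(min(out)), float(max(out)))


# ---------------------------------------------------------------------------
# comparisons and ranking
# ---------------------------------------------------------------------------

@dataclass
class ModeComparison:
    fold_mcs_over_2d: float
    large_difference: bool
    status: str  # "ok" | "not-comparable"


def compare_modes(fit_2d: DoseResponseFit, fit_mcs: DoseResponseFit,
                  fold_threshold: float = 2.0) -> ModeComparison:
    """Fold change of IC50 between culture modes.

    Flagged as a "large" difference when the two IC50 confidence
    intervals are disjoint AND the fold change is >= fold_threshold.
    """
    if not (fit_2d.converged and fit_mcs.converged):
        return ModeComparison(float("nan"), False, "not-comparable")
    fold = fit_mcs.ic50 / fit_2d.ic50
    disjoint = (fit_mcs.ci_ic50[0] > fit_2d.ci_ic50[1]
                or fit_2d.ci_ic50[0] > fit_mcs.ci_ic50[1])
    big = max(fold, 1.0 / fold) >= fold_threshold
    return ModeComparison(float(fold), bool(disjoint and big), "ok")


def resistance_rank_from_ic50(
    fits: dict[str, dict[str, DoseResponseFit]],
) -> pd.DataFrame:
    """Rank cell lines by IC50 across their shared drugs.

    Returns a DataFrame indexed by cell line with per-drug ranks
    (1 = lowest IC50 = most sensitive; ties share the mean rank) and a
    ``mean_rank`` aggregate, sorted ascending so the most drug-sensitive
    line comes first.
    """
    if len(fits) < 2:
        raise ValueError("need at least two cell lines")
    shared = None
    for line, by_drug in fits.items():
        drugs = {d for d, f in by_drug.items() if f.converged}
        shared = drugs if shared is None else shared & drugs
    if not shared:
        raise ValueError("no shared drugs with converged fits")
    shared = sorted(shared)
    lines = list(fits)
    table = pd.DataFrame(
        {d: [fits[l][d].ic50 for l in lines] for d in shared}, index=lines
    )
    ranks = table.rank(axis=0, method="average")
    ranks["mean_rank"] = ranks.mean(axis=1)
    return ranks.sort_values("mean_rank")
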