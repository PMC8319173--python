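"""Constrained four-parameter-logistic concentration-response analysis.

Validated screen hits are retested in six-point semi-log series and
fitted with the descending 4PL

    y(x) = bottom + (100 - bottom) / (1 + (x / IC50)^hill)

with the top plateau pinned at 100% of the stimulated control, leaving
(bottom, IC50, hill) free.  IC50 is fitted on the log10 scale for
conditioning.  Curves acquired in the priming protocol (compound added
with LPS) and the activation protocol (compound added after LPS) are
compared by their IC50 ratio to locate a compound's stage of action,
and each fit is sorted into the screen's curve-quality categories:

* A — complete inhibition with a standard sigmoidal slope,
* B — complete inhibition but implausibly steep,
* C — incomplete curve with at least 30% inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CRCurve",
    "FourPLFit",
    "ModeComparison",
    "CurveClass",
    "DoseResponseError",
    "four_pl_response",
    "fit_4pl",
    "compare_modes",
    "classify_curve",
    "potency_table",
]

TOP = 100.0
#: fits whose observed response spans less than this are declared flat;
#: 5 percentage points keeps curves with bottoms up to ~90% fittable
#: while refusing data that never leaves the control plateau
FLAT_RANGE_FLOOR = 5.0


class DoseResponseError(ValueError):
    pass


def four_pl_response(x, bottom, ic50, hill, top=TOP):
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


@dataclass(frozen=True)
class CRCurve:
    """Pooled replicate observations of one compound in one protocol mode."""

    compound_id: str
    mode: str  # priming | activation
    concentrations: np.ndarray  # molar, one entry per observation
    responses: np.ndarray  # % of stimulated control
    n_replicates: int = 1

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.shape != resp.shape:
            raise DoseResponseError("concentrations and responses differ in length")
        if np.any(conc <= 0):
            raise DoseResponseError("concentrations must be strictly positive")
        if not np.all(np.isfinite(resp)):
            raise DoseResponseError("responses must be finite")
        if np.unique(conc).size < 2:
            raise DoseResponseError("need >= 2 distinct concentrations")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound_id: str | None = None,
                   mode: str | None = None) -> "CRCurve":
        """Build from a tidy table (compound_id, mode, conc_M, response_pct, replicate)."""
        sub = df
        if compound_id is not None:
            sub = sub[sub["compound_id"] == compound_id]
        if mode is not None:
            sub = sub[sub["mode"] == mode]
        if sub.empty:
            raise DoseResponseError(f"no rows for {compound_id!r}/{mode!r}")
        n_rep = sub["replicate"].nunique() if "replicate" in sub.columns else 1
        return cls(
            compound_id=str(sub["compound_id"].iloc[0]) if "compound_id" in sub else "",
            mode=str(sub["mode"].iloc[0]) if "mode" in sub else "priming",
            concentrations=sub["conc_M"].to_numpy(),
            responses=sub["response_pct"].to_numpy(),
            n_replicates=int(n_rep),
        )


@dataclass(frozen=True)
class FourPLFit:
    """Result of a top-constrained 4PL fit.

    ``max_observed_inhibition`` (100 minus the smallest per-
    concentration mean response) is retained so unconverged curves can
    still be categorized.
    """

    compound_id: str = ""
    mode: str = "priming"
    top: float = TOP
    bottom: float = float("nan")
    ic50: float = float("nan")
    hill: float = float("nan")
    converged: bool = False
    rss: float = float("nan")
    se_ic50: float | None = None
    max_observed_inhibition: float = float("nan")
    message: str = ""

    @property
    def max_inhibition(self) -> float:
        """Fitted maximal inhibition, 100 - bottom."""
        return TOP - self.bottom

    def predict(self, x):
        return four_pl_response(x, self.bottom, self.ic50, self.hill)


@dataclass(frozen=True)
class ModeComparison:
    compound_id: str
    ic50_priming: float
    ic50_activation: float
    potency_ratio: float  # ic50_activation / ic50_priming
    max_inhibition_priming: float
    max_inhibition_activation: float
    verdict: str  # priming-biased | activation-biased | equipotent


@dataclass(frozen=True)
class CurveClass:
    category: str  # A | B | C | none
    max_inhibition: float
    hill: float
    converged: bool


def _per_conc_means(conc: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(conc)
    means = np.array([resp[conc == c].mean() for c in levels])
    return levels, means


def fit_4pl(curve: CRCurve, flat_range_floor: float = FLAT_RANGE_FLOOR) -> FourPLFit:
    """Least-squares 4PL fit with top fixed at 100.

    Replicates are fitted as pooled points with equal weight.  Free
    parameters are (bottom, log10 IC50, hill) with bottom bounded to
    [0, 100] and hill to (0, 10]; declining curves therefore carry a
    positive Hill slope, and data the optimizer can only explain with a
    non-positive slope come back unconverged.  Initialization: hill = 1,
    bottom = the smallest observed response (clamped to [0, 100]), IC50
    = the concentration whose mean response is nearest (100+bottom)/2,
    with two further log-spaced IC50 starts tried if the first fails.
    Curves whose mean responses span less than ``flat_range_floor``
    percentage points are declared flat and returned unconverged.
    """
    conc = curve.concentrations
    resp = curve.responses
    levels, means = _per_conc_means(conc, resp)
    observed_inh = TOP - float(means.min())
    base = dict(
        compound_id=curve.compound_id, mode=curve.mode,
        max_observed_inhibition=observed_inh,
    )
    if float(means.max() - means.min()) < flat_range_floor:
        return FourPLFit(**base, message="flat data: response range below floor")

    logc = np.log10(conc)
    b0 = float(np.clip(resp.min(), 0.0, 100.0))
    mid = (TOP + b0) / 2.0
    start_ic50 = float(levels[np.argmin(np.abs(means - mid))])
    lo = [0.0, logc.min() - 2.0, 1e-3]
    hi = [100.0, logc.max() + 2.0, 10.0]

    def residuals(theta):
        bottom, log_ic50, hill = theta
        return four_pl_response(conc, bottom, 10.0**log_ic50, hill) - resp

    starts = [math.log10(start_ic50)]
    span = logc.max() - logc.min()
    starts += [logc.min() + span / 4.0, logc.max() - span / 4.0]

    best = None
    for i, s in enumerate(starts):
        theta0 = np.clip([b0, s, 1.0], lo, hi)
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi))
        except Exception:  # numerical failure on this start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and i == 0:
            break  # multi-start only on failure of the primary start
    if best is None:
        return FourPLFit(**base, message="optimizer failed from all starts")

    bottom, log_ic50, hill = best.x
    rss = float(2.0 * best.cost)
    se_ic50 = _ic50_standard_error(best, conc.size)
    # a slope pinned at the lower bound means the data never declined
    if hill <= lo[2] * 1.01:
        return FourPLFit(
            **base, bottom=float(bottom), ic50=float(10.0**log_ic50),
            hill=float(hill), rss=rss, message="non-positive Hill slope",
        )
    return FourPLFit(
        **base,
        bottom=float(bottom),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        converged=True,
        rss=rss,
        se_ic50=se_ic50,
    )


def _ic50_standard_error(sol, n_obs: int) -> float | None:
    """Delta-method SE of IC50 from the Jacobian at the optimum."""
    try:
        dof = n_obs - sol.x.size
        if dof <= 0:
            return None
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_log = math.sqrt(max(cov[1, 1], 0.0))
        return float(se_log * math.log(10.0) * 10.0 ** sol.x[1])
    except np.linalg.LinAlgError:
        return None


def compare_modes(
    fit_priming: FourPLFit, fit_activation: FourPLFit, fold_margin: float = 2.0
) -> ModeComparison:
    """Compare a compound's potency between protocol modes.

    ``potency_ratio = IC50_activation / IC50_priming``; the compound is
    priming-biased when the ratio is at least ``fold_margin`` (the
    boundary is inclusive), activation-biased when at most
    ``1/fold_margin``, else equipotent.
    """
    for fit, mode in ((fit_priming, "priming"), (fit_activation, "activation")):
        if not fit.converged:
            raise DoseResponseError(f"compare_modes: {mode} fit did not converge")
    ratio = fit_activation.ic50 / fit_priming.ic50
    if ratio >= fold_margin:
        verdict = "priming-biased"
    elif ratio <= 1.0 / fold_margin:
        verdict = "activation-biased"
    else:
        verdict = "equipotent"
    return ModeComparison(
        compound_id=fit_priming.compound_id,
        ic50_priming=fit_priming.ic50,
        ic50_activation=fit_activation.ic50,
        potency_ratio=ratio,
        max_inhibition_priming=fit_priming.max_inhibition,
        max_inhibition_activation=fit_activation.max_inhibition,
        verdict=verdict,
    )


def classify_curve(
    fit: FourPLFit,
    min_inhibition: float = 30.0,
    complete_inhibition_floor: float = 80.0,
    steep_hill: float = 3.0,
) -> CurveClass:
    """Sort a fit into curve-quality category A, B, C or none.

    A: maximal inhibition >= the completeness floor with a standard
    (non-steep) slope from a converged fit; B: complete inhibition but a
    steep slope; C: incomplete inhibition of at least ``min_inhibition``
    (an unconverged curve whose best observed inhibition clears that bar
    also lands here); none otherwise.
    """
    if fit.converged:
        mi = fit.max_inhibition
        hill = abs(fit.hill)
        if mi >= complete_inhibition_floor and hill < steep_hill:
            cat = "A"
        elif mi >= complete_inhibition_floor:
            cat = "B"
        elif min_inhibition <= mi:
            cat = "C"
        else:
            cat = "none"
        return CurveClass(cat, mi, fit.hill, True)
    obs = fit.max_observed_inhibition
    cat = "C" if (np.isfinite(obs) and obs >= min_inhibition) else "none"
    return CurveClass(cat, obs, fit.hill, False)


def potency_table(fits: Sequence[FourPLFit], fold_margin: float = 2.0) -> pd.DataFrame:
    """One row per compound x mode: potency, efficacy, category, verdict.

    Rows are ordered by ascending priming IC50 (compounds lacking a
    converged priming fit sort last); the mode-comparison verdict is
    attached wherever both modes converged.
    """
    if not fits:
        raise DoseResponseError("potency_table: no fits given")
    by_compound: dict[str, dict[str, FourPLFit]] = {}
    for f in fits:
        by_compound.setdefault(f.compound_id, {})[f.mode] = f

    rows = []
    for cid, modes in by_compound.items():
        verdict = ""
        if "priming" in modes and "activation" in modes:
            try:
                verdict = compare_modes(
                    modes["priming"], modes["activation"], fold_margin
                ).verdict
            except DoseResponseError:
                verdict = "unresolved"
        prim = modes.get("priming")
        sort_key = prim.ic50 if prim is not None and prim.converged else math.inf
        for mode, f in modes.items():
            rows.append(
                {
                    "compound_id": cid,
                    "mode": mode,
                    "ic50_M": f.ic50,
                    "hill": f.hill,
                    "max_inhibition_pct": f.max_inhibition if f.converged
                    else f.max_observed_inhibition,
                    "converged": f.converged,
                    "category": classify_curve(f).category,
                    "verdict": verdict,
                    "_sort": sort_key,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["_sort", "compound_id", "mode"], ignore_index=True
    )
    return df.drop(columns="_sort")
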