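"""Plate quality control for 384-well speck screening plates.

Implements the screening QC toolbox: robust Z-prime and plain Z-prime,
SSMD, percent CV, replicate Pearson correlation, normalization of well
readouts to on-plate maximum-speck controls, per-plate pass/fail
evaluation against acceptance specifications, and a simplified
inter-/intra-plate uniformity assessment.

Conventions
-----------
* Robust Z' uses medians and MADs with the 1.4826 Gaussian-consistency
  factor; the plain Z' (means/SDs) is available for comparison.
* SSMD is the method-of-moments form ``(mean_neg - mean_pos) /
  sqrt(sd_neg**2 + sd_pos**2)`` with sample SDs.
* %CV is computed on raw (pre-normalization) negative-control values.
* Normalization is single-point to the median of the maximum-speck
  (vehicle + stimulus) negative controls; an optional two-point mode
  also subtracts the fully-inhibited positive-control median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROLES",
    "CONTROL_ROLES",
    "PlateLayout",
    "QCSpec",
    "PlateQCReport",
    "QCError",
    "robust_zprime",
    "zprime",
    "ssmd",
    "percent_cv",
    "replicate_pearson",
    "normalize_to_controls",
    "evaluate_metrics",
    "qc_plate",
    "uniformity_assessment",
]

#: Well roles on a screening plate.  ``neg_ctrl_max`` is the vehicle +
#: LPS + nigericin maximum-speck control (the normalization reference);
#: the two MCC950 roles are the half-maximal (50 nM) and fully
#: inhibiting (5 uM) positive controls.
ROLES = (
    "library",
    "neg_ctrl_max",
    "pos_ctrl_mcc950_50nM",
    "pos_ctrl_mcc950_5uM",
    "cells_alone",
    "vehicle_only",
)

#: Roles that must each occupy at least two wells so that spreads are
#: estimable.
CONTROL_ROLES = (
    "neg_ctrl_max",
    "pos_ctrl_mcc950_50nM",
    "pos_ctrl_mcc950_5uM",
)

N_ROWS, N_COLS = 16, 24
LIBRARY_CAPACITY = 280


class QCError(ValueError):
    """Raised for undefined metrics, insufficient data or bad layouts."""


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'-style 384-well name."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of every well of a 384-well plate to a role.

    The default layout places the 280 library positions in rows A-N of
    columns 3-22 and distributes the control roles over the outer
    columns and the two bottom rows.
    """

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.roles) != N_ROWS * N_COLS:
            raise QCError(
                f"layout must assign all {N_ROWS * N_COLS} wells, got {len(self.roles)}"
            )
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise QCError(f"unknown roles in layout: {sorted(bad)}")
        counts = self.role_counts()
        for role in CONTROL_ROLES:
            if counts.get(role, 0) < 2:
                raise QCError(
                    f"control role {role!r} needs >= 2 wells for variance "
                    f"estimation, has {counts.get(role, 0)}"
                )

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.roles.values():
            out[r] = out.get(r, 0) + 1
        return out

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, r in self.roles.items() if r == role)

    @property
    def library_wells(self) -> list[str]:
        return self.wells_with_role("library")

    @classmethod
    def default(cls) -> "PlateLayout":
        """Standard screening layout: 280 library wells, controls around."""
        roles: dict[str, str] = {}
        for row in range(N_ROWS):
            for col in range(N_COLS):
                w = well_name(row, col)
                if col == 0:
                    roles[w] = "neg_ctrl_max"
                elif col == 1:
                    roles[w] = "pos_ctrl_mcc950_50nM"
                elif col == 22:
                    roles[w] = "pos_ctrl_mcc950_5uM"
                elif col == 23:
                    roles[w] = "cells_alone" if row < 8 else "vehicle_only"
                elif row < 14:
                    roles[w] = "library"
                elif row == 14:
                    roles[w] = "neg_ctrl_max"
                else:
                    roles[w] = "pos_ctrl_mcc950_5uM"
        layout = cls(roles=roles)
        assert len(layout.library_wells) == LIBRARY_CAPACITY
        return layout

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"well": list(self.roles), "role": list(self.roles.values())}
        ).sort_values("well", ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        return cls(roles=dict(zip(df["well"], df["role"])))


@dataclass(frozen=True)
class QCSpec:
    """Acceptance specifications for a screening plate.

    Defaults are the screen's acceptance criteria: robust Z' > 0.6 for
    the fully inhibiting positive control, robust Z' > 0.2 for the
    half-maximal one, SSMD > 5 and negative-control %CV < 10.
    """

    min_rzprime_5uM: float = 0.6
    min_rzprime_50nM: float = 0.2
    min_ssmd: float = 5.0
    max_cv_pct: float = 10.0
    min_replicate_pearson: float = 0.9


@dataclass
class PlateQCReport:
    plate_id: str
    rzprime_5uM: float
    rzprime_50nM: float
    ssmd: float
    cv_neg_pct: float
    passes: dict[str, bool] = field(default_factory=dict)
    overall_pass: bool = False
    failure_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "rzprime_5uM": self.rzprime_5uM,
            "rzprime_50nM": self.rzprime_50nM,
            "ssmd": self.ssmd,
            "cv_neg_pct": self.cv_neg_pct,
            "passes": dict(self.passes),
            "overall_pass": self.overall_pass,
            "failure_reasons": list(self.failure_reasons),
        }


# ---------------------------------------------------------------------------
# metrics


def _as_array(values: Iterable[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise QCError(f"{name}: need >= {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise QCError(f"{name}: non-finite values present")
    return arr


def robust_zprime(neg_values: Iterable[float], pos_values: Iterable[float]) -> float:
    """Robust Z' = 1 - 3*(MADsd_neg + MADsd_pos) / |median_neg - median_pos|.

    MADsd is the median absolute deviation scaled by 1.4826 so it
    estimates the SD for Gaussian data.  Always <= 1; equals 1 only when
    both spreads are zero.
    """
    neg = _as_array(neg_values, "robust_zprime neg")
    pos = _as_array(pos_values, "robust_zprime pos")
    med_n, med_p = np.median(neg), np.median(pos)
    if med_n == med_p:
        raise QCError("robust_zprime undefined: group medians are equal")
    # conventional Gaussian-consistency factor (rounded, as usually quoted)
    sig_n = 1.4826 * stats.median_abs_deviation(neg)
    sig_p = 1.4826 * stats.median_abs_deviation(pos)
    return 1.0 - 3.0 * (sig_n + sig_p) / abs(med_n - med_p)


def zprime(neg_values: Iterable[float], pos_values: Iterable[float]) -> float:
    """Plain Z' factor using means and sample SDs."""
    neg = _as_array(neg_values, "zprime neg")
    pos = _as_array(pos_values, "zprime pos")
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        raise QCError("zprime undefined: group means are equal")
    return 1.0 - 3.0 * (neg.std(ddof=1) + pos.std(ddof=1)) / abs(mu_n - mu_p)


def ssmd(neg_values: Iterable[float], pos_values: Iterable[float]) -> float:
    """Strictly standardized mean difference, method-of-moments form."""
    neg = _as_array(neg_values, "ssmd neg")
    pos = _as_array(pos_values, "ssmd pos")
    var = neg.var(ddof=1) + pos.var(ddof=1)
    if var == 0:
        raise QCError("ssmd undefined: both group variances are zero")
    return float((neg.mean() - pos.mean()) / np.sqrt(var))


def percent_cv(values: Iterable[float]) -> float:
    """100 * sample SD / mean."""
    arr = _as_array(values, "percent_cv")
    mean = arr.mean()
    if mean == 0:
        raise QCError("percent_cv undefined: zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def replicate_pearson(
    plate_r1_values: Iterable[float], plate_r2_values: Iterable[float]
) -> float:
    """Pearson correlation between paired library-well readouts.

    Callers are expected to pass library wells only (controls excluded);
    pairs with a missing value on either side are dropped.
    """
    r1 = np.asarray(list(plate_r1_values), dtype=float)
    r2 = np.asarray(list(plate_r2_values), dtype=float)
    if r1.size != r2.size:
        raise QCError(f"replicate_pearson: length mismatch {r1.size} vs {r2.size}")
    keep = np.isfinite(r1) & np.isfinite(r2)
    r1, r2 = r1[keep], r2[keep]
    if r1.size < 3:
        raise QCError("replicate_pearson: need >= 3 complete pairs")
    if np.ptp(r1) == 0 or np.ptp(r2) == 0:
        raise QCError("replicate_pearson undefined: constant replicate vector")
    return float(stats.pearsonr(r1, r2).statistic)


# ---------------------------------------------------------------------------
# normalization


def normalize_to_controls(
    plate_table: pd.DataFrame,
    layout: PlateLayout | None = None,
    *,
    two_point: bool = False,
) -> pd.DataFrame:
    """Attach %speck formation and %inhibition columns to a plate table.

    ``pct_formation = 100 * value / median(neg_ctrl_max)`` and
    ``pct_inhibition = 100 - pct_formation``, so the two always sum to
    100 exactly.  With ``two_point=True`` the fully inhibited positive
    control median is first subtracted from every well (min-max
    rescaling).

    Parameters
    ----------
    plate_table
        DataFrame with at least ``well`` and ``value`` columns.  A
        ``role`` column is used if present, otherwise ``layout`` must be
        given.
    """
    df = plate_table.copy()
    if "role" not in df.columns:
        if layout is None:
            raise QCError("normalize_to_controls: no role column and no layout")
        df["role"] = df["well"].map(layout.roles)
    neg = df.loc[df["role"] == "neg_ctrl_max", "value"]
    if neg.empty:
        raise QCError("normalize_to_controls: no neg_ctrl_max wells on plate")
    ref = float(neg.median())
    floor = 0.0
    if two_point:
        pos = df.loc[df["role"] == "pos_ctrl_mcc950_5uM", "value"]
        if pos.empty:
            raise QCError("normalize_to_controls: two_point needs pos_ctrl_mcc950_5uM")
        floor = float(pos.median())
    if ref - floor == 0:
        raise QCError("normalize_to_controls: zero negative-control reference")
    df["pct_formation"] = 100.0 * (df["value"] - floor) / (ref - floor)
    df["pct_inhibition"] = 100.0 - df["pct_formation"]
    return df


# ---------------------------------------------------------------------------
# per-plate QC


def evaluate_metrics(
    plate_id: str,
    rzprime_5uM: float,
    rzprime_50nM: float,
    ssmd_value: float,
    cv_neg_pct: float,
    spec: QCSpec | None = None,
) -> PlateQCReport:
    """Compare already-computed plate metrics with an acceptance spec.

    The overall verdict is the conjunction of the per-metric flags;
    every failing metric is named in ``failure_reasons``.
    """
    spec = spec or QCSpec()
    checks = {
        "rzprime_5uM": (rzprime_5uM > spec.min_rzprime_5uM,
                        f"rzprime_5uM {rzprime_5uM:.3g} <= {spec.min_rzprime_5uM}"),
        "rzprime_50nM": (rzprime_50nM > spec.min_rzprime_50nM,
                         f"rzprime_50nM {rzprime_50nM:.3g} <= {spec.min_rzprime_50nM}"),
        "ssmd": (ssmd_value > spec.min_ssmd,
                 f"ssmd {ssmd_value:.3g} <= {spec.min_ssmd}"),
        "cv_neg_pct": (cv_neg_pct < spec.max_cv_pct,
                       f"cv_neg_pct {cv_neg_pct:.3g} >= {spec.max_cv_pct}"),
    }
    passes = {k: bool(ok) for k, (ok, _) in checks.items()}
    reasons = [msg for ok, msg in checks.values() if not ok]
    return PlateQCReport(
        plate_id=plate_id,
        rzprime_5uM=rzprime_5uM,
        rzprime_50nM=rzprime_50nM,
        ssmd=ssmd_value,
        cv_neg_pct=cv_neg_pct,
        passes=passes,
        overall_pass=all(passes.values()),
        failure_reasons=reasons,
    )


def qc_plate(
    plate_table: pd.DataFrame,
    spec: QCSpec | None = None,
    layout: PlateLayout | None = None,
    plate_id: str | None = None,
) -> PlateQCReport:
    """Compute control-based QC metrics for one plate and grade them.

    Uses raw (pre-normalization) well values: robust Z' of both MCC950
    controls against the maximum-speck negative control, SSMD of the
    5 uM control, and the %CV of the negative controls.
    """
    df = plate_table
    if "role" not in df.columns:
        if layout is None:
            raise QCError("qc_plate: no role column and no layout")
        df = df.assign(role=df["well"].map(layout.roles))
    if plate_id is None:
        plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else "plate"
    pid = plate_id
    groups = {}
    for role in CONTROL_ROLES:
        vals = df.loc[df["role"] == role, "value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise QCError(f"qc_plate: missing or underfilled control role {role!r}")
        groups[role] = vals
    neg = groups["neg_ctrl_max"]
    return evaluate_metrics(
        pid,
        rzprime_5uM=robust_zprime(neg, groups["pos_ctrl_mcc950_5uM"]),
        rzprime_50nM=robust_zprime(neg, groups["pos_ctrl_mcc950_50nM"]),
        ssmd_value=ssmd(neg, groups["pos_ctrl_mcc950_5uM"]),
        cv_neg_pct=percent_cv(neg),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# uniformity assessment


def uniformity_assessment(
    plates: Sequence[pd.DataFrame],
    spec: QCSpec | None = None,
    day_of_plate: Sequence[int] | None = None,
) -> dict:
    """Simplified inter-/intra-plate uniformity assessment.

    Each plate table must carry a ``signal`` column assigning wells to
    the three uniformity signal levels: ``max`` (fully stimulated),
    ``mid`` (half-maximal inhibition) and ``min`` (fully inhibited).
    Reports per-plate mean/SD/%CV at each level, between-plate and
    between-day mean shifts of the max signal, a row/column edge-effect
    summary of the max wells, and pass flags against the spec's CV bound.
    """
    spec = spec or QCSpec()
    if len(plates) < 3:
        raise QCError(f"uniformity_assessment: need >= 3 plates, got {len(plates)}")
    days = list(day_of_plate) if day_of_plate is not None else [1] * len(plates)
    levels = ("max", "mid", "min")
    per_plate = []
    for i, df in enumerate(plates):
        if "signal" not in df.columns:
            raise QCError("uniformity_assessment: plate table lacks a 'signal' column")
        entry: dict = {"plate_index": i, "day": days[i]}
        for lvl in levels:
            vals = df.loc[df["signal"] == lvl, "value"].to_numpy(dtype=float)
            if vals.size < 2:
                raise QCError(f"uniformity_assessment: plate {i} has <2 '{lvl}' wells")
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            entry[lvl] = {
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if mean else float("inf"),
            }
        per_plate.append(entry)

    max_means = np.array([e["max"]["mean"] for e in per_plate])
    grand = float(max_means.mean())
    between_plate_shift_pct = [
        100.0 * (m - grand) / grand for m in max_means
    ]
    day_means = {d: float(max_means[[i for i, dd in enumerate(days) if dd == d]].mean())
                 for d in sorted(set(days))}
    day_vals = list(day_means.values())
    between_day_shift_pct = (
        100.0 * (max(day_vals) - min(day_vals)) / grand if len(day_vals) > 1 else 0.0
    )

    # edge effects: mean of max-signal wells by plate row and column
    rows: dict[str, list[float]] = {}
    cols: dict[int, list[float]] = {}
    for df in plates:
        sub = df[df["signal"] == "max"]
        for w, v in zip(sub["well"], sub["value"]):
            rows.setdefault(w[0], []).append(float(v))
            cols.setdefault(int(w[1:]), []).append(float(v))
    row_means = {r: float(np.mean(v)) for r, v in sorted(rows.items())}
    col_means = {c: float(np.mean(v)) for c, v in sorted(cols.items())}
    extreme_row = max(row_means, key=lambda r: abs(row_means[r] - grand))
    extreme_col = max(col_means, key=lambda c: abs(col_means[c] - grand))

    cv_flags = {
        lvl: all(e[lvl]["cv_pct"] < spec.max_cv_pct for e in per_plate)
        for lvl in ("max", "mid")
    }
    return {
        "per_plate": per_plate,
        "between_plate_shift_pct": between_plate_shift_pct,
        "between_day_shift_pct": between_day_shift_pct,
        "row_means_max": row_means,
        "col_means_max": col_means,
        "extreme_row": extreme_row,
        "extreme_col": extreme_col,
        "cv_pass": cv_flags,
        "overall_pass": all(cv_flags.values()),
    }
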