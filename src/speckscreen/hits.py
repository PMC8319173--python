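"""Hit calling and campaign summaries for the single-concentration screen.

A library compound scores as an inhibitor hit when it reduces
control-normalized speck formation by at least 30% on a plate that
passed quality control.  Compounds that *increase* speck formation
beyond a symmetric margin are flagged separately as activators.
Compounds sitting on QC-failed plates are held out of the screened
denominator until a passing repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "HitCall",
    "ScreenSummary",
    "HitCallingError",
    "call_hits",
    "flag_activators",
    "duplicate_concordance",
]

DEFAULT_INHIBITION_THRESHOLD = 30.0


class HitCallingError(ValueError):
    pass


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    plate_id: str
    well: str
    pct_inhibition: float
    call: str  # inhibitor_hit | activator_flag | inactive
    qc_pass_of_parent_plate: bool


@dataclass(frozen=True)
class ScreenSummary:
    n_compounds_total: int        # all library compounds dosed, incl. failed plates
    n_compounds_screened: int     # compounds on QC-passing plates (the denominator)
    n_hits: int
    hit_rate_pct: float
    n_activator_flags: int
    n_plates: int
    n_plates_failed_qc: int
    plate_failure_rate_pct: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], op: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        hint = (
            " — run plate QC and control normalization first"
            if "plate_qc_pass" in missing or "pct_inhibition" in missing
            else ""
        )
        raise HitCallingError(f"{op}: missing columns {missing}{hint}")


def call_hits(
    normalized_table: pd.DataFrame,
    threshold_pct: float = DEFAULT_INHIBITION_THRESHOLD,
    activation_threshold_pct: float = DEFAULT_INHIBITION_THRESHOLD,
) -> tuple[list[HitCall], ScreenSummary]:
    """Apply the >= threshold% inhibition rule and summarize the campaign.

    The table must carry per-well ``pct_inhibition``/``pct_formation``
    (from control normalization) and a ``plate_qc_pass`` flag.  Rows
    with a ``role`` column are restricted to library wells.  The hit
    boundary is inclusive: exactly ``threshold_pct`` inhibition scores.
    Rates are reported to one decimal.
    """
    _require_columns(
        normalized_table,
        ["compound_id", "plate_id", "well", "pct_inhibition", "plate_qc_pass"],
        "call_hits",
    )
    df = normalized_table
    if "role" in df.columns:
        df = df[df["role"] == "library"]

    calls: list[HitCall] = []
    for row in df.itertuples(index=False):
        qc_ok = bool(row.plate_qc_pass)
        inhibition = float(row.pct_inhibition)
        if qc_ok and inhibition >= threshold_pct:
            call = "inhibitor_hit"
        elif qc_ok and -inhibition >= activation_threshold_pct:
            call = "activator_flag"
        else:
            call = "inactive"
        calls.append(
            HitCall(
                compound_id=str(row.compound_id),
                plate_id=str(row.plate_id),
                well=str(row.well),
                pct_inhibition=inhibition,
                call=call,
                qc_pass_of_parent_plate=qc_ok,
            )
        )

    n_total = len(calls)
    screened = [c for c in calls if c.qc_pass_of_parent_plate]
    n_hits = sum(c.call == "inhibitor_hit" for c in screened)
    n_act = sum(c.call == "activator_flag" for c in screened)
    plates = df["plate_id"].unique()
    failed = df.loc[~df["plate_qc_pass"].astype(bool), "plate_id"].unique()
    summary = ScreenSummary(
        n_compounds_total=n_total,
        n_compounds_screened=len(screened),
        n_hits=n_hits,
        hit_rate_pct=round(100.0 * n_hits / len(screened), 1) if screened else 0.0,
        n_activator_flags=n_act,
        n_plates=len(plates),
        n_plates_failed_qc=len(failed),
        plate_failure_rate_pct=round(100.0 * len(failed) / len(plates), 1)
        if len(plates)
        else 0.0,
    )
    return calls, summary


def flag_activators(
    normalized_table: pd.DataFrame, activation_threshold_pct: float = 30.0
) -> list[HitCall]:
    """Speck-increasing compounds: formation >= 100 + threshold percent.

    The activation margin mirrors the inhibition rule by symmetry and is
    inclusive at the boundary.
    """
    calls, _ = call_hits(
        normalized_table, activation_threshold_pct=activation_threshold_pct
    )
    return [c for c in calls if c.call == "activator_flag"]


def calls_to_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def duplicate_concordance(
    calls_r1: Sequence[HitCall], calls_r2: Sequence[HitCall]
) -> dict:
    """Cross-tabulate replicate-run calls for the duplicate screening phase.

    Returns the call-by-call contingency table, the fraction of
    compounds receiving the same call in both replicates, and the
    compounds hit in exactly one replicate.  Under the union rule a
    compound counts as a screen hit if it scores in either replicate.
    """
    m1 = {c.compound_id: c for c in calls_r1}
    m2 = {c.compound_id: c for c in calls_r2}
    if set(m1) != set(m2):
        diff = sorted(set(m1) ^ set(m2))
        raise HitCallingError(f"duplicate_concordance: compound sets differ: {diff}")
    compounds = sorted(m1)
    tab = pd.crosstab(
        pd.Series([m1[c].call for c in compounds], name="r1"),
        pd.Series([m2[c].call for c in compounds], name="r2"),
    )
    concordant = sum(m1[c].call == m2[c].call for c in compounds)
    single = sorted(
        c
        for c in compounds
        if (m1[c].call == "inhibitor_hit") ^ (m2[c].call == "inhibitor_hit")
    )
    union_hits = sorted(
        c
        for c in compounds
        if m1[c].call == "inhibitor_hit" or m2[c].call == "inhibitor_hit"
    )
    return {
        "table": tab,
        "fraction_concordant": concordant / len(compounds) if compounds else 1.0,
        "hit_in_one_replicate": single,
        "union_hits": union_hits,
    }
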