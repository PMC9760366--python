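"""Plate-level signal normalization and assay quality control.

Raw AlphaScreen counts are normalized to cell viability (nuclei numbers)
and expressed as percent of the vehicle-control mean, the convention under
which the control group anchors at exactly 100%. Assay robustness is
summarised by the Z'-factor, Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|,
computed from positive and negative assay-control wells; conditions
failing a viability gate (default: more than 20% toxicity relative to
vehicle) are flagged and excluded from hit calling, never silently
dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    InvalidWellError,
    MissingControlError,
    UndefinedSeparationError,
)
from .simgen import NEG_CTRL, POS_CTRL, VEHICLE

logger = logging.getLogger(__name__)

#: condition labels never treated as test compounds
ASSAY_CONTROL_LABELS = (POS_CTRL, NEG_CTRL)


def per_nucleus_signal(alpha_counts: float, nuclei: int) -> float:
    """Raw counts divided by the nuclei count of the same well.

    Raises :class:`InvalidWellError` for wells with zero nuclei; such
    wells carry no viable cells and are excluded downstream.
    """
    if not math.isfinite(alpha_counts) or alpha_counts < 0:
        raise InvalidWellError(f"alpha_counts must be finite and >= 0, got {alpha_counts!r}")
    if nuclei <= 0:
        raise InvalidWellError(f"well has no nuclei (nuclei={nuclei}); cannot normalize")
    return float(alpha_counts) / float(nuclei)


@dataclass
class ScreenTable:
    """Normalized screen: per-well percents plus a per-condition summary.

    ``wells`` adds ``per_nucleus`` and ``percent`` columns to the raw
    records; ``summary`` has one row per (context, condition) with columns
    ``context, condition, compound, dose, n, percent_mean, percent_sem,
    viability`` (and, after :func:`viability_gate`, ``viability_pass``).
    """

    wells: pd.DataFrame
    summary: pd.DataFrame
    control_label: str = VEHICLE

    def condition_values(self, context: str, condition: str) -> np.ndarray:
        w = self.wells
        sel = (w["context"] == context) & (w["condition"] == condition)
        return w.loc[sel, "percent"].to_numpy()


def percent_of_control(
    wells: pd.DataFrame, control_label: str = VEHICLE
) -> ScreenTable:
    """Normalize a raw well table to percent of the vehicle-control mean.

    Per-nucleus signals are divided, within each cell-line context, by the
    mean per-nucleus signal of that context's control wells and scaled to
    percent; the control group's mean is therefore exactly 100. Wells with
    zero nuclei are excluded (logged). Viability per condition is the mean
    nuclei count relative to the control's.
    """
    required = {"condition", "alpha_counts", "nuclei", "context"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")

    df = wells.copy()
    bad = df["nuclei"] <= 0
    if bad.any():
        logger.warning("excluding %d wells with zero nuclei", int(bad.sum()))
        df = df.loc[~bad].copy()

    df["per_nucleus"] = df["alpha_counts"] / df["nuclei"]

    out = []
    for context, sub in df.groupby("context", sort=False):
        ctrl = sub.loc[sub["condition"] == control_label]
        if len(ctrl) < 2:
            raise MissingControlError(
                f"context {context!r}: need >= 2 control wells "
                f"labelled {control_label!r}, found {len(ctrl)}")
        ctrl_mean = ctrl["per_nucleus"].mean()
        if ctrl_mean <= 0:
            raise MissingControlError(f"context {context!r}: control mean signal is zero")
        sub = sub.copy()
        sub["percent"] = sub["per_nucleus"] / ctrl_mean * 100.0
        sub["_ctrl_nuclei_mean"] = ctrl["nuclei"].mean()
        out.append(sub)
    df = pd.concat(out, ignore_index=True)

    if "compound" not in df.columns:
        df["compound"] = df["condition"]
    if "dose" not in df.columns:
        df["dose"] = np.nan

    grouped = df.groupby(["context", "condition"], sort=False)
    summary = grouped.agg(
        compound=("compound", "first"),
        dose=("dose", "first"),
        n=("percent", "size"),
        percent_mean=("percent", "mean"),
        percent_sem=("percent", "sem"),
        nuclei_mean=("nuclei", "mean"),
        ctrl_nuclei=("_ctrl_nuclei_mean", "first"),
    ).reset_index()
    summary["viability"] = summary["nuclei_mean"] / summary["ctrl_nuclei"]
    summary = summary.drop(columns=["nuclei_mean", "ctrl_nuclei"])
    df = df.drop(columns=["_ctrl_nuclei_mean"])
    return ScreenTable(wells=df, summary=summary, control_label=control_label)


@dataclass
class ZPrimeQC:
    """The four control moments and the Z'-factor they imply."""

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float

    @property
    def zprime(self) -> float:
        return 1.0 - 3.0 * (self.sigma_p + self.sigma_n) / abs(self.mu_p - self.mu_n)


def zprime(pos: np.ndarray, neg: np.ndarray) -> ZPrimeQC:
    """Z'-factor from positive- and negative-control samples.

    Uses sample standard deviations (n-1 denominator). Z' <= 1 always;
    values above ~0.5 mark an excellent assay. Symmetric in the two
    groups. Raises :class:`UndefinedSeparationError` when the means
    coincide and :class:`DegenerateDataError` for groups of fewer than
    two values.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateDataError("zprime needs >= 2 values per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise UndefinedSeparationError("control means coincide; Z' undefined")
    return ZPrimeQC(
        mu_p=mu_p,
        sigma_p=float(pos.std(ddof=1)),
        mu_n=mu_n,
        sigma_n=float(neg.std(ddof=1)),
    )


def plate_zprime(
    wells: pd.DataFrame,
    context: str | None = None,
    pos_label: str = POS_CTRL,
    neg_label: str = NEG_CTRL,
) -> ZPrimeQC:
    """Z'-factor of a raw plate from its assay-control wells.

    Controls are compared on the per-nucleus signal scale (the same scale
    the screen is read on). ``context`` restricts to one cell line.
    """
    df = wells if context is None else wells.loc[wells["context"] == context]
    sig = {}
    for label in (pos_label, neg_label):
        sub = df.loc[(df["condition"] == label) & (df["nuclei"] > 0)]
        if len(sub) < 2:
            raise MissingControlError(f"need >= 2 wells labelled {label!r} for Z'")
        sig[label] = (sub["alpha_counts"] / sub["nuclei"]).to_numpy()
    return zprime(sig[pos_label], sig[neg_label])


def viability_gate(table: ScreenTable, max_toxicity: float = 0.20) -> ScreenTable:
    """Flag conditions whose viability falls below ``1 - max_toxicity``.

    Adds a boolean ``viability_pass`` column to the summary; excluded
    conditions are reported via logging, never dropped, so downstream hit
    calling can skip them explicitly.
    """
    if not 0 <= max_toxicity < 1:
        raise ValueError("max_toxicity must lie in [0, 1)")
    summary = table.summary.copy()
    summary["viability_pass"] = summary["viability"] >= 1.0 - max_toxicity
    failed = summary.loc[~summary["viability_pass"], ["context", "condition"]]
    for _, row in failed.iterrows():
        logger.warning("condition %s (%s) excluded: toxicity above %.0f%%",
                       row["condition"], row["context"], 100 * max_toxicity)
    return ScreenTable(wells=table.wells, summary=summary,
                       control_label=table.control_label)
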