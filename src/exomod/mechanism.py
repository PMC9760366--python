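"""Hit calling and the dual-readout mechanism classifier.

A compound's extracellular (ExoScreen) and intracellular (LBPA granule)
percent-of-control readouts are each reduced to a three-level state —
LOW below the 80% cut-off, HIGH above the 120% cut-off, else UNCHANGED —
and the pair of states determines the mechanism call through a fixed,
total decision table:

* low extracellular with elevated intracellular LBPA means vesicles are
  made but not released (release inhibitor);
* low extracellular with low intracellular LBPA means vesicles are never
  made (biogenesis inhibitor);
* both readouts high marks a biogenesis activator.

By default the LOW call on the ExoScreen side follows the plain cut-off
while HIGH additionally requires Dunnett significance; the LBPA side
requires significance in both directions. Both behaviours are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import ExomodError
from .platescreen import ASSAY_CONTROL_LABELS, ScreenTable
from .screenstats import ComparisonResult, significance_stars

logger = logging.getLogger(__name__)

LOW_CUT = 80.0
HIGH_CUT = 120.0


class Level(str, Enum):
    LOW = "LOW"
    UNCHANGED = "UNCHANGED"
    HIGH = "HIGH"


class Mechanism(str, Enum):
    RELEASE_INHIBITOR = "RELEASE_INHIBITOR"
    BIOGENESIS_INHIBITOR = "BIOGENESIS_INHIBITOR"
    BIOGENESIS_ACTIVATOR = "BIOGENESIS_ACTIVATOR"
    INACTIVE = "INACTIVE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class ReadoutState:
    """One readout reduced to value / three-level state / significance."""

    value: float  # percent of control
    state: Level
    significant: bool


@dataclass
class MechanismCall:
    """Final per-compound label from the dual-readout decision table."""

    compound: str
    context: str
    exo: ReadoutState
    lbpa: ReadoutState
    call: Mechanism


#: the total decision table over all 3x3 state pairs (exo, lbpa).
#: Only three pairs carry a biological label; an ExoScreen hit without a
#: corroborating LBPA change (or with a contradictory one) stays
#: UNCLASSIFIED, and LBPA-only changes are INACTIVE (no hit).
DECISION_TABLE: dict[tuple[Level, Level], Mechanism] = {
    (Level.LOW, Level.HIGH): Mechanism.RELEASE_INHIBITOR,
    (Level.LOW, Level.LOW): Mechanism.BIOGENESIS_INHIBITOR,
    (Level.LOW, Level.UNCHANGED): Mechanism.UNCLASSIFIED,
    (Level.HIGH, Level.HIGH): Mechanism.BIOGENESIS_ACTIVATOR,
    (Level.HIGH, Level.LOW): Mechanism.UNCLASSIFIED,
    (Level.HIGH, Level.UNCHANGED): Mechanism.UNCLASSIFIED,
    (Level.UNCHANGED, Level.HIGH): Mechanism.INACTIVE,
    (Level.UNCHANGED, Level.LOW): Mechanism.INACTIVE,
    (Level.UNCHANGED, Level.UNCHANGED): Mechanism.INACTIVE,
}


def readout_state(
    percent: float,
    significant: bool,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
    require_significance_low: bool = False,
    require_significance_high: bool = True,
) -> ReadoutState:
    """Reduce a percent-of-control value to a three-level state.

    Cut-offs are strict inequalities: exactly 80.0 (or 120.0) is
    UNCHANGED. A direction whose ``require_significance_*`` flag is set
    falls back to UNCHANGED without a significant comparison.
    """
    if percent < low_cut and (significant or not require_significance_low):
        level = Level.LOW
    elif percent > high_cut and (significant or not require_significance_high):
        level = Level.HIGH
    else:
        level = Level.UNCHANGED
    return ReadoutState(value=float(percent), state=level, significant=bool(significant))


def _stats_lookup(stats: list[ComparisonResult]) -> dict[str, ComparisonResult]:
    return {r.condition: r for r in stats}


def call_exoscreen_hits(
    table: ScreenTable,
    stats: list[ComparisonResult],
    context: str,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
    require_significance_low: bool = False,
    require_significance_high: bool = True,
) -> dict[str, ReadoutState]:
    """Three-level ExoScreen state per gated condition of one context.

    LOW follows the plain cut-off (inhibitor side); HIGH additionally
    requires a significant Dunnett comparison (activator side). The
    vehicle control and the assay-control wells are not called;
    conditions excluded by the viability gate are skipped (logged). A
    condition missing from ``stats`` is an error.
    """
    by_cond = _stats_lookup(stats)
    summary = table.summary
    sel = summary["context"] == context
    gated = "viability_pass" in summary.columns
    out: dict[str, ReadoutState] = {}
    for _, row in summary.loc[sel].iterrows():
        cond = row["condition"]
        if cond == table.control_label or cond in ASSAY_CONTROL_LABELS:
            continue
        if gated and not row["viability_pass"]:
            logger.info("skipping %s (%s): failed viability gate", cond, context)
            continue
        if cond not in by_cond:
            raise ExomodError(f"condition {cond!r} missing from Dunnett results")
        out[cond] = readout_state(
            row["percent_mean"], by_cond[cond].significant,
            low_cut=low_cut, high_cut=high_cut,
            require_significance_low=require_significance_low,
            require_significance_high=require_significance_high,
        )
    return out


def lbpa_state(
    percent: float,
    stats: ComparisonResult | bool,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
) -> ReadoutState:
    """Three-level LBPA state; both directions require significance."""
    significant = stats.significant if isinstance(stats, ComparisonResult) else bool(stats)
    return readout_state(
        percent, significant, low_cut=low_cut, high_cut=high_cut,
        require_significance_low=True, require_significance_high=True,
    )


def classify_mechanism(exo: ReadoutState, lbpa: ReadoutState) -> Mechanism:
    """Look up the (exo, lbpa) state pair in the decision table.

    The table is total over all nine pairs, so this never fails; the
    classification is pure — identical states always yield the same call.
    """
    return DECISION_TABLE[(exo.state, lbpa.state)]


@dataclass
class ScreenReport:
    """Bundle of per-compound calls plus QC and dose-response context."""

    calls: pd.DataFrame          # context, compound, role, exo/lbpa %, states, call
    qc: pd.DataFrame             # context, mu/sigma of both controls, zprime
    trends: pd.DataFrame         # compound, statistic, permutation p, monotone
    inhibitor_counts: dict[str, int]

    def summary(self) -> str:
        lines = ["Screen summary", "=============="]
        for context, count in self.inhibitor_counts.items():
            hits = self.calls.loc[
                (self.calls["context"] == context)
                & (self.calls["role"] == "test")
                & (self.calls["exo_state"] == Level.LOW.value),
                "compound",
            ].tolist()
            lines.append(f"{context}: {count} inhibitor hit(s)"
                         + (f" ({', '.join(hits)})" if hits else ""))
        for _, row in self.qc.iterrows():
            lines.append(f"Z' [{row['context']}]: {row['zprime']:.3f}")
        if len(self.trends):
            mono = self.trends.loc[self.trends["monotone"], "compound"].tolist()
            lines.append("Dose-dependent inhibition: "
                         + (", ".join(mono) if mono else "none"))
        return "\n".join(lines)

    def to_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.calls.to_csv(d / "mechanism_calls.csv", index=False)
        self.qc.to_csv(d / "plate_qc.csv", index=False)
        self.trends.to_csv(d / "dose_trends.csv", index=False)


def screen_report(
    calls: list[MechanismCall],
    qc: pd.DataFrame | None = None,
    trends: pd.DataFrame | None = None,
    roles: dict[tuple[str, str], str] | None = None,
    stats_stars: dict[tuple[str, str], float] | None = None,
) -> ScreenReport:
    """Assemble the final report from per-compound mechanism calls.

    ``roles`` maps (context, compound) to "test" or "control"; unknown
    compounds default to "test". The inhibitor count per context counts
    test compounds with a LOW ExoScreen state (the screen's hit
    definition). An empty call list yields an empty, valid report.
    """
    rows = []
    for c in calls:
        role = (roles or {}).get((c.context, c.compound), "test")
        adj_p = (stats_stars or {}).get((c.context, c.compound))
        rows.append({
            "context": c.context,
            "compound": c.compound,
            "role": role,
            "exo_percent": c.exo.value,
            "exo_state": c.exo.state.value,
            "exo_significant": c.exo.significant,
            "lbpa_percent": c.lbpa.value,
            "lbpa_state": c.lbpa.state.value,
            "lbpa_significant": c.lbpa.significant,
            "call": c.call.value,
            "stars": significance_stars(adj_p) if adj_p is not None else "",
        })
    calls_df = pd.DataFrame(
        rows,
        columns=["context", "compound", "role", "exo_percent", "exo_state",
                 "exo_significant", "lbpa_percent", "lbpa_state",
                 "lbpa_significant", "call", "stars"],
    )
    counts: dict[str, int] = {}
    for context in calls_df["context"].unique():
        sel = (
            (calls_df["context"] == context)
            & (calls_df["role"] == "test")
            & (calls_df["exo_state"] == Level.LOW.value)
        )
        counts[str(context)] = int(sel.sum())
    qc = qc if qc is not None else pd.DataFrame(
        columns=["context", "mu_p", "sigma_p", "mu_n", "sigma_n", "zprime"])
    trends = trends if trends is not None else pd.DataFrame(
        columns=["compound", "statistic", "permutation_p", "direction", "monotone"])
    return ScreenReport(calls=calls_df, qc=qc, trends=trends,
                        inhibitor_counts=counts)
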