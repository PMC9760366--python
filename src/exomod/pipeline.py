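"""End-to-end orchestration: normalize, gate, test, call, classify.

:func:`analyze_screen` runs the full dual-readout analysis on a raw
ExoScreen well table plus a well-level LBPA table; :func:`analyze_reference_screen`
applies it to the deterministic packaged 14-compound fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import granulequant, mechanism, platescreen, screenstats, simgen


@dataclass
class ScreenAnalysis:
    """Everything the pipeline computed for one screen."""

    screen_table: platescreen.ScreenTable
    lbpa_table: pd.DataFrame
    exo_stats: dict[str, list[screenstats.ComparisonResult]]   # per context
    lbpa_stats: dict[str, list[screenstats.ComparisonResult]]
    calls: list[mechanism.MechanismCall]
    report: mechanism.ScreenReport


def _condition_groups(wells: pd.DataFrame, value_col: str, context: str,
                      control_label: str) -> tuple[dict[str, np.ndarray], np.ndarray]:
    sub = wells.loc[wells["context"] == context]
    control = sub.loc[sub["condition"] == control_label, value_col].to_numpy()
    groups = {
        str(cond): g[value_col].to_numpy()
        for cond, g in sub.groupby("condition", sort=False)
        if cond != control_label and cond not in platescreen.ASSAY_CONTROL_LABELS
    }
    return groups, control


def analyze_screen(
    exo_wells: pd.DataFrame,
    lbpa_wells: pd.DataFrame,
    dose_response: pd.DataFrame | None = None,
    control_label: str = simgen.VEHICLE,
    max_toxicity: float = 0.20,
    roles: dict[tuple[str, str], str] | None = None,
    seed: int = 0,
) -> ScreenAnalysis:
    """Run the full convergent analysis on raw well tables.

    Per context: percent-of-control normalization, viability gating,
    Dunnett many-to-one tests on both readouts, three-level state calls,
    decision-table classification, and (optionally) dose-response trend
    tests. Z'-factor QC is computed from the assay-control wells where
    present.
    """
    table = platescreen.percent_of_control(exo_wells, control_label)
    table = platescreen.viability_gate(table, max_toxicity)
    lbpa_pct = granulequant.lbpa_percent_of_control(lbpa_wells, control_label)

    contexts = list(table.summary["context"].unique())
    exo_stats: dict[str, list[screenstats.ComparisonResult]] = {}
    lbpa_stats: dict[str, list[screenstats.ComparisonResult]] = {}
    calls: list[mechanism.MechanismCall] = []
    qc_rows = []
    star_lookup: dict[tuple[str, str], float] = {}

    for context in contexts:
        groups, control = _condition_groups(
            table.wells, "percent", context, control_label)
        exo_stats[context] = screenstats.dunnett_many_to_one(
            groups, control, seed=seed)
        exo_states = mechanism.call_exoscreen_hits(
            table, exo_stats[context], context)

        lgroups, lcontrol = _condition_groups(
            lbpa_pct, "percent", context, control_label)
        lbpa_stats[context] = screenstats.dunnett_many_to_one(
            lgroups, lcontrol, seed=seed)
        lbpa_by_cond = {r.condition: r for r in lbpa_stats[context]}

        for cond, exo_state in exo_states.items():
            if cond not in lbpa_by_cond:
                continue  # no intracellular readout for this condition
            lr = lbpa_by_cond[cond]
            lstate = mechanism.lbpa_state(lr.mean, lr)
            calls.append(mechanism.MechanismCall(
                compound=cond, context=context,
                exo=exo_state, lbpa=lstate,
                call=mechanism.classify_mechanism(exo_state, lstate),
            ))
            star_lookup[(context, cond)] = next(
                r.adjusted_p for r in exo_stats[context] if r.condition == cond)

        has_ctrl_wells = {
            lab: ((exo_wells["context"] == context)
                  & (exo_wells["condition"] == lab)).sum() >= 2
            for lab in platescreen.ASSAY_CONTROL_LABELS
        }
        if all(has_ctrl_wells.values()):
            qc = platescreen.plate_zprime(exo_wells, context=context)
            qc_rows.append({"context": context, "mu_p": qc.mu_p,
                            "sigma_p": qc.sigma_p, "mu_n": qc.mu_n,
                            "sigma_n": qc.sigma_n, "zprime": qc.zprime})

    trend_rows = []
    if dose_response is not None and len(dose_response):
        for compound, sub in dose_response.groupby("compound", sort=False):
            doses = sorted(sub["dose"].unique())
            if len(doses) < 3:
                continue
            values = [sub.loc[sub["dose"] == d, "percent"].to_numpy()
                      for d in doses]
            tr = screenstats.trend_test(doses, values, compound=str(compound),
                                        seed=seed)
            trend_rows.append({"compound": tr.compound,
                               "statistic": tr.statistic,
                               "permutation_p": tr.permutation_p,
                               "direction": tr.direction,
                               "monotone": tr.monotone})

    report = mechanism.screen_report(
        calls,
        qc=pd.DataFrame(qc_rows) if qc_rows else None,
        trends=pd.DataFrame(trend_rows) if trend_rows else None,
        roles=roles,
        stats_stars=star_lookup,
    )
    return ScreenAnalysis(screen_table=table, lbpa_table=lbpa_pct,
                          exo_stats=exo_stats, lbpa_stats=lbpa_stats,
                          calls=calls, report=report)


def analyze_reference_screen(seed: int = 0) -> ScreenAnalysis:
    """Run the full analysis on the packaged deterministic 14-compound
    two-context fixture (breast-cancer screen conditions)."""
    ref = simgen.generate_reference_screen()
    roles = {(r.context, r.compound): r.role
             for r in ref.classes.itertuples(index=False)}
    return analyze_screen(
        ref.exoscreen, ref.lbpa, dose_response=ref.dose_response,
        roles=roles, seed=seed,
    )
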