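"""Four-category conformational-state classification of repeated runs.

Repeated equilibrations of a low-affinity (LA) alpha-I domain show four
qualitatively different behaviours of the alpha7 helix, read off two
core-aligned helix RMSD series (against the LA and the high-affinity, HA,
crystal references) plus the swing-out angle series:

1. **stay-LA** -- the helix keeps its LA placement: RMSD to LA stays low,
   RMSD to HA stays high.
2. **swing-in / slight downward drift** -- the two reference series
   approach each other and converge at a conformation matching neither
   crystal endpoint.
3. **large downward transition** -- the descending-HA / ascending-LA
   crossover of a spontaneous LA -> intermediate/HA transition.
4. **swing-out** -- the helix axis rotates away (tens of degrees); both
   RMSD series are high and fluctuating.

The categories come from visual inspection in the source study; the
numeric decision rule here is this module's own operationalisation.  All
thresholds are explicit, documented parameters; each call reports the
evidence (tail means, gap, drop, swing) so borderline runs surface
instead of being silently forced into a bin.  Rules are evaluated in
priority order 4 -> 3 -> 2 -> 1 (swing-out is geometrically the most
distinctive); if no rule fires the category with the strongest margin is
chosen and the call is flagged as a fallback.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observables import SwingAngleSeries
from .superpose import RMSDSeries

__all__ = [
    "CATEGORY_LABELS",
    "ClassifierParams",
    "StateCall",
    "classify_run",
    "classify_replicates",
]

CATEGORY_LABELS = {
    1: "stay-LA",
    2: "swing-in/slight-down",
    3: "large-downward-transition",
    4: "swing-out",
}


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of the decision rule.

    tail_window : ns
        Portion at the end of the run summarised by the tail statistics
        (and, mirrored at the start, by the head statistics).
    low_rmsd : A
        A tail-mean RMSD at or below this counts as "still at the
        reference" (category 1 against the LA reference).
    high_rmsd : A
        Tail means at or above this against *both* references mark a
        conformation far from every crystal endpoint (category 4 branch).
    convergence_gap : A
        Maximal |LA-tail - HA-tail| for the two series to count as
        converged (category 2); category 3 additionally requires the LA
        series to end *above* the HA series by more than this gap, which
        keeps converged runs out of the transition bin.
    transition_drop : A
        Required decrease of the HA-reference series from the head window
        to the tail window for category 3.
    swingout_min : degrees
        Minimal tail-mean swing-out angle for category 4.
    fluctuation_sd : A
        Tail standard deviation above which a series counts as
        "fluctuating" (category 4's second branch).
    """

    tail_window: float = 4.0
    low_rmsd: float = 2.5
    high_rmsd: float = 5.0
    convergence_gap: float = 1.5
    transition_drop: float = 3.0
    swingout_min: float = 25.0
    fluctuation_sd: float = 1.0

    def __post_init__(self):
        if self.low_rmsd >= self.high_rmsd:
            raise ValueError("low_rmsd must be < high_rmsd")
        for name in (
            "tail_window", "low_rmsd", "high_rmsd", "convergence_gap",
            "transition_drop", "swingout_min", "fluctuation_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StateCall:
    """One classified run: category, rule that fired, and its evidence."""

    category: int
    rule: str
    evidence: dict[str, float]
    notes: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self.category]


def _window_stats(times: np.ndarray, values: np.ndarray, window: float):
    tail = times >= times[-1] - window
    head = times <= times[0] + window
    return (
        float(np.mean(values[tail])),
        float(np.std(values[tail])),
        float(np.mean(values[head])),
    )


def classify_run(
    series_la: RMSDSeries,
    series_ha: RMSDSeries,
    swing: SwingAngleSeries,
    params: ClassifierParams = ClassifierParams(),
    series_ia: RMSDSeries | None = None,
) -> StateCall:
    """Classify one equilibration run into one of the four categories.

    ``series_la`` / ``series_ha`` are the core-aligned alpha7 RMSD series
    against the LA and HA crystal references; ``swing`` is the swing-out
    angle series on the same time base.  An optional intermediate-affinity
    series only annotates the evidence of a category-3 call (whether the
    run ends closer to the IA than the HA endpoint); it takes no part in
    the decision.
    """
    times = series_la.times
    for other, label in ((series_ha, "HA"), (swing, "swing")):
        other_times = other.times
        if len(other_times) != len(times) or not np.allclose(other_times, times):
            raise ValueError(f"{label} series does not share the LA series time base")
    span = times[-1] - times[0]
    if params.tail_window > span:
        raise ValueError(
            f"tail_window {params.tail_window} ns exceeds run span {span:.3g} ns"
        )

    tail_la, sd_la, head_la = _window_stats(times, series_la.values, params.tail_window)
    tail_ha, sd_ha, head_ha = _window_stats(times, series_ha.values, params.tail_window)
    tail_swing = float(np.mean(swing.angles_deg[times >= times[-1] - params.tail_window]))
    gap = abs(tail_la - tail_ha)
    drop = head_ha - tail_ha

    evidence = {
        "tail_la_A": tail_la,
        "tail_ha_A": tail_ha,
        "tail_sd_la_A": sd_la,
        "tail_sd_ha_A": sd_ha,
        "head_ha_A": head_ha,
        "tail_swing_deg": tail_swing,
        "gap_A": gap,
        "ha_drop_A": drop,
    }
    notes: list[str] = []
    if series_ia is not None:
        tail_ia, _, _ = _window_stats(times, series_ia.values, params.tail_window)
        evidence["tail_ia_A"] = tail_ia

    fluctuating = sd_la > params.fluctuation_sd or sd_ha > params.fluctuation_sd
    both_high = tail_la >= params.high_rmsd and tail_ha >= params.high_rmsd

    if tail_swing >= params.swingout_min or (both_high and fluctuating):
        rule = (
            "swing-out: tail swing angle >= swingout_min"
            if tail_swing >= params.swingout_min
            else "swing-out: both reference RMSDs high and fluctuating"
        )
        return StateCall(4, rule, evidence, notes)
    # Category 3 requires the run to *end* clearly nearer the HA endpoint
    # (LA tail above HA tail by more than the convergence gap); a merely
    # converged run (category 2) also shows a large HA drop, and this
    # margin is what separates the two.
    if drop >= params.transition_drop and tail_la - tail_ha > params.convergence_gap:
        if series_ia is not None:
            notes.append(
                "tail IA < tail HA"
                if evidence["tail_ia_A"] < tail_ha
                else "tail IA >= tail HA"
            )
        return StateCall(3, "transition: HA series dropped and run ends HA-like", evidence, notes)
    if gap <= params.convergence_gap:
        return StateCall(2, "convergence: reference series meet off both endpoints", evidence, notes)
    if tail_la <= params.low_rmsd and tail_ha > tail_la:
        return StateCall(1, "stay-LA: low RMSD to LA, higher to HA", evidence, notes)

    margins = {
        1: params.low_rmsd - tail_la,
        2: params.convergence_gap - gap,
        3: min(drop - params.transition_drop, (tail_la - tail_ha) - params.convergence_gap),
        4: tail_swing - params.swingout_min,
    }
    category = max(margins, key=lambda c: margins[c])
    evidence.update({f"margin_{c}": m for c, m in margins.items()})
    notes.append("fallback: no rule fired, strongest margin chosen")
    return StateCall(category, "fallback: strongest margin", evidence, notes)


def classify_replicates(runs, params: ClassifierParams = ClassifierParams()):
    """Classify a list of runs and tally the category census.

    ``runs`` is a sequence of ``(series_la, series_ha, swing)`` or
    ``(series_la, series_ha, swing, series_ia)`` tuples.  A run that
    raises is skipped with a warning; its error does not abort the batch.

    Returns
    -------
    (list of StateCall, dict)
        Per-run calls (None for skipped runs) and a census mapping every
        category 1-4 to its count.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to classify")
    calls: list[StateCall | None] = []
    counter: Counter[int] = Counter()
    for i, run in enumerate(runs):
        try:
            series_la, series_ha, swing, *rest = run
            call = classify_run(
                series_la, series_ha, swing, params=params,
                series_ia=rest[0] if rest else None,
            )
        except Exception as err:  # propagate per-run problems as warnings
            warnings.warn(f"run {i + 1} skipped: {err}", stacklevel=2)
            calls.append(None)
            continue
        calls.append(call)
        counter[call.category] += 1
    census = {category: counter.get(category, 0) for category in CATEGORY_LABELS}
    return calls, census


def calls_to_frame(calls, run_names=None) -> pd.DataFrame:
    """Tabulate per-run calls (evidence columns flattened) for CSV export."""
    rows = []
    for i, call in enumerate(calls):
        name = run_names[i] if run_names else f"run{i + 1}"
        if call is None:
            rows.append({"run": name, "category": None, "label": "skipped"})
            continue
        row = {"run": name, "category": call.category, "label": call.label,
               "rule": call.rule, "notes": "; ".join(call.notes)}
        row.update(call.evidence)
        rows.append(row)
    return pd.DataFrame(rows)
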