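"""Trial scoring, participant exclusion and CCE computation.

The crossmodal congruency effect (CCE) for a cell is the mean RT of
correct incongruent trials minus the mean RT of correct congruent
trials, computed per participant, condition and laterality
(ipsilateral: visual distractor on the same side as the stimulated
hand).  The per-participant quantity carried into the hypothesis models
is ``d_ms``, the ipsilateral-minus-contralateral CCE difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgen import RESPONSE_TOKENS

__all__ = [
    "ExclusionReport",
    "score_trials",
    "exclude_low_accuracy",
    "compute_cce",
    "cce_difference",
    "derive_trial_labels",
]

log = logging.getLogger(__name__)

_EXPECTED_BY_KIND = {"control_light": "LUCI", "false_stimulation": "NIENTE"}


@dataclass
class ExclusionReport:
    threshold: float
    accuracies: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    no_scorable_trials: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "accuracies": self.accuracies,
            "excluded": self.excluded,
            "no_scorable_trials": self.no_scorable_trials,
        }


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a boolean ``correct`` column.

    Experimental trials are correct iff the token matches the tactile
    elevation (TAH = high, TOH = low); control-light trials expect LUCI;
    false-stimulation trials expect NIENTE.  Unknown tokens raise, naming
    the offending rows.
    """
    trials = trials.copy()
    bad = ~trials["response"].isin(RESPONSE_TOKENS)
    if bad.any():
        rows = trials.index[bad].tolist()[:10]
        raise ValueError(
            f"unknown response token(s) in rows {rows}: "
            f"{sorted(trials.loc[bad, 'response'].unique())}")

    expected = trials["trial_kind"].map(_EXPECTED_BY_KIND)
    exp_mask = trials["trial_kind"] == "experimental"
    expected = expected.where(
        ~exp_mask,
        np.where(trials["tactile_elevation"] == "high", "TAH", "TOH"))
    trials["correct"] = trials["response"] == expected
    return trials


def derive_trial_labels(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive congruency and laterality labels for experimental trials."""
    trials = trials.copy()
    exp = trials["trial_kind"] == "experimental"
    trials["congruent"] = pd.array([pd.NA] * len(trials), dtype="boolean")
    trials.loc[exp, "congruent"] = (
        trials.loc[exp, "tactile_elevation"] == trials.loc[exp, "visual_elevation"])
    lat = pd.Series(pd.NA, index=trials.index, dtype="object")
    lat[exp] = np.where(
        trials.loc[exp, "tactile_hand"] == trials.loc[exp, "visual_side"],
        "ipsilateral", "contralateral")
    trials["laterality"] = lat
    return trials


def exclude_low_accuracy(
    trials: pd.DataFrame,
    threshold: float = 0.44,
    include_control: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participants whose accuracy is <= ``threshold``.

    Accuracy is counted over experimental + false-stimulation trials;
    control-light (yellow LED) trials are excluded from the count unless
    ``include_control`` is set.  Participants with no scorable trials are
    excluded and flagged.
    """
    if "correct" not in trials.columns:
        trials = score_trials(trials)
    scorable = trials if include_control else trials[
        trials["trial_kind"] != "control_light"]

    report = ExclusionReport(threshold=threshold)
    for pid, sub in scorable.groupby("participant_id", sort=True):
        if len(sub) == 0:
            continue
        acc = float(sub["correct"].mean())
        report.accuracies[str(pid)] = acc
        if acc <= threshold:
            report.excluded.append(str(pid))

    all_pids = set(map(str, trials["participant_id"].unique()))
    scored_pids = set(report.accuracies)
    for pid in sorted(all_pids - scored_pids):
        report.no_scorable_trials.append(pid)
        report.excluded.append(pid)
    report.excluded.sort()

    kept = trials[~trials["participant_id"].astype(str).isin(report.excluded)]
    if report.excluded:
        log.info("excluded %d participant(s) at accuracy <= %.0f%%: %s",
                 len(report.excluded), 100 * threshold, report.excluded)
    return kept.copy(), report


def compute_cce(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, condition, laterality) CCE in ms.

    Uses correct experimental trials only.  A cell with no correct trials
    on one side of the congruency contrast yields a missing (NaN) CCE and
    a logged warning.
    """
    if "correct" not in trials.columns:
        trials = score_trials(trials)
    if "laterality" not in trials.columns:
        trials = derive_trial_labels(trials)

    exp = trials[(trials["trial_kind"] == "experimental") & trials["correct"]]
    keys = ["participant_id", "group", "condition", "laterality"]
    have_group = "group" in trials.columns
    if not have_group:
        keys.remove("group")

    rows = []
    full = trials[trials["trial_kind"] == "experimental"]
    full = full if "congruent" in full.columns else derive_trial_labels(full)
    for key_vals, _ in full.groupby(keys, sort=True):
        sub = exp
        for k, v in zip(keys, key_vals):
            sub = sub[sub[k] == v]
        cong = sub.loc[sub["congruent"] == True, "rt_ms"]  # noqa: E712
        incong = sub.loc[sub["congruent"] == False, "rt_ms"]  # noqa: E712
        row = dict(zip(keys, key_vals))
        if len(cong) == 0 or len(incong) == 0:
            row["cce_ms"] = np.nan
            log.warning("empty congruency cell after rejection: %s", row)
        else:
            row["cce_ms"] = float(incong.mean() - cong.mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["cce_ms"])


def cce_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Ipsilateral-minus-contralateral CCE per (participant, condition).

    Rows missing one laterality (or with a NaN CCE) are skipped and
    reported via a log warning.
    """
    keys = [c for c in ("participant_id", "group", "condition")
            if c in table.columns]
    rows = []
    for key_vals, sub in table.groupby(keys, sort=True):
        by_lat = sub.set_index("laterality")["cce_ms"]
        if ("ipsilateral" not in by_lat.index
                or "contralateral" not in by_lat.index
                or by_lat[["ipsilateral", "contralateral"]].isna().any()):
            log.warning("missing laterality for %s; row skipped",
                        dict(zip(keys, key_vals)))
            continue
        row = dict(zip(keys, key_vals))
        row["d_ms"] = float(by_lat["ipsilateral"] - by_lat["contralateral"])
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["d_ms"])
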