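"""Synthetic crossmodal-congruency-task (CCT) data generation.

Produces trial tables, Likert questionnaire tables and voice-response
waveforms with the statistical structure the downstream analyses assume,
so every stage of the pipeline is testable without external data.

Design of a session, per condition: ``trials_per_combo`` repetitions of
each of the 16 visuo-tactile combinations (2 tactile hands x 2 tactile
elevations x 2 visual sides x 2 visual elevations), plus control-light
trials (expected response token LUCI) and false-stimulation trials
(expected token NIENTE).  With the defaults (9/9/9) that is 162 trials
per condition, 144 of them experimental.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "EffectSpec",
    "LikertProfile",
    "TRIAL_COLUMNS",
    "RESPONSE_TOKENS",
    "QUESTIONNAIRE_COMPONENTS",
    "generate_cct_dataset",
    "generate_questionnaire",
    "generate_voice_wav",
    "default_control_profile",
    "likert_cell_probabilities",
    "likert_expected_score",
    "write_wav",
    "read_wav",
]

RESPONSE_TOKENS = ("TAH", "TOH", "LUCI", "NIENTE")

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "block",
    "trial_kind",
    "tactile_hand",
    "tactile_elevation",
    "visual_side",
    "visual_elevation",
    "response",
    "rt_ms",
]

QUESTIONNAIRE_COMPONENTS = ("embodiment", "loss", "movement", "compliance")

# Stimulus timing constants carried as metadata (not simulated): three
# 50 ms tactile pulses separated by 50 ms gaps, visual distractor
# leading the tactile train by 30 ms.
STIMULUS_TIMING_MS = {
    "pulse_ms": 50,
    "gap_ms": 50,
    "n_pulses": 3,
    "visual_lead_ms": 30,
}

_HANDS = ("left", "right")
_ELEVATIONS = ("high", "low")
_SIDES = ("left", "right")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of a CCT session."""

    groups: tuple[str, ...] = ("control",)
    conditions: tuple[str, ...] = ("real", "fake", "void")
    n_participants_per_group: int = 18
    n_blocks: int = 3
    trials_per_combo: int = 9
    n_control: int = 9
    n_false: int = 9

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.groups or not self.conditions:
            raise ValueError("groups and conditions must be non-empty")
        for name, value in [
            ("n_participants_per_group", self.n_participants_per_group),
            ("n_blocks", self.n_blocks),
            ("trials_per_combo", self.trials_per_combo),
        ]:
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_control < 0 or self.n_false < 0:
            raise ValueError("n_control and n_false must be >= 0")

    @property
    def n_experimental_per_condition(self) -> int:
        return self.trials_per_combo * 16

    @property
    def n_trials_per_condition(self) -> int:
        return self.n_experimental_per_condition + self.n_control + self.n_false


@dataclass(frozen=True)
class EffectSpec:
    """Per-group generative RT model for a CCT session.

    ``cce_contra_ms[c]`` is the incongruency cost on contralateral trials
    in condition ``c``; ``cce_ipsi_extra_ms[c]`` is the additional cost on
    ipsilateral trials (zero means no ipsi-vs-contra difference, i.e. the
    signature of the spatial-representation effect is absent).
    """

    baseline_rt_ms: float = 650.0
    participant_sd_ms: float = 40.0
    residual_sd_ms: float = 150.0
    cce_contra_ms: dict[str, float] = field(default_factory=dict)
    cce_ipsi_extra_ms: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.07
    rt_family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.baseline_rt_ms <= 0:
            raise ValueError("baseline_rt_ms must be positive")
        if self.participant_sd_ms < 0:
            raise ValueError("participant_sd_ms must be non-negative")
        if self.residual_sd_ms < 0:
            raise ValueError("residual_sd_ms must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.rt_family not in ("lognormal", "normal"):
            raise ValueError("rt_family must be 'lognormal' or 'normal'")

    def contra(self, condition: str) -> float:
        return float(self.cce_contra_ms.get(condition, 0.0))

    def ipsi_extra(self, condition: str) -> float:
        return float(self.cce_ipsi_extra_ms.get(condition, 0.0))


@dataclass(frozen=True)
class LikertProfile:
    """Latent-logistic locations for 1-10 Likert generation.

    ``locations`` maps (component, condition, time) to a location on the
    latent logit scale; ``dispersion`` is the common latent scale.  Scores
    are drawn from the implied 10-category cut-point distribution.
    """

    locations: dict[tuple[str, str, str], float]
    dispersion: float = 1.0
    n_categories: int = 10

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def location(self, component: str, condition: str, time: str) -> float:
        key = (component, condition, time)
        if key not in self.locations:
            raise ValueError(f"LikertProfile has no cell {key!r}")
        return self.locations[key]


def _wrong_token(expected: str, rng: np.random.Generator) -> str:
    choices = [t for t in RESPONSE_TOKENS if t != expected]
    return choices[rng.integers(len(choices))]


def _draw_rt(mean_ms: np.ndarray, residual_sd: float, family: str,
             rng: np.random.Generator) -> np.ndarray:
    """Draw RTs with E[rt] = mean_ms and SD ~= residual_sd."""
    mean_ms = np.asarray(mean_ms, dtype=float)
    if residual_sd == 0.0:
        return mean_ms.copy()
    if family == "normal":
        return mean_ms + rng.normal(0.0, residual_sd, size=mean_ms.shape)
    # mean-preserving lognormal: rt = mean * exp(z - s^2/2), z ~ N(0, s^2)
    s2 = np.log1p((residual_sd / mean_ms) ** 2)
    z = rng.normal(0.0, 1.0, size=mean_ms.shape)
    return mean_ms * np.exp(np.sqrt(s2) * z - s2 / 2.0)


def generate_cct_dataset(
    design: ExperimentDesign,
    effects: dict[str, EffectSpec] | EffectSpec,
    seed: int,
) -> pd.DataFrame:
    """Generate a full trial table for every participant in the design.

    Returns a DataFrame with one row per trial (columns ``TRIAL_COLUMNS``).
    Incongruent experimental trials are slower by ``cce_contra_ms`` on
    contralateral trials and by ``cce_contra_ms + cce_ipsi_extra_ms`` on
    ipsilateral trials.  Each trial is independently marked incorrect with
    probability ``error_rate`` (a uniformly random wrong token is logged).
    """
    if isinstance(effects, EffectSpec):
        effects = {g: effects for g in design.groups}
    missing = [g for g in design.groups if g not in effects]
    if missing:
        raise ValueError(f"no EffectSpec for groups: {missing}")

    rng = np.random.default_rng(seed)
    combos = list(itertools.product(_HANDS, _ELEVATIONS, _SIDES, _ELEVATIONS))
    rows: list[dict] = []

    for group in design.groups:
        eff = effects[group]
        for i in range(design.n_participants_per_group):
            pid = f"{group}_{i + 1:02d}"
            p_shift = rng.normal(0.0, eff.participant_sd_ms) if eff.participant_sd_ms else 0.0
            for condition in design.conditions:
                trials: list[dict] = []
                for hand, t_elev, v_side, v_elev in combos:
                    for _ in range(design.trials_per_combo):
                        trials.append({
                            "trial_kind": "experimental",
                            "tactile_hand": hand,
                            "tactile_elevation": t_elev,
                            "visual_side": v_side,
                            "visual_elevation": v_elev,
                        })
                for _ in range(design.n_control):
                    trials.append({"trial_kind": "control_light"})
                for _ in range(design.n_false):
                    trials.append({"trial_kind": "false_stimulation"})
                order = rng.permutation(len(trials))
                for j, k in enumerate(order):
                    t = dict(trials[k])
                    t["participant_id"] = pid
                    t["group"] = group
                    t["condition"] = condition
                    t["block"] = j * design.n_blocks // len(trials) + 1
                    rows.append(t)
                block_rows = rows[-len(trials):]
                means = np.empty(len(trials))
                for j, t in enumerate(block_rows):
                    shift = 0.0
                    if t["trial_kind"] == "experimental":
                        congruent = t["tactile_elevation"] == t["visual_elevation"]
                        ipsi = t["tactile_hand"] == t["visual_side"]
                        if not congruent:
                            shift = eff.contra(condition)
                            if ipsi:
                                shift += eff.ipsi_extra(condition)
                    means[j] = eff.baseline_rt_ms + p_shift + shift
                rts = _draw_rt(means, eff.residual_sd_ms, eff.rt_family, rng)
                wrong = rng.random(len(trials)) < eff.error_rate
                for j, t in enumerate(block_rows):
                    if t["trial_kind"] == "experimental":
                        expected = "TAH" if t["tactile_elevation"] == "high" else "TOH"
                    elif t["trial_kind"] == "control_light":
                        expected = "LUCI"
                    else:
                        expected = "NIENTE"
                    t["response"] = _wrong_token(expected, rng) if wrong[j] else expected
                    t["rt_ms"] = float(rts[j])

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    for col in ("tactile_hand", "tactile_elevation"):
        df.loc[df["trial_kind"] != "experimental", col] = pd.NA
    return df


# ---------------------------------------------------------------------------
# Likert questionnaire generation


def _cutpoints(n_categories: int) -> np.ndarray:
    # equidistant, symmetric about 0: for K=10 -> -4, -3, ..., 4
    k = n_categories
    return np.arange(1, k) - k / 2.0


def likert_cell_probabilities(location: float, dispersion: float = 1.0,
                              n_categories: int = 10) -> np.ndarray:
    """Category probabilities of the latent-logistic cut-point model."""
    cuts = _cutpoints(n_categories)
    cdf = 1.0 / (1.0 + np.exp(-(cuts - location) / dispersion))
    cdf = np.concatenate([[0.0], cdf, [1.0]])
    return np.diff(cdf)


def likert_expected_score(location: float, dispersion: float = 1.0,
                          n_categories: int = 10) -> float:
    p = likert_cell_probabilities(location, dispersion, n_categories)
    return float(np.sum(p * np.arange(1, n_categories + 1)))


def generate_questionnaire(
    design: ExperimentDesign,
    profile: LikertProfile,
    seed: int,
    times: tuple[str, ...] = ("before", "after"),
    components: tuple[str, ...] = QUESTIONNAIRE_COMPONENTS,
    items_per_component: int = 2,
) -> pd.DataFrame:
    """Generate questionnaire answers: two items per component per cell.

    Returns one row per (participant, condition, time, component, item)
    with an integer score in 1..n_categories.  Raises if the profile does
    not cover every (component, condition, time) cell.
    """
    for comp in components:
        for cond in design.conditions:
            for time in times:
                profile.location(comp, cond, time)  # raises on missing cell

    rng = np.random.default_rng(seed)
    scores = np.arange(1, profile.n_categories + 1)
    rows = []
    for group in design.groups:
        for i in range(design.n_participants_per_group):
            pid = f"{group}_{i + 1:02d}"
            for cond in design.conditions:
                for time in times:
                    for comp in components:
                        p = likert_cell_probabilities(
                            profile.location(comp, cond, time),
                            profile.dispersion, profile.n_categories)
                        drawn = rng.choice(scores, size=items_per_component, p=p)
                        for item, sc in enumerate(drawn, start=1):
                            rows.append({
                                "participant_id": pid,
                                "group": group,
                                "condition": cond,
                                "time": time,
                                "component": comp,
                                "item": item,
                                "score": int(sc),
                            })
    return pd.DataFrame(rows)


def default_control_profile(
    conditions: tuple[str, ...] = ("real", "fake", "void"),
    times: tuple[str, ...] = ("before", "after"),
) -> LikertProfile:
    """A control-group-like profile: strong embodiment of the own (real)
    feet, floor-level embodiment elsewhere, floor loss/movement, high
    compliance everywhere."""
    locations: dict[tuple[str, str, str], float] = {}
    for cond in conditions:
        for time in times:
            locations[("embodiment", cond, time)] = 8.0 if cond == "real" else -8.0
            locations[("loss", cond, time)] = -8.0
            locations[("movement", cond, time)] = -8.0
            locations[("compliance", cond, time)] = 2.8
    return LikertProfile(locations=locations)


# ---------------------------------------------------------------------------
# Voice-response audio


def generate_voice_wav(
    onset_ms: float,
    duration_ms: float,
    sample_rate: int = 8000,
    noise_amplitude: float = 0.0,
    voice_amplitude: float = 0.5,
    voiced_ms: float = 300.0,
    f0_hz: float = 140.0,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Synthesize a mono voice-response waveform.

    Low-amplitude noise before ``onset_ms``, then a voiced (high-energy,
    amplitude-modulated harmonic) segment of ``voiced_ms``.  Returns
    ``(waveform, true_onset_sample)`` so tests can compare detected
    onsets against ground truth.
    """
    if onset_ms < 0:
        raise ValueError("onset_ms must be non-negative")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be non-negative")
    n = int(round(duration_ms * sample_rate / 1000.0))
    onset = int(round(onset_ms * sample_rate / 1000.0))
    n_voiced = int(round(voiced_ms * sample_rate / 1000.0))
    if onset + n_voiced > n:
        raise ValueError(
            f"voiced segment (onset {onset_ms} ms + {voiced_ms} ms) "
            f"does not fit within duration {duration_ms} ms")
    rng = np.random.default_rng(seed)
    wave = rng.normal(0.0, 1.0, size=n) * noise_amplitude
    t = np.arange(n_voiced) / sample_rate
    envelope = np.sin(np.pi * np.arange(n_voiced) / max(n_voiced, 1)) ** 0.5
    voiced = voice_amplitude * envelope * (
        np.sin(2 * np.pi * f0_hz * t)
        + 0.5 * np.sin(2 * np.pi * 2 * f0_hz * t)
        + 0.25 * np.sin(2 * np.pi * 3 * f0_hz * t))
    wave[onset:onset + n_voiced] += voiced
    return wave, onset


def write_wav(path, waveform: np.ndarray, sample_rate: int = 8000) -> None:
    """Write a float waveform in [-1, 1] as 16-bit PCM mono WAV."""
    import wave as _wave

    clipped = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    pcm = (clipped * 32767.0).astype("<i2")
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(sample_rate)
        fh.writeframes(pcm.tobytes())


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a 16-bit PCM mono WAV into a float waveform in [-1, 1]."""
    import wave as _wave

    with _wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1:
            raise ValueError("only mono WAV files are supported")
        if fh.getsampwidth() != 2:
            raise ValueError("only 16-bit PCM WAV files are supported")
        sr = fh.getframerate()
        data = np.frombuffer(fh.readframes(fh.getnframes()), dtype="<i2")
    return data.astype(float) / 32767.0, sr
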