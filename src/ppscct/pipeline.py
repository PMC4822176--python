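"""End-to-end experiment pipelines.

Builds the hypothesis spaces for the three CCT analyses and the
questionnaire, composes generation -> preprocessing -> model comparison,
and writes reproducible JSON reports.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, synthgen
from .bayes_models import (
    DEFAULT_LINEAR_PRIORS,
    DEFAULT_LOGIT_PRIORS,
    GaussianFamily,
    HypothesisSpec,
    OrdinalFamily,
    RegressionProblem,
    ordinal_problem_from_table,
    problem_from_table,
)
from .product_space import MCMCConfig, fit_pseudo_priors, run_product_space

__all__ = [
    "ExperimentConfig",
    "build_hypothesis_space_exp1",
    "build_hypothesis_space_exp2",
    "build_hypothesis_space_exp3",
    "build_questionnaire_hypotheses",
    "run_experiment",
    "load_config",
]

log = logging.getLogger(__name__)


def _subset_id(prefix: str, active: tuple[str, ...]) -> str:
    return f"{prefix}:" + "+".join(active) if active else "none"


def _binary_space(prefix: str, effects: tuple[str, ...],
                  priors) -> list[HypothesisSpec]:
    """All 2^k assignments of {null, active} over the effects."""
    specs = []
    for mask in itertools.product([False, True], repeat=len(effects)):
        active = tuple(e for e, on in zip(effects, mask) if on)
        labels = {e: ("active" if on else "null")
                  for e, on in zip(effects, mask)}
        specs.append(HypothesisSpec(id=_subset_id(prefix, active),
                                    effect_labels=labels, priors=priors))
    return specs


def build_hypothesis_space_exp1(
    conditions: tuple[str, ...] = ("real", "fake", "void"),
    priors=DEFAULT_LINEAR_PRIORS,
) -> list[HypothesisSpec]:
    """The 8 hypotheses over which conditions carry the ipsi-vs-contra
    effect: every {null, active} assignment to the three per-condition
    CCE-difference means."""
    if len(conditions) != 3:
        raise ValueError("this space is defined for exactly 3 conditions")
    return _binary_space("pps", tuple(conditions), priors)


def build_hypothesis_space_exp2(
    conditions: tuple[str, ...] = ("within", "outside"),
    priors=DEFAULT_LINEAR_PRIORS,
) -> list[HypothesisSpec]:
    """The 4 hypotheses over two conditions (2^2 assignments)."""
    if len(conditions) != 2:
        raise ValueError("this space is defined for exactly 2 conditions")
    return _binary_space("pps", tuple(conditions), priors)


def build_hypothesis_space_exp3(
    groups: tuple[str, ...] = ("motion", "no_motion"),
    priors=DEFAULT_LINEAR_PRIORS,
    cell_means: bool = False,
) -> list[HypothesisSpec]:
    """The 4 hypotheses over which groups show the effect.

    With ``cell_means=True`` the variant on per-laterality CCE means is
    returned: absence in a group constrains both its contralateral and
    ipsilateral means to the null prior; presence puts the active prior
    on the ipsilateral-minus-contralateral component.  Effect names are
    then ``mean:<group>`` (contralateral mean, shared by both
    lateralities) and ``pps:<group>`` (ipsilateral extra).
    """
    groups = tuple(groups)
    if len(groups) != 2:
        raise ValueError("this space is defined for exactly 2 groups")
    if not cell_means:
        return _binary_space("pps", groups, priors)
    specs = []
    for mask in itertools.product([False, True], repeat=2):
        active = tuple(g for g, on in zip(groups, mask) if on)
        labels = {}
        for g, on in zip(groups, mask):
            labels[f"mean:{g}"] = "null"
            labels[f"pps:{g}"] = "active" if on else "null"
        specs.append(HypothesisSpec(id=_subset_id("pps", active),
                                    effect_labels=labels, priors=priors))
    return specs


def build_questionnaire_hypotheses(
    conditions: tuple[str, ...] = ("real", "fake", "void"),
    times: tuple[str, ...] = ("before", "after"),
    priors=DEFAULT_LOGIT_PRIORS,
    scopes: tuple[str, ...] = ("both", "before_only", "after_only"),
) -> list[HypothesisSpec]:
    """Hypotheses over high/low assignments to (condition, time) cells.

    The shipped grammar — a reconstruction, configurable via ``scopes`` —
    is: the all-low hypothesis, plus for every non-empty subset of
    conditions and every time scope, "high in those conditions within
    that scope, low elsewhere".  With 3 conditions and both times this
    yields 1 + 7 * 3 = 22 hypotheses.
    """
    conditions = tuple(conditions)
    times = tuple(times)
    if len(times) != 2:
        raise ValueError("the time-scope grammar needs exactly 2 times")
    cells = [f"{c}:{t}" for c in conditions for t in times]
    scope_times = {"both": set(times), "before_only": {times[0]},
                   "after_only": {times[1]}}
    unknown = set(scopes) - set(scope_times)
    if unknown:
        raise ValueError(f"unknown scope(s): {sorted(unknown)}")

    specs = [HypothesisSpec(id="all_low",
                            effect_labels={c: "low" for c in cells},
                            priors=priors)]
    for r in range(1, len(conditions) + 1):
        for subset in itertools.combinations(conditions, r):
            for scope in scopes:
                labels = {}
                for c in conditions:
                    for t in times:
                        high = c in subset and t in scope_times[scope]
                        labels[f"{c}:{t}"] = "high" if high else "low"
                specs.append(HypothesisSpec(
                    id=f"high:{'+'.join(subset)}:{scope}",
                    effect_labels=labels, priors=priors))
    return specs


_SPACES = {"exp1", "exp2", "exp3", "exp3_cellmeans", "questionnaire"}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one analysis run."""

    space: str
    seed: int = 0
    design: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    likert_profile: dict | None = None
    mcmc: dict = field(default_factory=dict)
    pilot: dict = field(default_factory=dict)
    priors: dict | None = None
    trials_csv: str | None = None  # ingest instead of generating
    out: str | None = None
    summary: str | None = None

    def __post_init__(self) -> None:
        if self.space not in _SPACES:
            raise ValueError(
                f"unknown hypothesis space {self.space!r}; "
                f"choose from {sorted(_SPACES)}")

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(**{k: v for k, v in self.mcmc.items()
                             if k in ("n_chains", "burn_in", "n_samples")})

    def pilot_config(self) -> MCMCConfig:
        defaults = {"n_chains": 2, "burn_in": 200, "n_samples": 500}
        defaults.update(self.pilot)
        return MCMCConfig(**defaults)


def load_config(path: str | Path) -> ExperimentConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExperimentConfig(**raw)


def _build_design(cfg: ExperimentConfig) -> synthgen.ExperimentDesign:
    d = dict(cfg.design)
    for key in ("groups", "conditions"):
        if key in d:
            d[key] = tuple(d[key])
    return synthgen.ExperimentDesign(**d)


def _build_effects(cfg: ExperimentConfig,
                   design: synthgen.ExperimentDesign):
    if not cfg.effects:
        return {g: synthgen.EffectSpec() for g in design.groups}
    out = {}
    for g in design.groups:
        spec = cfg.effects.get(g, cfg.effects.get("default", {}))
        out[g] = synthgen.EffectSpec(**spec)
    return out


def _priors(cfg: ExperimentConfig, default):
    if cfg.priors is None:
        return default
    from .bayes_models import Prior
    return {lab: Prior(**p) for lab, p in cfg.priors.items()}


def _spm(family, cfg: ExperimentConfig, seed_seq: np.random.SeedSequence):
    pilot_seed, run_seed = [int(s.generate_state(1)[0]) % (2 ** 31)
                            for s in seed_seq.spawn(2)]
    pseudo = fit_pseudo_priors(family, cfg.pilot_config(), seed=pilot_seed)
    return run_product_space(family, pseudo, cfg.mcmc_config(),
                             seed=run_seed)


def run_experiment(config: ExperimentConfig | str | Path) -> dict:
    """Run one full analysis and return (and optionally write) the report.

    Stages: synthetic generation (or CSV ingestion) -> trial scoring,
    accuracy exclusion, CCE computation -> hypothesis space construction
    -> pseudo-prior pilots -> product-space model comparison.  The report
    is a plain dict, JSON-serializable, byte-identical across repeated
    runs with the same config and seed.
    """
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)
    cfg = config
    root_seq = np.random.SeedSequence(cfg.seed)
    gen_seq, analysis_seq = root_seq.spawn(2)

    report: dict = {"space": cfg.space, "seed": cfg.seed}

    if cfg.space == "questionnaire":
        return _run_questionnaire(cfg, gen_seq, analysis_seq, report)

    design = _build_design(cfg)
    if cfg.trials_csv:
        trials = pd.read_csv(cfg.trials_csv)
        log.info("loaded %d trials from %s", len(trials), cfg.trials_csv)
    else:
        trials = synthgen.generate_cct_dataset(
            design, _build_effects(cfg, design),
            seed=int(gen_seq.generate_state(1)[0]) % (2 ** 31))
        log.info("generated %d synthetic trials", len(trials))

    trials = preprocess.score_trials(trials)
    trials, exclusions = preprocess.exclude_low_accuracy(trials)
    cce = preprocess.compute_cce(trials).dropna(subset=["cce_ms"])
    report["exclusions"] = exclusions.to_dict()

    priors = _priors(cfg, DEFAULT_LINEAR_PRIORS)
    results: dict[str, dict] = {}

    if cfg.space in ("exp1", "exp2"):
        d_table = preprocess.cce_difference(cce)
        builder = (build_hypothesis_space_exp1 if cfg.space == "exp1"
                   else build_hypothesis_space_exp2)
        space = builder(tuple(design.conditions), priors=priors)
        for group, seq in zip(design.groups,
                              analysis_seq.spawn(len(design.groups))):
            sub = d_table[d_table["group"] == group]
            problem = problem_from_table(sub, effect_of="condition")
            family = GaussianFamily(problem, space)
            results[group] = _spm(family, cfg, seq).to_dict()
    elif cfg.space == "exp3":
        d_table = preprocess.cce_difference(cce)
        space = build_hypothesis_space_exp3(tuple(design.groups),
                                            priors=priors)
        problem = problem_from_table(d_table, effect_of="group")
        family = GaussianFamily(problem, space)
        results["all"] = _spm(family, cfg, analysis_seq).to_dict()
    else:  # exp3_cellmeans: per-laterality cell means
        space = build_hypothesis_space_exp3(tuple(design.groups),
                                            priors=priors, cell_means=True)
        columns = {}
        for g in design.groups:
            in_group = (cce["group"] == g).to_numpy(dtype=float)
            ipsi = (cce["laterality"] == "ipsilateral").to_numpy(dtype=float)
            columns[f"mean:{g}"] = in_group
            columns[f"pps:{g}"] = in_group * ipsi
        part = pd.Categorical(cce["participant_id"]).codes.astype(int)
        problem = RegressionProblem(
            y=cce["cce_ms"].to_numpy(dtype=float), columns=columns,
            participant=part)
        family = GaussianFamily(problem, space)
        results["all"] = _spm(family, cfg, analysis_seq).to_dict()

    report["results"] = results
    _write_report(cfg, report)
    return report


def _run_questionnaire(cfg: ExperimentConfig, gen_seq, analysis_seq,
                       report: dict) -> dict:
    design = _build_design(cfg)
    if cfg.likert_profile:
        profile = synthgen.LikertProfile(
            locations={tuple(k.split("|")): v
                       for k, v in cfg.likert_profile.items()})
    else:
        profile = synthgen.default_control_profile(tuple(design.conditions))
    answers = synthgen.generate_questionnaire(
        design, profile,
        seed=int(gen_seq.generate_state(1)[0]) % (2 ** 31))

    priors = _priors(cfg, DEFAULT_LOGIT_PRIORS)
    space = build_questionnaire_hypotheses(tuple(design.conditions),
                                           priors=priors)
    results: dict[str, dict] = {}
    components = sorted(answers["component"].unique())
    groups = list(design.groups)
    seqs = analysis_seq.spawn(len(groups) * len(components))
    i = 0
    for group in groups:
        for comp in components:
            sub = answers[(answers["group"] == group)
                          & (answers["component"] == comp)]
            problem = ordinal_problem_from_table(sub)
            family = OrdinalFamily(problem, space)
            results[f"{group}/{comp}"] = _spm(family, cfg, seqs[i]).to_dict()
            i += 1
    report["results"] = results
    _write_report(cfg, report)
    return report


def _write_report(cfg: ExperimentConfig, report: dict) -> None:
    if cfg.out:
        Path(cfg.out).parent.mkdir(parents=True, exist_ok=True)
        with open(cfg.out, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("report written to %s", cfg.out)
    if cfg.summary:
        with open(cfg.summary, "w") as fh:
            fh.write(format_summary(report))


def format_summary(report: dict) -> str:
    lines = [f"hypothesis space: {report['space']}   seed: {report['seed']}"]
    if "exclusions" in report:
        exc = report["exclusions"]
        lines.append(f"excluded participants (accuracy <= "
                     f"{exc['threshold']:.0%}): "
                     f"{exc['excluded'] or 'none'}")
    for unit, res in report.get("results", {}).items():
        lines.append(f"\n[{unit}]  best: {', '.join(res['best'])}")
        ranked = sorted(res["pi"].items(), key=lambda kv: (-kv[1], kv[0]))
        for mid, pi in ranked:
            lines.append(f"  pi[{mid}] = {pi:.3f} "
                         f"(SE {res['mc_se'][mid]:.4f}, "
                         f"visits {res['visit_counts'][mid]})")
        for w in res.get("warnings", []):
            lines.append(f"  warning: {w}")
    return "\n".join(lines) + "\n"
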