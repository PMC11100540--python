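"""End-to-end parameter-recovery studies.

A recovery run simulates a cohort at stated true parameters, fits the
matching hierarchical model, and reports per-contrast bias, 95%-interval
coverage, and the Bayes factors for the focal hypotheses: LTM-load effects
at each WM load (E1/E2) and proactive-facilitation / -interference
contrasts at each set size (E3; their mixture-model analogues for E4).
This is the package's main validation surface, standing in for the
unreleased human trial data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import choice_model, evidence, mixture_model
from .sampler import hdi
from .simulate import (
    ChoicePopulation,
    MixturePopulation,
    simulate_population,
    write_dataset,
)

DEFAULT_MCMC = {"chains": 4, "warmup": 2000, "samples": 3000, "target_accept": 0.85}


@dataclass
class RunConfig:
    """Fully determines a recovery run up to sampler stochasticity."""

    experiment: str = "E3"
    n_participants: int = 30
    seeds: dict = field(default_factory=lambda: {"data": 1, "sampler": 2})
    mcmc: dict = field(default_factory=lambda: dict(DEFAULT_MCMC))
    population: dict = field(default_factory=dict)
    out: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        mcmc = dict(DEFAULT_MCMC)
        mcmc.update(cfg.mcmc or {})
        cfg.mcmc = mcmc
        return cfg

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _parse_key(key):
    if isinstance(key, str):
        parts = [p.strip() for p in key.split(",")]
        return tuple(int(p) if p.lstrip("-").isdigit() else p for p in parts)
    if isinstance(key, (list, tuple)):
        return tuple(key)
    return (key,)


def build_population(config: RunConfig):
    pop = config.population
    if config.experiment in ("E1", "E2", "E3"):
        logits = {_parse_key(k): float(v) for k, v in pop["accuracy_logit"].items()}
        return ChoicePopulation(
            experiment_id=config.experiment,
            accuracy_logit=logits,
            sd_intercept=float(pop.get("sd_intercept", 0.5)),
        )
    if config.experiment == "E4":
        if "logits" in pop:
            logits = {_parse_key(k): tuple(v) for k, v in pop["logits"].items()}
            log_kappa = {int(k): float(v) for k, v in pop["log_kappa"].items()}
            return MixturePopulation(logits=logits, log_kappa=log_kappa,
                                     sd=tuple(pop.get("sd", (0.3, 0.3, 0.3, 0.2))))
        return MixturePopulation.from_probs(
            pop.get("probs", (0.7, 0.1, 0.1, 0.1)),
            pop.get("kappa", 12.0),
            sd=tuple(pop.get("sd", (0.3, 0.3, 0.3, 0.2))),
        )
    raise ValueError(f"unknown experiment {config.experiment!r}")


def _focal_choice_contrasts(experiment, cells_present):
    """Named cell contrasts matching the experiments' focal hypotheses."""
    out = []
    if experiment in ("E1", "E2"):
        for wm in (2, 4):
            a, b = (wm, 2), (wm, 0)
            if a in cells_present and b in cells_present:
                out.append((f"ltm_load_effect_wm{wm}", {a: 1.0, b: -1.0}))
    else:
        set_sizes = sorted({c[0] for c in cells_present})
        for ss in set_sizes:
            if (ss, "old_match") in cells_present and (ss, "new_new") in cells_present:
                out.append((f"facilitation_ss{ss}",
                            {(ss, "old_match"): 1.0, (ss, "new_new"): -1.0}))
            if (ss, "old_mismatch") in cells_present and (ss, "new_new") in cells_present:
                out.append((f"interference_ss{ss}",
                            {(ss, "old_mismatch"): 1.0, (ss, "new_new"): -1.0}))
    return out


def _contrast_report(name, definition, draws, true_value):
    from scipy.stats import norm

    cd = choice_model.contrast(draws, definition)
    prior_sd = choice_model.contrast_prior_sd(draws, definition)
    sd_bf = evidence.savage_dickey_bf(
        cd, norm.pdf(0.0, scale=prior_sd), parameter=name,
        prior=f"Normal(0, {prior_sd:.3g})",
    )
    direction = "positive" if true_value >= 0 else "negative"
    dbf = evidence.directed_bf(cd, direction, parameter=name)
    lo, hi = hdi(cd)
    return {
        "contrast": name,
        "true": float(true_value),
        "posterior_mean": float(np.mean(cd)),
        "hdi_lower": lo,
        "hdi_upper": hi,
        "bias": float(np.mean(cd) - true_value),
        "covered": bool(lo <= true_value <= hi),
        "bf10_savage_dickey": sd_bf.bf10,
        "bf10_directed": dbf.bf10,
        "bf_directed_bounded": dbf.bounded,
        "classification": sd_bf.classification,
    }


def run_recovery_study(config: RunConfig, require_convergence: bool = True) -> dict:
    """Simulate, fit, and score one recovery study; returns the report dict.

    Raises ``RuntimeError`` on non-convergence when ``require_convergence``.
    Writes data/report files under ``config.out`` when set (file names carry
    the config hash).
    """
    population = build_population(config)
    cohort = simulate_population(
        population, config.n_participants, seed=config.seeds.get("data")
    )
    mcmc = dict(DEFAULT_MCMC)
    mcmc.update(config.mcmc or {})
    sampler_seed = config.seeds.get("sampler")
    report: dict = {"config_hash": config.digest(), "experiment": config.experiment}

    if isinstance(population, ChoicePopulation):
        factors = ["wm_load", "ltm_load"] if config.experiment in ("E1", "E2") \
            else ["set_size", "pair_type"]
        cells = choice_model.aggregate_cells(cohort.data, factors)
        spec = choice_model.GLMMSpec(factors=tuple(factors), coding="cells")
        draws, conv = choice_model.fit_binomial_glmm(
            cells, spec,
            n_chains=mcmc["chains"], n_warmup=mcmc["warmup"],
            n_samples=mcmc["samples"], seed=sampler_seed,
            target_accept=mcmc.get("target_accept", 0.85),
        )
        if require_convergence and not conv.passed:
            raise RuntimeError(
                f"choice model did not converge (max R-hat {conv.max_rhat():.4f})"
            )
        present = set(population.accuracy_logit)
        contrasts = []
        for name, definition in _focal_choice_contrasts(config.experiment, present):
            truth = sum(w * population.accuracy_logit[c] for c, w in definition.items())
            contrasts.append(_contrast_report(name, definition, draws, truth))
        report["contrasts"] = contrasts
        report["convergence"] = {"max_rhat": conv.max_rhat(), "passed": conv.passed}
    else:
        draws, conv = mixture_model.fit_mixture_hierarchical(
            cohort.data,
            n_chains=mcmc["chains"], n_warmup=mcmc["warmup"],
            n_samples=mcmc["samples"], seed=sampler_seed,
            target_accept=mcmc.get("target_accept", 0.85),
        )
        if require_convergence and not conv.passed:
            raise RuntimeError(
                f"mixture model did not converge (max R-hat {conv.max_rhat():.4f})"
            )
        params = []
        for cell, (lm, ls, ll) in population.logits.items():
            true_p = mixture_model.softmax_probs((lm, ls, ll))
            for k, nm in enumerate(mixture_model.COMPONENTS):
                name = f"{nm}[{cell[0]},{cell[1]}]"
                if name not in draws.samples:
                    continue
                x = draws.flat(name)
                lo, hi = hdi(x)
                params.append({
                    "parameter": name, "true": float(true_p[k]),
                    "posterior_mean": float(np.mean(x)),
                    "bias": float(np.mean(x) - true_p[k]),
                    "hdi_lower": lo, "hdi_upper": hi,
                    "covered": bool(lo <= true_p[k] <= hi),
                })
        intrusions = []
        for ss in sorted({c[0] for c in population.logits}):
            try:
                cd = mixture_model.ltm_intrusion_test(draws, ss)
            except KeyError:
                continue
            dbf = evidence.directed_bf(cd, "positive", parameter=f"ltm_intrusion_ss{ss}")
            lo, hi = hdi(cd)
            intrusions.append({
                "set_size": ss, "posterior_mean": float(np.mean(cd)),
                "hdi_lower": lo, "hdi_upper": hi,
                "bf10_directed": dbf.bf10, "bounded": dbf.bounded,
            })
        report["parameters"] = params
        report["ltm_intrusion_contrasts"] = intrusions
        report["convergence"] = {"max_rhat": conv.max_rhat(), "passed": conv.passed}

    if config.out:
        outdir = Path(config.out)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = report["config_hash"]
        write_dataset(cohort.data, outdir / f"data_{tag}.csv")
        cohort.truth.to_csv(outdir / f"truth_{tag}.csv", index=False)
        with open(outdir / f"recovery_{tag}.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
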