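"""End-to-end orchestration of the two analysis arms.

:func:`run_fr_analysis` takes a functional-response dataset (a file, a
list of trials, or a simulation config), classifies each species x
temperature group as type II or III, fits the depletion-model likelihood
with the shape exponent fixed accordingly, computes profile CIs and the
cross-group CI-overlap comparison, and writes the report tables.

:func:`run_efficiency_analysis` computes Abbott efficiencies from matched
treatment-control pairs, fits the six candidate linear models, ranks them
by AIC, and runs the body-size test battery.

Every report row carries the run seed and a configuration hash so reruns
are auditable; input files are never mutated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import allometry, efficiency, fr_fit, response_type, synthetic, trials as trial_data

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FRAnalysisResult", "EfficiencyAnalysisResult",
           "run_fr_analysis", "run_efficiency_analysis", "group_fr_trials"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    seed: int = 0
    trials_path: str | None = None
    copepods_path: str | None = None
    simulation: synthetic.SimulationConfig | None = None
    simulator: str = "binomial"
    alpha: float = 0.05
    ci_level: float = 0.95
    out_dir: str | None = None
    exclusion_rules: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise ValueError("alpha and ci_level must lie in (0, 1)")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return {k: default(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): default(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [default(v) for v in o]
            return o

        payload = default(self)
        payload.pop("out_dir", None)  # where reports land must not change them
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class FRAnalysisResult:
    classifications: dict
    fits: dict
    comparisons: pd.DataFrame
    skipped: dict
    tables: dict = field(default_factory=dict)


@dataclass
class EfficiencyAnalysisResult:
    records: list
    model_fits: dict
    selection: pd.DataFrame
    selected: efficiency.LinearModelFit
    distribution: dict
    body_size_tests: pd.DataFrame
    tables: dict = field(default_factory=dict)


def _load_fr(config: PipelineConfig):
    if config.trials_path is not None:
        return trial_data.read_trials(config.trials_path, schema="FR"), None
    sim = config.simulation or synthetic.SimulationConfig(seed=config.seed)
    return synthetic.generate_fr_dataset(sim, simulator=config.simulator)


def group_fr_trials(all_trials: Sequence[trial_data.PredationTrial]) -> dict:
    """Split FR trials into species x temperature groups, controls included.

    Treatments carry their species directly.  Controls (species ``none``)
    are assigned to the group named in their trial id when it follows the
    ``FR|<species>|<temp>|...`` convention; otherwise a control is shared
    by every group at its temperature.
    """
    groups: dict[tuple[str, int], list] = {}
    for t in all_trials:
        if t.predator_count >= 1:
            groups.setdefault((t.species, t.temperature_C), []).append(t)
    for t in all_trials:
        if t.predator_count >= 1:
            continue
        parts = t.trial_id.split("|")
        if len(parts) >= 3 and (parts[1], t.temperature_C) in groups:
            groups[(parts[1], t.temperature_C)].append(t)
        else:
            for (sp, temp), members in groups.items():
                if temp == t.temperature_C:
                    members.append(t)
    return groups


def run_fr_analysis(config: PipelineConfig) -> FRAnalysisResult:
    """Classify, fit and compare every species x temperature group."""
    all_trials, _ = _load_fr(config)
    if config.exclusion_rules:
        all_trials, log = trial_data.apply_exclusions(all_trials, config.exclusion_rules)
        for _, row in log.iterrows():
            logger.info(
                "excluded %d trial(s) from %s/%dC: %s",
                row.n_excluded, row.species, row.temperature_C, row.reason,
            )
    groups = group_fr_trials(all_trials)
    if not groups:
        raise ValueError("dataset contains no predator-present trials; nothing to fit")

    classifications: dict = {}
    fits: dict = {}
    skipped: dict = {}
    for key in sorted(groups):
        members = [t for t in groups[key] if not t.excluded]
        densities = {t.initial_count for t in members if t.predator_count >= 1}
        if len(densities) < 2:
            skipped[key] = "fewer than 2 density levels"
            logger.info("skipping group %s: %s", key, skipped[key])
            continue
        cls = response_type.classify_response(members, alpha=config.alpha)
        classifications[key] = cls
        q_fixed = 1 if cls.classification == "type_III" else 0
        fit = fr_fit.fit_group(members, q_fixed=q_fixed, mortality_alpha=config.alpha)
        logger.info(
            "group %s: %s, variant=%s, converged=%s",
            key, cls.classification, fit.variant, fit.converged,
        )
        if fit.converged:
            for par in ("b", "h"):
                fr_fit.profile_ci(fit, par, members, level=config.ci_level)
        fits[key] = fit

    converged = {k: f for k, f in fits.items() if f.converged and f.profile_cis}
    comparisons = pd.DataFrame()
    if len(converged) >= 2:
        labels = [f"{sp}_{temp}" for sp, temp in converged]
        frames = [
            fr_fit.compare_groups(list(converged.values()), par, labels=labels)
            for par in ("b", "h")
        ]
        comparisons = pd.concat(frames, ignore_index=True)

    result = FRAnalysisResult(classifications, fits, comparisons, skipped)
    result.tables["response_type"] = _response_type_table(classifications)
    result.tables["fr_parameters"] = _fr_parameter_table(fits)
    result.tables["fr_comparisons"] = comparisons
    if config.out_dir is not None:
        _write_reports(config, result.tables, "fr")
    return result


def _response_type_table(classifications: dict) -> pd.DataFrame:
    rows = []
    for (sp, temp), cls in sorted(classifications.items()):
        row = {
            "group": f"{sp}_{temp}",
            "classification": cls.classification,
            "degree_used": cls.degree_used,
            "n_trials": cls.n_trials,
            "converged": cls.converged,
        }
        for name in cls.coefficients.names:
            est, se, p = cls.coefficients.term(name)
            row[f"{name}_estimate"] = est
            row[f"{name}_se"] = se
            row[f"{name}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _fr_parameter_table(fits: dict) -> pd.DataFrame:
    rows = []
    for (sp, temp), f in sorted(fits.items()):
        ci_b = f.profile_cis.get("b")
        ci_h = f.profile_cis.get("h")
        rows.append(
            {
                "group": f"{sp}_{temp}",
                "variant": f.variant,
                "q": f.q,
                "b": f.params.b,
                "b_se": f.wald_se.get("b"),
                "b_low": ci_b.low if ci_b else None,
                "b_high": ci_b.high if ci_b else None,
                "h": f.params.h,
                "h_se": f.wald_se.get("h"),
                "h_low": ci_h.low if ci_h else None,
                "h_high": ci_h.high if ci_h else None,
                "m": f.params.m,
                "mortality_p": f.mortality_p,
                "deviance": f.deviance,
                "converged": f.converged,
                "n_trials": f.n_trials,
            }
        )
    return pd.DataFrame(rows)


def _load_pe(config: PipelineConfig):
    if config.trials_path is not None:
        pe_trials = trial_data.read_trials(config.trials_path, schema="PE")
        copepods = (
            trial_data.read_copepods(config.copepods_path)
            if config.copepods_path
            else []
        )
        return pe_trials, copepods
    sim = config.simulation or synthetic.SimulationConfig(seed=config.seed)
    return synthetic.generate_efficiency_dataset(sim)


def run_efficiency_analysis(
    config: PipelineConfig,
    fr_copepods: Sequence[trial_data.CopepodRecord] | None = None,
) -> EfficiencyAnalysisResult:
    """Abbott efficiencies, the six candidate models, AIC ranking and
    body-size tests.

    ``fr_copepods`` (measured predators from the functional-response arm)
    extend the body-size battery with the cross-design comparisons; when
    the run is simulation-backed they are generated from the same config.
    """
    pe_trials, pe_copepods = _load_pe(config)
    if fr_copepods is None and config.trials_path is None:
        sim = config.simulation or synthetic.SimulationConfig(seed=config.seed)
        _, fr_copepods = synthetic.generate_fr_dataset(sim, simulator=config.simulator)
    records = efficiency.pair_treatments_controls(pe_trials, seed=config.seed)
    frame = efficiency.records_to_frame(records)

    have_mass = frame["copepod_mass_mg"].notna().all()
    fits: dict[str, efficiency.LinearModelFit] = {}
    for label, formula in efficiency.STANDARD_MODELS.items():
        if "mass" in label and not have_mass:
            logger.info("skipping model %s: copepod masses missing", label)
            continue
        fits[label] = efficiency.fit_ols(frame, formula, label=label)
    selection, selected = efficiency.model_selection(list(fits.values()))
    try:
        distribution = efficiency.describe_distribution(frame["efficiency_pct"])
    except ValueError:  # constant efficiencies (e.g. zero predation)
        x = frame["efficiency_pct"]
        distribution = {
            "min": float(x.min()), "max": float(x.max()),
            "median": float(x.median()), "skewness": float("nan"),
            "kurtosis": float("nan"),
        }

    body_rows = _body_size_battery(
        list(fr_copepods or []), list(pe_copepods), config.seed, config.alpha
    )

    result = EfficiencyAnalysisResult(
        records=records,
        model_fits=fits,
        selection=selection,
        selected=selected,
        distribution=distribution,
        body_size_tests=body_rows,
    )
    model_rows = []
    for label, f in fits.items():
        for name, est, se, t, p in f.terms:
            model_rows.append(
                {
                    "model": label, "term": name, "estimate": est, "se": se,
                    "t": t, "p": p, "n": f.n, "adjusted_r2": f.adjusted_r2,
                    "aic": f.aic,
                }
            )
    result.tables["efficiency_records"] = frame
    result.tables["efficiency_models"] = pd.DataFrame(model_rows)
    result.tables["model_selection"] = selection
    result.tables["body_size_tests"] = body_rows
    if config.out_dir is not None:
        _write_reports(config, result.tables, "pe")
    return result


def _body_size_battery(
    fr_copepods: list, pe_copepods: list, seed: int, alpha: float
) -> pd.DataFrame:
    """Shapiro-gated species comparisons and the paired-difference analysis."""
    rows = []

    def masses(records, species):
        return [r.mass_mg for r in records if r.species == species]

    by_exp = {"FR": fr_copepods, "PE": pe_copepods}
    diff_sets = {}
    for exp, recs in by_exp.items():
        alb = masses(recs, "M_albidus")
        vir = masses(recs, "M_viridis")
        if len(alb) < 3 or len(vir) < 3:
            continue
        res = allometry.choose_and_run_test(alb, vir, alpha=alpha)
        rows.append(
            {
                "comparison": f"{exp}: mass by species",
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "gate_W1": res.normality_gate[0][0],
                "gate_p1": res.normality_gate[0][1],
                "gate_W2": res.normality_gate[1][0],
                "gate_p2": res.normality_gate[1][1],
            }
        )
        alb_recs = [r for r in recs if r.species == "M_albidus"]
        vir_recs = [r for r in recs if r.species == "M_viridis"]
        diff_sets[exp] = allometry.random_species_pairing(
            alb_recs, vir_recs, seed=seed, experiment=exp
        )
    if len(diff_sets) == 2:
        res = allometry.wilcoxon_rank_sum(
            diff_sets["FR"].differences, diff_sets["PE"].differences
        )
        rows.append(
            {
                "comparison": "paired mass differences: FR vs PE",
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "gate_W1": None, "gate_p1": None, "gate_W2": None, "gate_p2": None,
            }
        )
    return pd.DataFrame(rows)


def _write_reports(config: PipelineConfig, tables: dict, arm: str) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    for name, df in tables.items():
        df = df.copy()
        df["seed"] = config.seed
        df["config_hash"] = chash
        df.to_csv(out / f"{name}.csv", index=False)
    meta = {
        "seed": config.seed,
        "config_hash": chash,
        "arm": arm,
        "alpha": config.alpha,
        "ci_level": config.ci_level,
        "simulator": config.simulator,
        "tables": sorted(tables),
    }
    with open(out / f"run_metadata_{arm}.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
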