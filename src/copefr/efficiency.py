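"""Abbott-corrected predation efficiency and its linear-model analysis.

Predation efficiency corrects the prey loss in a predator dish for the
background mortality seen in a matched predator-free control held at the
same temperature:

    efficiency (%) = 100 * (alive_control - alive_treatment) / alive_control

Efficiency is then explained with ordinary least-squares regressions on
copepod species or body mass, with and without temperature terms, and the
candidate models are ranked by AIC (a difference of at least 2 being the
conventional minimum for preferring one model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .allometry import length_to_mass
from .trials import PredationTrial

__all__ = [
    "EfficiencyRecord",
    "LinearModelFit",
    "abbott_efficiency",
    "pair_treatments_controls",
    "records_to_frame",
    "fit_ols",
    "model_selection",
    "describe_distribution",
    "STANDARD_MODELS",
]


@dataclass
class EfficiencyRecord:
    """A matched treatment-control pair with its Abbott efficiency."""

    pair_id: str
    species: str
    temperature_C: int
    alive_control: int
    alive_treatment: int
    efficiency_pct: float
    copepod_mass_mg: float | None


@dataclass
class LinearModelFit:
    """OLS fit summary: per-term estimates plus fit-quality measures.

    ``aic`` uses the Gaussian log-likelihood with the error variance
    counted as a parameter, so nested-model differences obey
    n log(RSS_small / RSS_big) - 2 dk exactly.
    """

    label: str
    terms: list[tuple[str, float, float, float, float]]  # name, est, se, t, p
    n: int
    df_resid: int
    r2: float
    adjusted_r2: float
    aic: float
    rss: float

    def term(self, fragment: str) -> tuple[str, float, float, float, float]:
        """First term whose name contains ``fragment``."""
        for row in self.terms:
            if fragment in row[0]:
                return row
        raise KeyError(fragment)


def abbott_efficiency(alive_control: int, alive_treatment: int) -> float:
    """Abbott's control-corrected predation efficiency, in percent.

    May be negative when treatment survival exceeds control survival.
    """
    if alive_control < 1:
        raise ValueError("alive_control must be >= 1")
    if alive_treatment < 0:
        raise ValueError("alive_treatment must be >= 0")
    return 100.0 * (alive_control - alive_treatment) / alive_control


def pair_treatments_controls(
    trials: Sequence[PredationTrial], seed: int
) -> list[EfficiencyRecord]:
    """Match each treatment dish to a same-temperature control dish.

    When controls are shared (fewer controls than treatments at a
    temperature) the assignment is a seeded random balanced allocation:
    each control serves as equal a number of treatments as possible.
    Copepod mass comes from the allometric conversion of the recorded
    length.  Excluded trials are ignored.
    """
    rng = np.random.default_rng(seed)
    use = [t for t in trials if not t.excluded]
    records: list[EfficiencyRecord] = []
    for temp in sorted({t.temperature_C for t in use}):
        treatments = [t for t in use if t.temperature_C == temp and t.predator_count >= 1]
        controls = [t for t in use if t.temperature_C == temp and t.predator_count == 0]
        if treatments and not controls:
            raise ValueError(f"temperature {temp}C has treatments but no controls")
        if not treatments:
            continue
        # balanced pool of control indices, shuffled, one per treatment
        reps = int(np.ceil(len(treatments) / len(controls)))
        pool = np.tile(np.arange(len(controls)), reps)[: len(treatments)]
        pool = rng.permutation(pool)
        order = rng.permutation(len(treatments))
        for k, t_idx in enumerate(order):
            t = treatments[t_idx]
            c = controls[pool[k]]
            mass = (
                length_to_mass(t.copepod_length_mm)
                if t.copepod_length_mm is not None
                else None
            )
            records.append(
                EfficiencyRecord(
                    pair_id=f"{t.trial_id}|{c.trial_id}",
                    species=t.species,
                    temperature_C=temp,
                    alive_control=c.survivors,
                    alive_treatment=t.survivors,
                    efficiency_pct=abbott_efficiency(c.survivors, t.survivors),
                    copepod_mass_mg=mass,
                )
            )
    records.sort(key=lambda r: r.pair_id)
    return records


def records_to_frame(records: Sequence[EfficiencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in records],
            "species": [r.species for r in records],
            "temperature_C": [r.temperature_C for r in records],
            "alive_control": [r.alive_control for r in records],
            "alive_treatment": [r.alive_treatment for r in records],
            "efficiency_pct": [r.efficiency_pct for r in records],
            "copepod_mass_mg": [r.copepod_mass_mg for r in records],
        }
    )


# The six candidate explanatory structures, keyed by label.  Categorical
# predictors use treatment coding with M. albidus and 15 C as references.
_SP = 'C(species, Treatment(reference="M_albidus"))'
_TMP = "C(temperature_C, Treatment(reference=15))"
STANDARD_MODELS: dict[str, str] = {
    "species+temperature": f"efficiency_pct ~ {_SP} + {_TMP}",
    "species*temperature": f"efficiency_pct ~ {_SP} * {_TMP}",
    "species": f"efficiency_pct ~ {_SP}",
    "mass+temperature": f"efficiency_pct ~ copepod_mass_mg + {_TMP}",
    "mass*temperature": f"efficiency_pct ~ copepod_mass_mg * {_TMP}",
    "mass": "efficiency_pct ~ copepod_mass_mg",
}

_PRETTY = {
    _SP + "[T.M_viridis]": "species[M_viridis]",
    _TMP + "[T.20]": "temperature[20]",
    _TMP + "[T.25]": "temperature[25]",
}


def _pretty(name: str) -> str:
    for raw, nice in _PRETTY.items():
        name = name.replace(raw, nice)
    return name


def fit_ols(data: pd.DataFrame, formula: str, label: str | None = None) -> LinearModelFit:
    """Least-squares fit of an efficiency regression.

    ``formula`` is a patsy model formula over the columns of ``data`` (the
    frame produced by :func:`records_to_frame`); the named models in
    :data:`STANDARD_MODELS` cover the standard candidate set.  A
    rank-deficient design raises with the aliased columns named.
    """
    model = smf.ols(formula, data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify aliased columns: those whose removal does not drop the rank
        aliased = [
            model.exog_names[j]
            for j in range(model.exog.shape[1])
            if np.linalg.matrix_rank(np.delete(model.exog, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    n = int(res.nobs)
    k_coef = int(res.df_model) + 1  # regression coefficients incl. intercept
    aic = -2.0 * res.llf + 2.0 * (k_coef + 1)  # error variance counted
    terms = [
        (
            _pretty(name),
            float(res.params.iloc[i]),
            float(res.bse.iloc[i]),
            float(res.tvalues.iloc[i]),
            float(res.pvalues.iloc[i]),
        )
        for i, name in enumerate(res.model.exog_names)
    ]
    return LinearModelFit(
        label=label or formula,
        terms=terms,
        n=n,
        df_resid=int(res.df_resid),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        aic=float(aic),
        rss=float(res.ssr),
    )


def model_selection(fits: Sequence[LinearModelFit]) -> tuple[pd.DataFrame, LinearModelFit]:
    """Rank candidate models by AIC and pick the best.

    All fits must be on the same response (same n).  The best model is
    *preferred* only when it beats the runner-up by at least 2 AIC units;
    near-ties are flagged in the returned table.
    """
    if len({f.n for f in fits}) != 1:
        raise ValueError("all models must be fitted to the same response vector")
    ranked = sorted(fits, key=lambda f: f.aic)
    best = ranked[0]
    delta = [f.aic - best.aic for f in ranked]
    preferred = len(ranked) < 2 or delta[1] >= 2.0
    table = pd.DataFrame(
        {
            "model": [f.label for f in ranked],
            "df_resid": [f.df_resid for f in ranked],
            "adjusted_r2": [f.adjusted_r2 for f in ranked],
            "aic": [f.aic for f in ranked],
            "delta_aic": delta,
            "preferred": [preferred and f is best for f in ranked],
        }
    )
    return table, best


def describe_distribution(values: Sequence[float]) -> dict[str, float]:
    """Min, max, median, moment skewness and plain (non-excess) kurtosis.

    Kurtosis uses the convention where a normal population scores 3.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("skewness and kurtosis undefined for a constant vector")
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "skewness": float(stats.skew(x, bias=True)),
        "kurtosis": float(stats.kurtosis(x, fisher=False, bias=True)),
    }
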