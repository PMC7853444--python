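"""Length-to-mass conversion and copepod body-size comparisons.

Copepod body lengths (mm, front of the cephalosome to the end of the last
urosomite) are converted to wet-mass estimates (mg) with the crustacean
allometric power law ``mass = 0.055 * length**2.73``.  Species comparisons
follow a normality-gated two-sample strategy: Shapiro-Wilk on each sample,
then Welch's t if both look normal, otherwise a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trials import CopepodRecord

__all__ = [
    "ALLOMETRIC_COEFFICIENT",
    "ALLOMETRIC_EXPONENT",
    "length_to_mass",
    "shapiro_wilk",
    "wilcoxon_rank_sum",
    "welch_t",
    "choose_and_run_test",
    "random_species_pairing",
    "TwoSampleTestResult",
    "PairedDifferenceSet",
]

ALLOMETRIC_COEFFICIENT = 0.055
ALLOMETRIC_EXPONENT = 2.73


def length_to_mass(length_mm: float) -> float:
    """Estimated body mass (mg) of a copepod of the given length (mm).

    ``mass = 0.055 * length**2.73``; strictly increasing, so mass ordering
    always matches length ordering.
    """
    if length_mm <= 0:
        raise ValueError("length_mm must be positive")
    return ALLOMETRIC_COEFFICIENT * length_mm**ALLOMETRIC_EXPONENT


@dataclass
class TwoSampleTestResult:
    test_name: str  # "wilcoxon_rank_sum" or "welch_t"
    statistic: float
    p_value: float
    n1: int
    n2: int
    # Shapiro-Wilk (W, p) per sample when the gate was run, else None
    normality_gate: tuple[tuple[float, float], tuple[float, float]] | None = None
    df: float | None = None


@dataclass
class PairedDifferenceSet:
    """Mass differences (viridis minus albidus) from random pairing."""

    differences: np.ndarray
    experiment: str
    n_pairs: int
    seed: int


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns ``(W, p)``.

    Valid for 3 <= n <= 5000.  A constant sample has no defined statistic
    and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TwoSampleTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses midranks for ties and the normal approximation with tie-corrected
    variance and continuity correction.  The reported statistic is the
    rank sum W of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U1 -> rank sum
    return TwoSampleTestResult(
        test_name="wilcoxon_rank_sum",
        statistic=w,
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> TwoSampleTestResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("Welch t undefined when both samples are constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TwoSampleTestResult(
        test_name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        df=float(res.df),
    )


def choose_and_run_test(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TwoSampleTestResult:
    """Normality-gated comparison of two samples.

    Shapiro-Wilk is run on each sample; if both p-values are >= ``alpha``
    the samples are treated as normal and Welch's t-test is used, otherwise
    the Wilcoxon rank-sum test.  The gate results are recorded on the
    returned object.
    """
    gate = (shapiro_wilk(x), shapiro_wilk(y))
    if gate[0][1] >= alpha and gate[1][1] >= alpha:
        result = welch_t(x, y)
    else:
        result = wilcoxon_rank_sum(x, y)
    result.normality_gate = gate
    return result


def random_species_pairing(
    albidus: Sequence[CopepodRecord],
    viridis: Sequence[CopepodRecord],
    seed: int,
    experiment: str = "FR",
) -> PairedDifferenceSet:
    """Randomly pair individuals across species and difference their masses.

    Each pairing is uniform without replacement; when group sizes differ
    the surplus individuals of the larger group are dropped uniformly at
    random.  Differences are mass(viridis) - mass(albidus) in mg.
    Deterministic for a given seed.
    """
    if len(albidus) == 0 or len(viridis) == 0:
        raise ValueError("need at least one record per species")
    rng = np.random.default_rng(seed)
    n_pairs = min(len(albidus), len(viridis))
    a_idx = rng.permutation(len(albidus))[:n_pairs]
    v_idx = rng.permutation(len(viridis))[:n_pairs]
    a_mass = np.array([albidus[i].mass_mg for i in a_idx])
    v_mass = np.array([viridis[i].mass_mg for i in v_idx])
    return PairedDifferenceSet(
        differences=v_mass - a_mass,
        experiment=experiment,
        n_pairs=n_pairs,
        seed=seed,
    )
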