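"""Significance of decoding accuracies and speed-vs-direction comparison.

An electrode's accuracy gamma-hat (a proportion over n cross-validation
decisions) is significantly above chance when the lower bound of its Wald
confidence interval,

    gamma_hat - z* * sqrt(gamma_hat * (1 - gamma_hat) / n),

exceeds the chance level 1/K (z* is the two-sided standard-normal quantile
at alpha = 0.01 by default).  Across the 31 electrodes of one subject, cue,
and condition, a Holm-Bonferroni step-down correction controls the
family-wise error rate.  Cue preference per subject is assessed with a
paired two-tailed t-test over the 31 electrode accuracies, and the spatial
relationship between the cues with the Pearson correlation of the same
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .decode import AccuracyMap

__all__ = [
    "ci_half_width",
    "chance_level",
    "significance_vs_chance",
    "holm_reject",
    "holm_bonferroni",
    "electrode_significance",
    "CueComparison",
    "compare_cues",
]


def chance_level(n_classes: int) -> float:
    """1/K for a balanced K-class task (9.1% for 11 classes)."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 1.0 / n_classes


def ci_half_width(gamma_hat: float, n: int, alpha: float = 0.01) -> float:
    """Wald confidence-interval half-width for a proportion.

    ``z* sqrt(gamma_hat (1 - gamma_hat) / n)`` with z* the two-sided
    standard-normal quantile for ``alpha``.  Degenerate proportions (0 or 1)
    give zero width.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= gamma_hat <= 1.0:
        raise ValueError("gamma_hat must be a proportion in [0, 1]")
    z = spstats.norm.ppf(1.0 - alpha / 2.0)
    return float(z * np.sqrt(gamma_hat * (1.0 - gamma_hat) / n))


def _one_sided_p(gamma_hat: float, n: int, chance: float) -> float:
    """Normal-approximation p-value for gamma_hat > chance (Wald SE).

    This is the p-value whose alpha/2 threshold is exactly equivalent to the
    CI-lower-bound-above-chance rule, so the Holm correction operates on the
    same test.
    """
    se = np.sqrt(gamma_hat * (1.0 - gamma_hat) / n)
    if se == 0.0:
        return 0.0 if gamma_hat > chance else 1.0
    return float(spstats.norm.sf((gamma_hat - chance) / se))


def significance_vs_chance(
    records: pd.DataFrame,
    chance: float,
    alpha: float = 0.01,
    n_column: str = "n_trials",
) -> pd.DataFrame:
    """Add CI half-widths, p-values, and the raw significance flag.

    ``records`` needs columns ``gamma_hat`` and ``n_column``.  The CI sample
    size defaults to the number of trials in the electrode's task
    (``n_trials``); set ``n_column="n_decisions"`` to use the number of
    cross-validation decisions instead.  An electrode is raw-significant
    when its CI lower bound exceeds chance.
    """
    out = records.copy()
    ns = out[n_column]
    out["chance"] = chance
    out["alpha"] = alpha
    out["n_ci"] = ns
    out["ci_half_width"] = [
        ci_half_width(g, n, alpha) for g, n in zip(out["gamma_hat"], ns)
    ]
    out["p_value"] = [
        _one_sided_p(g, n, chance) for g, n in zip(out["gamma_hat"], ns)
    ]
    out["raw_significant"] = out["gamma_hat"] - out["ci_half_width"] > chance
    return out


def holm_reject(p_values: Sequence[float], alpha: float = 0.01) -> np.ndarray:
    """Plain Holm step-down: boolean rejections at family-wise level ``alpha``."""
    reject, _, _, _ = multipletests(np.asarray(p_values), alpha=alpha, method="holm")
    return reject


def holm_bonferroni(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Holm step-down over one family (the 31 electrodes of a map).

    Operates on the one-sided p-values at family level ``alpha / 2`` so that
    the uncorrected test coincides with the CI rule; Holm-significant is
    therefore always a subset of raw-significant.
    """
    out = records.copy()
    if len(out) == 0:
        out["holm_significant"] = pd.Series(dtype=bool)
        return out
    out["holm_significant"] = holm_reject(out["p_value"].to_numpy(), alpha / 2.0)
    return out


def electrode_significance(
    acc_map: AccuracyMap, alpha: float = 0.01, n_column: str = "n_trials"
) -> pd.DataFrame:
    """Full significance table for one accuracy map (one cue/condition)."""
    records = acc_map.to_frame()
    chance = chance_level(acc_map.n_classes)
    records = significance_vs_chance(records, chance, alpha, n_column=n_column)
    return holm_bonferroni(records, alpha)


@dataclass
class CueComparison:
    """Per-subject comparison of speed vs direction accuracy across electrodes."""

    subject: str
    condition: Optional[str]
    electrodes: Sequence[str]
    speed_gamma: np.ndarray
    direction_gamma: np.ndarray
    t_statistic: float
    p_value: float
    pearson_r: float  # NaN when either accuracy vector is constant
    pearson_note: str
    preferred_cue: Literal["speed", "direction", "none"]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [self.subject],
                "condition": [self.condition],
                "t_statistic": [self.t_statistic],
                "p_value": [self.p_value],
                "pearson_r": [self.pearson_r],
                "preferred_cue": [self.preferred_cue],
                "alpha": [self.alpha],
            }
        )


def compare_cues(
    speed_map: AccuracyMap,
    direction_map: AccuracyMap,
    alpha: float = 0.01,
    subject: str = "S1",
    paired: bool = True,
) -> CueComparison:
    """Two-tailed t-test and Pearson correlation over paired electrode accuracies.

    The test is paired by default (each electrode contributes one accuracy
    under each cue); ``paired=False`` performs an independent-samples test
    instead.  ``preferred_cue`` is assigned by the sign of the mean
    difference when p < alpha.
    """
    electrodes = speed_map.electrodes
    if set(electrodes) != set(direction_map.electrodes):
        raise ValueError("speed and direction maps cover different electrodes")
    s = speed_map.gammas(electrodes)
    d = direction_map.gammas(electrodes)

    if np.allclose(s, d):
        t_stat, p_val = 0.0, 1.0
    elif paired:
        t_stat, p_val = spstats.ttest_rel(s, d)
    else:
        t_stat, p_val = spstats.ttest_ind(s, d)

    if np.ptp(s) == 0 or np.ptp(d) == 0:
        r, note = float("nan"), "undefined: at least one accuracy vector is constant"
    else:
        r = float(spstats.pearsonr(s, d).statistic)
        note = ""

    if p_val < alpha:
        preferred = "speed" if s.mean() > d.mean() else "direction"
    else:
        preferred = "none"

    return CueComparison(
        subject=subject,
        condition=speed_map.condition,
        electrodes=electrodes,
        speed_gamma=s,
        direction_gamma=d,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        pearson_r=r,
        pearson_note=note,
        preferred_cue=preferred,
        alpha=alpha,
    )
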