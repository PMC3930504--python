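"""Empirical probabilities, composite scores and scenario likelihood ratios.

Observed statistic values are located within simulated null ensembles: the
empirical percentile F is folded into a two-tailed probability
p = 2 min(F, 1-F), so a value at the ensemble median scores 1 and values in
either tail score small.  Probabilities for a combination of statistics are
multiplied into a composite, and the likelihood ratio of a sweep scenario
against neutrality is the ratio of the two composites, both computed under
the same recombination landscape.

Combinations must cover the three complementary signatures of a selective
sweep - population differentiation (FST, dDAF), haplotype structure
(XP-EHH) and the site frequency spectrum (Tajima's D, Fu & Li's D,
Fay & Wu's H) - and FST and dDAF never co-occur (they are nearly redundant).

Probabilities are floored at 1/R (R = ensemble size) so that an observation
outside the simulated range yields a small finite probability rather than
zero; floored values are flagged in the evaluation metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SIGNATURE_CLASSES",
    "StatisticCombination",
    "ScenarioEvaluation",
    "two_tailed_prob",
    "composite_prob",
    "likelihood_ratio",
    "enumerate_combinations",
    "evaluate_table",
    "per_statistic_table",
]

SIGNATURE_CLASSES: dict[str, str] = {
    "fst": "differentiation",
    "ddaf": "differentiation",
    "xp_ehh": "haplotype",
    "tajima_d": "sfs",
    "fu_li_d": "sfs",
    "fay_wu_h": "sfs",
}


@dataclass(frozen=True)
class StatisticCombination:
    """A set of statistics covering all three sweep signatures."""

    members: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        classes = set()
        for m in self.members:
            if m not in SIGNATURE_CLASSES:
                raise ValueError(f"unknown statistic {m!r}")
            classes.add(SIGNATURE_CLASSES[m])
        if classes != {"differentiation", "haplotype", "sfs"}:
            raise ValueError(
                "a combination needs at least one statistic from each of the "
                "three signature classes (differentiation, haplotype, SFS)"
            )
        if "fst" in self.members and "ddaf" in self.members:
            raise ValueError("FST and dDAF must not co-occur in a combination")
        if not self.name:
            object.__setattr__(self, "name", "-".join(self.members))


def two_tailed_prob(
    observed: float, ensemble_values: np.ndarray, floor: bool = True
) -> float:
    """Two-tailed empirical probability of one observation in an ensemble.

    F = #(ensemble <= observed) / R (ties count as <=); p = 2 min(F, 1-F),
    so an observation at the median scores exactly 1.  With ``floor`` the
    result is bounded below by 1/R.  NaN observations give NaN.
    """
    ens = np.asarray(ensemble_values, dtype=float)
    ens = ens[~np.isnan(ens)]
    if ens.size == 0:
        raise ValueError("ensemble must contain at least one defined value")
    if np.isnan(observed):
        return float("nan")
    r = ens.size
    f = float(np.sum(ens <= observed)) / r
    p = 2.0 * min(f, 1.0 - f)
    if floor:
        p = max(p, 1.0 / r)
    return p


def composite_prob(
    per_statistic_probs: dict[str, float], combination: StatisticCombination
) -> float:
    """Product of the member statistics' empirical probabilities."""
    prod = 1.0
    for m in combination.members:
        if m not in per_statistic_probs:
            raise KeyError(f"missing probability for statistic {m!r}")
        p = per_statistic_probs[m]
        if np.isnan(p):
            raise ValueError(f"probability for statistic {m!r} is undefined")
        prod *= p
    return prod


def likelihood_ratio(composite_sweep: float, composite_neutral: float) -> float:
    """P(observed | sweep) / P(observed | neutral); > 1 favors the sweep."""
    if composite_sweep <= 0 or composite_neutral <= 0:
        raise ValueError("composite probabilities must be positive")
    return composite_sweep / composite_neutral


def enumerate_combinations(
    available_statistics: tuple[str, ...] = tuple(SIGNATURE_CLASSES),
    allow_ddaf: bool = False,
) -> list[StatisticCombination]:
    """All minimal one-per-class combinations plus the all-statistics set.

    By default dDAF-containing duplicates of FST combinations are excluded,
    and the all-statistics set is {FST, XP-EHH, Tajima's D, Fu & Li's D,
    Fay & Wu's H}.
    """
    by_class: dict[str, list[str]] = {"differentiation": [], "haplotype": [], "sfs": []}
    for s in available_statistics:
        cls = SIGNATURE_CLASSES.get(s)
        if cls is None:
            raise ValueError(f"unknown statistic {s!r}")
        if s == "ddaf" and not allow_ddaf:
            continue
        by_class[cls].append(s)
    for cls, members in by_class.items():
        if not members:
            raise ValueError(f"no available statistic for signature class {cls!r}")
    minimal = [
        StatisticCombination(members=combo)
        for combo in product(*by_class.values())
    ]
    all_members = tuple(
        s for cls in ("differentiation", "haplotype", "sfs") for s in by_class[cls]
        if not (s == "ddaf" and "fst" in by_class["differentiation"])
    )
    combos = list(minimal)
    if set(all_members) not in [set(c.members) for c in minimal]:
        combos.append(StatisticCombination(members=all_members, name="all_combined"))
    return combos


@dataclass
class ScenarioEvaluation:
    """Evaluation of one sweep scenario against observed summaries."""

    scenario: str
    statistic_probs: dict[str, float]
    composite_probs: dict[str, float]
    likelihood_ratios: dict[str, float]
    floored_statistics: tuple[str, ...] = ()
    skipped_combinations: dict[str, str] = field(default_factory=dict)


def _scenario_probs(
    observed: dict[str, float], summaries: pd.DataFrame
) -> tuple[dict[str, float], list[str]]:
    probs: dict[str, float] = {}
    floored: list[str] = []
    for stat in summaries.columns:
        if stat not in observed:
            continue
        ens = summaries[stat].to_numpy(dtype=float)
        p = two_tailed_prob(observed[stat], ens)
        pre = two_tailed_prob(observed[stat], ens, floor=False)
        if not np.isnan(p) and pre < p:
            floored.append(stat)
        probs[stat] = p
    return probs, floored


def evaluate_table(
    observed_summaries: dict[str, float],
    ensembles: dict[str, pd.DataFrame],
    combinations: list[StatisticCombination] | None = None,
    neutral_scenario: str = "neutral_hotspot",
) -> list[ScenarioEvaluation]:
    """Evaluate observed summaries against every scenario ensemble.

    ``ensembles`` maps scenario names to per-replicate summary frames; the
    neutral reference (same recombination landscape as the sweep scenarios,
    per the composite-likelihood convention) must be present.  Likelihood
    ratios are reported for sweep scenarios sharing the neutral scenario's
    landscape; every scenario gets per-statistic probabilities.  A
    combination containing an undefined observed statistic is skipped with a
    logged reason; the remainder are still reported.
    """
    if neutral_scenario not in ensembles:
        raise ValueError(
            f"missing neutral reference ensemble {neutral_scenario!r}; "
            f"available: {sorted(ensembles)}"
        )
    combinations = combinations or enumerate_combinations()
    neutral_probs, _ = _scenario_probs(
        observed_summaries, ensembles[neutral_scenario]
    )
    evaluations: list[ScenarioEvaluation] = []
    for name, summaries in ensembles.items():
        probs, floored = _scenario_probs(observed_summaries, summaries)
        composites: dict[str, float] = {}
        lrs: dict[str, float] = {}
        skipped: dict[str, str] = {}
        for combo in combinations:
            undefined = [m for m in combo.members if np.isnan(probs.get(m, np.nan))]
            if undefined:
                reason = f"undefined observed statistic(s): {', '.join(undefined)}"
                skipped[combo.name] = reason
                logger.warning("scenario %s, %s skipped: %s", name, combo.name, reason)
                continue
            composites[combo.name] = composite_prob(probs, combo)
            if name != neutral_scenario:
                neutral_undef = [
                    m for m in combo.members
                    if np.isnan(neutral_probs.get(m, np.nan))
                ]
                if not neutral_undef:
                    lrs[combo.name] = likelihood_ratio(
                        composites[combo.name],
                        composite_prob(neutral_probs, combo),
                    )
        evaluations.append(
            ScenarioEvaluation(
                scenario=name,
                statistic_probs=probs,
                composite_probs=composites,
                likelihood_ratios=lrs,
                floored_statistics=tuple(floored),
                skipped_combinations=skipped,
            )
        )
    return evaluations


def likelihood_table(
    evaluations: list[ScenarioEvaluation],
    neutral_scenario: str = "neutral_hotspot",
) -> pd.DataFrame:
    """Combination x scenario table of likelihood ratios vs neutrality."""
    rows: dict[str, dict[str, float]] = {}
    for ev in evaluations:
        if ev.scenario == neutral_scenario:
            continue
        for combo, lr in ev.likelihood_ratios.items():
            rows.setdefault(combo, {})[ev.scenario] = lr
    return pd.DataFrame(rows).T.sort_index()


def per_statistic_table(evaluations: list[ScenarioEvaluation]) -> pd.DataFrame:
    """Statistic x scenario table of two-tailed empirical probabilities."""
    return pd.DataFrame(
        {ev.scenario: ev.statistic_probs for ev in evaluations}
    ).sort_index()
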