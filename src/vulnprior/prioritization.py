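"""The filtration waterfall: from screen matrices to a ranked target list.

Stages:

1. keep genes essential (dependency probability >= threshold) in >= 1 line;
2. intersect with the druggable gene universe;
3. remove the union of common-essential and core-fitness genes;
4. remove genes essential in fewer than ``min_frac`` of screened lines.

Survivors are ranked by number of dependent lines (descending), then median
gene-effect score over the dependent lines (ascending, i.e. strongest
dependency first), then symbol.  Every stage is recorded in a
:class:`PrioritizationAudit` whose conservation law (n_in = n_out +
|removed|) is enforced at construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, EmptySetError
from .panel_io import GeneSet, ScreenMatrix

logger = logging.getLogger(__name__)

DEFAULT_PROB_THRESHOLD = 0.5
DEFAULT_MIN_FRAC = 0.09

SUMMARY_COLUMNS = [
    "n_essential",
    "n_screened",
    "frac_essential",
    "median_effect_dependent",
    "median_effect_all",
]


@dataclass
class EssentialityCall:
    """Boolean line x gene essentiality matrix plus per-gene screened counts."""

    essential: pd.DataFrame  # bool, lines x genes
    screened_n: pd.Series  # per gene: lines with non-missing probability
    threshold: float

    @property
    def n_essential(self) -> pd.Series:
        return self.essential.sum(axis=0).astype(int)


def call_essential(
    prob: ScreenMatrix, threshold: float = DEFAULT_PROB_THRESHOLD
) -> EssentialityCall:
    """Call a (line, gene) essential when its dependency probability >= threshold.

    The threshold is inclusive.  Missing probabilities are never essential
    and do not count toward the screened denominator.
    """
    if prob.role != "probability":
        raise ConfigError(f"call_essential needs a probability matrix, got role {prob.role!r}")
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"probability threshold {threshold} outside (0, 1]")
    vals = prob.data
    essential = (vals >= threshold).fillna(False).astype(bool)
    screened = vals.notna().sum(axis=0).astype(int)
    return EssentialityCall(essential, screened, threshold)


def summarize_essentiality(effect: ScreenMatrix, calls: EssentialityCall) -> pd.DataFrame:
    """Per-gene dependency summary: counts, fraction, and median effects.

    ``median_effect_dependent`` is the median Chronos effect over the lines
    where the gene is essential (NaN when there are none);
    ``median_effect_all`` is over every line with a non-missing effect.
    """
    eff = effect.data
    ess = calls.essential
    extra_genes = set(eff.columns) ^ set(ess.columns)
    extra_lines = set(eff.index) ^ set(ess.index)
    if extra_genes or extra_lines:
        raise AlignmentError(
            "effect and probability matrices disagree: "
            f"genes {sorted(extra_genes)[:5]}, lines {sorted(extra_lines)[:5]}"
        )
    ess = ess.loc[eff.index, eff.columns]

    n_essential = ess.sum(axis=0).astype(int)
    n_screened = calls.screened_n.loc[eff.columns]
    masked = eff.where(ess)  # effects restricted to dependent lines
    summary = pd.DataFrame(
        {
            "n_essential": n_essential,
            "n_screened": n_screened,
            "frac_essential": np.where(
                n_screened > 0, n_essential / n_screened.replace(0, np.nan), np.nan
            ),
            "median_effect_dependent": masked.median(axis=0),
            "median_effect_all": eff.median(axis=0),
        }
    )
    summary.index.name = "gene"
    return summary


@dataclass
class WaterfallStage:
    stage_name: str
    n_in: int
    n_out: int
    removed: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError(
                f"stage {self.stage_name}: n_in={self.n_in} n_out={self.n_out} "
                f"but |removed|={len(self.removed)}"
            )


@dataclass
class PrioritizationAudit:
    """The full filter waterfall: per-stage counts, removed genes, parameters."""

    stages: list[WaterfallStage]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"audit broken: {prev.stage_name}.n_out={prev.n_out} != "
                    f"{nxt.stage_name}.n_in={nxt.n_in}"
                )

    def stage(self, name: str) -> WaterfallStage:
        for s in self.stages:
            if s.stage_name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "parameters": dict(self.parameters),
            "stages": [
                {
                    "stage_name": s.stage_name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": len(s.removed),
                    "removed": sorted(s.removed),
                }
                for s in self.stages
            ],
        }


def run_waterfall(
    summary: pd.DataFrame,
    druggable: GeneSet,
    common_essential: GeneSet,
    core_fitness: GeneSet,
    min_frac: float = DEFAULT_MIN_FRAC,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    strict: bool = True,
    rank_by: str = "median_effect_dependent",
) -> tuple[pd.DataFrame, PrioritizationAudit]:
    """Run the four-stage filter over a per-gene essentiality summary.

    Returns the ranked survivor table (with a 1-based ``rank`` column) and
    the stage-by-stage audit.  ``rank_by`` selects which median is the
    secondary sort key (``median_effect_dependent`` by default;
    ``median_effect_all`` selectable).
    """
    if strict and len(druggable) == 0:
        raise EmptySetError("druggable gene set is empty (strict mode)")
    if rank_by not in ("median_effect_dependent", "median_effect_all"):
        raise ConfigError(f"unknown rank_by {rank_by!r}")
    if not 0.0 <= min_frac <= 1.0:
        raise ConfigError(f"min_frac {min_frac} outside [0, 1]")

    universe = set(summary.index.astype(str))
    stages: list[WaterfallStage] = []

    def apply(name: str, keep: set[str], current: set[str]) -> set[str]:
        removed = current - keep
        stages.append(
            WaterfallStage(name, len(current), len(current) - len(removed), frozenset(removed))
        )
        return current - removed

    ess = set(summary.index[summary["n_essential"] >= 1].astype(str))
    current = apply("essential_in_any_line", ess, universe)
    current = apply("druggable_intersection", set(druggable.symbols), current)
    excluded = set(common_essential.symbols) | set(core_fitness.symbols)
    current = apply("exclude_common_and_core", current - excluded, current)
    frequent = set(summary.index[summary["frac_essential"] >= min_frac].astype(str))
    current = apply("frequency_filter", frequent, current)

    ranked = _rank(summary.loc[sorted(current)].copy(), rank_by)

    audit = PrioritizationAudit(
        stages,
        parameters={
            "prob_threshold": prob_threshold,
            "min_frac": min_frac,
            "rank_by": rank_by,
        },
    )
    return ranked, audit


def _rank(table: pd.DataFrame, rank_by: str) -> pd.DataFrame:
    table = table.copy()
    table["_symbol"] = table.index.astype(str)
    table = table.sort_values(
        by=["n_essential", rank_by, "_symbol"], ascending=[False, True, True]
    ).drop(columns="_symbol")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass(frozen=True)
class ReleaseComparison:
    common: frozenset[str]
    added: frozenset[str]
    removed: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "added": len(self.added),
            "removed": len(self.removed),
        }


def compare_releases(list_a: GeneSet, list_b: GeneSet) -> ReleaseComparison:
    """Compare two prioritized lists: common = A∩B, added = B∖A, removed = A∖B."""
    a, b = set(list_a.symbols), set(list_b.symbols)
    return ReleaseComparison(frozenset(a & b), frozenset(b - a), frozenset(a - b))


def scatter_table(
    ranked: pd.DataFrame,
    common_essential: GeneSet | None = None,
    core_fitness: GeneSet | None = None,
    min_frac: float = DEFAULT_MIN_FRAC,
    effect_column: str = "median_effect_dependent",
) -> pd.DataFrame:
    """Plot-ready table: percent of lines dependent vs median gene effect.

    One row per gene in rank order, with membership flags for the
    common-essential / core-fitness / low-frequency overlays.
    """
    ces = common_essential.symbols if common_essential else frozenset()
    cfg = core_fitness.symbols if core_fitness else frozenset()
    symbols = ranked.index.astype(str)
    table = pd.DataFrame(
        {
            "gene": symbols,
            "pct_essential": (ranked["frac_essential"].astype(float) * 100.0).round(6),
            "median_effect": ranked[effect_column].astype(float),
            "is_common_essential": [s in ces for s in symbols],
            "is_core_fitness": [s in cfg for s in symbols],
            "is_low_frequency": (ranked["frac_essential"] < min_frac).to_numpy(),
        }
    ).reset_index(drop=True)
    return table


def clinical_triage(targets: pd.DataFrame) -> pd.DataFrame:
    """Flag prioritized targets whose clinical inhibitors could be repurposed.

    Expects columns ``gene``, ``max_phase`` (integer trial phase reached by
    any inhibitor) and ``has_disease_trial`` (boolean: a trial already
    exists for the cancer type of interest).  A target is ``repurposable``
    when an inhibitor has reached at least phase II elsewhere but no trial
    exists for the cancer type under study.
    """
    required = {"gene", "max_phase", "has_disease_trial"}
    missing = sorted(required - set(targets.columns))
    if missing:
        raise ConfigError(f"clinical triage table missing columns {missing}")
    out = targets.copy()
    out["has_phase2_inhibitor"] = out["max_phase"].astype(float) >= 2
    out["repurposable"] = out["has_phase2_inhibitor"] & ~out["has_disease_trial"].astype(bool)
    return out
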