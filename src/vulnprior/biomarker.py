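"""Genetic biomarkers of dependency.

* mutation-status flags and an effect-size-gated mutation/dependency
  association screen (significant ⟺ p < alpha AND |Cohen's d| >= gate);
* Pearson correlation of dependency with expression or copy number;
* GISTIC call classification, co-amplification frequencies, and
  amplification-stratified comparisons (Mann-Whitney);
* Kaplan-Meier curves with log-rank stratum comparison.

The screen applies no multiple-testing correction beyond the d-gate; a
Benjamini-Hochberg column is emitted for information only.  Cohen's d is
oriented mutant-minus-wildtype and the gate uses |d|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from . import stat_core
from .errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
)
from .panel_io import GeneSet, ScreenMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_D_GATE = 1.0
DEFAULT_MIN_PREVALENCE = 0.05

GISTIC_LEVELS = {
    -2: "deep_deletion",
    -1: "loss",
    0: "diploid",
    1: "gain",
    2: "amplification",
}


# ---------------------------------------------------------------------------
# mutation-dependency association
# ---------------------------------------------------------------------------


def mutation_flag(
    mutations: pd.DataFrame, gene: str, lines: Sequence[str]
) -> dict[str, str]:
    """Classify each line as mutant / wildtype / unknown for one gene.

    Mutant ⟺ the line has at least one record for the gene flagged hotspot
    or damaging.  Lines with records for other genes but none (flagged) for
    this one are wildtype.  Lines absent from the mutation table entirely
    are unknown and excluded downstream.
    """
    known = set(mutations["line_id"].astype(str))
    flagged = mutations[
        (mutations["gene"] == gene)
        & (mutations["is_hotspot"].astype(bool) | mutations["is_damaging"].astype(bool))
    ]
    mutant = set(flagged["line_id"].astype(str))
    out = {}
    for line in lines:
        line = str(line)
        if line not in known:
            out[line] = "unknown"
        elif line in mutant:
            out[line] = "mutant"
        else:
            out[line] = "wildtype"
    return out


@dataclass(frozen=True)
class AssociationResult:
    """One mutation-dependency test: group stats, p, Cohen's d, gate flag."""

    dependency_gene: str
    biomarker_gene: str
    n_mutant: int
    n_wildtype: int
    mean_mutant: float
    mean_wildtype: float
    t_statistic: float
    p_value: float
    cohens_d: float
    significant: bool


def associate(
    effect_vector: Mapping[str, float] | pd.Series,
    flags: Mapping[str, str],
    dependency_gene: str = "gene",
    biomarker_gene: str = "biomarker",
    alpha: float = DEFAULT_ALPHA,
    d_gate: float = DEFAULT_D_GATE,
    test: str = "welch_t",
) -> AssociationResult:
    """Two-sample t test of gene effect in mutant vs wildtype lines.

    Welch's t by default (Student's pooled t via ``test="student_t"``).
    Cohen's d = (mean_mutant - mean_wildtype) / pooled SD.  Unknown status
    excludes a line from both groups.  ``significant`` requires both
    p < alpha and |d| >= d_gate.
    """
    series = pd.Series(effect_vector, dtype=float)
    mut = [series[l] for l, f in flags.items() if f == "mutant" and l in series and not np.isnan(series[l])]
    wt = [series[l] for l, f in flags.items() if f == "wildtype" and l in series and not np.isnan(series[l])]
    if len(mut) < 2 or len(wt) < 2:
        raise InsufficientDataError(
            f"{dependency_gene} vs {biomarker_gene}: groups sized "
            f"{len(mut)}/{len(wt)}; need >= 2 each"
        )
    kernel = {"welch_t": stat_core.welch_t, "student_t": stat_core.student_t}.get(test)
    if kernel is None:
        raise ConfigError(f"unknown test {test!r}")
    res = kernel(mut, wt)
    d = stat_core.cohens_d(mut, wt)
    return AssociationResult(
        dependency_gene=dependency_gene,
        biomarker_gene=biomarker_gene,
        n_mutant=len(mut),
        n_wildtype=len(wt),
        mean_mutant=float(np.mean(mut)),
        mean_wildtype=float(np.mean(wt)),
        t_statistic=res.statistic,
        p_value=res.p_value,
        cohens_d=d,
        significant=bool(res.p_value < alpha and abs(d) >= d_gate),
    )


def association_screen(
    effect: ScreenMatrix,
    targets: GeneSet,
    biomarker_genes: GeneSet | Sequence[str],
    mutations: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    d_gate: float = DEFAULT_D_GATE,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    test: str = "welch_t",
) -> pd.DataFrame:
    """Full targets x biomarkers grid of mutation-dependency associations.

    Biomarker genes mutated in fewer than ``min_prevalence`` of lines with
    known status are excluded up front (recorded with status
    ``below_prevalence``).  A ``p_bh`` Benjamini-Hochberg column is added
    for information only; the significance gate is p < alpha AND |d| >=
    d_gate, as-is.
    """
    lines = effect.line_ids
    symbols = (
        sorted(biomarker_genes.symbols)
        if isinstance(biomarker_genes, GeneSet)
        else list(biomarker_genes)
    )
    records: list[dict] = []
    for biomarker in symbols:
        flags = mutation_flag(mutations, biomarker, lines)
        known = [l for l, f in flags.items() if f != "unknown"]
        n_mut = sum(1 for l in known if flags[l] == "mutant")
        prevalence = n_mut / len(known) if known else 0.0
        if prevalence < min_prevalence:
            records.append(
                {
                    "dependency_gene": "",
                    "biomarker_gene": biomarker,
                    "status": "below_prevalence",
                    "prevalence": prevalence,
                }
            )
            continue
        for target in sorted(targets.symbols):
            if target not in effect.data.columns:
                records.append(
                    {
                        "dependency_gene": target,
                        "biomarker_gene": biomarker,
                        "status": "target_not_in_matrix",
                    }
                )
                continue
            try:
                res = associate(
                    effect.column(target),
                    flags,
                    dependency_gene=target,
                    biomarker_gene=biomarker,
                    alpha=alpha,
                    d_gate=d_gate,
                    test=test,
                )
            except (InsufficientDataError, DegenerateDataError) as exc:
                records.append(
                    {
                        "dependency_gene": target,
                        "biomarker_gene": biomarker,
                        "status": f"error: {exc}",
                    }
                )
                continue
            records.append(
                {
                    "dependency_gene": target,
                    "biomarker_gene": biomarker,
                    "n_mutant": res.n_mutant,
                    "n_wildtype": res.n_wildtype,
                    "mean_mutant": res.mean_mutant,
                    "mean_wildtype": res.mean_wildtype,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "cohens_d": res.cohens_d,
                    "prevalence": prevalence,
                    "significant": res.significant,
                    "status": "ok",
                }
            )
    table = pd.DataFrame(records)
    if "p_value" in table.columns:
        ok = table["status"] == "ok"
        table.loc[ok, "p_bh"] = _benjamini_hochberg(table.loc[ok, "p_value"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (informational column only)."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# dependency vs covariate correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def dependency_expression_correlation(
    effect_vector: Mapping[str, float] | pd.Series,
    covariate_vector: Mapping[str, float] | pd.Series,
) -> CorrelationResult:
    """Pearson correlation of a dependency profile with a covariate profile.

    Vectors are joined on shared line ids; the p-value comes from the t
    distribution with n - 2 degrees of freedom.
    """
    eff = pd.Series(effect_vector, dtype=float)
    cov = pd.Series(covariate_vector, dtype=float)
    shared = eff.index.intersection(cov.index)
    r, p, n = stat_core.pearson_corr(eff.loc[shared].to_numpy(), cov.loc[shared].to_numpy())
    return CorrelationResult(r, p, n)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def classify_gistic(code: int) -> str:
    """Map a GISTIC code in {-2..2} to its copy-number class name."""
    code = int(code)
    if code not in GISTIC_LEVELS:
        raise ValueError(f"GISTIC code {code} outside {{-2..2}}")
    return GISTIC_LEVELS[code]


def is_copy_gain(code: int) -> bool:
    """Copy-gain predicate: GISTIC code >= 1 (gain or amplification)."""
    classify_gistic(code)
    return int(code) >= 1


def coamplification(
    anchor: str,
    partners: GeneSet | Sequence[str],
    calls: pd.DataFrame,
    level: int = 2,
) -> pd.DataFrame:
    """Per-partner co-amplification fraction among anchor-amplified tumours.

    ``calls`` is a tumour x gene GISTIC matrix; "amplified" means code >=
    ``level`` (2 = amplification, 1 would count any copy gain).
    """
    if anchor not in calls.columns:
        raise ConfigError(f"anchor gene {anchor!r} absent from GISTIC matrix")
    symbols = (
        sorted(partners.symbols) if isinstance(partners, GeneSet) else list(partners)
    )
    anchor_amp = calls.index[calls[anchor] >= level]
    if len(anchor_amp) == 0:
        raise DegenerateDataError(f"no tumours with {anchor} amplified at level >= {level}")
    rows = []
    for partner in symbols:
        if partner not in calls.columns:
            rows.append({"partner": partner, "n_both": 0, "n_anchor": len(anchor_amp), "fraction": np.nan})
            continue
        both = int((calls.loc[anchor_amp, partner] >= level).sum())
        rows.append(
            {
                "partner": partner,
                "n_both": both,
                "n_anchor": len(anchor_amp),
                "fraction": both / len(anchor_amp),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratifiedComparison:
    u_statistic: float
    p_value: float
    method: str
    n_amplified: int
    n_other: int
    median_amplified: float
    median_other: float


def stratify_by_amplification(
    values: Mapping[str, float] | pd.Series,
    amplified: Mapping[str, bool],
) -> StratifiedComparison:
    """Mann-Whitney comparison of a metric between amplified and other ids.

    Exact enumeration when both groups have <= 8 ids and no ties; otherwise
    the tie-corrected normal approximation.
    """
    series = pd.Series(values, dtype=float).dropna()
    amp = [series[i] for i in series.index if amplified.get(str(i), False)]
    other = [series[i] for i in series.index if not amplified.get(str(i), False)]
    if len(amp) < 2 or len(other) < 2:
        raise InsufficientDataError(
            f"amplification strata sized {len(amp)}/{len(other)}; need >= 2 each"
        )
    res = stat_core.mann_whitney(amp, other, mode="auto")
    return StratifiedComparison(
        u_statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
        n_amplified=len(amp),
        n_other=len(other),
        median_amplified=float(np.median(amp)),
        median_other=float(np.median(other)),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    chi_square: float
    p_value: float
    df: int
    medians: dict[str, float]
    curves: dict[str, pd.DataFrame]  # per stratum: timeline + survival prob


def km_logrank(
    tumours: pd.DataFrame, strata: Mapping[str, str]
) -> SurvivalComparison:
    """Log-rank comparison of Kaplan-Meier curves across tumour strata.

    ``tumours`` must carry tumour_id, os_months, os_event.  Each stratum
    needs at least one subject and, across strata, at least one event.
    """
    df = tumours.copy()
    df["tumour_id"] = df["tumour_id"].astype(str)
    df["stratum"] = df["tumour_id"].map(dict(strata))
    df = df.dropna(subset=["stratum", "os_months"])
    labels = sorted(df["stratum"].unique())
    if len(labels) < 2:
        raise InsufficientDataError(f"need >= 2 survival strata, got {labels}")
    for label in labels:
        if (df["stratum"] == label).sum() == 0:
            raise InsufficientDataError(f"stratum {label!r} has zero subjects")
    events = df["os_event"].astype(bool)
    if events.sum() == 0:
        raise InsufficientDataError("no events in any stratum; log-rank undefined")

    result = multivariate_logrank_test(
        df["os_months"].astype(float), df["stratum"], events.astype(int)
    )
    medians: dict[str, float] = {}
    curves: dict[str, pd.DataFrame] = {}
    for label in labels:
        sub = df[df["stratum"] == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"].astype(float), sub["os_event"].astype(bool), label=label)
        medians[label] = float(kmf.median_survival_time_)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[label] = curve
    return SurvivalComparison(
        chi_square=float(result.test_statistic),
        p_value=float(result.p_value),
        df=len(labels) - 1,
        medians=medians,
        curves=curves,
    )
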