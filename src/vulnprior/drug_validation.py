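"""Validate prioritized targets against inhibitor response data.

Cell lines are split into high / intermediate / low dependency strata by
the quartiles of the target's gene-effect distribution ("high" = most
negative effect).  Responses of high- vs low-dependency lines are then
compared with a Welch ANOVA plus Dunnett-adjusted contrasts against the
low-dependency stratum, falling back to a two-group test when only two
strata survive the join.  Response metrics are oriented so that lower
values mean a stronger response (ln IC50 or AUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import stat_core
from .errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    JoinError,
)
from .panel_io import GeneId

logger = logging.getLogger(__name__)

STRATA = ("high", "intermediate", "low")


@dataclass
class DependencyStrata:
    """Quartile-based dependency strata for one gene."""

    gene: GeneId
    assignment: dict[str, str]  # line_id -> high | intermediate | low
    q1: float
    q3: float

    def lines(self, stratum: str) -> list[str]:
        if stratum not in STRATA:
            raise ConfigError(f"unknown stratum {stratum!r}")
        return [l for l, s in self.assignment.items() if s == stratum]


def stratify_by_dependency(
    effect_vector: Mapping[str, float] | pd.Series, gene: GeneId | str = "gene"
) -> DependencyStrata:
    """Assign every line to a dependency stratum by effect-score quartiles.

    Quartiles use linear interpolation on the sorted values (position
    ``p * (n - 1)``).  Boundary membership is inclusive on both tails:
    high ⟺ effect <= q1, low ⟺ effect >= q3.
    """
    series = pd.Series(effect_vector, dtype=float).dropna()
    if series.size < 4:
        raise InsufficientDataError(
            f"stratification needs >= 4 non-missing effects, got {series.size}"
        )
    if series.nunique() == 1:
        raise DegenerateDataError("all effect values identical; quartiles undefined")
    q1, q3 = np.quantile(series.to_numpy(), [0.25, 0.75], method="linear")
    assignment = {
        str(line): ("high" if v <= q1 else "low" if v >= q3 else "intermediate")
        for line, v in series.items()
    }
    gid = gene if isinstance(gene, GeneId) else GeneId(str(gene))
    return DependencyStrata(gid, assignment, float(q1), float(q3))


@dataclass
class ValidationResult:
    """Outcome of the dependency-stratified drug-response comparison."""

    gene: str
    drug_id: str
    metric: str
    stratum_n: dict[str, int]
    stratum_mean: dict[str, float]
    omnibus: stat_core.TestResult
    pairwise_adjusted: dict[str, float] = field(default_factory=dict)
    direction: str = "none"  # "high_stronger" | "high_weaker" | "none"
    validated: bool = False
    dropped_strata: tuple[str, ...] = ()
    n_joined: int = 0
    n_dropped_lines: int = 0


def compare_response(
    strata: DependencyStrata,
    responses: pd.DataFrame,
    drug_id: str | None = None,
    metric: str = "ln_ic50",
    alpha: float = 0.05,
    two_group: str = "welch_t",
    dunnett_seed: int = 0,
    dunnett_mc: int = 100_000,
) -> ValidationResult:
    """Test whether high-dependency lines respond more strongly to a drug.

    With all three strata present: Welch ANOVA omnibus plus Dunnett-adjusted
    contrasts against the low-dependency control.  With two strata: Welch t
    (or Mann-Whitney via ``two_group="mann_whitney"``).  Strata with fewer
    than 2 response values are dropped with a warning.  ``validated`` means
    the high stratum responds more strongly (lower mean) than the low one
    with adjusted p < alpha.
    """
    rows = responses[responses["metric"] == metric]
    if drug_id is not None:
        rows = rows[rows["drug_id"] == drug_id]
    else:
        ids = rows["drug_id"].unique()
        if len(ids) != 1:
            raise ConfigError(f"response table holds {len(ids)} drugs; pass drug_id")
        drug_id = str(ids[0])
    rows = rows.dropna(subset=["value"])
    by_line = dict(zip(rows["line_id"].astype(str), rows["value"].astype(float)))

    joined: dict[str, list[float]] = {s: [] for s in STRATA}
    for line, stratum in strata.assignment.items():
        if line in by_line:
            joined[stratum].append(by_line[line])
    n_joined = sum(len(v) for v in joined.values())
    if n_joined == 0:
        raise JoinError(
            f"no overlap between dependency strata and response lines for drug {drug_id}"
        )
    n_dropped = len(by_line) - n_joined + sum(
        1 for l in strata.assignment if l not in by_line
    )

    dropped = tuple(s for s in STRATA if len(joined[s]) < 2)
    for s in dropped:
        logger.warning("drug %s: stratum %s has <2 responses; dropped", drug_id, s)
    usable = [s for s in STRATA if s not in dropped]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"drug {drug_id}: only {len(usable)} stratum has >= 2 responses"
        )

    means = {s: float(np.mean(joined[s])) for s in usable}
    ns = {s: len(joined[s]) for s in usable}

    pairwise: dict[str, float] = {}
    if len(usable) >= 3:
        omnibus = stat_core.welch_anova([joined[s] for s in usable])
        ordered = [s for s in usable if s != "low"] + ["low"]
        adj = stat_core.dunnett_adjust(
            [joined[s] for s in ordered],
            control_index=len(ordered) - 1,
            n_mc=dunnett_mc,
            seed=dunnett_seed,
        )
        pairwise = {f"{s}_vs_low": adj.adjusted[i] for i, s in enumerate(ordered[:-1])}
    else:
        a, b = (joined[s] for s in usable)
        if two_group == "welch_t":
            omnibus = stat_core.welch_t(a, b)
        elif two_group == "mann_whitney":
            omnibus = stat_core.mann_whitney(a, b)
        else:
            raise ConfigError(f"unknown two_group test {two_group!r}")
        if "low" in usable:
            other = next(s for s in usable if s != "low")
            pairwise = {f"{other}_vs_low": omnibus.p_value}

    direction = "none"
    if "high" in usable and "low" in usable:
        if means["high"] < means["low"]:
            direction = "high_stronger"
        elif means["high"] > means["low"]:
            direction = "high_weaker"
    validated = (
        direction == "high_stronger"
        and pairwise.get("high_vs_low", 1.0) < alpha
    )
    return ValidationResult(
        gene=strata.gene.symbol,
        drug_id=str(drug_id),
        metric=metric,
        stratum_n=ns,
        stratum_mean=means,
        omnibus=omnibus,
        pairwise_adjusted=pairwise,
        direction=direction,
        validated=validated,
        dropped_strata=dropped,
        n_joined=n_joined,
        n_dropped_lines=n_dropped,
    )


def dose_curve_groups(
    curves: pd.DataFrame, strata: DependencyStrata, drug_id: str | None = None
) -> tuple[pd.DataFrame, float, bool]:
    """Mean +/- SD viability per concentration for high vs low strata.

    Curves on misaligned concentration grids are linearly interpolated onto
    the union grid (the ``interpolated`` flag reports when this happened);
    outside a curve's measured range its endpoint values are carried.

    Returns ``(table, separation_score, interpolated)`` where the separation
    score is the mean over concentrations of (viability_high - viability_low);
    negative values mean high-dependency lines are less viable.
    """
    if drug_id is not None:
        curves = curves[curves["drug_id"] == drug_id]
    groups: dict[str, dict[str, np.ndarray]] = {"high": {}, "low": {}}
    for (drug, line), grp in curves.groupby(["drug_id", "line_id"]):
        stratum = strata.assignment.get(str(line))
        if stratum in groups:
            grp = grp.sort_values("concentration")
            groups[stratum][str(line)] = (
                grp["concentration"].to_numpy(float),
                grp["viability"].to_numpy(float),
            )
    for name, curveset in groups.items():
        if not curveset:
            raise InsufficientDataError(f"no dose curves in the {name!r} stratum")

    grids = [conc.tobytes() for cs in groups.values() for conc, _ in cs.values()]
    interpolated = len(set(grids)) > 1
    grid = np.unique(
        np.concatenate([conc for cs in groups.values() for conc, _ in cs.values()])
    )

    rows = []
    means: dict[str, np.ndarray] = {}
    for name, curveset in groups.items():
        mat = np.vstack(
            [np.interp(grid, conc, viab) for conc, viab in curveset.values()]
        )
        means[name] = mat.mean(axis=0)
        for i, c in enumerate(grid):
            rows.append(
                {
                    "concentration": c,
                    "stratum": name,
                    "mean_viability": mat[:, i].mean(),
                    "sd_viability": mat[:, i].std(ddof=1) if mat.shape[0] > 1 else 0.0,
                    "n_curves": mat.shape[0],
                }
            )
    separation = float((means["high"] - means["low"]).mean())
    table = pd.DataFrame(rows).sort_values(["concentration", "stratum"]).reset_index(drop=True)
    return table, separation, interpolated


def validate_targets(
    effect,
    responses: pd.DataFrame,
    target_symbols: list[str],
    metric: str = "ln_ic50",
    alpha: float = 0.05,
    dunnett_seed: int = 0,
) -> pd.DataFrame:
    """Run the stratified comparison for every (target, drug) pair available.

    ``effect`` is a ScreenMatrix of gene-effect scores; drugs are matched to
    targets via the ``target_genes`` column (semicolon-separated symbols).
    Pairs that fail preconditions are recorded with a ``status`` note rather
    than aborting the sweep.
    """
    records = []
    for target in target_symbols:
        if target not in effect.data.columns:
            records.append({"gene": target, "drug_id": "", "status": "target not in effect matrix"})
            continue
        try:
            strata = stratify_by_dependency(effect.column(target), target)
        except (InsufficientDataError, DegenerateDataError) as exc:
            records.append({"gene": target, "drug_id": "", "status": str(exc)})
            continue
        mask = responses["target_genes"].fillna("").str.split(";").map(
            lambda genes: target in [g.strip() for g in genes]
        )
        for drug in sorted(responses.loc[mask, "drug_id"].unique()):
            try:
                res = compare_response(
                    strata,
                    responses[mask],
                    drug_id=drug,
                    metric=metric,
                    alpha=alpha,
                    dunnett_seed=dunnett_seed,
                )
            except (InsufficientDataError, JoinError, DegenerateDataError) as exc:
                records.append({"gene": target, "drug_id": str(drug), "status": str(exc)})
                continue
            records.append(
                {
                    "gene": target,
                    "drug_id": res.drug_id,
                    "metric": res.metric,
                    "n_high": res.stratum_n.get("high", 0),
                    "n_intermediate": res.stratum_n.get("intermediate", 0),
                    "n_low": res.stratum_n.get("low", 0),
                    "mean_high": res.stratum_mean.get("high", np.nan),
                    "mean_low": res.stratum_mean.get("low", np.nan),
                    "omnibus_stat": res.omnibus.statistic,
                    "omnibus_p": res.omnibus.p_value,
                    "omnibus_method": res.omnibus.method,
                    "p_high_vs_low": res.pairwise_adjusted.get("high_vs_low", np.nan),
                    "direction": res.direction,
                    "validated": res.validated,
                    "status": "ok",
                }
            )
    return pd.DataFrame(records)
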