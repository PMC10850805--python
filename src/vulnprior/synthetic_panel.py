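"""Synthetic study generator with planted ground truth.

Produces a complete file bundle in the ``panel_io`` schemas — gene-effect
and dependency-probability matrices, expression, copy number, cell-line
annotations, mutation table, gene lists, drug responses, dose curves, and
a tumour cohort — so every pipeline stage is testable without downloads.

Design:

* gene class labels (planted target / common essential / core fitness /
  neutral) are fixed by the config alone; no RNG touches them;
* each output draws from its own RNG stream derived from the master seed,
  so adding a new output never perturbs existing ones;
* the same seed yields a byte-identical bundle.

Effect-score shape mirrors DepMap's scaling: non-essential genes centre at
0, pan-essential genes at -1, and lower scores mean stronger dependency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_io import (
    GeneId,
    GeneSet,
    ScreenMatrix,
    write_gene_set,
    write_matrix,
    write_table,
)

# stable stream indices; append only, never reorder
_STREAMS = {
    "effect": 0,
    "probability": 1,
    "expression": 2,
    "copy_number": 3,
    "mutations": 4,
    "drug": 5,
    "dose": 6,
    "tumour": 7,
    "survival": 8,
}

BIOMARKER_GENES = ("TP53", "PIK3CA", "CDKN2A", "NOTCH1", "FAT1")
AMPLICON_PARTNERS = ("PIK3CA", "SOX2", "ETV5", "BCL6", "TP63")


@dataclass(frozen=True)
class PanelConfig:
    """Everything the generator needs; truth labels derive from this alone."""

    n_lines: int = 87
    n_hnscc: int = 63  # remainder are tagged as the second subtype
    n_genes: int = 2000
    n_druggable: int = 260
    n_common_essential: int = 40
    n_core_fitness: int = 30
    n_planted_targets: int = 20
    planted_dependent_fraction: float = 0.3
    # per-class effect distributions: (mean, sd)
    effect_nonessential: tuple[float, float] = (0.0, 0.15)
    effect_essential: tuple[float, float] = (-1.0, 0.2)
    effect_planted_dependent: tuple[float, float] = (-0.6, 0.15)
    # mutation prevalences per biomarker gene
    biomarker_prevalence: tuple[tuple[str, float], ...] = (
        ("TP53", 0.80),
        ("PIK3CA", 0.30),
        ("CDKN2A", 0.25),
        ("NOTCH1", 0.15),
        ("FAT1", 0.20),
    )
    # (dependency target, biomarker gene, shift in noise-SD units applied
    #  to the target's effect in mutant lines)
    planted_association: tuple[tuple[str, str, float], ...] = ()
    # amplicon block: first gene is the anchor
    amplicon_genes: tuple[str, ...] = ("TGT0000",) + AMPLICON_PARTNERS
    amplicon_line_fraction: float = 0.2
    amplicon_damping: float = 0.5  # amplified lines' anchor effect scaled by (1 - damping)
    amplicon_tumour_amp_fraction: float = 0.123  # GISTIC code 2
    amplicon_tumour_gain_fraction: float = 0.577  # GISTIC code 1 (gain+amp ~= 0.70)
    # (drug_id, target symbol, slope linking effect score to ln IC50)
    planted_drugs: tuple[tuple[str, str, float], ...] = (("DRUG0001", "TGT0000", 2.0),)
    planted_expression_correlation: float = 0.6
    n_tumours: int = 523
    n_hpv_positive: int = 72
    n_hpv_unknown: int = 36
    survival_rate_gain: float = 0.02  # exponential hazard per month
    survival_rate_diploid: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        n_special = len(self._special_genes())
        n_classed = (
            self.n_planted_targets
            + self.n_common_essential
            + self.n_core_fitness
            + n_special
        )
        if n_classed > self.n_genes:
            raise ConfigError(
                f"class sizes sum to {n_classed} > n_genes={self.n_genes}"
            )
        if not 0.0 < self.planted_dependent_fraction < 1.0:
            raise ConfigError("planted_dependent_fraction must lie in (0, 1)")
        if self.n_hnscc > self.n_lines:
            raise ConfigError("n_hnscc exceeds n_lines")
        if self.n_hpv_positive + self.n_hpv_unknown > self.n_tumours:
            raise ConfigError("HPV-positive + unknown exceeds n_tumours")
        if self.n_druggable < self.n_planted_targets:
            raise ConfigError("n_druggable must cover the planted targets")

    # -- deterministic gene universe --------------------------------------

    def _special_genes(self) -> list[str]:
        seen: list[str] = []
        for sym in BIOMARKER_GENES + AMPLICON_PARTNERS:
            if sym not in seen:
                seen.append(sym)
        return seen

    def gene_classes(self) -> dict[str, str]:
        """Ordered symbol -> class mapping; pure function of the config."""
        self.validate()
        classes: dict[str, str] = {}
        for i in range(self.n_planted_targets):
            classes[f"TGT{i:04d}"] = "planted_target"
        for i in range(self.n_common_essential):
            classes[f"CES{i:04d}"] = "common_essential"
        for i in range(self.n_core_fitness):
            classes[f"CFG{i:04d}"] = "core_fitness"
        for sym in self._special_genes():
            classes[sym] = "neutral"
        i = 0
        while len(classes) < self.n_genes:
            sym = f"NEU{i:04d}"
            if sym not in classes:
                classes[sym] = "neutral"
            i += 1
        return classes

    def druggable_symbols(self) -> list[str]:
        """Planted targets + half of each exclusion class + neutral decoys."""
        classes = self.gene_classes()
        by_class: dict[str, list[str]] = {}
        for sym, cls in classes.items():
            by_class.setdefault(cls, []).append(sym)
        drug = list(by_class.get("planted_target", []))
        drug += by_class.get("common_essential", [])[: self.n_common_essential // 2]
        drug += by_class.get("core_fitness", [])[: self.n_core_fitness // 2]
        decoys = [s for s in by_class.get("neutral", []) if s.startswith("NEU")]
        need = self.n_druggable - len(drug)
        if need < 0:
            raise ConfigError("n_druggable smaller than mandatory druggable members")
        if need > len(decoys):
            raise ConfigError("not enough neutral genes to fill the druggable set")
        drug += decoys[:need]
        return drug


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth implied by a :class:`PanelConfig` (labels are RNG-free)."""

    gene_classes: dict[str, str]
    expected_waterfall_survivors: tuple[str, ...]
    planted_pairs: tuple[tuple[str, str, float], ...]
    drug_directions: dict[str, str]  # drug_id -> expected validation direction
    n_dependent_lines: int

    def to_dict(self) -> dict:
        return {
            "gene_classes": self.gene_classes,
            "expected_waterfall_survivors": list(self.expected_waterfall_survivors),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "drug_directions": dict(self.drug_directions),
            "n_dependent_lines": self.n_dependent_lines,
        }


@dataclass
class PanelBundle:
    """In-memory synthetic study; ``write`` emits the file bundle."""

    config: PanelConfig
    effect: ScreenMatrix
    probability: ScreenMatrix
    expression: ScreenMatrix
    copy_number: ScreenMatrix
    annotations: pd.DataFrame
    mutations: pd.DataFrame
    druggable: GeneSet
    common_essential: GeneSet
    core_fitness: GeneSet
    drug_response: pd.DataFrame
    dose_curves: pd.DataFrame
    tumours: pd.DataFrame
    gistic: pd.DataFrame
    truth: PlantedTruth
    amplified_lines: frozenset[str] = field(default_factory=frozenset)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def p(name: str) -> Path:
            paths[name] = out / name
            return paths[name]

        write_matrix(self.effect, p("effect.csv"))
        write_matrix(self.probability, p("probability.csv"))
        write_matrix(self.expression, p("expression.csv"))
        write_matrix(self.copy_number, p("copy_number.csv"))
        write_table(self.annotations, p("annotations.csv"))
        write_table(self.mutations, p("mutations.csv"))
        write_gene_set(self.druggable, p("druggable.txt"))
        write_gene_set(self.common_essential, p("common_essential.txt"))
        write_gene_set(self.core_fitness, p("core_fitness.txt"))
        write_table(self.drug_response, p("drug_response.csv"))
        write_table(self.dose_curves, p("dose_curves.csv"))
        write_table(self.tumours, p("tumours.csv"))
        self.gistic.index.name = "tumour_id"
        self.gistic.to_csv(p("tumour_gistic.csv"))
        p("truth.json").write_text(json.dumps(self.truth.to_dict(), indent=1, sort_keys=True) + "\n")
        return paths


def _rng(config: PanelConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def generate_panel(config: PanelConfig | None = None, out_dir: str | Path | None = None) -> PanelBundle:
    """Generate the full synthetic study for a config (writes files if asked)."""
    config = config or PanelConfig()
    config.validate()
    classes = config.gene_classes()
    symbols = list(classes)
    n_lines, n_genes = config.n_lines, len(symbols)
    line_ids = [f"LINE{i:04d}" for i in range(n_lines)]
    genes = [GeneId(sym, idx + 1) for idx, sym in enumerate(symbols)]
    col_index = {sym: j for j, sym in enumerate(symbols)}

    mu_ne, sd_ne = config.effect_nonessential
    mu_es, sd_es = config.effect_essential
    mu_pl, sd_pl = config.effect_planted_dependent

    # ---- effect + dependent-line structure -------------------------------
    rng_eff = _rng(config, "effect")
    effect = rng_eff.normal(mu_ne, sd_ne, size=(n_lines, n_genes))
    n_dep = int(round(config.planted_dependent_fraction * n_lines))
    dependent_mask = np.zeros((n_lines, n_genes), dtype=bool)
    for j, sym in enumerate(symbols):
        cls = classes[sym]
        if cls in ("common_essential", "core_fitness"):
            effect[:, j] = rng_eff.normal(mu_es, sd_es, size=n_lines)
            dependent_mask[:, j] = True
        elif cls == "planted_target":
            dep_lines = rng_eff.choice(n_lines, size=n_dep, replace=False)
            effect[dep_lines, j] = rng_eff.normal(mu_pl, sd_pl, size=n_dep)
            dependent_mask[dep_lines, j] = True

    # ---- amplicon structure in cell lines --------------------------------
    rng_cn = _rng(config, "copy_number")
    n_amp_lines = int(round(config.amplicon_line_fraction * n_lines))
    amp_line_idx = rng_cn.choice(n_lines, size=n_amp_lines, replace=False)
    amplified_lines = frozenset(line_ids[i] for i in amp_line_idx)
    copy_number = rng_cn.normal(0.0, 0.15, size=(n_lines, n_genes))
    amplicon_present = [g for g in config.amplicon_genes if g in col_index]
    for sym in amplicon_present:
        copy_number[amp_line_idx, col_index[sym]] += 1.2
    # amplified lines depend less on the anchor (damped toward 0)
    if amplicon_present:
        anchor_j = col_index[amplicon_present[0]]
        effect[amp_line_idx, anchor_j] *= 1.0 - config.amplicon_damping

    # ---- mutations -------------------------------------------------------
    rng_mut = _rng(config, "mutations")
    mut_rows: list[dict] = []
    mutant_lines: dict[str, np.ndarray] = {}
    for gene_sym, prevalence in config.biomarker_prevalence:
        mask = rng_mut.random(n_lines) < prevalence
        mutant_lines[gene_sym] = mask
        for i in np.flatnonzero(mask):
            hotspot = bool(rng_mut.random() < 0.5)
            mut_rows.append(
                {
                    "line_id": line_ids[i],
                    "gene": gene_sym,
                    "variant_class": "missense" if hotspot else "frameshift",
                    "is_hotspot": hotspot,
                    "is_damaging": not hotspot,
                }
            )
    covered = {r["line_id"] for r in mut_rows}
    for line in line_ids:  # guarantee table coverage: silent benign record
        if line not in covered:
            mut_rows.append(
                {
                    "line_id": line,
                    "gene": symbols[-1],
                    "variant_class": "silent",
                    "is_hotspot": False,
                    "is_damaging": False,
                }
            )
    mutations = pd.DataFrame(mut_rows)

    # planted mutation-dependency associations shift the target's effect in
    # mutant lines; the shift is in units of the column's pre-shift SD so the
    # realized Cohen's d tracks the configured magnitude
    for target, biomarker, shift in config.planted_association:
        if target not in col_index or biomarker not in mutant_lines:
            raise ConfigError(f"planted association ({target}, {biomarker}) not in universe")
        j = col_index[target]
        effect[mutant_lines[biomarker], j] += shift * float(effect[:, j].std(ddof=1))

    # ---- probability -----------------------------------------------------
    rng_prob = _rng(config, "probability")
    u = rng_prob.random(size=(n_lines, n_genes))
    probability = np.where(dependent_mask, 0.6 + 0.4 * u, 0.4 * u)

    # ---- expression ------------------------------------------------------
    rng_expr = _rng(config, "expression")
    expression = rng_expr.normal(5.0, 1.0, size=(n_lines, n_genes))
    rho = config.planted_expression_correlation
    for j, sym in enumerate(symbols):
        if classes[sym] == "planted_target":
            z = (effect[:, j] - effect[:, j].mean()) / max(effect[:, j].std(), 1e-12)
            noise = rng_expr.standard_normal(n_lines)
            expression[:, j] = 5.0 + rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
    expression = np.clip(expression, 0.0, None)

    # ---- drug responses --------------------------------------------------
    rng_drug = _rng(config, "drug")
    rng_dose = _rng(config, "dose")
    drug_rows: list[dict] = []
    dose_rows: list[dict] = []
    concentrations = 10.0 ** np.arange(-3, 4)
    drug_directions: dict[str, str] = {}
    for drug_id, target, slope in config.planted_drugs:
        if target not in col_index:
            raise ConfigError(f"planted drug target {target!r} not in gene universe")
        ln_ic50 = slope * effect[:, col_index[target]] + rng_drug.normal(0.0, 0.3, n_lines)
        drug_directions[drug_id] = "high_stronger" if slope > 0 else "high_weaker"
        for i, line in enumerate(line_ids):
            drug_rows.append(
                {
                    "drug_id": drug_id,
                    "drug_name": f"{target} inhibitor",
                    "target_genes": target,
                    "line_id": line,
                    "metric": "ln_ic50",
                    "value": float(ln_ic50[i]),
                }
            )
            ic50 = float(np.exp(ln_ic50[i]))
            for c in concentrations:
                viab = 1.0 / (1.0 + c / ic50)
                viab = float(np.clip(viab + rng_dose.normal(0.0, 0.02), 0.0, 1.0))
                dose_rows.append(
                    {
                        "drug_id": drug_id,
                        "line_id": line,
                        "concentration": float(c),
                        "viability": viab,
                    }
                )
    drug_response = pd.DataFrame(
        drug_rows,
        columns=["drug_id", "drug_name", "target_genes", "line_id", "metric", "value"],
    )
    dose_curves = pd.DataFrame(
        dose_rows, columns=["drug_id", "line_id", "concentration", "viability"]
    )

    # ---- annotations -----------------------------------------------------
    annotations = pd.DataFrame(
        {
            "line_id": line_ids,
            "lineage": ["upper_aerodigestive"] * n_lines,
            "subtype": ["HNSCC"] * config.n_hnscc
            + ["ESCC"] * (n_lines - config.n_hnscc),
            "hpv_status": ["negative"] * n_lines,
            "amplicon_amplified": [line in amplified_lines for line in line_ids],
        }
    )

    # ---- tumour cohort ---------------------------------------------------
    rng_tum = _rng(config, "tumour")
    rng_surv = _rng(config, "survival")
    n_t = config.n_tumours
    tumour_ids = [f"TUM{i:04d}" for i in range(n_t)]
    hpv = (
        ["positive"] * config.n_hpv_positive
        + ["unknown"] * config.n_hpv_unknown
        + ["negative"] * (n_t - config.n_hpv_positive - config.n_hpv_unknown)
    )
    gistic_genes = list(dict.fromkeys(list(config.amplicon_genes) + list(BIOMARKER_GENES)))
    gistic_genes = [g for g in gistic_genes if g in col_index]
    gistic = np.zeros((n_t, len(gistic_genes)), dtype=int)
    u_state = rng_tum.random(n_t)
    amp_state = np.where(
        u_state < config.amplicon_tumour_amp_fraction,
        2,
        np.where(
            u_state < config.amplicon_tumour_amp_fraction + config.amplicon_tumour_gain_fraction,
            1,
            0,
        ),
    )
    for j, sym in enumerate(gistic_genes):
        if sym in amplicon_present:
            flip = rng_tum.random(n_t) < 0.05  # occasional breakpoint inside the block
            gistic[:, j] = np.where(flip, 0, amp_state)
        else:
            noise = rng_tum.random(n_t)
            gistic[:, j] = np.where(noise < 0.03, -1, np.where(noise > 0.97, 1, 0))
    tp53_mutant = rng_tum.random(n_t) < dict(config.biomarker_prevalence).get("TP53", 0.8)

    rate = np.where(amp_state >= 1, config.survival_rate_gain, config.survival_rate_diploid)
    latent = rng_surv.exponential(1.0 / rate)
    censor = rng_surv.uniform(0.0, 120.0, n_t)
    os_months = np.minimum(latent, censor)
    os_event = latent <= censor
    tumours = pd.DataFrame(
        {
            "tumour_id": tumour_ids,
            "hpv_status": hpv,
            "tp53_mutant": tp53_mutant,
            "os_months": np.round(os_months, 4),
            "os_event": os_event,
        }
    )
    gistic_df = pd.DataFrame(gistic, index=tumour_ids, columns=gistic_genes)

    # ---- assemble --------------------------------------------------------
    def matrix(role: str, values: np.ndarray) -> ScreenMatrix:
        df = pd.DataFrame(np.round(values, 6), index=line_ids, columns=symbols)
        return ScreenMatrix(role, df, list(genes))

    druggable_set = GeneSet.from_symbols(config.druggable_symbols(), "druggable", "druggable")
    ces_set = GeneSet.from_symbols(
        [s for s, c in classes.items() if c == "common_essential"],
        "common_essential",
        "common_essential",
    ) if config.n_common_essential else GeneSet("common_essential", "common_essential", frozenset())
    cfg_set = GeneSet.from_symbols(
        [s for s, c in classes.items() if c == "core_fitness"], "core_fitness", "core_fitness"
    ) if config.n_core_fitness else GeneSet("core_fitness", "core_fitness", frozenset())

    survivors: tuple[str, ...] = ()
    if n_dep / n_lines >= 0.09:
        survivors = tuple(s for s, c in classes.items() if c == "planted_target")
    truth = PlantedTruth(
        gene_classes=classes,
        expected_waterfall_survivors=survivors,
        planted_pairs=tuple(config.planted_association),
        drug_directions=drug_directions,
        n_dependent_lines=n_dep,
    )

    bundle = PanelBundle(
        config=config,
        effect=matrix("effect", effect),
        probability=matrix("probability", np.round(probability, 6)),
        expression=matrix("expression", expression),
        copy_number=matrix("copy_number", copy_number),
        annotations=annotations,
        mutations=mutations,
        druggable=druggable_set,
        common_essential=ces_set,
        core_fitness=cfg_set,
        drug_response=drug_response,
        dose_curves=dose_curves,
        tumours=tumours,
        gistic=gistic_df,
        truth=truth,
        amplified_lines=amplified_lines,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def generate_null_panel(config: PanelConfig | None = None, out_dir: str | Path | None = None) -> PanelBundle:
    """A panel with zero planted effects, for calibration and false-positive checks."""
    config = config or PanelConfig()
    null_config = dataclasses.replace(
        config,
        n_planted_targets=0,
        planted_association=(),
        planted_drugs=(),
        amplicon_genes=tuple(g for g in config.amplicon_genes if not g.startswith("TGT")),
        amplicon_damping=0.0,
    )
    return generate_panel(null_config, out_dir=out_dir)
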