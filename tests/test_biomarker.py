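import numpy as np
import pandas as pd
import pytest

from vulnprior import biomarker as bm
from vulnprior.errors import ConfigError, DegenerateDataError, InsufficientDataError
from vulnprior.panel_io import GeneSet
from vulnprior.synthetic_panel import PanelConfig, generate_panel


def mut_table(rows):
    return pd.DataFrame(
        rows, columns=["line_id", "gene", "variant_class", "is_hotspot", "is_damaging"]
    )


class TestMutationFlag:
    TABLE = mut_table(
        [
            ("L1", "TP53", "missense", True, False),
            ("L2", "TP53", "silent", False, False),
            ("L2", "EGFR", "missense", True, True),
            ("L4", "EGFR", "frameshift", False, True),
        ]
    )

    def test_hotspot_is_mutant(self):
        flags = bm.mutation_flag(self.TABLE, "TP53", ["L1"])
        assert flags["L1"] == "mutant"

    def test_unflagged_record_is_wildtype(self):
        flags = bm.mutation_flag(self.TABLE, "TP53", ["L2"])
        assert flags["L2"] == "wildtype"

    def test_absent_line_is_unknown(self):
        flags = bm.mutation_flag(self.TABLE, "TP53", ["L3"])
        assert flags["L3"] == "unknown"

    def test_line_with_other_gene_records_is_wildtype(self):
        flags = bm.mutation_flag(self.TABLE, "TP53", ["L4"])
        assert flags["L4"] == "wildtype"


class TestAssociate:
    def test_hand_cohens_d(self):
        eff = pd.Series(
            {"M1": -0.2, "M2": 0.0, "M3": -0.1, "W1": -1.0, "W2": -0.8, "W3": -0.9}
        )
        flags = {k: ("mutant" if k.startswith("M") else "wildtype") for k in eff.index}
        res = bm.associate(eff, flags)
        assert res.cohens_d == pytest.approx(8.0)
        assert res.n_mutant == 3 and res.n_wildtype == 3
        assert res.significant  # p ~ 6e-4, |d| = 8

    def test_identical_groups_not_significant(self):
        eff = pd.Series({"M1": 1.0, "M2": 2.0, "M3": 3.0, "W1": 1.0, "W2": 2.0, "W3": 3.0})
        flags = {k: ("mutant" if k.startswith("M") else "wildtype") for k in eff.index}
        res = bm.associate(eff, flags)
        assert res.cohens_d == 0.0 and not res.significant

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        eff = pd.Series(rng.normal(size=12), index=[f"L{i}" for i in range(12)])
        flags = {f"L{i}": ("mutant" if i < 5 else "wildtype") for i in range(12)}
        swapped = {k: ("wildtype" if v == "mutant" else "mutant") for k, v in flags.items()}
        r1, r2 = bm.associate(eff, flags), bm.associate(eff, swapped)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_unknown_excluded(self):
        eff = pd.Series({f"L{i}": float(i) for i in range(6)})
        flags = {"L0": "mutant", "L1": "mutant", "L2": "wildtype", "L3": "wildtype",
                 "L4": "unknown", "L5": "unknown"}
        res = bm.associate(eff, flags)
        assert res.n_mutant + res.n_wildtype == 4

    def test_small_group_error(self):
        eff = pd.Series({"L0": 1.0, "L1": 2.0, "L2": 3.0})
        flags = {"L0": "mutant", "L1": "wildtype", "L2": "wildtype"}
        with pytest.raises(InsufficientDataError):
            bm.associate(eff, flags)

    def test_power_planted_shift(self):
        # 1.5 pooled-SD shift at n = 10/10 detected by the joint gate >= 80%
        rng = np.random.default_rng(123)
        lines = [f"L{i}" for i in range(20)]
        flags = {l: ("mutant" if i < 10 else "wildtype") for i, l in enumerate(lines)}
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            eff = pd.Series(
                np.concatenate([rng.normal(-1.5, 1, 10), rng.normal(0, 1, 10)]),
                index=lines,
            )
            hits += bm.associate(eff, flags).significant
        assert hits / n_reps >= 0.8


BAL_PREV = (("TP53", 0.5), ("PIK3CA", 0.4), ("CDKN2A", 0.35), ("NOTCH1", 0.3), ("FAT1", 0.3))
BIOMARKERS = [g for g, _ in BAL_PREV]


class TestAssociationScreen:
    def test_grid_dimensions(self, small_bundle):
        b = small_bundle
        targets = GeneSet.from_symbols([f"TGT{i:04d}" for i in range(5)], "t", "prioritized")
        table = bm.association_screen(b.effect, targets, ["TP53", "PIK3CA"], b.mutations)
        assert (table["status"] == "ok").sum() == 10

    def test_prevalence_prefilter(self, small_bundle):
        b = small_bundle
        # a gene mutated in ~4% of lines is excluded up front
        rare = b.mutations.copy()
        n_rare = max(1, int(0.04 * len(b.effect.line_ids)))
        extra = mut_table(
            [(l, "RARE1", "missense", True, False) for l in b.effect.line_ids[:n_rare]]
        )
        rare = pd.concat([rare, extra], ignore_index=True)
        targets = GeneSet.from_symbols(["TGT0000"], "t", "prioritized")
        table = bm.association_screen(b.effect, targets, ["RARE1"], rare)
        assert (table["status"] == "below_prevalence").all()

    def test_planted_pair_recovery(self):
        # exactly the planted (target, biomarker) pair is flagged, per seed
        targets = GeneSet.from_symbols([f"TGT{i:04d}" for i in range(20)], "t", "prioritized")
        for seed in range(10):
            b = generate_panel(
                PanelConfig(
                    seed=seed,
                    biomarker_prevalence=BAL_PREV,
                    planted_association=(("TGT0001", "TP53", -2.0),),
                )
            )
            table = bm.association_screen(b.effect, targets, BIOMARKERS, b.mutations)
            hits = table[(table["status"] == "ok") & table["significant"]]
            assert set(zip(hits["dependency_gene"], hits["biomarker_gene"])) == {
                ("TGT0001", "TP53")
            }

    def test_bh_column_informational(self, small_bundle):
        b = small_bundle
        targets = GeneSet.from_symbols([f"TGT{i:04d}" for i in range(5)], "t", "prioritized")
        table = bm.association_screen(b.effect, targets, ["TP53"], b.mutations)
        ok = table[table["status"] == "ok"]
        assert (ok["p_bh"] >= ok["p_value"] - 1e-12).all()


class TestCorrelation:
    def test_exact_linear(self):
        eff = pd.Series({f"L{i}": float(i) for i in range(5)})
        res = bm.dependency_expression_correlation(eff, eff)
        assert res.r == 1.0 and res.p_value == 0.0 and res.n == 5

    def test_exact_inverse(self):
        eff = pd.Series({f"L{i}": float(i) for i in range(5)})
        res = bm.dependency_expression_correlation(eff, -eff)
        assert res.r == -1.0

    def test_planted_rho_recovered(self):
        rng = np.random.default_rng(3)
        rho = -0.6
        rs = []
        for _ in range(500):
            x = rng.standard_normal(50)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(50)
            idx = [f"L{i}" for i in range(50)]
            rs.append(
                bm.dependency_expression_correlation(
                    pd.Series(x, index=idx), pd.Series(y, index=idx)
                ).r
            )
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_zero_variance_error(self):
        eff = pd.Series({"L0": 1.0, "L1": 1.0, "L2": 1.0})
        cov = pd.Series({"L0": 1.0, "L1": 2.0, "L2": 3.0})
        with pytest.raises(DegenerateDataError):
            bm.dependency_expression_correlation(eff, cov)

    def test_joins_on_shared_lines(self):
        eff = pd.Series({"L0": 1.0, "L1": 2.0, "L2": 3.0, "L9": 9.0})
        cov = pd.Series({"L0": 2.0, "L1": 4.0, "L2": 6.5, "L8": 0.0})
        assert bm.dependency_expression_correlation(eff, cov).n == 3


class TestGistic:
    @pytest.mark.parametrize(
        "code,label",
        [(-2, "deep_deletion"), (-1, "loss"), (0, "diploid"), (1, "gain"), (2, "amplification")],
    )
    def test_total_mapping(self, code, label):
        assert bm.classify_gistic(code) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bm.classify_gistic(3)

    def test_copy_gain_predicate(self):
        assert bm.is_copy_gain(1) and bm.is_copy_gain(2)
        assert not bm.is_copy_gain(0) and not bm.is_copy_gain(-2)


class TestCoamplification:
    def _calls(self, rows, genes):
        return pd.DataFrame(rows, columns=genes, index=[f"T{i}" for i in range(len(rows))])

    def test_always_coamplified(self):
        calls = self._calls([[2, 2], [2, 2], [0, 0]], ["ANCH", "P1"])
        out = bm.coamplification("ANCH", ["P1"], calls)
        assert out["fraction"].iloc[0] == 1.0

    def test_never_coamplified(self):
        calls = self._calls([[2, 0], [2, 1]], ["ANCH", "P1"])
        out = bm.coamplification("ANCH", ["P1"], calls)
        assert out["fraction"].iloc[0] == 0.0

    def test_zero_anchor_error(self):
        calls = self._calls([[0, 2]], ["ANCH", "P1"])
        with pytest.raises(DegenerateDataError):
            bm.coamplification("ANCH", ["P1"], calls)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        calls = self._calls(rng.integers(-2, 3, size=(40, 3)), ["ANCH", "P1", "P2"])
        shuffled = calls.sample(frac=1.0, random_state=9)
        a = bm.coamplification("ANCH", ["P1", "P2"], calls)
        b = bm.coamplification("ANCH", ["P1", "P2"], shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_block_rates(self, small_bundle):
        b = small_bundle
        partners = [g for g in b.config.amplicon_genes[1:] if g in b.gistic.columns]
        out = bm.coamplification(b.config.amplicon_genes[0], partners, b.gistic)
        n_anchor = out["n_anchor"].iloc[0]
        # block genes share the amplicon state with a 5% independent flip to
        # diploid, so the expected co-amplification rate is 95%
        for frac in out["fraction"]:
            se = 3 * np.sqrt(0.95 * 0.05 / n_anchor)
            assert abs(frac - 0.95) < se + 0.05


class TestStratifyByAmplification:
    def test_exact_small_groups(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0, "f": 6.0}
        amplified = {k: k in "abc" for k in values}
        res = bm.stratify_by_amplification(values, amplified)
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "mann_whitney_exact"

    def test_identical_groups(self):
        values = {f"a{i}": float(i) for i in range(4)} | {f"b{i}": float(i) for i in range(4)}
        amplified = {k: k.startswith("a") for k in values}
        res = bm.stratify_by_amplification(values, amplified)
        assert res.p_value == 1.0

    def test_group_sizes_reported(self):
        rng = np.random.default_rng(6)
        values = {f"L{i}": float(v) for i, v in enumerate(rng.normal(size=48))}
        amplified = {f"L{i}": i < 10 for i in range(48)}
        res = bm.stratify_by_amplification(values, amplified)
        assert res.n_amplified == 10 and res.n_other == 38

    def test_small_group_error(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(InsufficientDataError):
            bm.stratify_by_amplification(values, {"a": True, "b": False, "c": False})

    def test_damped_dependency_detected(self):
        cfg = PanelConfig(seed=5, amplicon_damping=0.9, amplicon_line_fraction=0.3)
        b = generate_panel(cfg)
        anchor = cfg.amplicon_genes[0]
        amplified = {l: (l in b.amplified_lines) for l in b.effect.line_ids}
        res = bm.stratify_by_amplification(b.effect.column(anchor), amplified)
        assert res.median_amplified > res.median_other


class TestSurvival:
    def _cohort(self, times_a, events_a, times_b, events_b):
        n = len(times_a) + len(times_b)
        df = pd.DataFrame(
            {
                "tumour_id": [f"T{i}" for i in range(n)],
                "hpv_status": "negative",
                "os_months": list(times_a) + list(times_b),
                "os_event": list(events_a) + list(events_b),
            }
        )
        strata = {f"T{i}": ("A" if i < len(times_a) else "B") for i in range(n)}
        return df, strata

    def test_identical_strata(self):
        times = [5.0, 10.0, 15.0, 20.0]
        events = [True, True, False, True]
        df, strata = self._cohort(times, events, times, events)
        res = bm.km_logrank(df, strata)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        rej = 0
        n_reps = 200
        for _ in range(n_reps):
            t_a = rng.exponential(50, 100)
            t_b = rng.exponential(50, 100)
            df, strata = self._cohort(t_a, [True] * 100, t_b, [True] * 100)
            rej += bm.km_logrank(df, strata).p_value < 0.05
        assert 0.02 <= rej / n_reps <= 0.08

    def test_hazard_ratio_power(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(100):
            t_a = rng.exponential(50, 100)
            t_b = rng.exponential(25, 100)  # hazard ratio 2
            df, strata = self._cohort(t_a, [True] * 100, t_b, [True] * 100)
            ps.append(bm.km_logrank(df, strata).p_value)
        assert np.median(ps) < 0.05

    def test_no_events_error(self):
        df, strata = self._cohort([1.0, 2.0], [False, False], [3.0, 4.0], [False, False])
        with pytest.raises(InsufficientDataError):
            bm.km_logrank(df, strata)

    def test_single_stratum_error(self):
        df, strata = self._cohort([1.0, 2.0], [True, True], [], [])
        with pytest.raises(InsufficientDataError):
            bm.km_logrank(df, strata)
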