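"""Paired differential expression: detection, paired t, BH, collapsing, volcano."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptoa.de import DEResult, collapse_probes, detect_probes, paired_de, volcano_classify
from ptoa.errors import ConfigurationError, InsufficientReplicationError
from ptoa.synthetic import SimConfig, simulate_experiment

from conftest import make_paired_experiment


class TestDetectProbes:
    def _exp_with_detection(self, det_values):
        exp = make_paired_experiment({"p1": [0, 0], "p2": [0, 0]})
        exp.detection = pd.DataFrame(det_values, index=exp.matrix.index, columns=exp.matrix.columns)
        return exp

    def test_all_confident_all_pass(self):
        exp = self._exp_with_detection(0.001)
        assert detect_probes(exp, 0.05, 0.5).all()

    def test_none_confident_none_pass(self):
        exp = self._exp_with_detection(0.99)
        assert not detect_probes(exp, 0.05, 0.5).any()

    def test_one_limb_group_suffices(self):
        exp = make_paired_experiment({"p1": [0, 0]})
        det = pd.DataFrame(index=exp.matrix.index, columns=exp.matrix.columns, dtype=float)
        ipsi = exp.samples.index[exp.samples["limb"] == "ipsi"]
        contra = exp.samples.index[exp.samples["limb"] == "contra"]
        det[ipsi] = 0.01
        det[contra] = 0.9
        exp.detection = det
        assert detect_probes(exp, 0.05, 0.5).all()

    def test_missing_detection_passes_all_with_warning(self, caplog):
        exp = make_paired_experiment({"p1": [0, 0]})
        with caplog.at_level("WARNING"):
            flags = detect_probes(exp)
        assert flags.all()
        assert "no detection p-values" in caplog.text

    def test_bad_min_fraction_rejected(self):
        exp = make_paired_experiment({"p1": [0, 0]})
        with pytest.raises(ConfigurationError, match="min_fraction"):
            detect_probes(exp, 0.05, 0.0)


class TestPairedDE:
    def test_three_pair_toy_matches_hand_computation(self):
        """Differences (1, 2, 3): t = mean/(sd/sqrt(3)) = 2*sqrt(3), p vs t(2)."""
        exp = make_paired_experiment({"p1": [1.0, 2.0, 3.0]})
        res = paired_de(exp, "2w")
        t_expected = 2.0 * np.sqrt(3.0)
        p_expected = 2.0 * stats.t.sf(t_expected, df=2)
        row = res.probes.loc["p1"]
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["p_raw"] == pytest.approx(p_expected, abs=1e-12)

    def test_matches_scipy_ttest_rel(self):
        """Vectorised statistic agrees with the scipy paired test per probe."""
        rng = np.random.default_rng(0)
        diffs = {f"p{i}": rng.normal(0.3, 1.0, size=6) for i in range(20)}
        exp = make_paired_experiment(diffs)
        res = paired_de(exp, "2w")
        for pid, d in diffs.items():
            ref = stats.ttest_rel(d + 8.0, np.full_like(d, 8.0))
            assert res.probes.loc[pid, "p_raw"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_noise_planted_gene_recovered_exactly(self, zero_noise_experiment):
        cfg, exp, truth = zero_noise_experiment
        res = paired_de(exp, "2w")
        planted = truth[(truth["timepoint"] == "2w") & truth["is_de"]].set_index("gene")
        for gene, row in planted.iterrows():
            assert res.genes.loc[gene, "log2fc"] == pytest.approx(row["log2fc_true"], abs=1e-12)
            assert bool(res.genes.loc[gene, "significant"])

    def test_constant_probe_gets_p_one(self):
        exp = make_paired_experiment({"flat": [0.0, 0.0, 0.0, 0.0], "var": [1.0, -1.0, 0.5, 2.0]})
        res = paired_de(exp, "2w")
        assert res.probes.loc["flat", "p_raw"] == 1.0

    def test_insufficient_pairs_raises(self):
        exp = make_paired_experiment({"p1": [1.0, 2.0]})
        with pytest.raises(InsufficientReplicationError, match="3"):
            paired_de(exp, "2w")

    def test_bh_monotone_and_order_independent(self):
        rng = np.random.default_rng(5)
        diffs = {f"p{i:03d}": rng.normal(0.2, 1.0, size=8) for i in range(50)}
        exp = paired = make_paired_experiment(diffs)
        res = paired_de(exp, "2w")
        ranked = res.probes.dropna().sort_values("p_raw")
        assert (ranked["p_adj"].diff().dropna() >= -1e-15).all()
        # permuted probe order gives identical per-probe results
        shuffled = {k: diffs[k] for k in reversed(list(diffs))}
        res2 = paired_de(make_paired_experiment(shuffled), "2w")
        pd.testing.assert_frame_equal(
            res.probes.sort_index(), res2.probes.sort_index()
        )

    def test_null_simulation_controls_fdr(self):
        """de_counts=0: BH-significant gene fraction stays at the nominal level."""
        n_seeds, fracs = 60, []
        for seed in range(n_seeds):
            cfg = SimConfig(n_genes=300, n_probes=300, de_counts=(0,), timepoints=("2w",), seed=seed)
            exp, _ = simulate_experiment(cfg)
            res = paired_de(exp, "2w")
            fracs.append(len(res.significant_genes) / len(res.genes))
        mean = float(np.mean(fracs))
        se = float(np.std(fracs, ddof=1) / np.sqrt(n_seeds))
        assert mean <= 0.05 + 3 * se


class TestCollapseProbes:
    def _frame(self, rows):
        df = pd.DataFrame(rows).set_index("probe_id")
        df["fold_change"] = 2.0 ** df["log2fc"]
        df["detected"] = True
        return df

    def test_best_probe_wins(self):
        probes = self._frame([
            {"probe_id": "pA", "gene": "G1", "log2fc": 1.0, "p_raw": 0.005, "p_adj": 0.01, "significant": True},
            {"probe_id": "pB", "gene": "G1", "log2fc": 0.14, "p_raw": 0.15, "p_adj": 0.20, "significant": False},
        ])
        pm = probes["gene"]
        genes = collapse_probes(probes, pm)
        assert bool(genes.loc["G1", "significant"])
        assert genes.loc["G1", "fold_change"] == pytest.approx(2.0)
        assert genes.loc["G1", "n_probes_collapsed"] == 2

    def test_single_probe_identity(self):
        probes = self._frame([
            {"probe_id": f"p{i}", "gene": f"G{i}", "log2fc": 0.5 * i, "p_raw": 0.01 * (i + 1),
             "p_adj": 0.02 * (i + 1), "significant": i < 2}
            for i in range(4)
        ])
        genes = collapse_probes(probes, probes["gene"])
        assert len(genes) == 4
        for i in range(4):
            assert genes.loc[f"G{i}", "p_adj"] == pytest.approx(0.02 * (i + 1))

    def test_tie_broken_by_larger_magnitude(self):
        probes = self._frame([
            {"probe_id": "pA", "gene": "G", "log2fc": 1.0, "p_raw": 0.005, "p_adj": 0.01, "significant": True},
            {"probe_id": "pB", "gene": "G", "log2fc": -2.0, "p_raw": 0.005, "p_adj": 0.01, "significant": True},
        ])
        genes = collapse_probes(probes, probes["gene"])
        assert abs(genes.loc["G", "log2fc"]) == pytest.approx(2.0)

    def test_full_tie_broken_lexicographically(self):
        probes = self._frame([
            {"probe_id": "pB", "gene": "G", "log2fc": 1.0, "p_raw": 0.005, "p_adj": 0.01, "significant": True},
            {"probe_id": "pA", "gene": "G", "log2fc": -1.0, "p_raw": 0.005, "p_adj": 0.01, "significant": True},
        ])
        genes = collapse_probes(probes, probes["gene"])
        assert genes.loc["G", "log2fc"] == pytest.approx(-1.0)  # pA


class TestVolcanoClassify:
    def _de(self, fc, significant):
        genes = pd.DataFrame({
            "log2fc": np.log2(fc),
            "fold_change": fc,
            "p_raw": 0.01,
            "p_adj": 0.01,
            "detected": True,
            "significant": significant,
            "n_probes_collapsed": 1,
        }, index=[f"G{i}" for i in range(len(fc))])
        return DEResult(timepoint="2w", genes=genes, probes=pd.DataFrame())

    def test_boundary_is_strict(self):
        labels = volcano_classify(self._de(np.array([2.8]), [True]), up_fc=2.8, down_fc=0.35)
        assert labels.iloc[0] == "other"

    def test_up_and_down_partition(self):
        labels = volcano_classify(self._de(np.array([3.0, 0.3, 1.0]), [True, True, True]),
                                  up_fc=2.8, down_fc=0.35)
        assert list(labels) == ["highlighted-up", "highlighted-down", "other"]

    def test_significance_gates_highlighting(self):
        labels = volcano_classify(self._de(np.array([0.3]), [False]), up_fc=2.8, down_fc=0.35)
        assert labels.iloc[0] == "other"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigurationError, match="down_fc"):
            volcano_classify(self._de(np.array([1.0]), [True]), up_fc=0.9, down_fc=0.35)
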