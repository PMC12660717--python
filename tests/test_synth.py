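"""Synthetic count generator, stand-in DE, recovery scoring."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from hiffl.synth import (
    PlantedClass,
    SyntheticDesign,
    default_planted_classes,
    evaluate_recovery,
    generate_counts,
    run_recovery_benchmark,
    standin_de,
)


def _wt_cols(samples, condition):
    return samples.loc[(samples.genotype == "WT")
                       & (samples.condition == condition), "sample"].tolist()


class TestGenerateCounts:
    def test_design_shape(self):
        counts, samples, truth = generate_counts(SyntheticDesign(n_genes=100, seed=0))
        assert counts.shape == (100, 27)
        assert len(samples) == 27
        assert set(samples.genotype) == {"WT", "TP53KD", "NOTCH1KD"}
        assert set(samples.condition) == {"N", "H", "O"}
        assert truth.gene.is_unique and len(truth) == 100

    def test_same_seed_is_byte_identical(self):
        a = generate_counts(SyntheticDesign(n_genes=200, seed=42))[0]
        b = generate_counts(SyntheticDesign(n_genes=200, seed=42))[0]
        pd.testing.assert_frame_equal(a, b)
        c = generate_counts(SyntheticDesign(n_genes=200, seed=43))[0]
        assert not a.equals(c)

    def test_poisson_limit_variance_mean_ratio(self):
        """With dispersion -> 0, no effects and equal libraries, counts are
        Poisson: the average variance/mean ratio is ~1."""
        design = SyntheticDesign(
            n_genes=2000, dispersion=1e-10, libsize_cv=0.0, baseline_sigma=0.0,
            planted_classes=(), seed=5,
        )
        counts, _, _ = generate_counts(design)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_ordering_of_condition_means(self):
        design = SyntheticDesign(n_genes=400, seed=3)
        counts, samples, truth = generate_counts(design)
        g = truth[truth.pattern == "H<N<O"].gene
        mn = counts.loc[g, _wt_cols(samples, "N")].mean(axis=1)
        mh = counts.loc[g, _wt_cols(samples, "H")].mean(axis=1)
        mo = counts.loc[g, _wt_cols(samples, "O")].mean(axis=1)
        assert ((mh < mn) & (mn < mo)).mean() > 0.95

    def test_kd_silencing_removes_pattern_and_shifts_baseline(self):
        design = SyntheticDesign(n_genes=400, seed=3)
        counts, samples, truth = generate_counts(design)
        dep = truth[(truth.tf == "TP53") & (truth.tf_sign == 1)]
        kd_n = samples.loc[(samples.genotype == "TP53KD")
                           & (samples.condition == "N"), "sample"].tolist()
        lfc = np.log2(counts.loc[dep.gene, kd_n].mean(axis=1) + 0.5) - np.log2(
            counts.loc[dep.gene, _wt_cols(samples, "N")].mean(axis=1) + 0.5)
        # activator targets drop by ~kd_log2fc in the knockdown
        assert lfc.median() == pytest.approx(-design.kd_log2fc, abs=0.5)

    def test_invalid_designs(self):
        with pytest.raises(ValueError):
            SyntheticDesign(replicates=1)
        with pytest.raises(ValueError):
            SyntheticDesign(dispersion=0.0)
        with pytest.raises(ValueError):
            SyntheticDesign(planted_classes=(
                PlantedClass("H<N<O", (0, -2, 2), 0.8),
                PlantedClass("O<N<H", (0, 2, -2), 0.3),
            ))


class TestStandinDE:
    def test_single_gene_bh_is_identity(self):
        design = SyntheticDesign(n_genes=1, seed=2, planted_classes=())
        counts, samples, _ = generate_counts(design)
        de = standin_de(counts, samples, (_wt_cols(samples, "H"),
                                          _wt_cols(samples, "N")))
        assert de.padj[0] == pytest.approx(de.pvalue[0])

    def test_planted_two_log2_units_power(self):
        """A 4-fold planted change at dispersion 0.1 and r=3 is detected
        with the right sign in >=95% of genes."""
        cls = (PlantedClass("N<H<O", (0.0, 2.0, 2.0), 0.25),)
        hits, total = 0, 0
        for seed in range(5):
            design = SyntheticDesign(n_genes=400, seed=seed, planted_classes=cls)
            counts, samples, truth = generate_counts(design)
            de = standin_de(counts, samples, (_wt_cols(samples, "H"),
                                              _wt_cols(samples, "N"))).set_index("gene")
            planted = truth[truth.pattern == "N<H<O"].gene
            hits += ((de.loc[planted, "padj"] < 0.05)
                     & (de.loc[planted, "log2fc"] > 0)).sum()
            total += len(planted)
        assert hits / total >= 0.95

    def test_size_factors_reduce_composition_bias(self):
        """With 20% of genes planted asymmetrically, median-of-ratios
        scaling leaves the null genes far less biased than total-count
        (CPM) scaling would."""
        design = SyntheticDesign(n_genes=1000, seed=9)
        counts, samples, truth = generate_counts(design)
        ha, nb = _wt_cols(samples, "H"), _wt_cols(samples, "N")
        de = standin_de(counts, samples, (ha, nb)).set_index("gene")
        null = truth[truth.pattern == "null"].gene
        cpm = counts / counts.sum(axis=0) * 1e6
        logx = np.log2(cpm + 0.5)
        cpm_lfc = logx[ha].mean(axis=1) - logx[nb].mean(axis=1)
        assert abs(de.loc[null, "log2fc"].median()) < 0.2
        assert abs(de.loc[null, "log2fc"].median()) < abs(cpm_lfc[null].median()) / 2

    def test_null_type_i_control(self):
        sig = []
        for seed in range(5):
            design = SyntheticDesign(n_genes=500, seed=100 + seed,
                                     planted_classes=())
            counts, samples, _ = generate_counts(design)
            de = standin_de(counts, samples, (_wt_cols(samples, "H"),
                                              _wt_cols(samples, "N")))
            sig.append((de.padj < 0.05).mean())
        assert max(sig) <= 0.05

    def test_small_group_rejected(self):
        design = SyntheticDesign(n_genes=10, seed=0, planted_classes=())
        counts, samples, _ = generate_counts(design)
        with pytest.raises(ValueError):
            standin_de(counts, samples, (_wt_cols(samples, "H")[:1],
                                         _wt_cols(samples, "N")))


class TestEvaluateRecovery:
    def _truth(self):
        return pd.DataFrame({
            "gene": ["a", "b", "c"],
            "pattern": ["H<N<O", "N<O<H", "null"],
            "tf": ["TP53", "", ""],
            "tf_sign": [1, 0, 0],
            "tf_dependent": [True, False, False],
        })

    def test_perfect_calls(self):
        calls = pd.DataFrame({"gene": ["a", "b", "c"],
                              "pattern": ["H<N<O", "N<O<H", "NOT_SIGNIFICANT"]})
        sens, fdr, confusion = evaluate_recovery(calls, self._truth())
        assert sens == 1.0 and fdr == 0.0
        assert confusion.loc["H<N<O", "H<N<O"] == 1

    def test_all_not_significant(self):
        calls = pd.DataFrame({"gene": ["a", "b", "c"],
                              "pattern": ["NOT_SIGNIFICANT"] * 3})
        sens, fdr, _ = evaluate_recovery(calls, self._truth())
        assert sens == 0.0
        assert math.isnan(fdr)

    def test_universe_mismatch(self):
        calls = pd.DataFrame({"gene": ["a", "b"], "pattern": ["H<N<O", "H<N<O"]})
        with pytest.raises(ValueError):
            evaluate_recovery(calls, self._truth())


def _scaled_classes(scale):
    return tuple(
        dataclasses.replace(c, effects=tuple(e * scale for e in c.effects))
        for c in default_planted_classes()
    )


class TestRecoveryBenchmark:
    def test_sensitivity_monotone_in_effect_size(self):
        sens = []
        for scale in (0.4, 1.0, 2.0):
            design = SyntheticDesign(n_genes=600, seed=17,
                                     planted_classes=_scaled_classes(scale))
            sens.append(run_recovery_benchmark(design)["sensitivity"])
        assert sens[0] <= sens[1] + 0.02 and sens[1] <= sens[2] + 0.02
        assert sens[2] > sens[0]

    def test_sensitivity_monotone_in_replicates(self):
        sens = []
        for r in (2, 3, 6):
            design = SyntheticDesign(n_genes=600, seed=23, replicates=r,
                                     planted_classes=_scaled_classes(0.5))
            sens.append(run_recovery_benchmark(design)["sensitivity"])
        assert sens[0] <= sens[1] + 0.02 and sens[1] <= sens[2] + 0.02
        assert sens[2] > sens[0]
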