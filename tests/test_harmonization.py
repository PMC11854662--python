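import subprocess
import textwrap

import numpy as np
import pytest

from petww.harmonization import (
    benjamini_hochberg,
    combat_apply,
    combat_fit,
    combat_harmonize,
    drop_unharmonized,
    outcome_scanner_test,
    wilcoxon_scanner_test,
)
from petww.imaging_io import FeatureTable
from petww.phantom import synthetic_feature_table


class TestWilcoxon:
    def test_exact_small_sample(self):
        """(1,2,3) vs (4,5,6): the most extreme of C(6,3)=20 rank splits,
        both tails -> exact two-sided p = 2/20 = 0.1."""
        t = synthetic_feature_table(6, n_features=1, seed=0)
        df = t.data.copy()
        df.iloc[:, 2] = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        df["scanner"] = ["A", "A", "A", "B", "B", "B"]
        audit = wilcoxon_scanner_test(FeatureTable(df))
        assert audit.results["p_raw"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_single_group_rejected(self):
        t = synthetic_feature_table(6, n_features=2, seed=0)
        df = t.data.copy()
        df["scanner"] = "A"
        with pytest.raises(ValueError, match="two scanner groups"):
            wilcoxon_scanner_test(FeatureTable(df))

    def test_null_rarely_significant(self):
        """Identical scanner distributions, 81 features, n=38: the
        FDR-significant count is 0 in >= 95% of seeds."""
        zero = sum(
            wilcoxon_scanner_test(
                synthetic_feature_table(38, n_features=81, frac_a=16 / 38, seed=s)
            ).n_significant
            == 0
            for s in range(60)
        )
        assert zero >= 0.95 * 60

    def test_outcome_scanner_test_null(self, rng):
        ttt = rng.uniform(3, 134, 38)
        labels = np.array(["A"] * 16 + ["B"] * 22)
        assert outcome_scanner_test(ttt, labels) > 0.001


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        """(0.01, 0.02, 0.04), m=3: step-up gives (0.03, 0.03, 0.04)."""
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCombat:
    def test_batch_effect_removed(self):
        """Injected +2 SD location and x2 scale: group-mean separation
        drops by >= 90% and the FDR-significant count collapses."""
        t = synthetic_feature_table(
            50, n_features=81, location_shift_sd=2.0, scale_factor=2.0, seed=3
        )
        pre = wilcoxon_scanner_test(t)
        assert pre.n_significant >= 0.8 * 81
        harm, _ = combat_harmonize(t)
        post = wilcoxon_scanner_test(harm)
        assert post.n_significant <= 0.05 * 81
        lab = t.scanner.to_numpy()
        f_pre = t.features().to_numpy()
        f_post = harm.features().to_numpy()
        a, b = lab == "A", lab == "B"
        gap_pre = np.abs(f_pre[a].mean(0) - f_pre[b].mean(0))
        gap_post = np.abs(f_post[a].mean(0) - f_post[b].mean(0))
        assert np.median(gap_post / gap_pre) < 0.1

    def test_null_data_barely_changed(self):
        t = synthetic_feature_table(40, n_features=81, seed=4)
        harm, _ = combat_harmonize(t)
        scale = t.features().std().to_numpy()
        delta = np.abs(harm.features().to_numpy() - t.features().to_numpy())
        assert np.max(delta / scale) < 1.0  # bounded by any injected-effect scale
        assert wilcoxon_scanner_test(harm).n_significant <= 4

    def test_repeated_harmonization_contracts(self):
        """EB shrinkage leaves a residual batch offset, so ComBat is only
        approximately idempotent: each extra pass changes the data by less
        and the batch-mean gap shrinks monotonically toward zero."""
        t = synthetic_feature_table(40, n_features=30, seed=5)
        lab = t.scanner.to_numpy()
        a, b = lab == "A", lab == "B"

        def gap(tab):
            f = tab.features().to_numpy()
            return np.abs(f[a].mean(0) - f[b].mean(0)).mean()

        once, _ = combat_harmonize(t)
        twice, _ = combat_harmonize(once)
        thrice, _ = combat_harmonize(twice)
        scale = np.abs(once.features().to_numpy()).max()
        d1 = np.abs(twice.features().to_numpy() - once.features().to_numpy()).max()
        d2 = np.abs(thrice.features().to_numpy() - twice.features().to_numpy()).max()
        assert gap(twice) < gap(once) < gap(t)
        assert d2 < d1 < 0.05 * scale

    def test_grand_mean_preserved(self):
        t = synthetic_feature_table(30, n_features=40, location_shift_sd=1.0, seed=6)
        harm, _ = combat_harmonize(t)
        np.testing.assert_allclose(
            harm.features().mean().to_numpy(),
            t.features().mean().to_numpy(),
            rtol=1e-8,
        )

    def test_constant_feature_passed_through(self):
        t = synthetic_feature_table(20, n_features=10, seed=7)
        df = t.data.copy()
        col = t.feature_columns[0]
        df[col] = 1.5
        t = FeatureTable(df)
        harm, model = combat_harmonize(t)
        assert col in model.constant_features
        assert (harm.features()[col] == 1.5).all()

    def test_single_batch_rejected(self):
        t = synthetic_feature_table(10, n_features=5, seed=8)
        df = t.data.copy()
        df["scanner"] = "A"
        with pytest.raises(ValueError, match="two batches"):
            combat_fit(FeatureTable(df))

    def test_apply_unknown_batch_rejected(self):
        t = synthetic_feature_table(10, n_features=5, seed=9)
        model = combat_fit(t)
        df = t.data.copy()
        df["scanner"] = ["A"] * 5 + ["C"] * 5
        with pytest.raises(ValueError, match="unknown batch"):
            combat_apply(model, FeatureTable(df))

    def test_matches_bioconductor_sva_up_to_recentering(self, tmp_path):
        """Independent oracle: sva::ComBat on the same table agrees with our
        adjustment modulo the documented per-feature re-centering constant,
        to within the EB iteration's convergence tolerance (both stop at
        1e-4 relative change, so adjusted values agree to ~1e-4)."""
        t = synthetic_feature_table(
            30, n_features=20, location_shift_sd=1.0, scale_factor=1.5, seed=5
        )
        ours = combat_harmonize(t)[0].features().to_numpy()
        X = t.features().to_numpy().T
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        batch = (t.scanner.to_numpy() == "B").astype(int) + 1
        np.savetxt(tmp_path / "batch.csv", batch, fmt="%d")
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            args <- commandArgs(trailingOnly=TRUE)
            X <- as.matrix(read.csv(file.path(args[1], "X.csv"), header=FALSE))
            batch <- scan(file.path(args[1], "batch.csv"))
            out <- ComBat(dat=X, batch=batch, mod=NULL, par.prior=TRUE)
            write.table(out, file.path(args[1], "out.csv"), sep=",",
                        row.names=FALSE, col.names=FALSE)
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script, str(tmp_path)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        theirs = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
        diff = ours - theirs
        centered = diff - diff.mean(axis=0)
        assert np.abs(centered).max() < 1e-3
        assert np.median(np.abs(centered)) < 1e-6


class TestDropUnharmonized:
    def test_no_significant_unchanged(self):
        t = synthetic_feature_table(20, n_features=10, seed=1)
        audit = wilcoxon_scanner_test(t)
        audit.results["significant"] = False
        assert drop_unharmonized(t, audit) is t

    def test_flagged_features_removed(self):
        t = synthetic_feature_table(20, n_features=81, seed=2)
        audit = wilcoxon_scanner_test(t)
        flagged = list(audit.results.index[:2])
        audit.results["significant"] = audit.results.index.isin(flagged)
        out = drop_unharmonized(t, audit)
        assert len(out.feature_columns) == 79
        assert not set(flagged) & set(out.feature_columns)

    def test_all_flagged_is_fatal(self):
        t = synthetic_feature_table(20, n_features=5, seed=3)
        audit = wilcoxon_scanner_test(t)
        audit.results["significant"] = True
        with pytest.raises(ValueError, match="every feature"):
            drop_unharmonized(t, audit)
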