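import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from ntcpbench.combat import CombatError, CombatModel, combat_apply, combat_fit


def two_batch_table(seed=0, n_a=120, n_b=80, shift=0.0, scale=1.0):
    """Batch A at baseline; batch B location-shifted and scale-inflated."""
    rng = np.random.default_rng(seed)
    base = {
        "mean_dose": (46.0, 10.0),
        "max_dose": (62.0, 8.0),
        "age": (60.0, 10.0),
    }
    cols_a = {k: rng.normal(mu, sd, n_a) for k, (mu, sd) in base.items()}
    cols_b = {k: rng.normal(mu, sd, n_b) * scale + shift for k, (mu, sd) in base.items()}
    table = pd.DataFrame({k: np.concatenate([cols_a[k], cols_b[k]]) for k in base})
    batch = ["A"] * n_a + ["B"] * n_b
    return table, batch


class TestValidation:
    def test_single_batch_rejected(self):
        table, _ = two_batch_table()
        with pytest.raises(CombatError, match="nothing to correct"):
            combat_fit(table, ["A"] * len(table))

    def test_tiny_batch_rejected(self):
        table, batch = two_batch_table(n_a=2, n_b=10)
        with pytest.raises(CombatError, match="fewer than 3"):
            combat_fit(table, batch)

    def test_zero_variance_feature_named_in_error(self):
        table, batch = two_batch_table()
        table["constant"] = 1.0
        with pytest.raises(CombatError, match="constant"):
            combat_fit(table, batch)

    def test_missing_values_rejected(self):
        table, batch = two_batch_table()
        table.iloc[0, 0] = np.nan
        with pytest.raises(CombatError, match="missing"):
            combat_fit(table, batch)

    def test_unseen_batch_rejected_at_apply(self):
        table, batch = two_batch_table()
        model = combat_fit(table, batch)
        with pytest.raises(CombatError, match="not seen"):
            combat_apply(model, table, ["C"] * len(table))

    def test_outcome_covariate_hook_refused(self):
        table, batch = two_batch_table()
        with pytest.raises(NotImplementedError):
            combat_fit(table, batch, covariates=pd.DataFrame({"x": np.zeros(len(table))}))


class TestCorrection:
    def test_no_batch_effect_is_near_identity(self):
        table, batch = two_batch_table(seed=5, shift=0.0, scale=1.0)
        model = combat_fit(table, batch)
        corrected = combat_apply(model, table, batch)
        # only sampling noise separates the batches; correction must not
        # move any value by more than a fraction of a feature SD
        sds = table.std(axis=0)
        max_change = (corrected - table).abs().max(axis=0)
        assert (max_change < 0.5 * sds).all()

    def test_shift_and_scale_discrepancies_reduced(self):
        # multi-feature table: EB shrinkage leaves a small residual in the
        # empirical SD ratio (the exact-match case is the single-feature
        # path tested below), so the bound here is looser than for one
        # feature
        table, batch = two_batch_table(seed=1, shift=10.0, scale=2.0)
        n_a = batch.count("A")
        model = combat_fit(table, batch)
        corrected = combat_apply(model, table, batch)
        for col in table.columns:
            before_gap = abs(table[col][:n_a].mean() - table[col][n_a:].mean())
            after_gap = abs(corrected[col][:n_a].mean() - corrected[col][n_a:].mean())
            before_sd = abs(table[col][:n_a].std() / table[col][n_a:].std() - 1)
            after_sd = abs(corrected[col][:n_a].std() / corrected[col][n_a:].std() - 1)
            assert after_gap <= 0.1 * before_gap
            assert after_sd <= 0.25 * before_sd

    def test_delta_star_positive_and_grand_mean_preserved(self):
        table, batch = two_batch_table(seed=2, shift=10.0, scale=2.0)
        model = combat_fit(table, batch)
        assert (model.delta_star > 0).all()
        corrected = combat_apply(model, table, batch)
        np.testing.assert_allclose(
            corrected.mean(axis=0), model.grand_mean, rtol=0, atol=0.2
        )

    def test_refit_on_corrected_data_finds_no_effects(self):
        table, batch = two_batch_table(seed=3, shift=10.0, scale=2.0)
        corrected = combat_apply(combat_fit(table, batch), table, batch)
        refit = combat_fit(corrected, batch)
        assert np.abs(refit.gamma_star).max() < 0.1
        np.testing.assert_allclose(refit.delta_star, 1.0, atol=0.15)

    def test_per_batch_means_agree_within_sampling_error(self):
        for seed in range(20):
            table, batch = two_batch_table(seed=seed, shift=8.0, scale=1.5)
            n_a = batch.count("A")
            corrected = combat_apply(combat_fit(table, batch), table, batch)
            for col in table.columns:
                a, b = corrected[col][:n_a], corrected[col][n_a:]
                se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
                assert abs(a.mean() - b.mean()) < 2 * se

    def test_single_feature_table_moment_matches_exactly(self):
        # one feature: nothing to shrink across, so correction equalizes
        # batch moments on the standardized scale exactly
        table, batch = two_batch_table(seed=4, shift=10.0, scale=2.0)
        single = table[["mean_dose"]]
        n_a = batch.count("A")
        corrected = combat_apply(combat_fit(single, batch), single, batch)
        a, b = corrected["mean_dose"][:n_a], corrected["mean_dose"][n_a:]
        assert abs(a.mean() - b.mean()) < 1e-9
        assert abs(a.std(ddof=1) / b.std(ddof=1) - 1) < 1e-9

    def test_model_json_round_trip(self, tmp_path):
        table, batch = two_batch_table(seed=6)
        model = combat_fit(table, batch)
        model.to_json(tmp_path / "model.json")
        import json

        back = CombatModel.from_dict(json.loads((tmp_path / "model.json").read_text()))
        np.testing.assert_allclose(back.gamma_star, model.gamma_star)
        np.testing.assert_allclose(back.delta_star, model.delta_star)


R_COMBAT_SCRIPT = """
suppressMessages(library(sva))
dat <- as.matrix(read.csv('{features}', row.names=1, check.names=FALSE))
batch <- scan('{batch}', what=character(), quiet=TRUE)
out <- ComBat(dat=dat, batch=batch, par.prior=TRUE, mean.only=FALSE)
write.csv(out, '{out}')
"""


def test_agrees_with_reference_combat_implementation(tmp_path):
    """Element-wise agreement with Bioconductor sva's parametric ComBat."""
    assert shutil.which("Rscript"), "Rscript with sva is part of the toolchain"
    table, batch = two_batch_table(seed=9, shift=10.0, scale=2.0)
    # sva expects features x samples
    table.T.to_csv(tmp_path / "features.csv")
    (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
    script = tmp_path / "run_combat.R"
    script.write_text(
        R_COMBAT_SCRIPT.format(
            features=tmp_path / "features.csv",
            batch=tmp_path / "batch.txt",
            out=tmp_path / "ref.csv",
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    reference = pd.read_csv(tmp_path / "ref.csv", index_col=0).T
    corrected = combat_apply(combat_fit(table, batch), table, batch)
    np.testing.assert_allclose(
        corrected.to_numpy(), reference.to_numpy(), rtol=0, atol=1e-6
    )
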