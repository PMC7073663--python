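import dataclasses

import numpy as np
import pytest

from pai_allocate import ScenarioConfig, VariableSpec, generate_trial, preset, write_trial
from pai_allocate.synthetic import ConfigurationError, PRESETS, _draw_block_sizes


def simple_config(**overrides) -> ScenarioConfig:
    base = dict(
        n_patients=40,
        covariate_schema=(
            VariableSpec("severity", "continuous", params={"mean": 15.0, "sd": 5.0}),
            VariableSpec("marker", "binary", params={"p": 0.5}),
        ),
        beta_tau={"severity": 0.5},
        beta_blend={"severity": 0.5},
        intercept_tau=4.0,
        intercept_blend=4.0,
        noise_sd=3.0,
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def test_identical_arms_give_zero_true_pai():
    table, truth = generate_trial(simple_config())
    assert np.all(truth.frame["true_pai"].to_numpy() == 0.0)
    assert set(truth.frame["true_optimal"]) == {"either"}


def test_block_randomization_balances_arms_exactly_for_even_n():
    # 40 patients decompose into full even blocks: exact 1:1 overall
    table, _ = generate_trial(simple_config(n_patients=40, block_sizes=(8, 10)))
    counts = table.data["arm"].value_counts()
    assert counts["TAU"] == counts["BLEND"] == 20


def test_arm_sizes_differ_at_most_by_final_block():
    for seed in range(5):
        table, _ = generate_trial(simple_config(n_patients=251, seed=seed))
        counts = table.data["arm"].value_counts()
        assert abs(counts["TAU"] - counts["BLEND"]) <= 1  # odd pad block only


def test_block_size_decomposition_uses_configured_sizes():
    rng = np.random.default_rng(0)
    sizes = _draw_block_sizes(100, (8, 10, 12, 14), rng)
    assert sum(sizes) == 100
    assert all(s in (8, 10, 12, 14) for s in sizes[:-1])


def test_near_zero_noise_recovers_truth_exactly():
    # integer-valued linear predictor, negligible noise, no clipping:
    # the rounded observed outcome equals the truth linear predictor
    cfg = simple_config(
        covariate_schema=(VariableSpec("marker", "binary", params={"p": 0.5}),),
        beta_tau={"marker": 3.0},
        beta_blend={"marker": 5.0},
        intercept_tau=10.0,
        intercept_blend=8.0,
        noise_sd=1e-9,
    )
    table, truth = generate_trial(cfg)
    received = np.where(
        table.data["arm"] == "TAU", truth.frame["mu_tau"], truth.frame["mu_blend"]
    )
    np.testing.assert_array_equal(table.data["outcome"].to_numpy(), received)


def test_truth_invariant_to_missingness_mask():
    cfg = simple_config(seed=11)
    masked = dataclasses.replace(cfg, miss_rates={"severity": 0.4, "marker": 0.3})
    _, truth_clean = generate_trial(cfg)
    _, truth_masked = generate_trial(masked)
    np.testing.assert_array_equal(
        truth_clean.frame["true_pai"].to_numpy(), truth_masked.frame["true_pai"].to_numpy()
    )


def test_realized_missingness_matches_configured_rate():
    rate = 0.3
    cfg = simple_config(n_patients=2000, miss_rates={"severity": rate}, seed=5)
    table, _ = generate_trial(cfg)
    realized = float(table.data["severity"].isna().mean())
    tol = 4 * np.sqrt(rate * (1 - rate) / 2000)  # four binomial sd
    assert abs(realized - rate) < tol


def test_mar_hook_ties_missingness_to_driver():
    cfg = simple_config(
        n_patients=3000,
        miss_rates={"marker": 0.3},
        missing_mechanism="mar",
        mar_driver="severity",
        mar_slope=1.5,
        seed=2,
    )
    table, _ = generate_trial(cfg)
    sev = table.data["severity"]
    miss = table.data["marker"].isna()
    high = miss[sev > sev.median()].mean()
    low = miss[sev <= sev.median()].mean()
    assert high > low + 0.1


def test_same_seed_same_preset_byte_identical(tmp_path):
    a, _ = generate_trial(preset("ecompared_like", seed=9))
    b, _ = generate_trial(preset("ecompared_like", seed=9))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_trial(a, pa)
    write_trial(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_ecompared_like_preset_shape():
    cfg = preset("ecompared_like")
    assert cfg.n_patients == 251
    assert len(cfg.covariate_schema) == 28
    kinds = {s.name: s for s in cfg.covariate_schema}
    assert len(kinds["country"].levels) == 4
    assert kinds["marital_status"].kind == "nominal"
    rates = list(cfg.miss_rates.values())
    assert 0.0 < min(rates) <= 0.02 + 1e-9 and max(rates) <= 0.41


def test_null_preset_has_no_prescriptive_contrast():
    cfg = preset("null")
    assert cfg.beta_tau == cfg.beta_blend
    assert cfg.intercept_tau == cfg.intercept_blend
    assert cfg.beta_tau["phq9_baseline"] > 0


def test_prescriptive_preset_truth_matches_linear_predictor_oracle():
    cfg = preset("prescriptive", seed=4)
    table, truth = generate_trial(cfg)
    # oracle: recompute |mu_tau - mu_blend| directly from the generating
    # coefficients and the realized marker column
    marker = table.data["benefit_marker"].to_numpy()
    delta_intercept = cfg.intercept_tau - cfg.intercept_blend
    delta_beta = cfg.beta_tau["benefit_marker"] - cfg.beta_blend["benefit_marker"]
    oracle = np.abs(delta_intercept + delta_beta * marker)
    np.testing.assert_allclose(truth.frame["true_pai"].to_numpy(), oracle, atol=1e-12)


def test_unknown_preset_lists_alternatives():
    with pytest.raises(ValueError) as err:
        preset("bogus")
    for name in PRESETS:
        assert name in str(err.value)


@pytest.mark.parametrize(
    "overrides, message",
    [
        ({"beta_tau": {"nonexistent": 1.0}}, "unknown design column"),
        ({"noise_sd": 0.0}, "noise_sd"),
        ({"miss_rates": {"nope": 0.1}}, "unknown covariate"),
        ({"block_sizes": (7,)}, "even"),
        ({"outcome_dropout_rate": 0.5}, "outcome_dropout_rate"),
    ],
)
def test_invalid_configurations_rejected(overrides, message):
    with pytest.raises(ConfigurationError, match=message):
        generate_trial(simple_config(**overrides))
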