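"""The canonical parameter fixture, validation, and file round-trips."""

import math

import pytest

from oralcea import (ParameterSet, ParameterValidationError, load_parameter_set,
                     save_parameter_set, table1_defaults, validate)

# Every published input cell: (path, base estimate, family, low, high).
# Bounds are None for fixed parameters.
TABLE1_CELLS = [
    ("config.median_age", 50, "fixed", None, None),
    ("config.occult_metastasis_rate", 0.23, "beta", 0.2, 0.3),
    ("accuracy_slnb.sensitivity", 0.81, "beta", 0.77, 0.85),
    ("accuracy_slnb.npv", 0.93, "beta", 0.88, 0.98),
    ("accuracy_endfs.sensitivity", 0.84, "beta", 0.80, 0.88),
    ("accuracy_endfs.npv", 0.93, "beta", 0.88, 1.00),
    ("utilities.snd_without_morbidity", 0.862, "beta", 0.82, 0.91),
    ("utilities.snd_with_morbidity", 0.747, "beta", 0.71, 0.78),
    ("utilities.mnd_without_morbidity", 0.821, "beta", 0.78, 0.86),
    ("utilities.mnd_with_morbidity", 0.711, "beta", 0.68, 0.75),
    ("utilities.dfs_primary_resection", 0.891, "beta", 0.85, 0.94),
    ("utilities.dfs_after_neck_dissection", 0.819, "beta", 0.78, 0.86),
    ("utilities.lrr", 0.659, "beta", 0.63, 0.69),
    ("utilities.dm", 0.508, "beta", 0.48, 0.53),
    ("utilities.salvaged", 0.264, "beta", 0.25, 0.28),
    ("transitions.dfs_to_lrr_node_pos", 0.065, "dirichlet", 0.062, 0.069),
    ("transitions.dfs_to_lrr_node_neg", 0.043, "dirichlet", 0.041, 0.045),
    ("transitions.dfs_to_dm_node_pos", 0.0136, "dirichlet", 0.013, 0.014),
    ("transitions.dfs_to_dm_node_neg", 0.004, "dirichlet", 0.004, 0.005),
    ("transitions.lrr_to_dm", 0.076, "dirichlet", 0.072, 0.08),
    ("transitions.lrr_to_salvage_dissected", 0.083, "dirichlet", 0.079, 0.087),
    ("transitions.lrr_to_salvage_undissected", 0.146, "dirichlet", 0.139, 0.154),
    ("transitions.lrr_to_death_cancer", 0.613, "dirichlet", 0.582, 0.643),
    ("transitions.salvage_to_lrr_dissected", 0.136, "dirichlet", 0.129, 0.143),
    ("transitions.salvage_to_lrr_undissected", 0.115, "dirichlet", 0.109, 0.121),
    ("transitions.salvage_to_dm_dissected", 0.032, "dirichlet", 0.030, 0.033),
    ("transitions.salvage_to_dm_undissected", 0.030, "dirichlet", 0.029, 0.032),
    ("transitions.dm_median_survival_months", 7.5, "fixed", None, None),
    ("transitions.all_cause_mortality[51-55]", 0.008, "fixed", None, None),
    ("transitions.all_cause_mortality[56-60]", 0.013, "fixed", None, None),
    ("transitions.all_cause_mortality[61-65]", 0.019, "fixed", None, None),
    ("transitions.all_cause_mortality[66-70]", 0.029, "fixed", None, None),
    ("transitions.all_cause_mortality[71-75]", 0.151, "fixed", None, None),
    ("transitions.all_cause_mortality[76-80]", 0.066, "fixed", None, None),
    ("transitions.all_cause_mortality[80+]", 0.103, "fixed", None, None),
    ("costs.cbc", 155, "normal", 124, 186),
    ("costs.lft", 259, "normal", 207, 311),
    ("costs.rft", 259, "normal", 207, 311),
    ("costs.electrolytes", 460, "normal", 368, 552),
    ("costs.tsh", 104, "normal", 83, 125),
    ("costs.cisplatin_weekly", 2_900, "gamma", 2_600, 3_100),
    ("costs.cisplatin_high", 11_950, "gamma", 10_800, 12_800),
    ("costs.rt_2d", 13_390, "gamma", 12_100, 14_300),
    ("costs.rt_3dcrt", 25_540, "gamma", 23_100, 27_300),
    ("costs.rt_imrt", 85_050, "gamma", 77_000, 91_000),
    ("costs.high_end_radiology", 5_560, "gamma", 5_000, 5_800),
    ("costs.paclitaxel", 14_380, "gamma", 13_000, 15_400),
    ("costs.paclitaxel_carboplatin", 17_540, "gamma", 16_000, 18_200),
    ("costs.basic_supportive_care", 10_215, "gamma", 9_900, 10_350),
    ("costs.slnb", 28_670, "gamma", 28_670 * 0.8, 28_670 * 1.2),
    ("costs.mnd", 36_870, "gamma", 33_300, 39_900),
    ("costs.snd", 26_040, "gamma", 23_500, 28_200),
    ("costs.salvage_surgery", 60_550, "gamma", 54_600, 65_600),
    ("costs.frozen_section", 8_500, "gamma", 5_000, 12_000),
]


@pytest.mark.parametrize("path,value,family,low,high",
                         TABLE1_CELLS, ids=[c[0] for c in TABLE1_CELLS])
def test_default_fixture_matches_published_cells(table1, path, value, family, low, high):
    assert table1.get_path(path) == pytest.approx(value)
    spec = table1.distributions[path]
    assert spec.family == family
    assert spec.mean == pytest.approx(value)
    if low is not None:
        assert spec.low == pytest.approx(low)
        assert spec.high == pytest.approx(high)


def test_every_sampled_parameter_has_a_distribution(table1):
    for name, spec in table1.distributions.items():
        if spec.family != "fixed":
            assert spec.low is not None and spec.high is not None, name
            assert spec.low <= spec.mean <= spec.high, name


def test_slnb_cost_bounds_repaired_with_printed_pair_kept(table1):
    spec = table1.distributions["costs.slnb"]
    assert spec.printed_bounds == (25_900, 25_900)
    assert spec.low == pytest.approx(28_670 * 0.8)
    assert spec.high == pytest.approx(28_670 * 1.2)


def test_defaults_validate_clean(table1):
    assert validate(table1) == []


def test_save_load_roundtrip(params, tmp_path):
    path = tmp_path / "params.json"
    save_parameter_set(params, path)
    loaded = load_parameter_set(path)
    assert loaded.to_dict() == params.to_dict()


def test_load_rejects_out_of_range_probability(params, tmp_path):
    params.transitions.dfs_to_lrr_node_pos = 1.2
    path = tmp_path / "bad.json"
    save_parameter_set(params, path)
    with pytest.raises(ParameterValidationError, match="dfs_to_lrr_node_pos"):
        load_parameter_set(path)


def test_load_rejects_unknown_keys(params, tmp_path):
    data = params.to_dict()
    data["costs"]["helicopter"] = 1.0
    path = tmp_path / "unknown.json"
    path.write_text(__import__("json").dumps(data))
    with pytest.raises(ParameterValidationError, match="helicopter"):
        load_parameter_set(path)


def test_load_names_missing_required_cost(params, tmp_path):
    data = params.to_dict()
    del data["costs"]["mnd"]
    path = tmp_path / "missing.json"
    path.write_text(__import__("json").dumps(data))
    with pytest.raises(ParameterValidationError, match="costs.mnd"):
        load_parameter_set(path)


def test_validate_reports_utility_ordering_violation(params):
    params.utilities.snd_with_morbidity = 0.9  # above the 0.862 morbidity-free value
    violations = validate(params)
    assert len(violations) == 1
    assert "snd_with_morbidity" in violations[0].field


def test_validate_reports_rt_weight_sum_violation(params):
    params.costs.rt_modality_weights = (0.5, 0.5, 0.5)
    violations = validate(params)
    assert any("rt_modality_weights" in v.field and "sum" in v.rule for v in violations)


def test_validate_is_total_on_garbage_values(params):
    params.utilities.dm = float("nan")
    params.costs.slnb = -5.0
    params.transitions.lrr_to_death_cancer = 2.0
    params.config.discount_rate = -0.1
    violations = validate(params)  # must not raise
    fields = {v.field for v in violations}
    assert {"utilities.dm", "costs.slnb", "config.discount_rate"} <= fields
    assert any("lrr" in f for f in fields)


def test_path_access_roundtrip(params):
    params.set_path("transitions.all_cause_mortality[80+]", 0.2)
    assert params.get_path("transitions.all_cause_mortality[80+]") == 0.2
    params.set_path("costs.slnb", 1.0)
    assert params.costs.slnb == 1.0
    assert math.isclose(params.get_path("utilities.lrr"), 0.659)
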