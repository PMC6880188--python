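import numpy as np
import pandas as pd
import pytest

from bagclust import residualize


def _zscore(y):
    return (y - y.mean()) / y.std(ddof=1)


def _frame(values, ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    return pd.DataFrame({"f1": values}, index=pd.Index(ids, name="participant_id"))


def _covariates(age, sex=None, scanner=None, ids=None):
    n = len(age)
    ids = ids or [f"p{i}" for i in range(n)]
    data = {"age": age}
    if sex is not None:
        data["sex"] = sex
    if scanner is not None:
        data["scanner"] = scanner
    return pd.DataFrame(data, index=pd.Index(ids, name="participant_id"))


@pytest.mark.parametrize("mode", ["sequential", "joint"])
def test_feature_orthogonal_to_covariates_is_only_zscored(mode):
    rng = np.random.default_rng(0)
    n = 40
    age = rng.uniform(6, 18, n)
    sex = np.where(np.arange(n) % 2 == 0, "F", "M")
    design = np.column_stack([np.ones(n), age, (sex == "M").astype(float)])
    raw = rng.normal(size=n)
    beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
    y = raw - design @ beta  # exactly orthogonal to intercept, age and sex
    res = residualize(_frame(y), _covariates(age, sex), mode=mode)
    np.testing.assert_allclose(res.values["f1"].to_numpy(), _zscore(y), atol=1e-8)


@pytest.mark.parametrize("mode", ["sequential", "joint"])
def test_feature_equal_to_covariate_gives_constant_column_error(mode):
    age = np.array([6.0, 8.0, 10.0, 12.0, 14.0, 16.0])
    with pytest.raises(ValueError, match="f1"):
        residualize(_frame(2.0 * age), _covariates(age), mode=mode)


def test_sequential_matches_normal_equations_oracle():
    """Six participants, age + binary sex, against hand-rolled two-stage OLS."""
    age = np.array([6.0, 9.0, 10.0, 12.0, 15.0, 17.0])
    sex = np.array(["F", "M", "F", "M", "F", "M"])
    y = np.array([2.1, 3.3, 2.9, 4.8, 3.5, 6.1])

    def stage(y, x):
        X = np.column_stack([np.ones(len(x)), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        return y - X @ beta

    r = stage(y, age)
    r = stage(r, (sex == "M").astype(float))
    expected = _zscore(r)
    res = residualize(_frame(y), _covariates(age, sex), mode="sequential")
    np.testing.assert_allclose(res.values["f1"].to_numpy(), expected, atol=1e-10)
    assert res.covariate_order == ("age", "sex")


def test_joint_residuals_orthogonal_to_design():
    rng = np.random.default_rng(1)
    n = 60
    age = rng.uniform(6, 18, n)
    sex = rng.choice(["F", "M"], n)
    scanner = rng.choice(["s1", "s2"], n)
    view = pd.DataFrame(
        rng.normal(size=(n, 4)) + np.outer(age, np.ones(4)) * 0.1,
        index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"),
        columns=list("abcd"),
    )
    res = residualize(view, _covariates(age, sex, scanner), mode="joint")
    Z = res.values.to_numpy()
    for cov in [age, (sex == "M").astype(float), (scanner == "s2").astype(float)]:
        c = (cov - cov.mean()) / cov.std(ddof=1)
        assert np.abs(c @ Z).max() / len(c) < 1e-8


def test_sequential_equals_joint_for_orthogonal_covariates():
    # centered age is exactly orthogonal to the centered sex dummy
    age = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
    sex = np.array(["F", "M", "F", "M", "F", "M", "F", "M"])
    rng = np.random.default_rng(2)
    y = rng.normal(size=8) + 0.5 * age
    a = residualize(_frame(y), _covariates(age, sex), mode="sequential")
    b = residualize(_frame(y), _covariates(age, sex), mode="joint")
    np.testing.assert_allclose(
        a.values.to_numpy(), b.values.to_numpy(), atol=1e-8
    )


@pytest.mark.parametrize("mode", ["sequential", "joint"])
def test_invariant_to_affine_rescaling_of_age(mode):
    rng = np.random.default_rng(3)
    n = 30
    age_years = rng.uniform(6, 18, n)
    sex = rng.choice(["F", "M"], n)
    y = rng.normal(size=n) + 0.3 * age_years
    res_years = residualize(_frame(y), _covariates(age_years, sex), mode=mode)
    res_months = residualize(_frame(y), _covariates(age_years * 12.0 + 4.0, sex), mode=mode)
    np.testing.assert_allclose(
        res_years.values.to_numpy(), res_months.values.to_numpy(), atol=1e-8
    )


def test_single_level_categorical_covariate_is_skipped(caplog):
    rng = np.random.default_rng(4)
    age = rng.uniform(6, 18, 20)
    scanner = np.array(["only"] * 20)
    y = rng.normal(size=20)
    with caplog.at_level("WARNING", logger="bagclust"):
        res = residualize(_frame(y), _covariates(age, scanner=scanner))
    assert res.covariate_order == ("age",)
    assert any("single level" in r.message for r in caplog.records)
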