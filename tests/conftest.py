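import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netenergy import EnergyBalance, datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table3():
    return datasets.load_table3()


@pytest.fixture(scope="session")
def table4():
    return datasets.load_table4()


@pytest.fixture(scope="session")
def table5():
    return datasets.load_table5()


@pytest.fixture(scope="session")
def table6():
    return datasets.load_table6()


@pytest.fixture(scope="session")
def table7():
    return datasets.load_table7()


def balances_from_table4(table4) -> list[EnergyBalance]:
    """Published ad-libitum partition cells as EnergyBalance objects."""
    return [
        EnergyBalance(
            diet_id=r["diet_id"],
            feeding_level=1.0,
            replicate_id="pub",
            bwg=r["adg_g_day"],
            w_avg=r["bw_avg_kg"],
            w_meta=r["w_meta_kg075"],
            fi=np.nan,
            mei=r["mei_kcal_day"],
            re=r["re_kcal_day"],
            hp=r["hp_kcal_day"],
            nem=r["nem_kcal_day"],
            hi=r["hi_kcal_day"],
            ne=r["ne_kcal_day"],
        )
        for _, r in table4.iterrows()
    ]


@pytest.fixture(scope="session")
def table4_balances(table4):
    return balances_from_table4(table4)


def ols_oracle(x, y):
    """Brute-force normal-equations OLS oracle: returns (intercept, slope, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return float(beta[0]), float(beta[1]), r2
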