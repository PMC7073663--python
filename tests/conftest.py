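import numpy as np
import pandas as pd
import pytest

from pai_allocate import ScenarioConfig, TrialTable, VariableSpec
from pai_allocate.trial import make_table


def build_table(rows: list[dict], schema: tuple[VariableSpec, ...]) -> TrialTable:
    """Assemble a validated table from literal row dicts."""
    return make_table(pd.DataFrame(rows), schema)


@pytest.fixture
def toy_schema() -> tuple[VariableSpec, ...]:
    return (
        VariableSpec("severity", "continuous", params={"mean": 15.0, "sd": 5.0}),
        VariableSpec("mostly_missing", "continuous", params={"mean": 0.0, "sd": 1.0}),
        VariableSpec("country", "nominal", levels=("A", "B", "C", "D")),
    )


@pytest.fixture
def toy_table(toy_schema) -> TrialTable:
    """10 patients; outcome missing for 3; one covariate missing in 55% of
    the completer rows."""
    nan = np.nan
    rows = []
    for i in range(10):
        rows.append(
            {
                "patient_id": f"P{i}",
                "arm": "TAU" if i % 2 == 0 else "BLEND",
                "severity": 10.0 + i,
                # rows 0-3 observed, rest missing
                "mostly_missing": float(i) if i < 3 else nan,
                "country": "ABCD"[i % 4],
                "outcome": nan if i in (1, 4, 8) else float(5 + i),
            }
        )
    # on the 7 completers, mostly_missing is observed for rows 0 and 2 only:
    # missing fraction 5/7 ~ 0.71 >= 0.5 (dropped); severity fully observed
    return build_table(rows, toy_schema)


@pytest.fixture
def correlated_config():
    """Small scenario with strongly correlated continuous covariates plus
    one binary, used by the imputation-quality checks."""

    def factory(seed: int) -> ScenarioConfig:
        schema = tuple(
            VariableSpec(f"v{j}", "continuous", params={"mean": 10.0, "sd": 3.0}, loading=0.8)
            for j in range(5)
        ) + (VariableSpec("b0", "binary", params={"p": 0.5}, loading=0.7),)
        return ScenarioConfig(
            n_patients=120,
            covariate_schema=schema,
            beta_tau={"v0": 0.5},
            beta_blend={"v0": 0.5},
            intercept_tau=5.0,
            intercept_blend=5.0,
            noise_sd=3.0,
            seed=seed,
        )

    return factory
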