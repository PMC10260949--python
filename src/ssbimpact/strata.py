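"""Stratum definitions and the baseline table.

Every quantity in the model lives on a fixed grid of 70 strata:
7 ten-year age groups (25-34 ... 85+) x 2 sexes x 5 quintiles of the
Index of Multiple Deprivation (IMD; quintile 1 most affluent, 5 most
deprived). The five quintiles collapse to three socio-economic
circumstance (SEC) groups for intake and price-response purposes:
quintiles 1+2 -> "low" deprivation, 3 -> "mid", 4+5 -> "high".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = (
    "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+",
)
SEXES: tuple[str, ...] = ("male", "female")
IMD_QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: default IMD quintile -> SEC group mapping (quintiles 1+2 pooled, 4+5 pooled)
DEFAULT_SEC_GROUPING: dict[int, str] = {1: "low", 2: "low", 3: "mid", 4: "high", 5: "high"}
SEC_GROUPS: tuple[str, ...] = ("low", "mid", "high")

#: CHD vital-status subgroups used for median-survival weighting of LYG
CHD_STATUSES: tuple[str, ...] = ("diagnosed_chd", "undiagnosed_chd", "no_chd")

STRATUM_KEYS = ["age_group", "sex", "imd_quintile"]

BASELINE_COLUMNS = STRATUM_KEYS + [
    "deaths",
    "population",
    "intake",
    "overweight_prevalence",
    "p_diagnosed_chd",
    "p_undiagnosed_chd",
    "p_no_chd",
    "survival_diagnosed_chd",
    "survival_undiagnosed_chd",
    "survival_no_chd",
]

_PROP_COLS = ["p_diagnosed_chd", "p_undiagnosed_chd", "p_no_chd"]
_SURV_COLS = ["survival_diagnosed_chd", "survival_undiagnosed_chd", "survival_no_chd"]


class BaselineError(ValueError):
    """Raised when a baseline table is incomplete or inconsistent."""


def stratum_grid() -> pd.DataFrame:
    """Return the full 70-row (age_group, sex, imd_quintile) grid."""
    idx = pd.MultiIndex.from_product(
        [AGE_GROUPS, SEXES, IMD_QUINTILES], names=STRATUM_KEYS
    )
    return idx.to_frame(index=False)


class BaselineTable:
    """Per-stratum baseline inputs for one model run.

    Wraps a :class:`pandas.DataFrame` with one row per stratum carrying
    projected CHD deaths, population, mean SSB intake (g/day), overweight
    prevalence, the proportion of CHD deaths occurring in each CHD vital
    status and the corresponding median survivals (years).

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain :data:`BASELINE_COLUMNS` and exactly one row for each
        of the 70 strata.
    validate : bool, default True
        Check invariants (non-negative counts, fractions in [0, 1],
        status proportions summing to 1, positive survivals).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        missing = [c for c in BASELINE_COLUMNS if c not in data.columns]
        if missing:
            raise BaselineError(f"baseline table missing columns: {missing}")
        df = data[BASELINE_COLUMNS].copy()
        df["imd_quintile"] = df["imd_quintile"].astype(int)
        df = df.sort_values(STRATUM_KEYS, key=_stratum_sort_key, ignore_index=True)
        if validate:
            _validate(df)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:  # mostly for tests
        return isinstance(other, BaselineTable) and self.data.equals(other.data)

    @property
    def total_deaths(self) -> float:
        return float(self.data["deaths"].sum())

    @property
    def total_population(self) -> float:
        return float(self.data["population"].sum())

    @property
    def mean_intake(self) -> float:
        """Population-weighted mean SSB intake, g/day."""
        d = self.data
        return float(np.average(d["intake"], weights=d["population"]))

    def sec_group(self, grouping: dict[int, str] | None = None) -> pd.Series:
        """SEC group label for each row under `grouping` (default 1+2/3/4+5)."""
        grouping = DEFAULT_SEC_GROUPING if grouping is None else grouping
        try:
            return self.data["imd_quintile"].map(lambda q: grouping[int(q)])
        except KeyError as e:  # pragma: no cover - mapping errors surface below
            raise BaselineError(f"IMD quintile {e} has no SEC group") from None

    # --- I/O ----------------------------------------------------------------

    @classmethod
    def read_csv(cls, path_or_buf) -> "BaselineTable":
        return cls(pd.read_csv(path_or_buf))

    def to_csv(self, path_or_buf=None) -> str | None:
        return self.data.to_csv(path_or_buf, index=False, float_format="%.17g")

    def copy(self) -> "BaselineTable":
        return BaselineTable(self.data.copy(), validate=False)

    def __repr__(self) -> str:
        return (
            f"<BaselineTable: {len(self)} strata, "
            f"{self.total_deaths:.0f} CHD deaths, "
            f"mean intake {self.mean_intake:.1f} g/d>"
        )


def _stratum_sort_key(s: pd.Series) -> pd.Series:
    if s.name == "age_group":
        order = {a: i for i, a in enumerate(AGE_GROUPS)}
        return s.map(order)
    if s.name == "sex":
        order = {x: i for i, x in enumerate(SEXES)}
        return s.map(order)
    return s


def _validate(df: pd.DataFrame) -> None:
    expected = stratum_grid()
    got = df[STRATUM_KEYS].reset_index(drop=True)
    if len(df) != len(expected) or not got.equals(expected):
        bad_age = set(df["age_group"]) - set(AGE_GROUPS)
        bad_sex = set(df["sex"]) - set(SEXES)
        bad_q = set(df["imd_quintile"]) - set(IMD_QUINTILES)
        detail = []
        if bad_age:
            detail.append(f"unknown age groups {sorted(bad_age)}")
        if bad_sex:
            detail.append(f"unknown sexes {sorted(bad_sex)}")
        if bad_q:
            detail.append(f"unknown IMD quintiles {sorted(bad_q)}")
        raise BaselineError(
            "baseline table must contain exactly one row per stratum "
            f"({len(expected)} rows); got {len(df)}"
            + (": " + "; ".join(detail) if detail else "")
        )
    num = df[BASELINE_COLUMNS[3:]]
    if num.isna().any().any():
        raise BaselineError("baseline table contains missing values")
    if (df["deaths"] < 0).any() or (df["population"] < 0).any():
        raise BaselineError("deaths and population must be non-negative")
    if (df["intake"] < 0).any():
        raise BaselineError("intake must be non-negative")
    ow = df["overweight_prevalence"]
    if ((ow < 0) | (ow > 1)).any():
        raise BaselineError("overweight prevalence must lie in [0, 1]")
    props = df[_PROP_COLS]
    if ((props < 0) | (props > 1)).any().any():
        raise BaselineError("CHD-status proportions must lie in [0, 1]")
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
        raise BaselineError("CHD-status proportions must sum to 1 per stratum")
    if (df[_SURV_COLS] <= 0).any().any():
        raise BaselineError("median survivals must be positive")
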