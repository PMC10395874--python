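"""The 20 candidate predictors screened against each outcome.

Fifteen clinical characteristics (sex, age group, type of malignancy, relapse
status, chemotherapy intensity, central venous access device, bone marrow
involvement, time since diagnosis, prior FN episodes, prior FN episodes with
bacteremia, season, time of presentation, temperature >= 39 C, severely
reduced general condition, SIRS at presentation) and five hematological ones
(hemoglobin, leucocyte count, ANC, AMC, platelet count).

Each characteristic knows how to expand itself into reference-coded design
columns.  The blood counts enter the final decision rules as the dichotomies
the rules use (leucocyte count < 0.3 G/L, platelet count < 50 G/L); those are
registered as derived binary characteristics alongside the linear forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

MALIGNANCY_LEVELS = ("ALL", "AML", "Hodgkin", "NHL", "CNS_tumor", "other_solid")
AGE_GROUP_LEVELS = ("<6", "6-11", ">=12")


@dataclass(frozen=True)
class Characteristic:
    """A candidate predictor and its design-matrix encoding."""

    name: str
    kind: str  # 'binary' | 'categorical' | 'continuous'
    levels: tuple[str, ...] | None = None  # categorical only; levels[0] is reference
    transform: Callable[[pd.DataFrame], np.ndarray] | None = None  # derived columns

    def design(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Return (n x k) design columns and their labels (reference omitted)."""
        if self.transform is not None:
            x = np.asarray(self.transform(table), dtype=float)
            return x.reshape(-1, 1), [self.name]
        if self.kind == "categorical":
            col = table[self.name].astype(str)
            unknown = set(col.unique()) - set(self.levels)
            if unknown:
                raise ValueError(f"{self.name}: unknown levels {sorted(unknown)}")
            cols = [np.asarray(col == lv, dtype=float) for lv in self.levels[1:]]
            labels = [f"{self.name}[{lv}]" for lv in self.levels[1:]]
            return np.column_stack(cols), labels
        return np.asarray(table[self.name], dtype=float).reshape(-1, 1), [self.name]


def _binary(name: str) -> Characteristic:
    return Characteristic(name, "binary")


def _derived(name: str, fn: Callable[[pd.DataFrame], np.ndarray]) -> Characteristic:
    return Characteristic(name, "binary", transform=fn)


CHARACTERISTICS: dict[str, Characteristic] = {
    c.name: c
    for c in [
        _binary("sex"),
        Characteristic("age_group", "categorical", AGE_GROUP_LEVELS),
        Characteristic("malignancy_type", "categorical", MALIGNANCY_LEVELS),
        _binary("relapse"),
        _binary("chemo_intensity_above_ALL_maintenance"),
        _binary("cvad"),
        _binary("bone_marrow_involvement"),
        Characteristic("months_since_diagnosis", "continuous"),
        Characteristic("prior_fn_count", "continuous"),
        Characteristic("prior_fn_bacteremia_count", "continuous"),
        _binary("season_spring_summer"),
        _binary("out_of_office_presentation"),
        _derived("temperature_ge_39",
                 lambda t: (t["temperature_at_presentation"] >= 39.0).to_numpy()),
        _binary("severely_reduced_general_condition"),
        _binary("sirs_at_presentation"),
        Characteristic("hemoglobin", "continuous"),
        Characteristic("leucocyte_count", "continuous"),
        Characteristic("anc", "continuous"),
        Characteristic("amc", "continuous"),
        Characteristic("platelet_count", "continuous"),
        # dichotomized blood counts as used by the decision rules
        _derived("leucocyte_lt_0_3", lambda t: (t["leucocyte_count"] < 0.3).to_numpy()),
        _derived("platelet_lt_50", lambda t: (t["platelet_count"] < 50.0).to_numpy()),
    ]
}

#: the 20 characteristics entering the univariable screen, with blood counts
#: in the dichotomized form the decision rules use
SCREEN_CHARACTERISTICS: tuple[str, ...] = (
    "sex", "age_group", "malignancy_type", "relapse",
    "chemo_intensity_above_ALL_maintenance", "cvad", "bone_marrow_involvement",
    "months_since_diagnosis", "prior_fn_count", "prior_fn_bacteremia_count",
    "season_spring_summer", "out_of_office_presentation", "temperature_ge_39",
    "severely_reduced_general_condition", "sirs_at_presentation",
    "hemoglobin", "leucocyte_lt_0_3", "anc", "amc", "platelet_lt_50",
)


def get_characteristic(name: str) -> Characteristic:
    try:
        return CHARACTERISTICS[name]
    except KeyError:
        raise KeyError(f"unknown characteristic {name!r}")
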