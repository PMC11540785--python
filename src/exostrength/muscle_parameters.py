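"""Baseline muscle parameters and the composite strength index.

The dependent variables of the strength model come from a pre-measurement
battery: vertical jump (VJ, cm), one-repetition-maximum leg extension and
leg curl (RM LE / RM LC, kg), and isometric leg extension / curl force
(ISO LE / ISO LC, N). Load measures are normalized to body weight so
participants of different size are comparable; the overall index
``total_performance`` is the sum of cohort z-scores of VJ, RM(LE+LC)/weight
and ISO(LE+LC)/weight, hence dimensionless with cohort mean 0.

The z-scoring moments live in a :class:`CohortStandardizer` so they can be
fitted on one cohort and frozen for re-use (the bootstrap validation
recomputes the index on perturbed data with the original moments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: variables entering the composite index, in fixed order
COMPOSITE_VARS = ("vj", "rm_le_lc_weight", "iso_le_lc_weight")

#: all weight-normalized derived columns
DERIVED_VARS = (
    "rm_le_lc_weight",
    "rm_le_weight",
    "rm_lc_weight",
    "iso_le_lc_weight",
    "iso_le_weight",
    "iso_lc_weight",
)


@dataclass
class MuscleParameters:
    """One participant's raw strength battery plus derived ratios."""

    vj: float  # vertical jump height, cm (best of three trials)
    rm_le: float  # 1RM leg extension, kg
    rm_lc: float  # 1RM leg curl, kg
    iso_le: float  # isometric leg extension, N
    iso_lc: float  # isometric leg curl, N
    weight: float  # body weight, kg
    participant_id: str = ""
    # derived, filled by weight_normalize
    rm_le_lc_weight: float | None = None
    rm_le_weight: float | None = None
    rm_lc_weight: float | None = None
    iso_le_lc_weight: float | None = None
    iso_le_weight: float | None = None
    iso_lc_weight: float | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def weight_normalize(params: MuscleParameters) -> MuscleParameters:
    """Fill the six weight-normalized ratios (raw / body weight)."""
    if params.weight <= 0:
        raise ValueError("weight must be > 0")
    w = params.weight
    params.rm_le_weight = params.rm_le / w
    params.rm_lc_weight = params.rm_lc / w
    params.rm_le_lc_weight = (params.rm_le + params.rm_lc) / w
    params.iso_le_weight = params.iso_le / w
    params.iso_lc_weight = params.iso_lc / w
    params.iso_le_lc_weight = (params.iso_le + params.iso_lc) / w
    return params


@dataclass
class CohortStandardizer:
    """Per-variable mean and SD (sample SD, n-1 denominator) for z-scoring."""

    means: dict[str, float]
    sds: dict[str, float]
    source: str = "fitted"  # or "frozen"

    def __post_init__(self) -> None:
        for var, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"variable {var!r} has non-positive SD {sd}")

    def zscore(self, var: str, value: float | np.ndarray) -> float | np.ndarray:
        return (value - self.means[var]) / self.sds[var]

    def freeze(self) -> "CohortStandardizer":
        return CohortStandardizer(dict(self.means), dict(self.sds), source="frozen")

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"variable": list(self.means), "mean": list(self.means.values()),
             "sd": [self.sds[v] for v in self.means]}
        )
        df.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CohortStandardizer":
        df = pd.read_csv(path)
        return cls(
            means=dict(zip(df["variable"], df["mean"])),
            sds=dict(zip(df["variable"], df["sd"])),
            source="frozen",
        )


def fit_standardizer(cohort: list[MuscleParameters]) -> CohortStandardizer:
    """Fit z-score moments for the composite variables on a cohort.

    Every participant must already have the derived ratios filled
    (see :func:`weight_normalize`); errors name the offending variable.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 participants to standardize")
    means, sds = {}, {}
    for var in COMPOSITE_VARS:
        vals = np.array([_get_composite(p, var) for p in cohort], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"variable {var!r} has zero SD in this cohort")
        means[var], sds[var] = mean, sd
    return CohortStandardizer(means, sds)


def _get_composite(p: MuscleParameters, var: str) -> float:
    val = getattr(p, var)
    if val is None:
        raise ValueError(
            f"derived field {var!r} missing for participant {p.participant_id!r}; "
            "call weight_normalize first"
        )
    return float(val)


def total_performance(params: MuscleParameters, std: CohortStandardizer) -> float:
    """Composite strength index: z(VJ) + z(RM ratio) + z(ISO ratio)."""
    return float(sum(std.zscore(v, _get_composite(params, v)) for v in COMPOSITE_VARS))


def cohort_frame(cohort: list[MuscleParameters], std: CohortStandardizer | None = None) -> pd.DataFrame:
    """Tabulate a cohort (raw + derived, plus total_performance if std given)."""
    rows = []
    for p in cohort:
        row = {
            "participant_id": p.participant_id,
            "vj": p.vj, "rm_le": p.rm_le, "rm_lc": p.rm_lc,
            "iso_le": p.iso_le, "iso_lc": p.iso_lc, "weight": p.weight,
        }
        for var in DERIVED_VARS:
            row[var] = getattr(p, var)
        if std is not None:
            row["total_performance"] = total_performance(p, std)
        rows.append(row)
    return pd.DataFrame(rows)
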