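"""Shared construction of a small analysis table for bootstrap tests."""

import numpy as np
import pandas as pd

from exostrength.muscle_parameters import CohortStandardizer


def build_bootstrap_table(rng, n=30):
    """Analysis table with a predictor, raw composite columns and
    demographics, plus the frozen standardizer that defines the
    composite index."""
    latent = rng.standard_normal(n)
    vj = 45 + 6.4 * latent + 4.8 * rng.standard_normal(n)
    rm = 1.6 + 0.28 * latent + 0.21 * rng.standard_normal(n)
    iso = 6.0 + 0.96 * latent + 0.72 * rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "Squat_IS_Max": 8.47 + 1.9 * latent + 0.62 * rng.standard_normal(n),
            "vj": vj,
            "rm_le_lc_weight": rm,
            "iso_le_lc_weight": iso,
            "sex_male": (rng.random(n) < 0.6).astype(float),
            "age": 26 + 3 * rng.standard_normal(n),
        }
    )
    std = CohortStandardizer(
        means={
            "vj": float(vj.mean()),
            "rm_le_lc_weight": float(rm.mean()),
            "iso_le_lc_weight": float(iso.mean()),
        },
        sds={
            "vj": float(vj.std(ddof=1)),
            "rm_le_lc_weight": float(rm.std(ddof=1)),
            "iso_le_lc_weight": float(iso.std(ddof=1)),
        },
        source="frozen",
    )
    table["total_performance"] = (
        (vj - std.means["vj"]) / std.sds["vj"]
        + (rm - std.means["rm_le_lc_weight"]) / std.sds["rm_le_lc_weight"]
        + (iso - std.means["iso_le_lc_weight"]) / std.sds["iso_le_lc_weight"]
    )
    return table, std
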