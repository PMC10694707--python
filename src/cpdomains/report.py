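"""Rounded summary tables for study bundles.

Printed precision follows the field's reporting conventions: times to
1 decimal (s), CP to integer watts, W' to 1 decimal kJ, percentages to
1 decimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .critpower import MODEL_NAMES

__all__ = ["model_estimates_table", "prediction_agreement_table"]


def _mean_sd(x, fmt: str) -> str:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return "-"
    return f"{x.mean():{fmt}} ± {x.std(ddof=1):{fmt}}" if x.size > 1 else f"{x.mean():{fmt}}"


def model_estimates_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SD of CP, SEE%, W' and R² per model variant."""
    rows = {}
    for model in MODEL_NAMES:
        grp = fits[fits["model"] == model]
        if grp.empty:
            continue
        rows[model] = {
            "CP (W)": _mean_sd(grp["cp_W"], ".0f"),
            "CP SEE (%)": _mean_sd(grp["see_cp_pct"], ".1f"),
            "W' (kJ)": _mean_sd(grp["w_prime_J"] / 1000.0, ".1f"),
            "W' SEE (%)": _mean_sd(grp["see_wp_pct"], ".1f"),
            "R2": _mean_sd(grp["r2"], ".3f"),
        }
    return pd.DataFrame(rows)


def prediction_agreement_table(
    predictions: pd.DataFrame, agreement: pd.DataFrame
) -> pd.DataFrame:
    """Actual vs. predicted Tlim with bias ± SD [LoA] per intensity × model."""
    rows = []
    for intensity in ("i_high", "i_high_plus5"):
        pr = predictions[predictions["intensity"] == intensity]
        if pr.empty:
            continue
        actual = pr.groupby("athlete_id")["actual_s"].first()
        row = {"intensity": intensity, "actual Tlim (s)": _mean_sd(actual, ".0f")}
        for model in MODEL_NAMES:
            sub = pr[pr["model"] == model]
            ag = agreement[
                (agreement["intensity"] == intensity)
                & (agreement["model"] == model)
                & (agreement["mode"] == "raw")
            ]
            if sub.empty or ag.empty:
                continue
            a = ag.iloc[0]
            row[f"{model} Tlim (s)"] = _mean_sd(sub["predicted_s"], ".0f")
            row[f"{model} bias ± SD [LoA] (s)"] = (
                f"{a['bias']:.1f} ± {a['sd_diff']:.1f}"
                f" [{a['loa_low']:.1f} to {a['loa_high']:.1f}]"
            )
        rows.append(row)
    return pd.DataFrame(rows)
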