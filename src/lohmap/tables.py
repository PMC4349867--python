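"""Reproduce the derived columns of the published count tables.

The raw colony and event counts ship as small TSV fixtures; these functions
recompute every derived quantity (frequencies, exact CIs, fold increases,
per-colony averages, SCB/DSCB percentages) from those counts so the
arithmetic of the published tables can be checked end to end.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import fold_change, sector_frequency


def _load(name: str) -> pd.DataFrame:
    with resources.files("lohmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_sectoring_counts() -> pd.DataFrame:
    return _load("table1_sectoring.tsv")


def load_sectored_colony_counts() -> pd.DataFrame:
    return _load("table2_sectored_colonies.tsv")


def load_break_type_counts() -> pd.DataFrame:
    return _load("table3_break_types.tsv")


def load_single_colony_counts() -> pd.DataFrame:
    return _load("table4_single_colonies.tsv")


def report_sectoring() -> pd.DataFrame:
    """Sectored-colony frequencies with exact CIs and fold increases.

    Each irradiated row's fold increase is its frequency divided by the
    baseline row named in its ``baseline`` column (the unirradiated strain
    for the same marker interval, or the wild-type baseline where the table
    used that). Cross-genotype folds against the wild-type chromosome-IV
    baseline are reported in ``fold_vs_wt`` where defined.
    """
    df = load_sectoring_counts()
    freqs: dict[str, float] = {}
    rows = []
    for _, r in df.iterrows():
        if np.isfinite(r.get("freq_fixed", np.nan)):
            freq, lo, hi = float(r["freq_fixed"]), np.nan, np.nan
        else:
            est = sector_frequency(int(r["sectored"]), int(r["total"]))
            freq, lo, hi = est.frequency, est.ci_low, est.ci_high
        freqs[r["strain"]] = freq
        rows.append(
            {
                "strain": r["strain"],
                "genotype": r["genotype"],
                "sup4_location": r["sup4_location"],
                "uv_dose": r["uv_dose"],
                "frequency": freq,
                "ci_low": lo,
                "ci_high": hi,
                "crossover_rate": 2 * freq,
                "baseline": r.get("baseline", np.nan),
            }
        )
    out = pd.DataFrame(rows)
    folds = []
    folds_wt = []
    for _, r in out.iterrows():
        base = r["baseline"]
        folds.append(
            fold_change(r["frequency"], freqs[base]) if isinstance(base, str) else np.nan
        )
        # fold relative to the unirradiated wild-type chromosome-IV strain
        if r["sup4_location"] == "IV" and r["uv_dose"] != 0:
            folds_wt.append(fold_change(r["frequency"], freqs["JSC25_IV_0"]))
        else:
            folds_wt.append(np.nan)
    out["fold_increase"] = folds
    out["fold_vs_wt"] = folds_wt
    return out


def report_break_types() -> pd.DataFrame:
    """SCB/DSCB totals and percentages (selected + unselected events).

    Percentages are rounded to the nearest integer for display, as in the
    published table.
    """
    df = load_break_type_counts().fillna(0)
    out = df.copy()
    # component sums for cross-checking; the published totals are kept as
    # primary because one row's printed total differs from its components
    out["sum_scb"] = (df["selected_scb"] + df["unselected_scb"]).astype(int)
    out["sum_dscb"] = (df["selected_dscb"] + df["unselected_dscb"]).astype(int)
    denom = out["total_scb"] + out["total_dscb"]
    out["pct_scb"] = (100.0 * out["total_scb"] / denom).round().astype(int)
    out["pct_dscb"] = (100.0 * out["total_dscb"] / denom).round().astype(int)
    sel_denom = df["selected_scb"] + df["selected_dscb"]
    out["pct_selected_scb"] = (
        (100.0 * df["selected_scb"] / sel_denom).round().astype(int)
    )
    return out


def report_sectored_colonies() -> pd.DataFrame:
    """Per-sector averages and ratios to wild-type for sectored colonies."""
    df = load_sectored_colony_counts()
    out = df.copy()
    for col in ("interstitial", "crossovers", "bir", "total_loh"):
        out[f"ave_{col}"] = df[col] / df["sectors"]
    wt15 = out[(out["genotype"] == "WT") & (out["uv_dose"] == 15)].iloc[0]
    out["crossover_ratio_vs_wt15"] = out["ave_crossovers"] / wt15["ave_crossovers"]
    return out


def report_single_colonies() -> pd.DataFrame:
    """Per-colony averages and fold change vs the NER-deficient baseline."""
    df = load_single_colony_counts()
    out = df.copy()
    for col in ("interstitial", "co_bir", "total_loh"):
        out[f"ave_{col}"] = df[col] / df["colonies"]
    base = out[out["genotype"] == "rad14"].iloc[0]["ave_total_loh"]
    out["fold_vs_rad14"] = out["ave_total_loh"] / base
    return out
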