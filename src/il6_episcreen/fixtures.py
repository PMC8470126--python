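"""Loaders for the transcribed printed summary tables.

The two bundled fixtures are verbatim transcriptions of the study's printed
per-cohort summary tables:

* ``table1.tsv`` — per-cohort signed fold changes of IL6/IL6R/IL6ST (shown
  only when |FC| >= 1.4 and p <= 0.05) plus OS/PFI log-rank chi-squares with
  their favorable/unfavorable marks.
* ``table2.tsv`` — OS/PFI log-rank chi-squares for the selected IL6/IL6R CpG
  probes used as methylation stratifiers.

Blank cells (value not shown because it failed the display gate) are kept as
missing; the literal ``NA`` in table 1 marks endpoints that were not
applicable for a cohort and is loaded as missing too, with the distinction
preserved in the ``pfi_not_applicable`` flag.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

TABLE1_GENES = ("IL6", "IL6R", "IL6ST")
N_COHORTS = 33


def _fixture_path(name: str) -> Path:
    path = resources.files("il6_episcreen").joinpath("fixtures", name)
    with resources.as_file(path) as p:
        return Path(p)


def _read_fixture(name: str, key_cols: list[str]) -> pd.DataFrame:
    try:
        path = _fixture_path(name)
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise FormatError(f"fixture {name} missing from package data") from exc
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise FormatError(f"fixture {name}: missing columns {missing}")
    return df


def load_table1_fixture() -> pd.DataFrame:
    """Load the per-gene, per-cohort fold-change / survival summary table.

    Returns a DataFrame with one row per (cohort, gene) and columns
    ``fc`` (signed fold change, NaN when not shown), ``os_chi2``,
    ``os_direction``, ``pfi_chi2``, ``pfi_direction`` and the boolean
    ``pfi_not_applicable``.
    """
    df = _read_fixture(
        "table1.tsv",
        ["cohort", "gene", "fc", "os_chi2", "os_direction", "pfi_chi2", "pfi_direction"],
    )
    out = df.copy()
    out["pfi_not_applicable"] = df["pfi_chi2"].str.strip() == "NA"
    for col in ("fc", "os_chi2", "pfi_chi2"):
        cells = df[col].str.strip().replace({"": np.nan, "NA": np.nan})
        out[col] = pd.to_numeric(cells)
    for col in ("os_direction", "pfi_direction"):
        out[col] = df[col].str.strip().replace({"": None, "NA": None})
    if out["cohort"].nunique() != N_COHORTS:
        raise FormatError(
            f"table1 fixture: expected {N_COHORTS} cohorts, got {out['cohort'].nunique()}"
        )
    if set(out["gene"]) != set(TABLE1_GENES):
        raise FormatError(f"table1 fixture: unexpected gene set {set(out['gene'])}")
    if out.duplicated(subset=["cohort", "gene"]).any():
        raise FormatError("table1 fixture: duplicate (cohort, gene) rows")
    return out


def load_table2_fixture() -> pd.DataFrame:
    """Load the probe-methylation survival summary (one row per cohort x probe)."""
    df = _read_fixture(
        "table2.tsv",
        ["cohort", "probe", "gene", "os_chi2", "os_direction", "pfi_chi2", "pfi_direction"],
    )
    out = df.copy()
    for col in ("os_chi2", "pfi_chi2"):
        out[col] = pd.to_numeric(df[col].str.strip().replace({"": np.nan}))
    for col in ("os_direction", "pfi_direction"):
        out[col] = df[col].str.strip().replace({"": None})
    if out.duplicated(subset=["cohort", "probe"]).any():
        raise FormatError("table2 fixture: duplicate (cohort, probe) rows")
    return out


def table1_fold_change_records(alpha: float = 0.05) -> pd.DataFrame:
    """Re-express the table-1 fold-change cells as fold-change records.

    Every displayed FC passed the table's display gate (|FC| >= 1.4 and
    p <= 0.05), so shown cells become ``up``/``down`` records with the gate's
    alpha as an upper bound on p; blank cells become ``ns`` records.
    """
    t1 = load_table1_fixture()
    records = t1[["gene", "cohort", "fc"]].rename(columns={"fc": "fc_signed"}).copy()
    records["p_value"] = np.where(records["fc_signed"].notna(), alpha, np.nan)
    records["direction"] = np.select(
        [records["fc_signed"] >= 1.4, records["fc_signed"] <= -1.4],
        ["up", "down"],
        default="ns",
    )
    return records


def table1_survival_results() -> pd.DataFrame:
    """Re-express the table-1 survival cells as one row per significant result."""
    t1 = load_table1_fixture()
    rows = []
    for _, row in t1.iterrows():
        for endpoint, chi_col, dir_col in (
            ("OS", "os_chi2", "os_direction"),
            ("PFI", "pfi_chi2", "pfi_direction"),
        ):
            if pd.notna(row[chi_col]):
                rows.append(
                    {
                        "stratifier_id": row["gene"],
                        "cohort": row["cohort"],
                        "endpoint": endpoint,
                        "chi_square": row[chi_col],
                        "direction": row[dir_col],
                        "significant": True,
                    }
                )
    return pd.DataFrame(rows)
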