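"""Signed fold change, significance gating, and modulation summaries.

The tumor-vs-normal contrast works on log2-scale expression. The signed
fold change is ``sign(d) * 2**|d|`` with ``d = mean(log2 tumor) -
mean(log2 normal)``, so the magnitude is always >= 1 and the sign carries
the direction (``+1`` when the means are equal). Significance is a Welch
two-sample t-test; a cell is called modulated (``up``/``down``) only when
both the fold-change magnitude and the p-value pass their gates, mirroring
the display rule of the printed summary table (|FC| >= 1.4, p <= 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import OmicsMatrix, SampleAnnotation, TissueClass
from .exceptions import DegenerateDataError, InsufficientDataError, ValidationError

FC_THRESHOLD = 1.4
ALPHA = 0.05


def signed_fold_change(tumor_values, normal_values) -> float:
    """Signed fold change between two log2-scale samples.

    Missing values are dropped per arm; each arm needs >= 2 observations.
    """
    tumor = _clean(tumor_values, "tumor")
    normal = _clean(normal_values, "normal")
    delta = float(np.mean(tumor) - np.mean(normal))
    if delta == 0.0:
        return 1.0
    return math.copysign(2.0 ** abs(delta), delta)


def two_sample_t(tumor_values, normal_values) -> tuple[float, float]:
    """Welch unequal-variance t-test, two-sided.

    Both arms constant and equal returns (0, 1) by convention; both arms
    constant but unequal has no defined t statistic and raises.
    """
    tumor = _clean(tumor_values, "tumor")
    normal = _clean(normal_values, "normal")
    if np.ptp(tumor) == 0 and np.ptp(normal) == 0:
        if tumor[0] == normal[0]:
            return 0.0, 1.0
        raise DegenerateDataError(
            "both arms are constant with different values; the t statistic is undefined"
        )
    t, p = stats.ttest_ind(tumor, normal, equal_var=False)
    return float(t), float(p)


def classify_modulation(
    fc_signed: float, p: float, fc_threshold: float = FC_THRESHOLD, alpha: float = ALPHA
) -> str:
    """Direction call: ``up``/``down`` when both gates pass, else ``ns``."""
    if abs(fc_signed) < 1.0:
        raise ValidationError(f"signed fold change magnitude must be >= 1, got {fc_signed}")
    if p <= alpha and fc_signed >= fc_threshold:
        return "up"
    if p <= alpha and fc_signed <= -fc_threshold:
        return "down"
    return "ns"


def fold_change_table(
    expression: OmicsMatrix,
    annotations: list[SampleAnnotation],
    genes: list[str],
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per gene x cohort fold-change records from an annotated expression matrix.

    Cohorts with fewer than two tumor or two normal samples measured for a
    gene are skipped. Returns one row per computable (gene, cohort) with
    columns ``gene, cohort, fc_signed, p_value, n_tumor, n_normal, direction``.
    """
    by_cohort: dict[str, dict[str, list[str]]] = {}
    sample_set = set(expression.sample_ids)
    for ann in annotations:
        if ann.sample_id not in sample_set:
            continue
        slot = by_cohort.setdefault(ann.cohort.code, {"tumor": [], "normal": []})
        slot[ann.tissue_class.value].append(ann.sample_id)

    rows = []
    for gene in genes:
        if gene not in expression.values.index:
            raise ValidationError(f"gene {gene!r} not present in the expression matrix")
        values = expression.row(gene)
        for cohort, groups in sorted(by_cohort.items()):
            tumor = values[groups["tumor"]].dropna()
            normal = values[groups["normal"]].dropna()
            if len(tumor) < 2 or len(normal) < 2:
                continue
            fc = signed_fold_change(tumor, normal)
            try:
                _, p = two_sample_t(tumor, normal)
            except DegenerateDataError:
                continue
            rows.append(
                {
                    "gene": gene,
                    "cohort": cohort,
                    "fc_signed": fc,
                    "p_value": p,
                    "n_tumor": len(tumor),
                    "n_normal": len(normal),
                    "direction": classify_modulation(fc, p, fc_threshold, alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "cohort", "fc_signed", "p_value", "n_tumor", "n_normal", "direction"],
    )


@dataclass(frozen=True)
class ModulationSummary:
    gene: str
    n_cohorts: int
    n_modulated: int
    n_up: int
    n_down: int
    extreme_up: tuple[str, float] | None  # (cohort, fc) of the largest up FC
    extreme_down: tuple[str, float] | None  # (cohort, fc) of the most negative FC


def summarize_modulation(records: pd.DataFrame, gene: str) -> ModulationSummary:
    """Count up/down cohorts for one gene and report the extreme fold changes.

    Extremes are the max and min signed FC among modulated (non-``ns``)
    cohorts; both are absent when nothing is modulated.
    """
    sub = records[records["gene"] == gene]
    modulated = sub[sub["direction"].isin(["up", "down"])]
    extreme_up = extreme_down = None
    if not modulated.empty:
        top = modulated.loc[modulated["fc_signed"].idxmax()]
        bottom = modulated.loc[modulated["fc_signed"].idxmin()]
        extreme_up = (str(top["cohort"]), float(top["fc_signed"]))
        extreme_down = (str(bottom["cohort"]), float(bottom["fc_signed"]))
    return ModulationSummary(
        gene=gene,
        n_cohorts=int(sub["cohort"].nunique()),
        n_modulated=int(len(modulated)),
        n_up=int((modulated["direction"] == "up").sum()),
        n_down=int((modulated["direction"] == "down").sum()),
        extreme_up=extreme_up,
        extreme_down=extreme_down,
    )


def concomitant_modulation(records: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Cohorts where every listed gene is modulated, with the direction signature.

    Returns one row per qualifying cohort with a column per gene holding its
    ``up``/``down`` call.
    """
    for gene in genes:
        if gene not in set(records["gene"]):
            raise ValidationError(f"no records for gene {gene!r}")
    table = records.pivot_table(
        index="cohort", columns="gene", values="direction", aggfunc="first"
    )
    table = table.reindex(columns=genes)
    mask = table[genes].isin(["up", "down"]).all(axis=1)
    return table[mask].reset_index().rename_axis(None, axis=1)


def _clean(values, label: str) -> np.ndarray:
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"{label} arm needs >= 2 non-missing values, got {arr.size}"
        )
    return arr
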