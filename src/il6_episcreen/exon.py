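"""Exon-level isoform usage: relative exon fold change, per-sample
exon-ratio stratifiers, and percent-spliced-in (PSI).

The transmembrane-isoform contrast compares the isoform-specific exon
(exon 9 of IL6R) against a constitutive exon (exon 2) measured in the same
samples, so the fold change uses the same signed ``2**|d|`` encoding as the
tumor/normal contrast but the test is paired. The per-sample relative
expression ``log2(exon9) - log2(exon2)`` is the stratifier used for
survival follow-up, and PSI is the binomial inclusion proportion.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError


def exon_relative_fc(exon9_values, exon2_values) -> tuple[float, float]:
    """Signed FC between paired per-sample log2 exon values, with paired-t p.

    Pairs with a missing value in either exon are dropped; >= 2 complete
    pairs are required.
    """
    e9 = pd.Series(np.asarray(exon9_values, dtype=float))
    e2 = pd.Series(np.asarray(exon2_values, dtype=float))
    if len(e9) != len(e2):
        raise ValidationError(
            f"exon vectors must be paired per sample: {len(e9)} vs {len(e2)} values"
        )
    keep = e9.notna() & e2.notna()
    e9, e2 = e9[keep].to_numpy(), e2[keep].to_numpy()
    if e9.size < 2:
        raise InsufficientDataError(f"need >= 2 complete sample pairs, got {e9.size}")
    delta = float(np.mean(e9) - np.mean(e2))
    fc = 1.0 if delta == 0.0 else math.copysign(2.0 ** abs(delta), delta)
    diffs = e9 - e2
    if np.ptp(diffs) == 0:
        p = 1.0 if delta == 0.0 else 0.0  # all per-sample differences identical
    else:
        _, p = stats.ttest_rel(e9, e2)
    return fc, float(p)


def per_sample_relative_expression(exon9_value: float, exon2_value: float) -> float:
    """Exon-ratio stratifier for one sample: exon9 - exon2 (inputs are log2)."""
    if pd.isna(exon9_value) or pd.isna(exon2_value):
        raise ValidationError("sample excluded: missing exon value")
    return float(exon9_value) - float(exon2_value)


def relative_expression_vector(exon9_values: pd.Series, exon2_values: pd.Series) -> pd.Series:
    """Per-sample exon ratio over a cohort; samples missing either exon are dropped."""
    e9, e2 = exon9_values.align(exon2_values, join="inner")
    keep = e9.notna() & e2.notna()
    return (e9[keep] - e2[keep]).astype(float)


def psi(inclusion_count: int, total_count: int) -> float:
    """Percent-spliced-in: fraction of transcripts including the exon."""
    if total_count == 0:
        raise ValidationError("PSI undefined: total transcript count is zero")
    if inclusion_count < 0 or inclusion_count > total_count:
        raise ValidationError(
            f"inclusion count {inclusion_count} outside [0, {total_count}]"
        )
    return inclusion_count / total_count


def exon_usage_table(
    exon_expression,
    annotations,
    exon9_id: str,
    exon2_id: str,
    psi_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cohort exon-usage records for the isoform-specific/constitutive pair.

    ``psi_counts`` (optional) is a per-sample DataFrame with columns
    ``inclusion`` and ``total``; when given, the cohort mean PSI is added.
    Returns columns ``cohort, fc_exon, p_value, n, mean_psi``.
    """
    from .data import TissueClass  # local import to avoid cycle at module load

    e9 = exon_expression.row(exon9_id)
    e2 = exon_expression.row(exon2_id)
    cohorts: dict[str, list[str]] = {}
    sample_set = set(exon_expression.sample_ids)
    for ann in annotations:
        if ann.tissue_class is TissueClass.TUMOR and ann.sample_id in sample_set:
            cohorts.setdefault(ann.cohort.code, []).append(ann.sample_id)
    rows = []
    for cohort, samples in sorted(cohorts.items()):
        pair9, pair2 = e9[samples], e2[samples]
        keep = pair9.notna() & pair2.notna()
        if keep.sum() < 2:
            continue
        fc, p = exon_relative_fc(pair9[keep], pair2[keep])
        mean_psi = np.nan
        if psi_counts is not None:
            counts = psi_counts.loc[psi_counts.index.intersection(samples)]
            if len(counts):
                mean_psi = float(
                    np.mean([psi(int(i), int(t)) for i, t in
                             zip(counts["inclusion"], counts["total"])])
                )
        rows.append(
            {"cohort": cohort, "fc_exon": fc, "p_value": p,
             "n": int(keep.sum()), "mean_psi": mean_psi}
        )
    return pd.DataFrame(rows, columns=["cohort", "fc_exon", "p_value", "n", "mean_psi"])
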