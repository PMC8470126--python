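"""Per-cohort Pearson screens and their cross-cohort consensus.

A "screen" correlates every feature of an omics layer (CpG probe betas or
miRNA expression) with a per-sample target (gene or exon expression) within
each cohort separately, then counts in how many cohorts the correlation is
both strong (|r| >= 0.3) and significant (p <= 0.05). A feature is "always
negative" when it has at least one such negative cohort and no positive
one; neutral cohorts (weak or non-significant r) do not break the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import OmicsMatrix, ProbeAnnotation, SampleAnnotation, TissueClass
from .exceptions import DegenerateDataError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.3
ALPHA = 0.05
MIN_PAIRS = 3


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from the t transform on n-2 df.

    Pairs with a missing value are dropped; needs >= 3 complete pairs and
    non-degenerate variance in both vectors. |r| = 1 returns p = 0 (the
    limit of the t transform).
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValidationError(f"unpaired vectors: {len(x)} vs {len(y)}")
    keep = x.notna() & y.notna()
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    n = x.size
    if n < MIN_PAIRS:
        raise InsufficientDataError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def correlate_layer(
    feature_matrix: OmicsMatrix,
    target_values: pd.Series,
    annotations: list[SampleAnnotation],
    target_id: str = "target",
    tumor_only: bool = True,
) -> pd.DataFrame:
    """One Pearson record per feature x cohort.

    ``target_values`` is a per-sample vector (e.g. one gene's expression).
    Cohorts with fewer than three complete pairs for a feature, or with a
    degenerate vector, are skipped with a logged reason. Raises when no
    cohort yields any record at all.
    """
    cohorts: dict[str, list[str]] = {}
    usable = set(feature_matrix.sample_ids) & set(target_values.index)
    for ann in annotations:
        if tumor_only and ann.tissue_class is not TissueClass.TUMOR:
            continue
        if ann.sample_id in usable:
            cohorts.setdefault(ann.cohort.code, []).append(ann.sample_id)

    rows = []
    target = target_values.astype(float)
    for cohort, samples in sorted(cohorts.items()):
        y = target[samples]
        for feature_id in feature_matrix.feature_ids:
            x = feature_matrix.row(feature_id)[samples]
            try:
                r, p, n = pearson_with_p(x, y)
            except (InsufficientDataError, DegenerateDataError) as exc:
                logger.debug("skipping %s in %s: %s", feature_id, cohort, exc)
                continue
            rows.append(
                {"feature_id": feature_id, "target_id": target_id,
                 "cohort": cohort, "r": r, "p_value": p, "n": n}
            )
    if not rows:
        raise InsufficientDataError("no cohort had enough paired samples to correlate")
    return pd.DataFrame(rows, columns=["feature_id", "target_id", "cohort", "r", "p_value", "n"])


@dataclass(frozen=True)
class ConsensusSummary:
    feature_id: str
    target_id: str
    n_sig_neg: int
    n_sig_pos: int
    always_negative: bool
    always_positive: bool
    qualifying_cohorts: tuple[str, ...] = field(default=())


def consensus(
    records: pd.DataFrame, r_threshold: float = R_THRESHOLD, alpha: float = ALPHA
) -> list[ConsensusSummary]:
    """Cross-cohort consensus per (feature, target) pair.

    A cohort qualifies negatively when r <= -r_threshold and p <= alpha
    (positively: r >= +r_threshold). ``always_negative`` requires at least
    one negative cohort and zero positive ones.
    """
    summaries = []
    if records.empty:
        return summaries
    for (feature_id, target_id), group in records.groupby(
        ["feature_id", "target_id"], sort=True
    ):
        sig = group["p_value"] <= alpha
        neg = group[sig & (group["r"] <= -r_threshold)]
        pos = group[sig & (group["r"] >= r_threshold)]
        qualifying = tuple(sorted(set(neg["cohort"]) | set(pos["cohort"])))
        summaries.append(
            ConsensusSummary(
                feature_id=feature_id,
                target_id=target_id,
                n_sig_neg=len(neg),
                n_sig_pos=len(pos),
                always_negative=len(neg) >= 1 and len(pos) == 0,
                always_positive=len(pos) >= 1 and len(neg) == 0,
                qualifying_cohorts=qualifying,
            )
        )
    return summaries


def consensus_frame(summaries: list[ConsensusSummary]) -> pd.DataFrame:
    """Tabular view of consensus summaries (one row per feature x target)."""
    return pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "target_id": s.target_id,
                "n_sig_neg": s.n_sig_neg,
                "n_sig_pos": s.n_sig_pos,
                "always_negative": s.always_negative,
                "always_positive": s.always_positive,
                "qualifying_cohorts": ",".join(s.qualifying_cohorts),
            }
            for s in summaries
        ],
        columns=["feature_id", "target_id", "n_sig_neg", "n_sig_pos",
                 "always_negative", "always_positive", "qualifying_cohorts"],
    )


def select_probes_for_survival(
    summaries: list[ConsensusSummary], gene: str, min_neg_cohorts: int
) -> list[str]:
    """Probes negatively correlated with ``gene`` in more than ``min_neg_cohorts``
    cohorts, sorted by count (descending) then probe id."""
    hits = [
        s for s in summaries if s.target_id == gene and s.n_sig_neg > min_neg_cohorts
    ]
    hits.sort(key=lambda s: (-s.n_sig_neg, s.feature_id))
    return [s.feature_id for s in hits]


def region_methylation_means(
    methylation: OmicsMatrix,
    probe_annotations: list[ProbeAnnotation],
    sample_annotations: list[SampleAnnotation],
    gene: str | None = None,
) -> pd.DataFrame:
    """Mean beta per probe per cohort, in genomic-position order.

    Unannotated probes are excluded with a warning; a probe with no measured
    samples in a cohort yields a missing cell. The returned frame carries a
    ``region`` column plus one column per cohort.
    """
    ann_by_probe = {
        a.probe_id: a for a in probe_annotations if gene is None or a.gene == gene
    }
    unannotated = [p for p in methylation.feature_ids if p not in ann_by_probe]
    for probe in unannotated:
        logger.warning("probe %s has no annotation; excluded from region means", probe)
    probes = sorted(
        (p for p in methylation.feature_ids if p in ann_by_probe),
        key=lambda p: ann_by_probe[p].position,
    )
    cohorts: dict[str, list[str]] = {}
    usable = set(methylation.sample_ids)
    for ann in sample_annotations:
        if ann.tissue_class is TissueClass.TUMOR and ann.sample_id in usable:
            cohorts.setdefault(ann.cohort.code, []).append(ann.sample_id)
    out = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    out["region"] = [ann_by_probe[p].region.value for p in probes]
    out["position"] = [ann_by_probe[p].position for p in probes]
    for cohort, samples in sorted(cohorts.items()):
        out[cohort] = methylation.values.loc[probes, samples].mean(axis=1, skipna=True)
    return out
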