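"""miRNA screens: prediction-gated correlation candidates, exon-9-specific
target screening, and ligand-driven negative-feedback detection.

All screens combine two evidence streams: external target predictions
(mirDIP ordinal class tiers for whole genes; StarMir site probabilities for
the isoform-specific exon) and per-cohort Pearson correlations between
miRNA and target expression. A feedback candidate is a miRNA positively
correlated with the ligand (IL6) in enough cohorts while negatively
correlated with a predicted receptor target (IL6R/IL6ST) in enough
cohorts — the signature of a ligand-induced repressor of its own receptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .correlation import ALPHA, R_THRESHOLD, ConsensusSummary, consensus
from .data import MirdipClass, PredictionSource, TargetPrediction

logger = logging.getLogger(__name__)

MIN_COHORTS = 5
LOGIT_THRESHOLD = 0.5


def filter_predicted(
    predictions: list[TargetPrediction],
    gene: str,
    min_class: MirdipClass | str = MirdipClass.HIGH,
) -> set[str]:
    """miRNAs predicted to target ``gene`` at confidence >= ``min_class``."""
    if isinstance(min_class, str):
        min_class = MirdipClass.parse(min_class)
    mirdip = [p for p in predictions if p.source is PredictionSource.MIRDIP]
    hits = {
        p.mirna_id for p in mirdip if p.gene == gene and p.class_score >= min_class
    }
    if not any(p.gene == gene for p in mirdip):
        logger.warning("no mirDIP predictions for gene %s", gene)
    return hits


@dataclass(frozen=True)
class CandidateMiRNA:
    mirna_id: str
    target_id: str
    prediction_class: MirdipClass | None
    consensus: ConsensusSummary
    passes: bool

    @property
    def direction_profile(self) -> str:
        if self.consensus.always_negative:
            return "always_negative"
        if self.consensus.always_positive:
            return "always_positive"
        return "mixed"


def candidate_mirnas(
    correlations: pd.DataFrame,
    predictions: list[TargetPrediction],
    gene: str,
    min_class: MirdipClass | str = MirdipClass.HIGH,
    r_threshold: float = R_THRESHOLD,
    alpha: float = ALPHA,
    min_cohorts: int = MIN_COHORTS,
) -> list[CandidateMiRNA]:
    """Predicted miRNAs whose correlation with ``gene`` is strong and
    significant in at least ``min_cohorts`` cohorts (either sign).

    ``correlations`` are per-cohort records with the miRNA in
    ``feature_id`` and ``gene`` in ``target_id``.
    """
    if isinstance(min_class, str):
        min_class = MirdipClass.parse(min_class)
    predicted = filter_predicted(predictions, gene, min_class)
    class_by_mirna = {
        p.mirna_id: p.class_score
        for p in predictions
        if p.source is PredictionSource.MIRDIP and p.gene == gene
    }
    records = correlations[
        (correlations["target_id"] == gene)
        & (correlations["feature_id"].isin(predicted))
    ]
    out = []
    for summary in consensus(records, r_threshold=r_threshold, alpha=alpha):
        n_sig = summary.n_sig_neg + summary.n_sig_pos
        if n_sig >= min_cohorts:
            out.append(
                CandidateMiRNA(
                    mirna_id=summary.feature_id,
                    target_id=gene,
                    prediction_class=class_by_mirna.get(summary.feature_id),
                    consensus=summary,
                    passes=True,
                )
            )
    out.sort(key=lambda c: c.mirna_id)
    return out


def exon9_target_screen(
    predictions: list[TargetPrediction],
    exon_correlations: pd.DataFrame,
    exon_id: str,
    logit_threshold: float = LOGIT_THRESHOLD,
    r_threshold: float = R_THRESHOLD,
    alpha: float = ALPHA,
    min_cohorts: int = 1,
) -> list[CandidateMiRNA]:
    """miRNAs with a StarMir site (LogitProb >= threshold) on the
    isoform-specific exon and a strong significant correlation with the
    exon's expression in at least ``min_cohorts`` cohorts."""
    site_hits = {
        p.mirna_id
        for p in predictions
        if p.source is PredictionSource.STARMIR
        and p.gene == exon_id
        and p.logit_prob >= logit_threshold
    }
    records = exon_correlations[
        (exon_correlations["target_id"] == exon_id)
        & (exon_correlations["feature_id"].isin(site_hits))
    ]
    out = []
    for summary in consensus(records, r_threshold=r_threshold, alpha=alpha):
        if summary.n_sig_neg + summary.n_sig_pos >= min_cohorts:
            out.append(
                CandidateMiRNA(
                    mirna_id=summary.feature_id,
                    target_id=exon_id,
                    prediction_class=None,
                    consensus=summary,
                    passes=True,
                )
            )
    out.sort(key=lambda c: c.mirna_id)
    return out


@dataclass(frozen=True)
class FeedbackCandidate:
    mirna_id: str
    receptor_gene: str
    cohorts_pos_ligand: frozenset[str]
    cohorts_neg_receptor: frozenset[str]
    both_satisfied_cohorts: frozenset[str] = field(default=frozenset())

    @property
    def n_pos(self) -> int:
        return len(self.cohorts_pos_ligand)

    @property
    def n_neg(self) -> int:
        return len(self.cohorts_neg_receptor)


def detect_feedback(
    ligand_correlations: pd.DataFrame,
    receptor_correlations: pd.DataFrame,
    predictions: list[TargetPrediction],
    min_class: MirdipClass | str = MirdipClass.MEDIUM,
    r_threshold: float = R_THRESHOLD,
    alpha: float = ALPHA,
    min_cohorts: int = MIN_COHORTS,
) -> list[FeedbackCandidate]:
    """Ligand-driven negative-feedback miRNAs.

    Emits (miRNA, receptor) pairs where the miRNA is positively correlated
    with the ligand (r >= +threshold, p <= alpha) in >= ``min_cohorts``
    cohorts AND negatively correlated (r <= -threshold, p <= alpha) with a
    predicted receptor target in >= ``min_cohorts`` cohorts. The prediction
    gate (mirDIP class >= ``min_class``) applies to the receptor arm only.
    The two cohort sets are counted separately; their intersection is
    reported so the same-cohort reading can be audited.
    """
    if isinstance(min_class, str):
        min_class = MirdipClass.parse(min_class)

    lig_sig = ligand_correlations[
        (ligand_correlations["p_value"] <= alpha)
        & (ligand_correlations["r"] >= r_threshold)
    ]
    pos_cohorts = {
        mirna: frozenset(group["cohort"])
        for mirna, group in lig_sig.groupby("feature_id")
    }

    rec_sig = receptor_correlations[
        (receptor_correlations["p_value"] <= alpha)
        & (receptor_correlations["r"] <= -r_threshold)
    ]

    out = []
    receptors = sorted(set(receptor_correlations["target_id"]))
    for receptor in receptors:
        predicted = filter_predicted(predictions, receptor, min_class)
        sub = rec_sig[rec_sig["target_id"] == receptor]
        for mirna, group in sub.groupby("feature_id"):
            if mirna not in predicted:
                continue
            pos = pos_cohorts.get(mirna, frozenset())
            neg = frozenset(group["cohort"])
            if len(pos) >= min_cohorts and len(neg) >= min_cohorts:
                out.append(
                    FeedbackCandidate(
                        mirna_id=mirna,
                        receptor_gene=receptor,
                        cohorts_pos_ligand=pos,
                        cohorts_neg_receptor=neg,
                        both_satisfied_cohorts=pos & neg,
                    )
                )
    out.sort(key=lambda c: (c.mirna_id, c.receptor_gene))
    return out


def candidates_frame(candidates: list[CandidateMiRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "target_id": c.target_id,
                "prediction_class": (
                    c.prediction_class.name.lower() if c.prediction_class is not None else ""
                ),
                "n_sig_neg": c.consensus.n_sig_neg,
                "n_sig_pos": c.consensus.n_sig_pos,
                "direction_profile": c.direction_profile,
                "qualifying_cohorts": ",".join(c.consensus.qualifying_cohorts),
            }
            for c in candidates
        ],
        columns=["mirna_id", "target_id", "prediction_class", "n_sig_neg",
                 "n_sig_pos", "direction_profile", "qualifying_cohorts"],
    )


def feedback_frame(candidates: list[FeedbackCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "receptor_gene": c.receptor_gene,
                "n_pos": c.n_pos,
                "n_neg": c.n_neg,
                "cohorts_pos_ligand": ",".join(sorted(c.cohorts_pos_ligand)),
                "cohorts_neg_receptor": ",".join(sorted(c.cohorts_neg_receptor)),
                "both_satisfied_cohorts": ",".join(sorted(c.both_satisfied_cohorts)),
            }
            for c in candidates
        ],
        columns=["mirna_id", "receptor_gene", "n_pos", "n_neg",
                 "cohorts_pos_ligand", "cohorts_neg_receptor", "both_satisfied_cohorts"],
    )
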