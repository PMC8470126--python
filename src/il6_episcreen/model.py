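"""End-to-end screening model in the Model/Results idiom.

``PanCancerScreen`` is built from a :class:`~il6_episcreen.simulate.CohortBundle`
(simulated or loaded from TSVs) plus the external prediction tables and the
screen thresholds; its :meth:`~PanCancerScreen.fit` runs every stage —
differential expression, exon usage, survival screens, methylation and
miRNA correlation consensus, feedback detection — and returns a
``ScreenResults`` carrying the per-stage record tables, a ``summary()``
text report, and TSV export. Everything is deterministic given the bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diffexpr, exon, mirna as mirna_mod
from .correlation import (
    consensus,
    consensus_frame,
    correlate_layer,
    region_methylation_means,
    select_probes_for_survival,
)
from .data import Endpoint, MirdipClass, OmicsMatrix, TargetPrediction, TissueClass
from .exceptions import EpiScreenError, InsufficientDataError
from .simulate import CohortBundle
from .survival import SurvivalResult, survival_screen


@dataclass
class ScreenThresholds:
    """All gates of the screening pipeline, with the study's defaults."""

    fc_threshold: float = 1.4
    alpha: float = 0.05
    r_threshold: float = 0.3
    min_cohorts: int = 5
    min_class: MirdipClass = MirdipClass.HIGH
    feedback_min_class: MirdipClass = MirdipClass.MEDIUM
    logit_threshold: float = 0.5
    split: str = "median"

    def as_dict(self) -> dict:
        d = {
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "r_threshold": self.r_threshold,
            "min_cohorts": self.min_cohorts,
            "min_class": self.min_class.name.lower(),
            "feedback_min_class": self.feedback_min_class.name.lower(),
            "logit_threshold": self.logit_threshold,
            "split": self.split,
        }
        return d


class PanCancerScreen:
    """The full epigenetic-regulation screen over one multi-omic study.

    Parameters
    ----------
    bundle:
        The study data (all omic layers, annotations, survival).
    predictions:
        External miRNA target evidence (mirDIP and/or StarMir records).
    genes:
        Genes to screen; defaults to every gene in the expression matrix.
    ligand / receptors:
        Roles for the feedback screen (ligand induces the miRNA, receptors
        are its predicted targets).
    thresholds:
        The screen gates; defaults reproduce the study's criteria.
    """

    def __init__(
        self,
        bundle: CohortBundle,
        predictions: list[TargetPrediction] | None = None,
        genes: list[str] | None = None,
        ligand: str = "IL6",
        receptors: list[str] | None = None,
        thresholds: ScreenThresholds | None = None,
    ):
        self.bundle = bundle
        self.predictions = predictions or []
        self.genes = genes or list(bundle.expression.feature_ids)
        self.ligand = ligand
        self.receptors = receptors or [g for g in self.genes if g != ligand]
        self.thresholds = thresholds or ScreenThresholds()

    # -- stages ---------------------------------------------------------------
    def fit(self) -> "ScreenResults":
        """Run every stage and collect the results."""
        th = self.thresholds
        bundle = self.bundle

        fold_changes = self._stage("differential_expression", diffexpr.fold_change_table,
                                   bundle.expression, bundle.sample_annotations,
                                   self.genes, th.fc_threshold, th.alpha)

        exon_usage = pd.DataFrame()
        if bundle.exon_expression is not None:
            exon9_id, exon2_id = bundle.exon_expression.feature_ids[:2]
            exon_usage = self._stage(
                "exon_usage", exon.exon_usage_table, bundle.exon_expression,
                bundle.sample_annotations, exon9_id, exon2_id, bundle.exon_counts,
            )

        survival_results = self._stage("survival_analysis", self._survival_stage)

        meth_records, meth_consensus, selected_probes, region_means = self._stage(
            "methylation_screen", self._methylation_stage
        )
        mirna_records, candidates, feedback, exon9_candidates = self._stage(
            "mirna_screen", self._mirna_stage
        )

        return ScreenResults(
            model=self,
            fold_changes=fold_changes,
            exon_usage=exon_usage,
            survival_results=survival_results,
            methylation_records=meth_records,
            methylation_consensus=meth_consensus,
            selected_probes=selected_probes,
            region_means=region_means,
            mirna_records=mirna_records,
            mirna_candidates=candidates,
            exon9_candidates=exon9_candidates,
            feedback_candidates=feedback,
        )

    def _stage(self, name, fn, *args):
        try:
            return fn(*args)
        except EpiScreenError as exc:
            raise EpiScreenError(f"stage {name!r} failed: {exc}") from exc

    def _tumor_samples_by_cohort(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ann in self.bundle.sample_annotations:
            if ann.tissue_class is TissueClass.TUMOR:
                out.setdefault(ann.cohort.code, []).append(ann.sample_id)
        return out

    def _survival_stage(self) -> pd.DataFrame:
        bundle = self.bundle
        th = self.thresholds
        rows: list[SurvivalResult] = []
        if not bundle.survival:
            return pd.DataFrame()
        by_cohort = self._tumor_samples_by_cohort()

        stratifiers: list[tuple[str, pd.Series]] = [
            (gene, bundle.expression.row(gene)) for gene in self.genes
        ]
        if bundle.exon_expression is not None:
            exon9_id, exon2_id = bundle.exon_expression.feature_ids[:2]
            ratio = exon.relative_expression_vector(
                bundle.exon_expression.row(exon9_id),
                bundle.exon_expression.row(exon2_id),
            )
            stratifiers.append(("exon_ratio", ratio))

        for endpoint in (Endpoint.OS, Endpoint.PFI):
            records = [r for r in bundle.survival if r.endpoint is endpoint]
            if not records:
                continue
            for cohort, samples in sorted(by_cohort.items()):
                sample_set = set(samples)
                cohort_records = [r for r in records if r.sample_id in sample_set]
                for strat_id, values in stratifiers:
                    try:
                        rows.append(
                            survival_screen(
                                values[values.index.isin(sample_set)],
                                cohort_records,
                                endpoint,
                                alpha=th.alpha,
                                stratifier_id=strat_id,
                                cohort=cohort,
                                split=th.split,
                            )
                        )
                    except EpiScreenError:
                        continue
        return pd.DataFrame(
            [
                {
                    "stratifier_id": r.stratifier_id,
                    "cohort": r.cohort,
                    "endpoint": r.endpoint,
                    "chi_square": r.chi_square,
                    "p_value": r.p_value,
                    "direction": r.direction,
                    "n_high": r.n_high,
                    "n_low": r.n_low,
                    "significant": r.significant,
                }
                for r in rows
            ]
        )

    def _methylation_stage(self):
        bundle = self.bundle
        th = self.thresholds
        empty = pd.DataFrame(), [], {}, pd.DataFrame()
        if bundle.methylation is None or not bundle.methylation.feature_ids:
            return empty
        probe_genes = {a.probe_id: a.gene for a in bundle.probe_annotations}
        record_frames = []
        for gene in self.genes:
            probes = [p for p, g in probe_genes.items()
                      if g == gene and p in set(bundle.methylation.feature_ids)]
            if not probes:
                continue
            sub = bundle.methylation.values.loc[probes]
            sub_matrix = OmicsMatrix(sub, "beta")
            try:
                record_frames.append(
                    correlate_layer(sub_matrix, bundle.expression.row(gene),
                                    bundle.sample_annotations, target_id=gene)
                )
            except InsufficientDataError:
                continue
        if not record_frames:
            return empty
        records = pd.concat(record_frames, ignore_index=True)
        summaries = consensus(records, th.r_threshold, th.alpha)
        selected = {
            gene: select_probes_for_survival(summaries, gene, th.min_cohorts)
            for gene in self.genes
        }
        region_means = region_methylation_means(
            bundle.methylation, bundle.probe_annotations, bundle.sample_annotations
        )
        return records, summaries, selected, region_means

    def _mirna_stage(self):
        bundle = self.bundle
        th = self.thresholds
        empty = pd.DataFrame(), [], [], []
        if bundle.mirna is None or not bundle.mirna.feature_ids:
            return empty
        record_frames = []
        for gene in self.genes:
            try:
                record_frames.append(
                    correlate_layer(bundle.mirna, bundle.expression.row(gene),
                                    bundle.sample_annotations, target_id=gene)
                )
            except InsufficientDataError:
                continue
        if not record_frames:
            return empty
        records = pd.concat(record_frames, ignore_index=True)

        candidates = []
        for gene in self.genes:
            candidates.extend(
                mirna_mod.candidate_mirnas(
                    records, self.predictions, gene,
                    min_class=th.min_class, r_threshold=th.r_threshold,
                    alpha=th.alpha, min_cohorts=th.min_cohorts,
                )
            )

        exon9_candidates = []
        if bundle.exon_expression is not None:
            exon9_id = bundle.exon_expression.feature_ids[0]
            exon_records = correlate_layer(
                bundle.mirna, bundle.exon_expression.row(exon9_id),
                bundle.sample_annotations, target_id=exon9_id,
            )
            records = pd.concat([records, exon_records], ignore_index=True)
            exon9_candidates = mirna_mod.exon9_target_screen(
                self.predictions, exon_records, exon9_id,
                logit_threshold=th.logit_threshold,
                r_threshold=th.r_threshold, alpha=th.alpha,
            )

        feedback = []
        if self.ligand in self.genes:
            ligand_records = records[records["target_id"] == self.ligand]
            receptor_records = records[records["target_id"].isin(self.receptors)]
            feedback = mirna_mod.detect_feedback(
                ligand_records, receptor_records, self.predictions,
                min_class=th.feedback_min_class, r_threshold=th.r_threshold,
                alpha=th.alpha, min_cohorts=th.min_cohorts,
            )
        return records, candidates, feedback, exon9_candidates


@dataclass
class ScreenResults:
    """All stage outputs of one fitted :class:`PanCancerScreen`."""

    model: PanCancerScreen
    fold_changes: pd.DataFrame
    exon_usage: pd.DataFrame
    survival_results: pd.DataFrame
    methylation_records: pd.DataFrame
    methylation_consensus: list
    selected_probes: dict[str, list[str]]
    region_means: pd.DataFrame
    mirna_records: pd.DataFrame
    mirna_candidates: list
    exon9_candidates: list
    feedback_candidates: list

    # -- presentation ---------------------------------------------------------
    def modulation_summary(self, gene: str) -> diffexpr.ModulationSummary:
        return diffexpr.summarize_modulation(self.fold_changes, gene)

    def table1_style_report(self) -> pd.DataFrame:
        return table1_style_report(self.fold_changes, self.survival_results,
                                   fc_threshold=self.model.thresholds.fc_threshold,
                                   alpha=self.model.thresholds.alpha)

    def counts_panel(self, which: str = "methylation") -> pd.DataFrame:
        summaries = (self.methylation_consensus if which == "methylation"
                     else [c.consensus for c in self.mirna_candidates])
        return counts_panel(summaries)

    def summary(self) -> str:
        """Human-readable multi-section report (deterministic body)."""
        lines = []
        truth = self.model.bundle.truth
        meta = {
            "thresholds": self.model.thresholds.as_dict(),
            "seed": truth.seed if truth is not None else None,
            "config_sha1": _config_hash(truth) if truth is not None else "external",
            "n_samples": len(self.model.bundle.sample_annotations),
        }
        lines.append("== run metadata ==")
        lines.append(json.dumps(meta, sort_keys=True))
        lines.append("")
        lines.append("== modulation summaries ==")
        for gene in self.model.genes:
            s = self.modulation_summary(gene)
            lines.append(
                f"{gene}: modulated in {s.n_modulated}/{s.n_cohorts} cohorts "
                f"({s.n_up} up, {s.n_down} down); extremes: "
                f"up={s.extreme_up}, down={s.extreme_down}"
            )
        lines.append("")
        lines.append("== fold-change / survival table ==")
        lines.append(self.table1_style_report().to_string())
        lines.append("")
        lines.append("== methylation consensus counts ==")
        lines.append(self.counts_panel("methylation").to_string())
        lines.append("")
        lines.append("== selected probes for survival follow-up ==")
        lines.append(json.dumps(self.selected_probes, sort_keys=True))
        lines.append("")
        lines.append("== miRNA candidates ==")
        lines.append(mirna_mod.candidates_frame(self.mirna_candidates).to_string())
        lines.append("")
        lines.append("== feedback candidates ==")
        lines.append(mirna_mod.feedback_frame(self.feedback_candidates).to_string())
        return "\n".join(lines) + "\n"

    def to_tsvs(self, out_dir: str | Path) -> None:
        """Write every stage table plus the consolidated report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fold_changes.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
        self.exon_usage.to_csv(out / "exon_usage.tsv", sep="\t", index=False)
        self.survival_results.to_csv(out / "survival.tsv", sep="\t", index=False)
        self.methylation_records.to_csv(out / "methylation_correlations.tsv",
                                        sep="\t", index=False)
        consensus_frame(self.methylation_consensus).to_csv(
            out / "methylation_consensus.tsv", sep="\t", index=False)
        self.region_means.to_csv(out / "region_methylation_means.tsv", sep="\t")
        self.mirna_records.to_csv(out / "mirna_correlations.tsv", sep="\t", index=False)
        mirna_mod.candidates_frame(self.mirna_candidates).to_csv(
            out / "mirna_candidates.tsv", sep="\t", index=False)
        mirna_mod.candidates_frame(self.exon9_candidates).to_csv(
            out / "exon9_candidates.tsv", sep="\t", index=False)
        mirna_mod.feedback_frame(self.feedback_candidates).to_csv(
            out / "feedback_candidates.tsv", sep="\t", index=False)
        (out / "report.txt").write_text(self.summary())


def table1_style_report(
    fc_records: pd.DataFrame,
    survival_results: pd.DataFrame,
    fc_threshold: float = 1.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Format the per-cohort summary with the display gates applied.

    Fold-change cells are blank unless |FC| >= ``fc_threshold`` and
    p <= ``alpha``; survival cells show "chi2 (+)"/"chi2 (-)" only when
    significant. The blanking is presentation-only — the stored records are
    never altered.
    """
    if fc_records.empty:
        return pd.DataFrame()
    genes = sorted(fc_records["gene"].unique())
    cohorts = sorted(fc_records["cohort"].unique())
    out = pd.DataFrame(index=pd.Index(cohorts, name="cohort"))
    for gene in genes:
        sub = fc_records[fc_records["gene"] == gene].set_index("cohort")
        fc_cells = []
        for cohort in cohorts:
            if cohort in sub.index:
                row = sub.loc[cohort]
                shown = (abs(row["fc_signed"]) >= fc_threshold
                         and row["p_value"] <= alpha)
                fc_cells.append(f"{row['fc_signed']:.2f}" if shown else "")
            else:
                fc_cells.append("")
        out[f"{gene}_FC"] = fc_cells
        if survival_results is not None and not survival_results.empty:
            surv = survival_results[survival_results["stratifier_id"] == gene]
            for endpoint in ("OS", "PFI"):
                cells = []
                ep = surv[surv["endpoint"] == endpoint].set_index("cohort")
                for cohort in cohorts:
                    if cohort in ep.index and ep.loc[cohort, "p_value"] <= alpha:
                        mark = "+" if ep.loc[cohort, "direction"] == "favorable" else "-"
                        cells.append(f"{ep.loc[cohort, 'chi_square']:.2f} ({mark})")
                    else:
                        cells.append("")
                out[f"{gene}_{endpoint}"] = cells
    return out


def counts_panel(summaries: list) -> pd.DataFrame:
    """Per-feature counts of significant-negative / significant-positive cohorts."""
    return pd.DataFrame(
        [
            {"feature_id": s.feature_id, "target_id": s.target_id,
             "n_sig_neg": s.n_sig_neg, "n_sig_pos": s.n_sig_pos}
            for s in summaries
        ],
        columns=["feature_id", "target_id", "n_sig_neg", "n_sig_pos"],
    )


def run_pipeline(
    bundle: CohortBundle,
    predictions: list[TargetPrediction] | None = None,
    thresholds: ScreenThresholds | None = None,
    out_dir: str | Path | None = None,
    **kwargs,
) -> ScreenResults:
    """Convenience wrapper: build the screen, fit it, optionally export TSVs."""
    results = PanCancerScreen(
        bundle, predictions=predictions, thresholds=thresholds, **kwargs
    ).fit()
    if out_dir is not None:
        results.to_tsvs(out_dir)
    return results


def _config_hash(config) -> str:
    from dataclasses import asdict

    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
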