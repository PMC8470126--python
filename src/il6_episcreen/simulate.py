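"""Synthetic multi-cohort, multi-omic studies with planted effects.

The generator emulates the statistical structure every downstream screen
assumes, so the whole pipeline is testable without external data:

* per-cohort tumor/normal gene expression on the log2 scale with planted
  mean shifts (drives the signed fold change);
* CpG probe beta values produced through a logistic link on expression
  (``beta = invlogit(a + b*expr + noise)``), giving a monotone coupling
  whose sign is ``sign(b)`` (drives the methylation correlation screen);
* miRNAs that repress target genes (``expr -= gamma * mirna``) and,
  optionally, respond to a ligand gene (``mirna = baseline + delta*ligand
  + noise``) — together these plant the negative-feedback motif;
* exon inclusion as a binomial proportion out of a per-sample transcript
  total, so PSI is the planted inclusion probability by construction; an
  additive per-exon log2 coverage offset lets the isoform-specific exon sit
  above or below the constitutive one;
* exponential survival times whose hazard is multiplied by the hazard
  ratio for samples above the cohort median of a stratifier gene, censored
  by an independent uniform over the follow-up window.

All randomness flows through one ``numpy`` generator seeded from the
config, so identical configs produce byte-identical serialized bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohorts import COHORT_SAMPLE_SIZES, CohortLabel, DEFAULT_COHORTS
from .data import (
    Endpoint,
    OmicsMatrix,
    ProbeAnnotation,
    ProbeRegion,
    SampleAnnotation,
    SurvivalRecord,
    TissueClass,
    write_matrix,
    write_probe_annotations,
    write_sample_annotations,
    write_survival,
)
from .exceptions import ValidationError


@dataclass
class CohortSpec:
    code: str
    n_tumor: int
    n_normal: int

    def validate(self) -> None:
        if self.n_tumor < 0 or self.n_normal < 0:
            raise ValidationError(f"cohort {self.code}: negative sample count")


@dataclass
class GeneSpec:
    """Log2 expression model: N(baseline + shift[cohort]*1[tumor], sd)."""

    name: str
    baseline: float = 8.0
    sd: float = 1.0
    shifts: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.sd <= 0:
            raise ValidationError(f"gene {self.name}: sd must be > 0")


@dataclass
class ProbeSpec:
    """Beta = invlogit(intercept + slope*expr + N(0, noise_sd)); tumor only."""

    probe_id: str
    gene: str
    region: str = "TSS1500"
    position: int = 1
    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.5

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError(f"probe {self.probe_id}: noise_sd must be > 0")
        ProbeRegion(self.region)  # raises on unknown label


@dataclass
class MirnaSpec:
    """miRNA = baseline + ligand_slope*ligand_expr + N(0, sd); each target
    gene's expression then receives ``- gamma * mirna``."""

    mirna_id: str
    baseline: float = 5.0
    sd: float = 1.0
    repression: dict[str, float] = field(default_factory=dict)  # gene -> gamma
    ligand: str | None = None
    ligand_slope: float = 0.0

    def validate(self) -> None:
        if self.sd <= 0:
            raise ValidationError(f"miRNA {self.mirna_id}: sd must be > 0")


@dataclass
class ExonSpec:
    """Binomial inclusion: K ~ Bin(T, psi[cohort]); the isoform-specific
    exon reads log2(1+K) + offset, the constitutive exon log2(1+T)."""

    gene: str = "IL6R"
    exon9_id: str = "IL6R_Exon9"
    exon2_id: str = "IL6R_Exon2"
    psi: float | dict[str, float] = 0.95
    transcript_scale: int = 500
    exon9_log2_offset: float = 0.7
    noise_sd: float = 0.0
    repression: dict[str, float] = field(default_factory=dict)  # mirna_id -> slope

    def psi_for(self, cohort: str) -> float:
        return self.psi if isinstance(self.psi, (int, float)) else self.psi[cohort]

    def validate(self, cohort_codes: list[str]) -> None:
        if self.transcript_scale <= 0:
            raise ValidationError("exon transcript_scale must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("exon noise_sd must be >= 0")
        for code in cohort_codes:
            pi = self.psi_for(code)
            if not (0.0 <= pi <= 1.0):
                raise ValidationError(f"exon psi for {code} outside [0, 1]: {pi}")


@dataclass
class SurvivalSpec:
    """Exponential event times; hazard = baseline_hazard * HR**1[expr > cohort
    median of the stratifier]; censoring ~ Uniform(0, max_followup)."""

    stratifier_gene: str = "IL6"
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    hazard_ratio: float = 2.0
    max_followup: float = 3000.0  # days

    def validate(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0 or self.max_followup <= 0:
            raise ValidationError("survival hazard parameters must be > 0")


@dataclass
class SimulationConfig:
    seed: int
    cohorts: list[CohortSpec]
    genes: list[GeneSpec]
    probes: list[ProbeSpec] = field(default_factory=list)
    mirnas: list[MirnaSpec] = field(default_factory=list)
    exon: ExonSpec | None = None
    survival: SurvivalSpec | None = None

    def validate(self) -> None:
        codes = [c.code for c in self.cohorts]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate cohort codes in config")
        for c in self.cohorts:
            c.validate()
        gene_names = [g.name for g in self.genes]
        if len(set(gene_names)) != len(gene_names):
            raise ValidationError("duplicate gene names in config")
        for g in self.genes:
            g.validate()
        for p in self.probes:
            p.validate()
            if p.gene not in gene_names:
                raise ValidationError(f"probe {p.probe_id}: unknown target gene {p.gene}")
        for m in self.mirnas:
            m.validate()
            for target in m.repression:
                if target not in gene_names:
                    raise ValidationError(
                        f"miRNA {m.mirna_id}: unknown repression target {target}"
                    )
            if m.ligand is not None and m.ligand not in gene_names:
                raise ValidationError(f"miRNA {m.mirna_id}: unknown ligand {m.ligand}")
        if self.exon is not None:
            self.exon.validate(codes)
            mirna_ids = {m.mirna_id for m in self.mirnas}
            for mid in self.exon.repression:
                if mid not in mirna_ids:
                    raise ValidationError(f"exon repression references unknown miRNA {mid}")
        if self.survival is not None:
            self.survival.validate()
            if self.survival.stratifier_gene not in gene_names:
                raise ValidationError(
                    f"survival stratifier {self.survival.stratifier_gene} not in genes"
                )

    # -- structured-text config ------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        cfg = cls(
            seed=int(raw["seed"]),
            cohorts=[CohortSpec(**c) for c in raw.get("cohorts", [])],
            genes=[GeneSpec(**g) for g in raw.get("genes", [])],
            probes=[ProbeSpec(**p) for p in raw.get("probes", [])],
            mirnas=[MirnaSpec(**m) for m in raw.get("mirnas", [])],
            exon=ExonSpec(**raw["exon"]) if raw.get("exon") else None,
            survival=SurvivalSpec(**raw["survival"]) if raw.get("survival") else None,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class CohortBundle:
    """All omic layers, annotations and survival for one simulated study.

    Tumor-only layers (methylation, miRNA, survival) cover only tumor
    samples; expression and exon expression cover the full sample universe.
    ``truth`` keeps the generating config for recovery tests.
    """

    expression: OmicsMatrix
    exon_expression: OmicsMatrix | None
    methylation: OmicsMatrix | None
    mirna: OmicsMatrix | None
    sample_annotations: list[SampleAnnotation]
    probe_annotations: list[ProbeAnnotation]
    survival: list[SurvivalRecord]
    exon_counts: pd.DataFrame | None
    truth: SimulationConfig | None = None

    def tumor_samples(self, cohort: str | None = None) -> list[str]:
        return [
            a.sample_id
            for a in self.sample_annotations
            if a.tissue_class is TissueClass.TUMOR
            and (cohort is None or a.cohort.code == cohort)
        ]

    def write(self, out_dir: str | Path) -> None:
        """Serialize every layer to the package's TSV formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.expression, out / "expression.tsv")
        if self.exon_expression is not None:
            write_matrix(self.exon_expression, out / "exon_expression.tsv")
        if self.methylation is not None:
            write_matrix(self.methylation, out / "methylation.tsv")
        if self.mirna is not None:
            write_matrix(self.mirna, out / "mirna.tsv")
        write_sample_annotations(self.sample_annotations, out / "samples.tsv")
        write_probe_annotations(self.probe_annotations, out / "probes.tsv")
        write_survival(self.survival, out / "survival.tsv")
        if self.exon_counts is not None:
            self.exon_counts.to_csv(out / "exon_counts.tsv", sep="\t",
                                    index_label="sample_id")


def load_bundle(in_dir: str | Path) -> "CohortBundle":
    """Load a bundle previously serialized with :meth:`CohortBundle.write`.

    Layers whose files are absent come back as ``None``; ``truth`` is not
    reconstructed for externally produced directories.
    """
    from .data import (
        read_matrix,
        read_probe_annotations,
        read_sample_annotations,
        read_survival,
    )

    src = Path(in_dir)

    def maybe(path: Path, layer: str) -> OmicsMatrix | None:
        return read_matrix(path, layer) if path.exists() else None

    exon_counts = None
    if (src / "exon_counts.tsv").exists():
        exon_counts = pd.read_csv(src / "exon_counts.tsv", sep="\t",
                                  index_col="sample_id")
    return CohortBundle(
        expression=read_matrix(src / "expression.tsv", "expression"),
        exon_expression=maybe(src / "exon_expression.tsv", "expression"),
        methylation=maybe(src / "methylation.tsv", "beta"),
        mirna=maybe(src / "mirna.tsv", "expression"),
        sample_annotations=read_sample_annotations(src / "samples.tsv"),
        probe_annotations=(
            read_probe_annotations(src / "probes.tsv")
            if (src / "probes.tsv").exists() else []
        ),
        survival=(
            read_survival(src / "survival.tsv")
            if (src / "survival.tsv").exists() else []
        ),
        exon_counts=exon_counts,
    )


def generate_cohort_bundle(config: SimulationConfig) -> CohortBundle:
    """Draw one study from the generative model described in the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_names = [g.name for g in config.genes]
    sample_ann: list[SampleAnnotation] = []
    expr_cols: dict[str, np.ndarray] = {}
    exon_cols: dict[str, np.ndarray] = {}
    meth_cols: dict[str, np.ndarray] = {}
    mirna_cols: dict[str, np.ndarray] = {}
    exon_count_rows: list[tuple[str, int, int]] = []
    survival: list[SurvivalRecord] = []

    for cohort in config.cohorts:
        label = DEFAULT_COHORTS.get(cohort.code, CohortLabel(cohort.code))
        tumor_ids = [f"{cohort.code}-T{i:04d}" for i in range(cohort.n_tumor)]
        normal_ids = [f"{cohort.code}-N{i:04d}" for i in range(cohort.n_normal)]
        for sid in tumor_ids:
            sample_ann.append(SampleAnnotation(sid, label, TissueClass.TUMOR))
        for sid in normal_ids:
            sample_ann.append(SampleAnnotation(sid, label, TissueClass.NORMAL))
        n_t, n_n = len(tumor_ids), len(normal_ids)

        # 1. baseline gene expression (log2 scale), with tumor shifts
        tumor_expr = np.empty((len(gene_names), n_t))
        normal_expr = np.empty((len(gene_names), n_n))
        for gi, gene in enumerate(config.genes):
            shift = gene.shifts.get(cohort.code, 0.0)
            tumor_expr[gi] = rng.normal(gene.baseline + shift, gene.sd, size=n_t)
            normal_expr[gi] = rng.normal(gene.baseline, gene.sd, size=n_n)

        # 2. miRNAs (tumor only), optionally driven by the pre-repression
        #    ligand level; then apply repression to target genes
        mirna_expr = np.empty((len(config.mirnas), n_t))
        for mi, mir in enumerate(config.mirnas):
            level = np.full(n_t, mir.baseline, dtype=float)
            if mir.ligand is not None:
                level = level + mir.ligand_slope * tumor_expr[gene_names.index(mir.ligand)]
            level = level + rng.normal(0.0, mir.sd, size=n_t)
            mirna_expr[mi] = level
        for mi, mir in enumerate(config.mirnas):
            for target, gamma in mir.repression.items():
                tumor_expr[gene_names.index(target)] -= gamma * mirna_expr[mi]

        # 3. methylation betas through the logistic link (tumor only)
        meth_expr = np.empty((len(config.probes), n_t))
        for pi, probe in enumerate(config.probes):
            expr = tumor_expr[gene_names.index(probe.gene)]
            logit = probe.intercept + probe.slope * expr
            logit = logit + rng.normal(0.0, probe.noise_sd, size=n_t)
            meth_expr[pi] = np.clip(expit(logit), 0.0, 1.0)

        # 4. exon layer: binomial inclusion counts out of the transcript scale
        if config.exon is not None:
            pi_c = config.exon.psi_for(cohort.code)
            t_scale = config.exon.transcript_scale
            all_ids = tumor_ids + normal_ids
            incl = rng.binomial(t_scale, pi_c, size=len(all_ids))
            e9 = np.log2(1.0 + incl) + config.exon.exon9_log2_offset
            e2 = np.full(len(all_ids), np.log2(1.0 + t_scale))
            # miRNA repression of the isoform-specific exon (tumor arm only;
            # the miRNA layer does not exist for normals)
            mirna_index = {m.mirna_id: mi for mi, m in enumerate(config.mirnas)}
            for mid, slope in config.exon.repression.items():
                e9[:n_t] -= slope * mirna_expr[mirna_index[mid]]
            if config.exon.noise_sd > 0:
                e9 = e9 + rng.normal(0.0, config.exon.noise_sd, size=len(all_ids))
                e2 = e2 + rng.normal(0.0, config.exon.noise_sd, size=len(all_ids))
            for si, sid in enumerate(all_ids):
                exon_cols[sid] = np.array([e9[si], e2[si]])
                exon_count_rows.append((sid, int(incl[si]), t_scale))

        # 5. survival endpoints (tumor only): exponential times, uniform censoring
        if config.survival is not None and n_t > 0:
            spec = config.survival
            strat = tumor_expr[gene_names.index(spec.stratifier_gene)]
            high = strat > np.median(strat)
            hazard = spec.baseline_hazard * np.where(high, spec.hazard_ratio, 1.0)
            for endpoint in (Endpoint.OS, Endpoint.PFI):
                event_t = rng.exponential(1.0 / hazard)
                censor_t = rng.uniform(0.0, spec.max_followup, size=n_t)
                time = np.minimum(event_t, censor_t)
                event = (event_t <= censor_t).astype(int)
                for si, sid in enumerate(tumor_ids):
                    survival.append(
                        SurvivalRecord(sid, endpoint, float(max(time[si], 1e-6)), int(event[si]))
                    )

        for si, sid in enumerate(tumor_ids):
            expr_cols[sid] = tumor_expr[:, si]
            if config.mirnas:
                mirna_cols[sid] = mirna_expr[:, si]
            if config.probes:
                meth_cols[sid] = meth_expr[:, si]
        for si, sid in enumerate(normal_ids):
            expr_cols[sid] = normal_expr[:, si]

    all_tumor_ids = [
        a.sample_id for a in sample_ann if a.tissue_class is TissueClass.TUMOR
    ]

    def matrix(cols: dict[str, np.ndarray], index: list[str],
               fallback_samples: list[str], layer: str) -> OmicsMatrix:
        if cols:
            return OmicsMatrix(pd.DataFrame(cols, index=index, dtype=float), layer)
        # zero features requested: an empty but well-formed matrix
        return OmicsMatrix(
            pd.DataFrame(index=pd.Index(index), columns=fallback_samples, dtype=float),
            layer,
        )

    expression = OmicsMatrix(
        pd.DataFrame(expr_cols, index=gene_names, dtype=float), "expression"
    )
    exon_matrix = None
    exon_counts = None
    if config.exon is not None:
        exon_matrix = matrix(exon_cols, [config.exon.exon9_id, config.exon.exon2_id],
                             [a.sample_id for a in sample_ann], "expression")
        exon_counts = pd.DataFrame(
            exon_count_rows, columns=["sample_id", "inclusion", "total"]
        ).set_index("sample_id")
    methylation = matrix(meth_cols, [p.probe_id for p in config.probes],
                         all_tumor_ids, "beta")
    mirna_matrix = matrix(mirna_cols, [m.mirna_id for m in config.mirnas],
                          all_tumor_ids, "expression")
    probe_ann = [
        ProbeAnnotation(p.probe_id, p.gene, ProbeRegion(p.region), p.position)
        for p in config.probes
    ]
    return CohortBundle(
        expression=expression,
        exon_expression=exon_matrix,
        methylation=methylation,
        mirna=mirna_matrix,
        sample_annotations=sample_ann,
        probe_annotations=probe_ann,
        survival=survival,
        exon_counts=exon_counts,
        truth=config,
    )


def generate_null_study(
    n_cohorts: int, n_features: int, n_samples: int, seed: int
) -> CohortBundle:
    """A study with every coupling zero: the type-I-error harness.

    One target gene, ``n_features`` uncoupled probes and ``n_features``
    uncoupled miRNAs per cohort, a unit hazard ratio, and no planted shift
    anywhere.
    """
    config = null_config(n_cohorts, n_features, n_samples, seed)
    return generate_cohort_bundle(config)


def null_config(
    n_cohorts: int, n_features: int, n_samples: int, seed: int
) -> SimulationConfig:
    cohorts = [
        CohortSpec(code=f"C{i + 1:02d}", n_tumor=n_samples, n_normal=n_samples)
        for i in range(n_cohorts)
    ]
    probes = [
        ProbeSpec(probe_id=f"cg{i + 1:08d}", gene="TARGET", position=i + 1,
                  slope=0.0, intercept=0.0, noise_sd=0.5)
        for i in range(n_features)
    ]
    mirnas = [
        MirnaSpec(mirna_id=f"miR-N{i + 1:04d}") for i in range(n_features)
    ]
    return SimulationConfig(
        seed=seed,
        cohorts=cohorts,
        genes=[GeneSpec(name="TARGET")],
        probes=probes,
        mirnas=mirnas,
        exon=None,
        survival=SurvivalSpec(stratifier_gene="TARGET", hazard_ratio=1.0),
    )


# ---------------------------------------------------------------------------
# The full pan-cancer study conditions
# ---------------------------------------------------------------------------

#: Ligand-driven feedback miRNAs and their receptor targets.
FEEDBACK_MIRNAS: dict[str, str] = {
    "miR-181a-3p": "IL6R",
    "miR-214-3p": "IL6R",
    "miR-18a-5p": "IL6ST",
    "miR-938": "IL6ST",
}

# Logistic-link coupling giving a population probe-expression correlation of
# about -0.6 when the target gene has unit log2 SD (|slope|/sqrt(slope^2 +
# noise_sd^2) = 0.6); the link is near-linear around beta = 0.5.
_PROBE_SLOPE = 0.3
_PROBE_NOISE = 0.4

# Ligand coupling delta and repression gamma sized so both arms of the
# feedback motif have population |r| of about 0.5.
_DELTA = 0.5
_MIRNA_NOISE = 0.866
_GAMMA = 0.577


def study_config(seed: int) -> "SimulationConfig":
    """The default full-study conditions: 33 cohorts at the printed tumor and
    normal sample sizes, with per-cohort expression shifts planted from the
    printed signed fold changes (log2 of the shown |FC|, signed; zero where
    the table shows no value).

    The methylation layer plants the named survival-probe couplings (two
    promoter probes negatively coupled to IL6, three gene-body probes
    negatively coupled to IL6R) beside neutral probes; the miRNA layer
    plants the four ligand-driven receptor repressors plus one repressor of
    IL6ST shared across genes and ten uncoupled decoys.
    """
    from .fixtures import load_table1_fixture

    t1 = load_table1_fixture()
    shifts: dict[str, dict[str, float]] = {g: {} for g in ("IL6", "IL6R", "IL6ST")}
    for _, row in t1.iterrows():
        if pd.notna(row["fc"]):
            fc = float(row["fc"])
            shifts[row["gene"]][row["cohort"]] = float(
                np.sign(fc) * np.log2(abs(fc))
            )

    genes = [
        GeneSpec("IL6", baseline=6.0, sd=1.0, shifts=shifts["IL6"]),
        GeneSpec("IL6R", baseline=9.0, sd=1.0, shifts=shifts["IL6R"]),
        GeneSpec("IL6ST", baseline=10.0, sd=1.0, shifts=shifts["IL6ST"]),
    ]

    probes = [
        # IL6 promoter probes: negatively coupled; the first TSS1500 probe is
        # the hypermethylated positively-coupled one
        ProbeSpec("cg17067544", "IL6", "TSS1500", 22766000, slope=_PROBE_SLOPE,
                  intercept=1.5 - _PROBE_SLOPE * 6.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg13104385", "IL6", "TSS1500", 22766400, slope=-_PROBE_SLOPE,
                  intercept=-1.0 + _PROBE_SLOPE * 6.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg05265849", "IL6", "TSS200", 22766700, slope=-_PROBE_SLOPE,
                  intercept=-1.0 + _PROBE_SLOPE * 6.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg01770232", "IL6", "Body", 22768000, noise_sd=_PROBE_NOISE,
                  intercept=0.5),
        # IL6R gene-body probes: the three survival probes are moderately
        # hypermethylated and negatively coupled
        ProbeSpec("cg26538164", "IL6R", "TSS1500", 154376500, noise_sd=_PROBE_NOISE,
                  intercept=2.0),
        ProbeSpec("cg09257526", "IL6R", "Body", 154402800, slope=-_PROBE_SLOPE,
                  intercept=0.5 + _PROBE_SLOPE * 9.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg04437762", "IL6R", "Body", 154403200, slope=-_PROBE_SLOPE,
                  intercept=0.5 + _PROBE_SLOPE * 9.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg05756780", "IL6R", "Body", 154403600, slope=-_PROBE_SLOPE,
                  intercept=0.5 + _PROBE_SLOPE * 9.0, noise_sd=_PROBE_NOISE),
        ProbeSpec("cg15633035", "IL6R", "3UTR", 154441000, noise_sd=_PROBE_NOISE,
                  intercept=1.0),
        # IL6ST probes: uncoupled (the inconclusive layer)
        ProbeSpec("cg00000101", "IL6ST", "TSS200", 55230000, noise_sd=_PROBE_NOISE,
                  intercept=-2.0),
        ProbeSpec("cg00000102", "IL6ST", "Body", 55260000, noise_sd=_PROBE_NOISE,
                  intercept=1.0),
        ProbeSpec("cg00000103", "IL6ST", "3UTR", 55290000, noise_sd=_PROBE_NOISE,
                  intercept=1.0),
    ]

    mirnas = [
        # shared repressor of the receptor complex (no ligand drive)
        MirnaSpec("miR-182-5p", baseline=0.0, sd=1.0,
                  repression={"IL6ST": _GAMMA}),
    ]
    for mirna_id, receptor in FEEDBACK_MIRNAS.items():
        mirnas.append(
            MirnaSpec(
                mirna_id,
                # center the miRNA near zero so repression does not move the
                # receptor's tumor mean except through the ligand shift itself
                baseline=-_DELTA * 6.0,
                sd=_MIRNA_NOISE,
                repression={receptor: _GAMMA},
                ligand="IL6",
                ligand_slope=_DELTA,
            )
        )
    mirnas.extend(
        MirnaSpec(f"miR-D{i:03d}", baseline=0.0, sd=1.0) for i in range(1, 11)
    )

    cohorts = [
        CohortSpec(code, *COHORT_SAMPLE_SIZES[code]) for code in DEFAULT_COHORTS
    ]
    return SimulationConfig(
        seed=seed,
        cohorts=cohorts,
        genes=genes,
        probes=probes,
        mirnas=mirnas,
        exon=ExonSpec(),
        survival=SurvivalSpec(stratifier_gene="IL6"),
    )


def study_predictions() -> list:
    """External-evidence tables matching the planted miRNAs of
    :func:`study_config`: mirDIP tiers for gene targets and StarMir site
    probabilities for the isoform-specific exon."""
    from .data import MirdipClass, PredictionSource, SiteRegion, TargetPrediction

    preds = [
        TargetPrediction("miR-182-5p", "IL6", PredictionSource.MIRDIP,
                         class_score=MirdipClass.HIGH),
        TargetPrediction("miR-182-5p", "IL6R", PredictionSource.MIRDIP,
                         class_score=MirdipClass.HIGH),
        TargetPrediction("miR-182-5p", "IL6ST", PredictionSource.MIRDIP,
                         class_score=MirdipClass.VERY_HIGH),
    ]
    for mirna_id, receptor in FEEDBACK_MIRNAS.items():
        preds.append(
            TargetPrediction(mirna_id, receptor, PredictionSource.MIRDIP,
                             class_score=MirdipClass.MEDIUM)
        )
    for i in range(1, 11):
        preds.append(
            TargetPrediction(f"miR-D{i:03d}", "IL6ST", PredictionSource.MIRDIP,
                             class_score=MirdipClass.LOW if i % 2 else MirdipClass.MEDIUM)
        )
    preds.append(
        TargetPrediction("miR-182-5p", "IL6R_Exon9", PredictionSource.STARMIR,
                         logit_prob=0.73, site_region=SiteRegion.CDS_SEED)
    )
    return preds
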