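import numpy as np
import pytest

from il6_episcreen.data import MirdipClass, PredictionSource, TargetPrediction
from il6_episcreen.simulate import (
    CohortSpec,
    ExonSpec,
    GeneSpec,
    MirnaSpec,
    ProbeSpec,
    SimulationConfig,
    SurvivalSpec,
    generate_cohort_bundle,
)


def small_config(seed: int = 7, n_cohorts: int = 6, n_tumor: int = 60,
                 n_normal: int = 40) -> SimulationConfig:
    """A compact study with every layer planted: an upshifted ligand in the
    first cohort, one negatively coupled probe, one feedback miRNA, the
    binomial exon layer, and a hazardous stratifier."""
    return SimulationConfig(
        seed=seed,
        cohorts=[CohortSpec(f"C{i:02d}", n_tumor, n_normal) for i in range(1, n_cohorts + 1)],
        genes=[
            GeneSpec("IL6", 6.0, 1.0, {"C01": 2.0}),
            GeneSpec("IL6R", 9.0, 1.0),
            GeneSpec("IL6ST", 10.0, 1.0),
        ],
        probes=[
            ProbeSpec("cg00000001", "IL6R", "Body", 154402800,
                      slope=-0.3, intercept=2.7, noise_sd=0.4),
            ProbeSpec("cg00000002", "IL6", "TSS200", 22766700, noise_sd=0.5),
        ],
        mirnas=[
            MirnaSpec("miR-FB", baseline=-3.0, sd=0.866,
                      repression={"IL6R": 0.577}, ligand="IL6", ligand_slope=0.5),
            MirnaSpec("miR-NULL", baseline=0.0, sd=1.0),
        ],
        exon=ExonSpec(psi=0.95, transcript_scale=500, exon9_log2_offset=0.7),
        survival=SurvivalSpec("IL6", hazard_ratio=3.0),
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort_bundle(small_config())


@pytest.fixture(scope="session")
def small_predictions():
    return [
        TargetPrediction("miR-FB", "IL6R", PredictionSource.MIRDIP,
                         class_score=MirdipClass.HIGH),
        TargetPrediction("miR-NULL", "IL6R", PredictionSource.MIRDIP,
                         class_score=MirdipClass.HIGH),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
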