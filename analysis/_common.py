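"""Shared study configuration for the numbered analysis scripts.

All scripts drive one pipeline instance over the same output directory
(results/study), so each stage picks up its predecessors' outputs and
the whole sequence is reproducible from the single master seed below.
"""

from pathlib import Path

from habitatrf.config import ModelSettings, PipelineConfig, PseudoAbsenceSettings
from habitatrf.pipeline import Pipeline
from habitatrf.synthetic import LandscapeConfig

MASTER_SEED = 20240901
RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"


def study_config() -> PipelineConfig:
    """Study conditions: 26 layers, selective truth, 56 + 440 points.

    The truth is driven by annual-mean-temperature, annual-precipitation
    and non-tree-vegetation analogues with a low intercept, so most of
    the territory is environmentally dissimilar to the occurrences (the
    arid-landscape situation the workflow is built for).
    """
    landscape = LandscapeConfig(
        seed=MASTER_SEED,
        resolutions={"climate": 0.01, "vegetation": 0.0025, "terrain": 0.00125},
        suitability_coefficients={
            "bio01": 2.0,
            "bio12": 2.0,
            "percent_nontree_vegetation": 1.0,
        },
        intercept=-3.0,
        n_presence=56,
    )
    return PipelineConfig(
        mode="synthetic",
        seed=MASTER_SEED,
        output_dir=str(STUDY_DIR),
        landscape=landscape,
        pseudo_absence=PseudoAbsenceSettings(n=440, policy="distance_threshold"),
        model=ModelSettings(tune=True, folds=5, repeats=10),
    )


def build_pipeline() -> Pipeline:
    return Pipeline(study_config())
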