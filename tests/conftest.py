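import numpy as np
import pytest

from coiegm.pipeline import PipelineConfig, process_record
from coiegm.synthetic import GeneratorConfig, generate_lesion_recording


@pytest.fixture(scope="session")
def clean_pfa_record():
    """Noise-free PFA transmural lesion, 30 s pre + 120 s post."""
    cfg = GeneratorConfig(duration_post_s=120.0, noise_sd_mV=0.0)
    return generate_lesion_recording(cfg, ("PFA", "T+"), seed=7)


@pytest.fixture(scope="session")
def noisy_pfa_record():
    """PFA transmural lesion with default measurement noise."""
    cfg = GeneratorConfig(duration_post_s=120.0)
    return generate_lesion_recording(cfg, ("PFA", "T+"), seed=7)


@pytest.fixture(scope="session")
def default_pipeline_config():
    return PipelineConfig()


def run_record(record, truth, config=None):
    """Convenience: one record through detection/segmentation/features."""
    cfg = config if config is not None else PipelineConfig()
    return process_record(record, cfg, truth)


@pytest.fixture(scope="session")
def pfa_cohort_result():
    """Default-dynamics PFA cohort (15 T+ / 6 T-) through the full
    pipeline; shared by the statistics and classifier checks."""
    from coiegm.pipeline import run_pipeline

    cfg = PipelineConfig(
        seed=20260929,
        cohort={
            "n_pfa": 21,
            "n_rfa": 0,
            "rfa_transmural": 0,
            "pfa_transmural": 15,
            "duration_post_s": 90.0,
        },
    )
    return run_pipeline(cfg)
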