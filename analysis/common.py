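"""Shared setup for the analysis drivers: the default synthetic cohort."""

from pathlib import Path

from respreset.pipeline import AnalysisConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def cohort_bundle(seed: int = 0, **overrides):
    """Run the default 13-subject synthetic cohort analysis."""
    cfg = AnalysisConfig(seed=seed, **overrides)
    return cfg, run_pipeline(cfg)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH
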