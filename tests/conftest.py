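import numpy as np
import pytest

from foliarchem.pipeline import PipelineConfig, run_pipeline
from foliarchem.synthetic import EffectConfig, StudyDesign, default_effect_config


def small_effect_config(**overrides) -> EffectConfig:
    """Reduced library (571 compounds) that still supports the 102-sample
    design; keeps pipeline tests fast."""
    base = dict(n_classes=40, compounds_per_class=10, singleton_fraction=0.3,
                compounds_per_species=12, seed=7)
    base.update(overrides)
    return default_effect_config(**base)


def tiny_design(n_congeners: int = 2, replicates: int = 2, blanks: int = 1) -> StudyDesign:
    """One-genus design for focused unit tests."""
    return StudyDesign(genera={"Inga": n_congeners},
                       focal_species={"Inga": "Inga_focalis"},
                       replicates_per_cell=replicates, include_blanks=blanks)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Full pipeline run on the 102-sample design with a reduced library."""
    out = tmp_path_factory.mktemp("small_pipeline")
    cfg = PipelineConfig(out_dir=out, n_perm=49, seed=7,
                         effect=dict(n_classes=40, compounds_per_class=10,
                                     singleton_fraction=0.3,
                                     compounds_per_species=12, seed=7))
    bundle = run_pipeline(cfg)
    bundle["config"] = cfg
    return bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full pipeline run at the study's default scale (1,302-compound
    library, 102 leaf samples, 999 permutations)."""
    out = tmp_path_factory.mktemp("default_pipeline")
    cfg = PipelineConfig(out_dir=out, n_perm=999, seed=11)
    bundle = run_pipeline(cfg)
    bundle["config"] = cfg
    return bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
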