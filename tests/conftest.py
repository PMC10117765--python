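"""Shared fixtures: one default simulated study per session, plus a full
pipeline run reused by the recovery tests."""

import numpy as np
import pandas as pd
import pytest

from riboseep.genome_io import FeatureRecord
from riboseep.pipeline import PipelineConfig, run_all
from riboseep.synthetic_data import SimConfig, make_genome, simulate_reads

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def study(sim_config):
    """(replicons, truth_annotation, truth, reads) under default conditions."""
    replicons, annotation, truth = make_genome(sim_config)
    reads = simulate_reads(truth, sim_config,
                           {r.id: r.length for r in replicons})
    return replicons, annotation, truth, reads


@pytest.fixture(scope="session")
def replicon_lengths(study):
    replicons = study[0]
    return {r.id: r.length for r in replicons}


@pytest.fixture(scope="session")
def truth_features(study):
    truth = study[2]
    feats = []
    for row in truth.itertuples():
        if row.feature_class in ("background",):
            continue
        feats.append(FeatureRecord(
            feature_id=row.feature_id, replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            feature_class={"CDS": "CDS", "sORF": "sORF", "uORF": "sORF",
                           "antisense_sORF": "sORF", "sRNA": "sRNA",
                           "hkRNA": "hkRNA"}.get(row.feature_class, "other"),
        ))
    return feats


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory):
    """Full simulate->accept pipeline run under default conditions."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=str(out), seed=DEFAULT_SEED)
    run_all(config)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def load(out, name) -> pd.DataFrame:
    return pd.read_csv(out / name, sep="\t")
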