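import math

import numpy as np
import pytest

import dmsfill as df


def make_toy_dataset() -> df.DMSDataset:
    """Two short domains with hand-set raw scores and nonsense anchors."""
    domains = {
        "P1": df.DomainEntry("P1", "ALKV", wt_score=2.0),
        "P2": df.DomainEntry("P2", "GWD", wt_score=1.0, family_id="FAMX"),
    }
    records = [
        df.DMSRecord(df.VariantKey("P1", 1, "A", "V"), raw_score=2.5),
        df.DMSRecord(df.VariantKey("P1", 1, "A", "G"), raw_score=1.0),
        df.DMSRecord(df.VariantKey("P1", 2, "L", "I"), raw_score=2.0),
        df.DMSRecord(df.VariantKey("P1", 2, "L", "P"), raw_score=1.2),
        df.DMSRecord(df.VariantKey("P1", 3, "K", "R"), raw_score=1.9),
        df.DMSRecord(df.VariantKey("P1", 1, "A", "*"), raw_score=1.0),
        df.DMSRecord(df.VariantKey("P1", 2, "L", "*"), raw_score=1.2),
        df.DMSRecord(df.VariantKey("P1", 3, "K", "*"), raw_score=0.8),
        df.DMSRecord(df.VariantKey("P2", 1, "G", "A"), raw_score=0.9),
        df.DMSRecord(df.VariantKey("P2", 2, "W", "F"), raw_score=0.7),
        df.DMSRecord(df.VariantKey("P2", 1, "G", "*"), raw_score=0.1),
    ]
    eve = np.array([0.1, 0.5, 0.05, 0.9, 0.2, np.nan, np.nan, np.nan,
                    0.3, 0.4, np.nan])
    return df.DMSDataset(domains=domains, records=records,
                         aux_columns={"eve": eve})


@pytest.fixture
def toy_dataset() -> df.DMSDataset:
    return make_toy_dataset()


@pytest.fixture(scope="session")
def small_corpus():
    """A small normalized synthetic corpus shared across model-level tests."""
    spec = df.SyntheticSpec(n_domains=8, length_range=(30, 50), seed=1)
    dataset, truth = df.simulate(spec)
    normalized = df.normalize_scores(dataset, df.estimate_all_baselines(dataset))
    archive = df.simulate_embeddings(normalized, truth, dim=8,
                                     signal_fraction=0.8, seed=1)
    return normalized, truth, archive


@pytest.fixture(scope="session")
def small_features(small_corpus):
    """Feature matrix + targets for the small corpus under esm_plus_mean."""
    normalized, truth, archive = small_corpus
    config = df.FeatureSetConfig.preset("esm_plus_mean")
    priors = {"mean_dms": df.positional_mean(normalized)}
    fm = df.assemble_features(normalized, config, priors=priors,
                              embeddings=archive)
    score_of = {r.key: r.norm_score for r in normalized.substitution_records()}
    y = np.array([score_of[k] for k in fm.keys])
    return fm, y
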