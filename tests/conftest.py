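import numpy as np
import pytest

from delphiahp import (
    load_final_framework,
    load_initial_framework,
    load_reference_score_sets,
    load_reference_stats,
)
from delphiahp.delphi import ScorePanel


@pytest.fixture(scope="session")
def final_h():
    return load_final_framework()


@pytest.fixture(scope="session")
def initial_h():
    return load_initial_framework()


@pytest.fixture(scope="session")
def ref_stats():
    return load_reference_stats()


@pytest.fixture(scope="session")
def ref_means(ref_stats):
    return dict(zip(ref_stats["indicator_id"], ref_stats["mean"].astype(float)))


@pytest.fixture(scope="session")
def ref_weights(ref_stats):
    return dict(zip(ref_stats["indicator_id"], ref_stats["weight"].astype(float)))


@pytest.fixture(scope="session")
def ref_score_sets():
    return load_reference_score_sets()


@pytest.fixture(scope="session")
def reference_panel(ref_score_sets):
    """15-expert panel whose score columns are the bundled reference
    multisets — its column means reproduce the reference means exactly."""
    ids = list(ref_score_sets.keys())
    scores = np.column_stack([ref_score_sets[i] for i in ids])
    return ScorePanel(
        round_id=2,
        expert_ids=[f"E{k:02d}" for k in range(1, 16)],
        indicator_ids=ids,
        scores=scores,
    )


def make_panel(scores, round_id=1, **kwargs):
    scores = np.atleast_2d(np.asarray(scores))
    m, n = scores.shape
    return ScorePanel(
        round_id=round_id,
        expert_ids=[f"E{k}" for k in range(m)],
        indicator_ids=[f"i{k}" for k in range(n)],
        scores=scores,
        **kwargs,
    )
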