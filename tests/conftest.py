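import numpy as np
import pytest

from famprobe.models import ModelSpec, build_cnn_classifier
from famprobe.synthetic import MotifFamilySpec, generate_motif_family
from famprobe.training import (OptimizerConfig, make_balanced_batches,
                               train_classifier)


@pytest.fixture(scope="session")
def small_family():
    """Compact planted-motif family for unit tests (40 pos / 80 neg)."""
    spec = MotifFamilySpec(n_pos=40, n_neg=80, seed=11)
    pos, neg, truth = generate_motif_family(spec)
    records = {r.id: r for r in pos + neg}
    return {"spec": spec, "pos": pos, "neg": neg, "truth": truth,
            "records": records}


@pytest.fixture(scope="session")
def small_trained_cnn(small_family):
    """A CNN trained briefly on the small family; enough signal for
    attribution sanity checks without the cost of a full run."""
    records = small_family["records"]
    pos_ids = [r.id for r in small_family["pos"]][:32]
    neg_ids = [r.id for r in small_family["neg"]][:64]
    plan = make_balanced_batches(pos_ids, neg_ids, 16, 120, seed=5)
    model = build_cnn_classifier(ModelSpec("cnn", seed=5))
    model, history = train_classifier(model, plan, records,
                                      OptimizerConfig(lr=3e-3, batch_size=16))
    return {"model": model, "history": history, "records": records,
            "pos_ids": pos_ids, "neg_ids": neg_ids,
            "truth": small_family["truth"]}
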