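"""Shared fixtures: the tiny synthetic study system and derived objects."""

import numpy as np
import pytest

from crestkit import model as mdl
from crestkit import preprocessing as prep
from crestkit import synth
from crestkit.genomic_io import one_hot_encode

TINY_SEED = 3


@pytest.fixture(scope="session")
def tiny_fixture():
    """Tiny synthetic system: genome, peaks, tracks, expression, truth."""
    return synth.make_fixture(synth.SyntheticSpec(seed=TINY_SEED))


@pytest.fixture(scope="session")
def peak_matrix(tiny_fixture):
    """Peak matrix over the tiny fixture: aggregated, annotated, split."""
    fx = tiny_fixture
    m = prep.compute_peak_matrix(fx.tracks, fx.regions, agg="mean", center_window=300)
    prep.annotate_gini(m)
    prep.select_specific_regions(m)
    prep.split_regions(m, "fraction", 0.15, 0.15, seed=7)
    return m


@pytest.fixture(scope="session")
def encoded_regions(tiny_fixture, peak_matrix):
    """One-hot encodings of every fixture region, in matrix order."""
    fx = tiny_fixture
    return np.stack([
        one_hot_encode(fx.genome.fetch(iv.chrom, iv.start, iv.end))
        for iv in peak_matrix.regions
    ])


@pytest.fixture(scope="session")
def trained_models(tiny_fixture, peak_matrix):
    """Base-trained and fine-tuned tiny dilated CNNs plus their histories.

    Trained once per session; used by the recovery checks. Problem sizes
    (300 regions, 500-bp input, <30k parameters) keep this a few minutes.
    """
    fx = tiny_fixture
    m = peak_matrix
    cfg = mdl.tiny_dilated_config(
        len(m.class_names), class_names=m.class_names, input_length=500
    )
    predictor = mdl.build_model(cfg, seed=11)
    tcfg = mdl.TrainingConfig(batch_size=32, epochs_max=40, seed=11)
    predictor, history = mdl.train(predictor, m, fx.genome, tcfg)

    ft_cfg = mdl.TrainingConfig(learning_rate=1e-5, batch_size=64, epochs_max=10, seed=11)
    # measure specific-region validation loss of the base model first
    flags = m.obs["specific"].to_numpy().astype(bool)
    val_mask = m.split_mask("val") & flags
    x_val = np.stack([
        one_hot_encode(fx.genome.fetch(iv.chrom, iv.start, iv.end))
        for i, iv in enumerate(m.regions) if val_mask[i]
    ])
    y_val = m.values[val_mask]
    base_specific_val = mdl.cosine_logmse_loss(
        y_val, predictor.predict(x_val), dynamic=True
    ).total
    finetuned, ft_history = mdl.finetune(predictor, m, fx.genome, ft_cfg)
    ft_specific_val = mdl.cosine_logmse_loss(
        y_val, finetuned.predict(x_val), dynamic=True
    ).total
    return {
        "base": predictor,
        "finetuned": finetuned,
        "history": history,
        "ft_history": ft_history,
        "base_specific_val": base_specific_val,
        "ft_specific_val": ft_specific_val,
    }
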