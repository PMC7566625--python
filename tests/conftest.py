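"""Shared fixtures. The expensive trained-model fixtures are session-scoped
so translator behaviour, workflow behaviour and the end-to-end checks all
reuse the same training runs."""

from __future__ import annotations

import numpy as np
import pytest

from shiftlab import evaluation as ev
from shiftlab import synthetic_data as sd
from shiftlab import translation as tr
from shiftlab import workflow as wf


@pytest.fixture(scope="session")
def phantom_pair():
    """One 256-px phantom with a single 40-px marker disk, noise-free."""
    spec = sd.PhantomSpec(height=256, width=256,
                          marker_regions=[(128, 128, 40)], noise_sd=0.0)
    return sd.generate_phantom_pair(spec, seed=1)


@pytest.fixture(scope="session")
def l1_training_run():
    """A single-sample phantom cohort split 200 train / 40 held-out, with an
    L1-only translator trained at the desk preset, plus held-out SSIM scores
    against true and shuffled partners."""
    cohort = sd.CohortSpec(
        samples=[sd.SampleSpec("A", 240, "c")],
        clusters={"c": sd.TextureParams()},
        tile_size=64,
        seed=11,
    )
    tiles = dict(sd.generate_cohort(cohort))["A"]
    train, test = tiles[:200], tiles[200:]
    cfg = tr.desk_config("l1_only", seed=0, max_steps=1200)
    model = tr.train_translator([(p.he, p.if_chan) for p in train], cfg)

    preds = [tr.translate_tile(model, p.he) for p in test]
    trues = [p.if_chan for p in test]
    rng = np.random.default_rng(0)
    shuffle = rng.permutation(len(test))
    ssim_true, ssim_shuffled = [], []
    for i, pred in enumerate(preds):
        j = shuffle[i] if shuffle[i] != i else (shuffle[i] + 1) % len(test)
        ssim_true.append(ev.ssim(pred, trues[i]))
        ssim_shuffled.append(ev.ssim(pred, trues[j]))
    return {
        "model": model,
        "train": train,
        "test": test,
        "preds": preds,
        "ssim_true": np.array(ssim_true),
        "ssim_shuffled": np.array(ssim_shuffled),
    }


@pytest.fixture(scope="session")
def two_cluster_cohort_spec():
    """Four samples in two texture clusters: A, B share one regime; C, D
    another (denser, larger nuclei, shifted stroma hue, larger marker
    regions) — the synthetic analog of a small heterogeneous cohort."""
    c1 = sd.TextureParams(nucleus_density=0.004, nucleus_radius=2.5)
    c2 = sd.TextureParams(nucleus_density=0.012, nucleus_radius=4.0,
                          stroma_rgb=(0.86, 0.63, 0.86), marker_radius=(10.0, 18.0))
    return sd.CohortSpec(
        samples=[sd.SampleSpec("A", 60, "c1"), sd.SampleSpec("B", 60, "c1"),
                 sd.SampleSpec("C", 60, "c2"), sd.SampleSpec("D", 60, "c2")],
        clusters={"c1": c1, "c2": c2},
        tile_size=64,
        seed=0,
    )


@pytest.fixture(scope="session")
def composition_experiment(two_cluster_cohort_spec):
    """Cross-cluster {B, D} vs within-cluster {A, B} training compositions,
    trained and scored on their held-out samples."""
    cfg = wf.ExperimentConfig(
        cohort=two_cluster_cohort_spec,
        compositions={"cross": ["B", "D"], "within": ["A", "B"]},
        translator=tr.desk_config("l1_only", max_steps=800),
        seed=5,
    )
    return wf.run_experiment(cfg)
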