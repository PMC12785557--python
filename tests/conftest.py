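"""Shared fixtures: synthetic patch datasets and trained models.

Training the NumPy Double U-Net is the expensive part of the suite, so
trained models are session-scoped and shared: a small fast model for
contract tests (checkpointing, inference determinism, blank fields) and
one full-size blue-channel model at the study scale (~800 patches) used
by the segmentation-performance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rishquant.pipeline import build_patch_dataset
from rishquant.preprocess import PreprocessConfig, preprocess_field
from rishquant.segmenter import DoubleUNetSegmenter
from rishquant.synthetic import CohortSpec, SyntheticFieldSpec, generate_cohort, generate_field

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_patch_dataset(
    n: int, seed: int, max_blue: int = 10, max_red: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n preprocessed 64x64 patches with well-separated dots + masks."""
    rng = np.random.default_rng(seed)
    X, yb, yr = [], [], []
    for _ in range(n):
        spec = SyntheticFieldSpec(
            height=64,
            width=64,
            n_blue=int(rng.integers(0, max_blue + 1)),
            n_red=int(rng.integers(0, max_red + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        f = generate_field(spec)
        X.append(preprocess_field(f.image).astype(np.float32))
        yb.append(f.blue_mask)
        yr.append(f.red_mask)
    return np.stack(X), np.stack(yb), np.stack(yr)


@pytest.fixture(scope="session")
def small_patches():
    """140 blue-only patches for fast training tests."""
    return make_patch_dataset(140, seed=2024)


@pytest.fixture(scope="session")
def tiny_blue_model(small_patches) -> DoubleUNetSegmenter:
    """A small Double U-Net trained briefly; good enough to behave, fast."""
    X, yb, _ = small_patches
    est = DoubleUNetSegmenter(
        channel="blue_WT", depth=2, base_filters=8, epochs=4, batch_size=8, seed=11
    )
    est.fit(X, yb)
    return est


@pytest.fixture(scope="session")
def study_scale_blue_model() -> DoubleUNetSegmenter:
    """Blue-channel model at the study's patch scale (~800 64x64 patches).

    Full-size architecture (depth 3, 16 base filters), dice loss, Adam
    lr 0.001; small batches give enough optimizer steps to converge
    within a few passes on one CPU.
    """
    X, yb, _ = make_patch_dataset(800, seed=4242)
    est = DoubleUNetSegmenter(
        channel="blue_WT",
        depth=3,
        base_filters=16,
        learning_rate=0.001,
        epochs=5,
        batch_size=8,
        train_fraction=0.8,
        seed=7,
    )
    est.fit(X, yb)
    return est


@pytest.fixture(scope="session")
def demo_cohort():
    """Small two-channel cohort with moderate dot densities."""
    cohort = CohortSpec(
        n_samples=3,
        fields_per_sample=10,
        blue_mean_range=(15.0, 80.0),
        red_mean_range=(8.0, 40.0),
        field=SyntheticFieldSpec(height=256, width=256),
        seed=99,
    )
    return generate_cohort(cohort)


@pytest.fixture(scope="session")
def preprocess_cfg():
    return PreprocessConfig()
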