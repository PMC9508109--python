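"""Synthetic per-frame feature vectors standing in for learned image features.

The tracking stage regresses landmark pixel positions from a D-dimensional
feature vector extracted per two-view frame pair. This module provides the
default feature source for synthetic trials: a fixed random affine map of
the frame's 2D landmark coordinates (both views concatenated), optionally
augmented with nonlinear distractor channels and Gaussian channel noise.
The affine map has full column rank on the signal subspace, so a linear
regressor can in principle recover every landmark coordinate exactly when
the noise is zero. Feature extraction is a pluggable contract (any callable
mapping a two-view observation pair to a (frames x D) matrix fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cameras import Observations2D


@dataclass
class FeatureSet:
    """Feature vectors for a sequence: one D-dimensional row per frame."""

    X: np.ndarray                     # (T, D)
    seed: int
    signal_dim: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be (frames, D)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    @property
    def D(self) -> int:
        return self.X.shape[1]


def landmark_signal(obs_d: Observations2D, obs_l: Observations2D) -> np.ndarray:
    """Concatenate both views' pixel coordinates into the latent signal z."""
    if obs_d.landmark_names != obs_l.landmark_names:
        raise ValueError("views disagree on the landmark catalog")
    return np.concatenate(
        [obs_d.uv.reshape(obs_d.n_frames, -1),
         obs_l.uv.reshape(obs_l.n_frames, -1)], axis=1)


def synthesize_features(
    obs_d: Observations2D,
    obs_l: Observations2D,
    D: int | None = None,
    *,
    noise_sd: float = 0.0,
    n_distractors: int = 8,
    seed: int = 0,
) -> FeatureSet:
    """Generate features as an affine image of the landmark coordinates.

    Channels are standardized to zero mean / unit variance over the
    sequence, after which ``noise_sd`` is the per-channel Gaussian noise
    level relative to the signal (0.01 = 1% of signal SD). ``D`` defaults
    to ``signal_dim + n_distractors``; it must leave at least ``signal_dim``
    linear channels or the map cannot be inverted.
    """
    z = landmark_signal(obs_d, obs_l)
    T, signal_dim = z.shape
    if D is None:
        D = signal_dim + n_distractors
    n_linear = D - n_distractors
    if n_linear < signal_dim:
        raise ValueError(
            f"D too small: need >= {signal_dim + n_distractors} channels "
            f"({signal_dim} signal + {n_distractors} distractors)")
    rng = np.random.default_rng(seed)
    # random rotation (orthonormal columns): invertible on the signal
    # subspace and well conditioned, like an information-preserving
    # feature embedding; applied to raw pixel coordinates so the feature
    # geometry mirrors the image geometry
    Q, _ = np.linalg.qr(rng.normal(size=(n_linear, signal_dim)))
    c = rng.normal(size=n_linear) * 10.0
    X = z @ Q.T + c
    if n_distractors:
        zs = (z - z.mean(axis=0)) / np.maximum(z.std(axis=0), 1e-9)
        B = rng.normal(size=(n_distractors, signal_dim)) / np.sqrt(signal_dim)
        scale = np.median(X.std(axis=0))
        X = np.concatenate([X, scale * np.sin(zs @ B.T)], axis=1)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        X = X + rng.normal(0.0, 1.0, size=X.shape) * (noise_sd * X.std(axis=0))
    return FeatureSet(X=X, seed=seed, signal_dim=signal_dim)


class SyntheticFeatureSource:
    """Feature-extractor contract bound to fixed synthesis parameters."""

    def __init__(self, D: int | None = None, noise_sd: float = 0.0,
                 n_distractors: int = 8, seed: int = 0):
        self.D = D
        self.noise_sd = noise_sd
        self.n_distractors = n_distractors
        self.seed = seed

    def __call__(self, obs_d: Observations2D, obs_l: Observations2D) -> FeatureSet:
        return synthesize_features(
            obs_d, obs_l, self.D, noise_sd=self.noise_sd,
            n_distractors=self.n_distractors, seed=self.seed)
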