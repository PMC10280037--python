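"""Training-time signal augmentations.

Two stochastic augmentations are applied to segments during contrastive
training: additive Gaussian noise (with SD drawn log-uniformly over a
configured range, default 1e-5 … 1e-2) and window slicing with permutation
(the segment is split into contiguous blocks which are then reordered at
random, both channels moving together).  Both preserve segment length and
channel count; slicing additionally preserves each channel's sample multiset
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signals import Segment

__all__ = ["AugmentPolicy", "add_gaussian_noise", "slice_permute", "apply_policy"]


@dataclass(frozen=True)
class AugmentPolicy:
    """Probabilities and ranges of the two augmentations.

    ``sigma_range`` bounds the noise SD (sampled log-uniformly);
    ``n_windows_range`` bounds the inclusive number of slicing blocks.
    """

    p_noise: float = 0.5
    sigma_range: tuple[float, float] = (1e-5, 1e-2)
    p_slice: float = 0.5
    n_windows_range: tuple[int, int] = (4, 10)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_noise <= 1.0 and 0.0 <= self.p_slice <= 1.0):
            raise ValueError("augmentation probabilities must be in [0, 1]")
        lo, hi = self.sigma_range
        if not 0 < lo <= hi:
            raise ValueError("sigma_range must satisfy 0 < low <= high")
        nlo, nhi = self.n_windows_range
        if nlo < 2 or nhi < nlo:
            raise ValueError("n_windows_range must satisfy 2 <= min <= max")


def add_gaussian_noise(seg: Segment, sigma: float,
                       rng: np.random.Generator) -> Segment:
    """Add i.i.d. zero-mean Gaussian noise of SD ``sigma`` to both channels."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return seg
    return replace(seg, samples=seg.samples + rng.normal(0, sigma, seg.samples.shape))


def slice_permute(seg: Segment, n_windows: int,
                  rng: np.random.Generator) -> Segment:
    """Split into ``n_windows`` contiguous blocks and reorder them randomly.

    The first n−1 blocks have equal length floor(L/n); the last absorbs the
    remainder.  Both channels move together, so per-channel sample multisets
    are preserved exactly.
    """
    L = seg.samples.shape[0]
    if not 2 <= n_windows <= L:
        raise ValueError(f"n_windows must be in [2, {L}], got {n_windows}")
    base = L // n_windows
    bounds = [i * base for i in range(n_windows)] + [L]
    blocks = [seg.samples[bounds[i]: bounds[i + 1]] for i in range(n_windows)]
    order = rng.permutation(n_windows)
    return replace(seg, samples=np.concatenate([blocks[i] for i in order]))


def apply_policy(seg: Segment, policy: AugmentPolicy,
                 rng: np.random.Generator) -> Segment:
    """Apply the policy: slice-permute with probability ``p_slice``, then
    Gaussian noise with probability ``p_noise`` (noise after reordering so
    block boundaries are not noise-free seams)."""
    if rng.random() < policy.p_slice:
        n = int(rng.integers(policy.n_windows_range[0],
                             policy.n_windows_range[1] + 1))
        seg = slice_permute(seg, n, rng)
    if rng.random() < policy.p_noise:
        lo, hi = policy.sigma_range
        sigma = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        seg = add_gaussian_noise(seg, sigma, rng)
    return seg
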