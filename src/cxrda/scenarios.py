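"""The standard two-domain synthetic study used by the test harness.

The source domain mimics a large archive with ~20% cardiomegaly prevalence
and clean acquisition; the target domain mimics a small clinical collection
with ~60% prevalence (its test split is exactly 20 positives + 13 negatives)
recorded under a strongly shifted protocol (``DomainShift.strong()``).
Phantoms are rendered at 96 px and preprocessed through the chest-cavity
pipeline to 64 x 64 x 3 network inputs — the desk-scale stand-in for the
full 299 px protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objectives import ONE_HOT
from .phantom import (
    DEFAULT_CTR_RANGES,
    DEFAULT_CTR_THRESHOLD,
    DomainShift,
    PhantomSpec,
    apply_domain_shift,
    render_phantom,
)
from .preprocess import PreprocessConfig, preprocess_pipeline

RENDER_SIDE = 96
NETWORK_SIDE = 64

#: (n_cardiomegaly, n_normal) per split.
SOURCE_COUNTS = {"train": (16, 64), "test": (8, 32)}
TARGET_COUNTS = {"train": (29, 19), "test": (20, 13)}


@dataclass
class DomainData:
    """Preprocessed arrays per split: images (n, s, s, 3), one-hot, labels."""

    images: dict[str, np.ndarray] = field(default_factory=dict)
    onehot: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, list[str]] = field(default_factory=dict)


def _generate_domain(counts: dict[str, tuple[int, int]], shift: DomainShift,
                     seed: int, pre_cfg: PreprocessConfig,
                     render_side: int = RENDER_SIDE) -> DomainData:
    data = DomainData()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE1]))
    for split, (n_pos, n_neg) in counts.items():
        images, labels = [], []
        for label, n in (("cardiomegaly", n_pos), ("normal", n_neg)):
            lo, hi = DEFAULT_CTR_RANGES[label]
            for _ in range(n):
                spec = PhantomSpec(image_side=render_side,
                                   ctr=float(rng.uniform(lo, hi)))
                s = int(rng.integers(0, 2**31 - 1))
                ph = render_phantom(spec, s, DEFAULT_CTR_THRESHOLD)
                img = apply_domain_shift(ph.image, shift, s + 1)
                images.append(preprocess_pipeline(img, pre_cfg))
                labels.append(ph.label)
        data.images[split] = np.stack(images).astype(np.float32)
        data.onehot[split] = np.asarray([ONE_HOT[l] for l in labels], dtype=np.float32)
        data.labels[split] = labels
    return data


def standard_scenario(seed: int, network_side: int = NETWORK_SIDE,
                      ) -> tuple[DomainData, DomainData, PreprocessConfig]:
    """Generate (source, target) domain data for one replicate seed."""
    pre_cfg = PreprocessConfig(output_side=network_side)
    source = _generate_domain(SOURCE_COUNTS, DomainShift.identity(), seed * 2 + 1, pre_cfg)
    target = _generate_domain(TARGET_COUNTS, DomainShift.strong(), seed * 2 + 2, pre_cfg)
    return source, target, pre_cfg
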