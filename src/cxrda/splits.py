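"""Stratified train/validation/test splitting with largest-remainder rounding."""

from __future__ import annotations

import numpy as np

from .manifest import SPLITS, DatasetManifest


def largest_remainder_allocation(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Allocate ``n`` items to bins proportionally to ``fractions``.

    Integer parts are assigned first; the remaining items go to the bins with
    the largest fractional remainders (ties broken by bin order).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("split fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {sum(fractions)}")
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_stratified(manifest: DatasetManifest, fractions: tuple[float, float, float],
                     seed: int, splits: tuple[str, ...] = SPLITS) -> DatasetManifest:
    """Assign split tags per class with proportional (largest-remainder) counts.

    Every class is shuffled independently under a seed-derived stream, then cut
    into contiguous blocks of the allocated sizes, so per-split class
    proportions deviate from the global proportions by at most one sample.
    """
    if len(fractions) != len(splits):
        raise ValueError("one fraction per split required")
    df = manifest.records.copy().reset_index(drop=True)
    ss = np.random.SeedSequence(seed)
    out_split = np.empty(len(df), dtype=object)
    for cls, child in zip(sorted(df["label"].unique()), ss.spawn(len(df["label"].unique()))):
        idx = df.index[df["label"] == cls].to_numpy()
        alloc = largest_remainder_allocation(len(idx), fractions)
        if any(a == 0 for a in alloc):
            raise ValueError(
                f"class {cls!r} with {len(idx)} samples cannot fill all "
                f"{len(splits)} splits at fractions {fractions}"
            )
        perm = np.random.default_rng(child).permutation(len(idx))
        pos = 0
        for name, count in zip(splits, alloc):
            out_split[idx[perm[pos : pos + count]]] = name
            pos += count
    df["split"] = out_split
    return DatasetManifest(df)
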