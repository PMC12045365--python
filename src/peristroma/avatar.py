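"""The sample-specific "digital avatar" permutation null.

A digital avatar of a tumor cross-section keeps every tumor-cell position
and the stroma geometry fixed, and redistributes the marker-positivity
labels uniformly at random among the tumor cells while preserving the
positive count K.  Comparing the observed positive-cell distance
distribution against avatars of the *same* sample controls for the
sample's own tumor/stroma architecture.

Because a uniformly random size-K subset of the cells has an expected
ECDF equal to the all-cell ECDF, the null expectation is available in
closed form (the R -> infinity limit of avatar averaging); sampled
ensembles are used where a null *distribution* (bands, empirical
p-values) is needed rather than an expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DistanceProfile, Ecdf, ecdf

DEFAULT_QUANTILE_GRID = np.linspace(0.1, 0.9, 9)


@dataclass
class AvatarEnsemble:
    """Null distribution of bias statistics over R marker-shuffled avatars.

    ``medians``, ``means`` and ``ks_d`` hold one value per replicate:
    the median/mean distance of the avatar's positives (microns) and the
    KS D of the avatar-positive distances against all-cell distances.
    ``mean_null_ecdf`` is the across-replicate mean of the avatar-positive
    ECDF evaluated at ``ecdf_grid`` (all-cell distance quantiles).
    """

    medians: np.ndarray
    means: np.ndarray
    ks_d: np.ndarray
    ecdf_grid: np.ndarray
    mean_null_ecdf: np.ndarray
    r: int
    n: int
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("ensemble needs at least one replicate")
        for arr in (self.medians, self.means, self.ks_d):
            if len(arr) != self.r or not np.all(np.isfinite(arr)):
                raise ValueError("null statistics must be finite, one per replicate")


def make_avatar(profile: DistanceProfile, rng: np.random.Generator) -> np.ndarray:
    """One avatar: a uniformly random size-K subset flagged positive.

    Distances and positions are untouched; only the returned label vector
    differs from the observed one.
    """
    n, k = profile.n, profile.k
    flags = np.zeros(n, dtype=bool)
    if k:
        flags[rng.choice(n, size=k, replace=False)] = True
    return flags


def expected_null_ecdf(profile: DistanceProfile) -> Ecdf:
    """Exact expectation of the avatar-positive ECDF: the all-cell ECDF.

    For a uniformly random size-K subset S of cells, E[1/K sum_{i in S}
    1(d_i <= t)] = 1/N sum_i 1(d_i <= t) at every t, so no sampling is
    needed for the expected null curve.
    """
    return ecdf(profile.distances)


def expected_null_summary(profile: DistanceProfile) -> tuple[float, float]:
    """Closed-form null (median, mean) in microns: the all-cell summary.

    The mean is the exact expectation of an avatar's positive-subset mean;
    the median is the median of the expected null ECDF.
    """
    if profile.n == 0:
        raise ValueError("empty profile")
    return float(np.median(profile.distances)), float(np.mean(profile.distances))


def null_ensemble(
    profile: DistanceProfile,
    r: int = 1000,
    seed: int | None = None,
    quantile_grid=DEFAULT_QUANTILE_GRID,
) -> AvatarEnsemble:
    """Sample R independent avatars and record their bias statistics.

    Replicate streams are counter-based (child seed sequences), so
    replicate ``i`` is identical whether the ensemble has 100 or 1000
    replicates, and ensembles are reproducible and extensible.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if profile.k == 0:
        raise ValueError("no marker-positive cells; the avatar null is undefined")
    d = profile.distances
    d_sorted = np.sort(d)
    grid_values = np.quantile(d_sorted, quantile_grid)

    children = np.random.SeedSequence(seed).spawn(r)
    medians = np.empty(r)
    means = np.empty(r)
    ks = np.empty(r)
    ecdf_acc = np.zeros(len(grid_values))
    k = profile.k
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pos = d[rng.choice(profile.n, size=k, replace=False)]
        medians[i] = np.median(pos)
        means[i] = pos.mean()
        pos.sort()
        # KS D of avatar positives vs all cells on the pooled (= all-cell) support
        fa = np.searchsorted(pos, d_sorted, side="right") / k
        fb = np.arange(1, d.size + 1) / d.size
        ks[i] = np.max(np.abs(fa - fb))
        ecdf_acc += np.searchsorted(pos, grid_values, side="right") / k
    return AvatarEnsemble(
        medians=medians,
        means=means,
        ks_d=ks,
        ecdf_grid=grid_values,
        mean_null_ecdf=ecdf_acc / r,
        r=r,
        n=profile.n,
        k=k,
        seed=seed,
    )


def empirical_pvalue(observed: float, null_values, tail: str = "left") -> float:
    """Add-one permutation p-value: ``(1 + #extreme) / (R + 1)``.

    ``tail="left"`` counts null values <= observed (proximity bias:
    observed distances smaller than null); ``"right"`` counts >=;
    ``"two-sided"`` doubles the smaller tail, capped at 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null ensemble")
    r = null_values.size
    left = (1 + int(np.sum(null_values <= observed))) / (r + 1)
    if tail == "left":
        return left
    right = (1 + int(np.sum(null_values >= observed))) / (r + 1)
    if tail == "right":
        return right
    if tail == "two-sided":
        return min(1.0, 2.0 * min(left, right))
    raise ValueError(f"unknown tail {tail!r}")
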