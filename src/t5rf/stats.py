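"""Resampling statistics for hierarchically sampled imaging data.

Neurons recorded in the same fly are not independent, so group comparisons
use fly-nested permutation tests (flies are permuted between groups, each
fly's neurons travel together). Pairing specificity of tuning maps is tested
by shuffling the pairings; effect sizes get percentile bootstrap confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stimuli import InvalidConfigError

__all__ = [
    "PermutationResult",
    "ShuffleCorrResult",
    "BootstrapCI",
    "UnderpoweredDesignError",
    "nested_permutation_test",
    "shuffled_pairing_test",
    "pearson_corr_test",
    "bootstrap_corr_ci",
]


class UnderpoweredDesignError(ValueError):
    """Nested design with too few flies per group to permute."""


@dataclass
class PermutationResult:
    observed_stat: float
    p_value: float  # add-one convention: (1 + exceedances) / (1 + n_perm)
    p_value_raw: float  # exceedances / n_perm, 0 reported as < 1/n
    n_permutations: int
    nested: bool
    seed: int


@dataclass
class ShuffleCorrResult:
    observed_mean_corr: float
    shuffled_mean: float
    shuffled_ci95: tuple[float, float]
    p_one_tailed: float  # exceedances / n_shuffles
    p_one_tailed_addone: float
    n_shuffles: int
    n_pairs: int


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 1000


def _diff_of_means(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a) - np.mean(b))


def nested_permutation_test(
    values,
    fly_ids,
    group_labels,
    statistic=None,
    n_perm: int = 10_000,
    seed: int = 0,
    nested: bool = True,
) -> PermutationResult:
    """Two-group permutation test, optionally nested by fly.

    In nested mode, fly-to-group assignments are permuted (preserving the
    number of flies per group) and all neurons of a fly keep their fly; this
    respects within-fly correlation. In non-nested mode neurons are permuted
    independently, appropriate when flies contribute too few neurons to carry
    within-fly structure. Two-tailed p uses the add-one convention
    (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm).
    """
    values = np.asarray(values, dtype=float)
    fly_ids = np.asarray(fly_ids)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise InvalidConfigError("exactly two groups required")
    if statistic is None:
        statistic = _diff_of_means
    mask_a = group_labels == groups[0]
    if mask_a.sum() == 0 or (~mask_a).sum() == 0:
        raise InvalidConfigError("empty group")
    obs = statistic(values[mask_a], values[~mask_a])
    rng = np.random.default_rng(seed)

    if nested:
        flies = np.unique(fly_ids)
        fly_group = {}
        for f in flies:
            fg = np.unique(group_labels[fly_ids == f])
            if len(fg) != 1:
                raise InvalidConfigError(f"fly {f!r} appears in both groups")
            fly_group[f] = fg[0]
        n_a = sum(1 for f in flies if fly_group[f] == groups[0])
        if n_a < 2 or len(flies) - n_a < 2:
            raise UnderpoweredDesignError(
                "nested test needs at least 2 flies per group"
            )
        fly_index = np.searchsorted(flies, fly_ids)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(flies))
            in_a = np.zeros(len(flies), dtype=bool)
            in_a[perm[:n_a]] = True
            sel = in_a[fly_index]
            s = statistic(values[sel], values[~sel])
            if abs(s) >= abs(obs):
                count += 1
    else:
        n_a = int(mask_a.sum())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(values))
            s = statistic(values[perm[:n_a]], values[perm[n_a:]])
            if abs(s) >= abs(obs):
                count += 1

    p = (1 + count) / (1 + n_perm)
    return PermutationResult(obs, p, count / n_perm, n_perm, nested, seed)


def _pairwise_corr_matrix(maps_a, maps_b) -> np.ndarray:
    """corr(a_i, b_j) for all i, j, via z-scored flattened maps."""
    A = np.stack([np.asarray(m, dtype=float).ravel() for m in maps_a])
    B = np.stack([np.asarray(m, dtype=float).ravel() for m in maps_b])
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(A, axis=1)
    sb = np.linalg.norm(B, axis=1)
    if np.any(sa == 0) or np.any(sb == 0):
        raise InvalidConfigError("constant map after exclusion")
    return (A / sa[:, None]) @ (B / sb[:, None]).T


def shuffled_pairing_test(
    maps_a, maps_b, n_shuffles: int = 10_000, seed: int = 0
) -> ShuffleCorrResult:
    """Pairing-specificity test for paired tuning maps.

    The observed statistic is the mean Pearson correlation over the true
    pairs. For each shuffle the pairings are permuted and the mean pairwise
    correlation recomputed; the one-tailed p-value is the fraction of
    shuffled means >= the observed mean (0 is reported alongside the add-one
    convention, i.e. "< 1/n_shuffles"). The 2.5/97.5 percentiles of the
    shuffled means are returned as the 95% interval of the mean correlation
    per shuffle. Zero-variance maps are excluded pairwise with a warning.
    """
    if len(maps_a) != len(maps_b):
        raise InvalidConfigError("paired lists must have equal length")
    keep = []
    for i, (a, b) in enumerate(zip(maps_a, maps_b)):
        if np.std(np.asarray(a, dtype=float)) == 0 or np.std(
            np.asarray(b, dtype=float)
        ) == 0:
            warnings.warn(f"pair {i} has a constant map; excluded", stacklevel=2)
        else:
            keep.append(i)
    if len(keep) < 3:
        raise InvalidConfigError("need at least 3 valid pairs")
    C = _pairwise_corr_matrix([maps_a[i] for i in keep], [maps_b[i] for i in keep])
    n = C.shape[0]
    observed = float(np.trace(C) / n)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    shuffled_means = C[np.arange(n)[None, :], perms].mean(axis=1)
    exceed = int(np.sum(shuffled_means >= observed))
    lo, hi = np.percentile(shuffled_means, [2.5, 97.5])
    return ShuffleCorrResult(
        observed_mean_corr=observed,
        shuffled_mean=float(shuffled_means.mean()),
        shuffled_ci95=(float(lo), float(hi)),
        p_one_tailed=exceed / n_shuffles,
        p_one_tailed_addone=(1 + exceed) / (1 + n_shuffles),
        n_shuffles=n_shuffles,
        n_pairs=n,
    )


def pearson_corr_test(x, y) -> tuple[float, float]:
    """Pearson correlation with the standard two-tailed t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidConfigError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidConfigError("undefined correlation: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bootstrap_corr_ci(
    x, y, n_boot: int = 1000, level: float = 0.95, seed: int = 0,
    max_retries: int = 100,
) -> BootstrapCI:
    """Percentile bootstrap confidence interval for a Pearson correlation.

    Cases (pairs) are resampled with replacement; degenerate resamples with
    zero variance are redrawn up to ``max_retries`` times.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise InvalidConfigError("need paired samples with n >= 5")
    r_obs, _ = pearson_corr_test(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            xs, ys = x[idx], y[idx]
            if np.std(xs) > 0 and np.std(ys) > 0:
                break
        else:
            raise InvalidConfigError("could not draw a non-degenerate resample")
        reps[b] = np.corrcoef(xs, ys)[0, 1]
    alpha = (1 - level) / 2
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(r_obs, float(lo), float(hi), level, n_boot)
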