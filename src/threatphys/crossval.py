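"""Cross-validated prediction of the CS⁺/CS⁻ difference from drug label.

How well does knowing whether a participant took drug or placebo predict
their conditioned discrimination?  A linear model (difference ~ group label)
is trained on two of three folds and predicts the held-out fold; the
statistic is the residual variance proportion — sum of squared prediction
errors divided by the number of data points and by the variance of the
data — averaged over the 3 folds and 10 random partitionings.  Significance
comes from permuting drug labels: the p value is the rate at which permuted
labels predict *better* (smaller statistic) than the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_MAX_PARTITION_RETRIES = 1000


@dataclass
class CVConfig:
    k_folds: int = 3
    n_partitionings: int = 10
    n_permutations: int = 1000
    seed: int = 0
    add_one_correction: bool = False   # literal counting rule by default

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_partitionings < 1 or self.n_permutations < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class CVResult:
    residual_variance_proportion: float
    permutation_distribution: np.ndarray
    p_value: float


def _draw_partitionings(n: int, labels01: np.ndarray,
                        config: CVConfig, rng: np.random.Generator) -> np.ndarray:
    """Fold assignments, shape (n_partitionings, n); sizes differ by <= 1.

    Partitionings are redrawn (bounded retries) until every training set
    contains both labels.
    """
    k = config.k_folds
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    out = np.empty((config.n_partitionings, n), dtype=int)
    for i in range(config.n_partitionings):
        for _ in range(_MAX_PARTITION_RETRIES):
            folds = rng.permutation(base)
            ok = all(
                len(np.unique(labels01[folds != f])) == 2 for f in range(k)
            )
            if ok:
                out[i] = folds
                break
        else:
            raise RuntimeError(
                "could not draw folds with both labels in every training set")
    return out


def _statistic(diffs: np.ndarray, labels01: np.ndarray,
               partitionings: np.ndarray, k: int) -> float:
    """Residual variance proportion averaged over folds and partitionings."""
    var = float(np.var(diffs))
    if var == 0:
        raise ValueError("zero variance in the CS+/CS- differences")
    total = 0.0
    count = 0
    for folds in partitionings:
        for f in range(k):
            test = folds == f
            train = ~test
            # linear model on a binary label = per-label training means
            pred = np.empty(test.sum())
            lab_test = labels01[test]
            for lab in (0, 1):
                m = labels01[train] == lab
                mu = diffs[train][m].mean() if m.any() else diffs[train].mean()
                pred[lab_test == lab] = mu
            err = diffs[test] - pred
            total += float(err @ err) / len(err) / var
            count += 1
    return total / count


def cv_statistic(diffs: np.ndarray, labels, config: CVConfig | None = None,
                 rng: np.random.Generator | None = None,
                 partitionings: np.ndarray | None = None) -> float:
    """Observed residual variance proportion (seed-deterministic).

    ``diffs``: one CS⁺/CS⁻ difference per participant; ``labels``: the drug
    group labels (two levels, any dtype).  Values near 0 mean the label
    predicts the difference almost perfectly; values near 1 mean it predicts
    no better than the grand mean.  ``partitionings`` (shape
    ``(n_partitionings, n)`` of fold ids) overrides the random draw.
    """
    config = config or CVConfig()
    diffs, labels01 = _as_arrays(diffs, labels, config)
    if partitionings is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        partitionings = _draw_partitionings(len(diffs), labels01, config, rng)
    return _statistic(diffs, labels01, np.asarray(partitionings),
                      config.k_folds)


def permutation_test(diffs: np.ndarray, labels,
                     config: CVConfig | None = None) -> CVResult:
    """Label-permutation test of the cross-validated statistic.

    The fold partitionings are shared between the observed and permuted
    statistics, which holds partitioning noise constant across the
    comparison.  The p value follows the literal counting rule: the
    fraction of permutations with a *smaller* statistic than observed
    (optionally with the add-one correction).
    """
    config = config or CVConfig()
    diffs, labels01 = _as_arrays(diffs, labels, config)
    rng = np.random.default_rng(config.seed)
    parts = _draw_partitionings(len(diffs), labels01, config, rng)
    observed = _statistic(diffs, labels01, parts, config.k_folds)
    perm = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        perm[i] = _statistic(diffs, rng.permutation(labels01), parts,
                             config.k_folds)
    smaller = int(np.sum(perm < observed))
    if config.add_one_correction:
        p = (smaller + 1) / (config.n_permutations + 1)
    else:
        p = smaller / config.n_permutations
    return CVResult(observed, perm, float(p))


def _as_arrays(diffs, labels, config: CVConfig):
    diffs = np.asarray(diffs, dtype=float)
    labels = np.asarray(labels)
    if len(diffs) != len(labels):
        raise ValueError("diffs and labels differ in length")
    if len(diffs) < config.k_folds:
        raise ValueError("need at least k_folds participants")
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("need exactly two label levels")
    return diffs, (labels == levels[1]).astype(int)
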