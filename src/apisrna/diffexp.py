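"""Differential small-RNA expression between tissue pairs.

The test is a conditioned exact negative-binomial test in the Robinson-Smyth
style: counts are scaled to a common effective library size, summed within
each tissue, and the observed split of the feature total between the two
tissues is compared with its conditional null distribution - binomial when
the common dispersion is zero, beta-binomial otherwise.  The two-sided
p-value sums the probabilities of all splits at most as probable as the one
observed.  Multiple testing is handled by Benjamini-Hochberg FDR.

A feature is called differentially expressed (DE) when FDR < 0.01, fold
change > 5 and the mean raw count is at least 5 in one of the tissues; a
feature is uniquely expressed in a tissue when it has zero raw counts in
every sample of the other tissue and mean normalized count >= 5 in its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class CountMatrix:
    """Feature x sample integer counts with a sample -> tissue map."""

    def __init__(self, counts: pd.DataFrame, sample_tissues: dict[str, str]) -> None:
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(sample_tissues)
        if missing:
            raise ValueError(f"samples without tissue assignment: {sorted(missing)}")
        self.counts = counts
        self.sample_tissues = dict(sample_tissues)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_tissues[s] == tissue]


@dataclass
class DEResult:
    table: pd.DataFrame
    summary: dict
    phi: float


def normalize_libsize(matrix: CountMatrix) -> pd.Series:
    """Per-sample scaling factors: library size over the geometric mean of
    library sizes.  Normalized count = count / factor."""
    totals = matrix.library_sizes.astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    geomean = float(np.exp(np.log(totals).mean()))
    return totals / geomean


def estimate_common_dispersion(matrix: CountMatrix) -> float:
    """Method-of-moments common dispersion on normalized counts.

    For every tissue with >= 2 replicates and every feature with positive
    within-group mean m and variance s^2, collect (s^2 - m) / m^2; the
    dispersion is the mean of these, floored at zero.  Returns 0 (with no
    replication there is no information about overdispersion) when no group
    has >= 2 replicates.
    """
    factors = normalize_libsize(matrix)
    norm = matrix.counts / factors
    terms = []
    for tissue in set(matrix.sample_tissues.values()):
        cols = matrix.samples_of(tissue)
        if len(cols) < 2:
            continue
        sub = norm[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        terms.append(((v[ok] - m[ok]) / m[ok] ** 2).to_numpy())
    if not terms:
        return 0.0
    return max(0.0, float(np.concatenate(terms).mean()))


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    factors_a: np.ndarray | None = None,
    factors_b: np.ndarray | None = None,
) -> float:
    """Two-sided conditioned exact test of equal means between two groups.

    Counts are scaled to common effective library sizes, summed per group
    and rounded; conditional on the total, the group-A sum is binomial
    (phi = 0) or beta-binomial (phi > 0) under the null.  The p-value sums
    the conditional probabilities of every split no more probable than the
    observed one, so p in (0, 1] and a zero total gives p = 1.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if factors_a is not None:
        counts_a = counts_a / np.asarray(factors_a, dtype=float)
    if factors_b is not None:
        counts_b = counts_b / np.asarray(factors_b, dtype=float)
    y_a = int(round(counts_a.sum()))
    y_b = int(round(counts_b.sum()))
    n_a, n_b = len(counts_a), len(counts_b)
    t = y_a + y_b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 0:
        pmf = stats.binom.pmf(k, t, n_a / (n_a + n_b))
    else:
        pmf = stats.betabinom.pmf(k, t, n_a / phi, n_b / phi)
    p_obs = pmf[y_a]
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, max(p, np.finfo(float).tiny))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    matrix: CountMatrix,
    tissue_pair: tuple[str, str],
    fdr_max: float = 0.01,
    fc_min: float = 5.0,
    min_count: float = 5.0,
    phi: float | None = None,
) -> DEResult:
    """Pairwise differential expression with DE and unique-expression flags.

    Fold change is the ratio of tissue-mean normalized counts (larger over
    smaller, >= 1, infinite when one tissue is all-zero); ``min_count``
    applies to the mean raw count of the more expressed tissue.
    """
    t1, t2 = tissue_pair
    s1, s2 = matrix.samples_of(t1), matrix.samples_of(t2)
    if not s1 or not s2:
        raise ValueError(f"tissue pair {tissue_pair} not present in the matrix")
    sub = CountMatrix(
        matrix.counts[s1 + s2], {s: matrix.sample_tissues[s] for s in s1 + s2}
    )
    factors = normalize_libsize(sub)
    if phi is None:
        phi = estimate_common_dispersion(sub)
    raw1, raw2 = sub.counts[s1], sub.counts[s2]
    norm1 = raw1 / factors[s1]
    norm2 = raw2 / factors[s2]
    mean_n1, mean_n2 = norm1.mean(axis=1), norm2.mean(axis=1)
    mean_r1, mean_r2 = raw1.mean(axis=1), raw2.mean(axis=1)

    f1 = factors[s1].to_numpy()
    f2 = factors[s2].to_numpy()
    pvals = np.array(
        [
            nb_exact_test(raw1.loc[i].to_numpy(), raw2.loc[i].to_numpy(), phi, f1, f2)
            for i in sub.counts.index
        ]
    )
    fdr = bh_fdr(pvals)

    hi = np.maximum(mean_n1, mean_n2)
    lo = np.minimum(mean_n1, mean_n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    direction = np.where(mean_n1 >= mean_n2, t1, t2)

    de = (fdr < fdr_max) & (fc > fc_min) & (np.maximum(mean_r1, mean_r2) >= min_count)
    # tolerance absorbs normalization round-off when libraries are equal
    eps = 1e-9 * min_count
    unique1 = (raw2.sum(axis=1) == 0) & (mean_n1 >= min_count - eps)
    unique2 = (raw1.sum(axis=1) == 0) & (mean_n2 >= min_count - eps)

    table = pd.DataFrame(
        {
            "mean_norm_t1": mean_n1,
            "mean_norm_t2": mean_n2,
            "mean_raw_t1": mean_r1,
            "mean_raw_t2": mean_r2,
            "fold_change": fc,
            "direction": direction,
            "p_value": pvals,
            "fdr": fdr,
            "de": de,
            "unique_in_t1": unique1,
            "unique_in_t2": unique2,
        },
        index=sub.counts.index,
    )
    up1 = de & (direction == t1)
    up2 = de & (direction == t2)
    summary = {
        "tissue_1": t1,
        "tissue_2": t2,
        "n_features": len(table),
        "n_de": int(de.sum()),
        "n_up_t1": int(up1.sum()),
        "n_up_t2": int(up2.sum()),
        "n_unique_t1": int((up1 & unique1).sum()),
        "n_unique_t2": int((up2 & unique2).sum()),
    }
    return DEResult(table=table, summary=summary, phi=float(phi))


def pca_profiles(matrix: CountMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample coordinates on the first principal components of log-CPM
    profiles (feature-centered SVD; sign fixed so each component's largest
    coordinate is positive)."""
    if matrix.counts.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    cpm = matrix.counts * 1e6 / matrix.library_sizes
    logged = np.log2(cpm + 1.0)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    coords = (vt[:n_components].T * s[:n_components])
    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords,
        index=matrix.counts.columns,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
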