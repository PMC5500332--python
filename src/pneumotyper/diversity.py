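"""Alpha and beta diversity: Chao1 with rarefaction, inverse Simpson,
Bray-Curtis distances and one-factor PERMANOVA.

Chao1 uses the classic estimator S_obs + F1²/(2·F2) when doubletons exist and
switches to the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) only at F2 = 0,
where the classic form is undefined.  Rarefaction draws without replacement
(multivariate hypergeometric), repeated ``n_reps`` times per depth; reported
SDs use the n−1 denominator.  PERMANOVA partitions the squared distances into
among/within-group sums of squares, with a permutation p-value carrying the
+1 correction so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_counts(row) -> np.ndarray:
    arr = np.asarray(row, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


@dataclass(frozen=True)
class Chao1Result:
    s_obs: int
    f1: int
    f2: int
    estimate: float


def chao1(row) -> Chao1Result:
    """Chao1 richness estimate for one sample's genus counts."""
    arr = _as_counts(row)
    if arr.sum() == 0:
        raise ValueError("Chao1 undefined for an all-zero sample")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0  # bias-corrected branch, F2 = 0
    return Chao1Result(s_obs, f1, f2, float(est))


def rarefy(row, depth: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Subsample a count row to ``depth`` reads without replacement."""
    arr = np.asarray(row, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(arr.sum())
    if total < depth:
        raise ValueError(f"sample total {total} is below rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


@dataclass(frozen=True)
class RarefactionCurve:
    depths: np.ndarray
    mean: np.ndarray  # mean Chao1 per depth
    sd: np.ndarray  # sample SD (n-1) per depth; 0 when n_reps == 1
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "chao1_mean": self.mean, "chao1_sd": self.sd}
        )


def rarefaction_curve(
    row,
    depths=None,
    n_reps: int = 50,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean ± SD of Chao1 over repeated rarefactions at each depth."""
    arr = np.asarray(row, dtype=np.int64)
    total = int(arr.sum())
    if depths is None:
        depths = [d for d in range(20, 341, 20) if d <= total]
    depths = np.asarray(sorted(depths), dtype=int)
    if len(depths) and depths[-1] > total:
        raise ValueError("maximum depth exceeds the sample total")
    rng = np.random.default_rng(seed)
    means = np.empty(len(depths))
    sds = np.empty(len(depths))
    for i, d in enumerate(depths):
        vals = np.array(
            [chao1(rarefy(arr, int(d), rng)).estimate for _ in range(n_reps)]
        )
        means[i] = vals.mean()
        sds[i] = vals.std(ddof=1) if n_reps > 1 else 0.0
    return RarefactionCurve(depths, means, sds, n_reps, seed)


def rarefied_chao1(
    row, depth: int = 340, n_reps: int = 50, seed: int = 0
) -> float:
    """Mean Chao1 at a single rarefaction depth (NaN if the row is too shallow)."""
    arr = np.asarray(row, dtype=np.int64)
    if int(arr.sum()) < depth:
        return float("nan")
    rng = np.random.default_rng(seed)
    return float(
        np.mean([chao1(rarefy(arr, depth, rng)).estimate for _ in range(n_reps)])
    )


def inverse_simpson(row) -> float:
    """1 / Σ p_i² — the effective number of equally abundant genera."""
    arr = _as_counts(row)
    total = arr.sum()
    if total == 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = arr / total
    return float(1.0 / np.sum(p * p))


def bray_curtis(x, y) -> float:
    """Σ|x−y| / Σ(x+y) between two count (or proportion) rows."""
    a = _as_counts(x)
    b = _as_counts(y)
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined when both rows are zero")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample × sample Bray-Curtis dissimilarity matrix."""
    mat = counts.to_numpy(dtype=float)
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(mat[i], mat[j])
    return pd.DataFrame(out, index=counts.index, columns=counts.index)


@dataclass(frozen=True)
class PermanovaResult:
    f_statistic: float
    p_value: float
    r_squared: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among / ss_total


def permanova(
    dist: pd.DataFrame | np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor permutational ANOVA on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations) under random
    relabeling with a fixed seed; R² is the among-group fraction of the total
    sum of squares.
    """
    if isinstance(dist, pd.DataFrame):
        labels = pd.Series(labels).reindex(dist.index) if hasattr(labels, "reindex") else pd.Series(list(labels), index=dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = pd.Series(list(labels))
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    counts = np.bincount(codes)
    if n_groups < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d * d
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        f_perm, _ = _pseudo_f(d2, rng.permutation(codes), n_groups)
        if f_perm >= f_obs:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), float(r2), n_permutations)
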