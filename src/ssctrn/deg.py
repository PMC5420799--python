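"""Integrative two-test differential expression across stage comparisons.

For each gene and each stage comparison the statistic combines a two-sample
Welch t-test with a median-ratio permutation test: the median-ratio statistic
is the median over all cross pairs (i, j) of b_j - a_i on the log2 scale, and
its p-value comes from permuting sample labels within the pooled vector
(exhaustively when the number of distinct label splits is small enough,
Monte Carlo otherwise). The two p-values are combined by Stouffer's method
with equal weights, adjusted across genes by Benjamini-Hochberg within each
comparison, and turned into a ternary call: +1 (up), -1 (down) or 0, using
adjusted p < alpha and |log2 fold change| > fc_threshold.

The reported log2 fold change is the median of cross-pair differences
(contrast minus baseline), consistent with the median-ratio statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

#: canonical stage comparisons, each as (name, baseline, contrast)
CANONICAL_COMPARISONS = (
    ("iSSC-vs-SSC", "SSC", "iSSC"),
    ("mSSC-vs-SSC", "SSC", "mSSC"),
    ("mSSC-vs-iSSC", "iSSC", "mSSC"),
)


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    baseline: str
    contrast: str


def canonical_specs() -> list[ComparisonSpec]:
    return [ComparisonSpec(*c) for c in CANONICAL_COMPARISONS]


# ---------------------------------------------------------------------------
# scalar statistics


def ttest_p(values_a, values_b) -> float:
    """Two-sided Welch t-test p-value; degenerate zero-variance cases defined.

    Both sides constant with equal means -> p = 1; with unequal means the
    p-value is floored at 1e-300.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ttest_p requires >= 2 replicates per side")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else P_FLOOR
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(max(p, P_FLOOR))


def cross_pair_median(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Median over all cross pairs (i, j) of b[..., j] - a[..., i]."""
    diffs = b[..., None, :] - a[..., :, None]
    return np.median(diffs.reshape(*diffs.shape[:-2], -1), axis=-1)


def _label_splits(n_a: int, n_b: int) -> np.ndarray:
    """All distinct assignments of n_a 'baseline' slots among n_a+n_b labels."""
    n = n_a + n_b
    return np.array(list(combinations(range(n), n_a)), dtype=int)


def _split_stats(pooled: np.ndarray, splits: np.ndarray) -> np.ndarray:
    """Median-ratio statistic for each label split; pooled is (..., n)."""
    n = pooled.shape[-1]
    out = []
    for split in splits:
        mask = np.zeros(n, dtype=bool)
        mask[split] = True
        out.append(cross_pair_median(pooled[..., mask], pooled[..., ~mask]))
    return np.stack(out, axis=0)


def median_ratio_p(values_a, values_b, n_perm: int = 10000, seed: int | None = None) -> float:
    """Two-sided permutation p-value of the cross-pair median-ratio statistic.

    When the number of distinct label splits C(n_a+n_b, n_a) does not exceed
    ``n_perm`` the splits are enumerated exhaustively (p = fraction of splits
    with |stat| >= |observed|, logged); otherwise ``n_perm`` random label
    permutations are drawn and p = (#{|stat| >= |observed|} + 1)/(n_perm + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("median_ratio_p requires >= 2 replicates per side")
    obs = cross_pair_median(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    if comb(pooled.size, n_a) <= n_perm:
        logger.debug("median_ratio_p: exhaustive enumeration of %d label splits",
                     comb(pooled.size, n_a))
        stats_ = _split_stats(pooled, _label_splits(n_a, b.size))
        return float(np.mean(np.abs(stats_) >= abs(obs)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(cross_pair_median(perm[:n_a], perm[n_a:])) >= abs(obs):
            count += 1
    return (count + 1) / (n_perm + 1)


def combine_p(p_t: float, p_mr: float) -> float:
    """Stouffer combination with equal weights.

    z = (z_t + z_mr)/sqrt(2) with z_x = Phi^-1(1 - p_x); inputs are clipped
    to [1e-300, 1 - 1e-16] before transformation.
    """
    for p in (p_t, p_mr):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    pt = min(max(p_t, P_FLOOR), P_CEIL)
    pm = min(max(p_mr, P_FLOOR), P_CEIL)
    z = (stats.norm.isf(pt) + stats.norm.isf(pm)) / np.sqrt(2.0)
    return float(min(max(stats.norm.sf(z), 0.0), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized per-comparison machinery


def _welch_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for (genes x reps) matrices, degenerate-safe."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    var0 = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(var0, np.where(equal, 1.0, P_FLOOR), p)
    return np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)


def _median_ratio_p_matrix(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    null: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized median-ratio test for (genes x reps) matrices.

    Returns (observed statistic, p-value) per gene. Label splits are
    enumerated exhaustively when C(n, n_a) <= n_perm, else Monte Carlo
    permutations are drawn.

    ``null="per-gene"`` compares each gene only against its own permuted
    statistics; its p-value floor is 1/#splits, far too coarse to survive an
    FDR adjustment at 2-3 replicates per stage. ``null="pooled"`` (default)
    pools the permuted statistics across all genes into one empirical null —
    genes are exchangeable up to their common noise scale — giving a
    resolution of ~1/(genes x splits) while remaining a valid permutation
    null under the global null.
    """
    obs = cross_pair_median(a, b)
    pooled = np.concatenate([a, b], axis=1)
    n_a = a.shape[1]
    n = pooled.shape[1]
    if comb(n, n_a) <= n_perm:
        splits = _label_splits(n_a, n - n_a)
        stats_ = _split_stats(pooled, splits)
        # the observed labeling (and its mirror when balanced) is not part
        # of the pooled null: true effects would contaminate the tail
        identity = tuple(range(n_a))
        mirror = tuple(range(n_a, n))
        null_rows = [
            i for i, s in enumerate(map(tuple, splits))
            if s != identity and (n - n_a != n_a or s != mirror)
        ]
        exhaustive = True
    else:
        draws = []
        for _ in range(n_perm):
            idx = rng.permutation(n)
            draws.append(cross_pair_median(pooled[:, idx[:n_a]], pooled[:, idx[n_a:]]))
        stats_ = np.stack(draws, axis=0)
        null_rows = list(range(n_perm))
        exhaustive = False
    abs_obs = np.abs(obs)
    abs_null = np.abs(stats_)
    if null == "pooled":
        flat = np.sort(abs_null[null_rows].ravel())
        count = flat.size - np.searchsorted(flat, abs_obs, side="left")
        return obs, (count + 1) / (flat.size + 1)
    if null != "per-gene":
        raise ValueError(f"unknown null scheme: {null!r}")
    if exhaustive:
        return obs, np.mean(abs_null >= abs_obs[None, :], axis=0)
    count = (abs_null >= abs_obs[None, :]).sum(axis=0)
    return obs, (count + 1) / (n_perm + 1)


def _combine_p_vector(p_t: np.ndarray, p_mr: np.ndarray) -> np.ndarray:
    zt = stats.norm.isf(np.clip(p_t, P_FLOOR, P_CEIL))
    zm = stats.norm.isf(np.clip(p_mr, P_FLOOR, P_CEIL))
    return np.clip(stats.norm.sf((zt + zm) / np.sqrt(2.0)), 0.0, 1.0)


def run_comparisons(
    matrix: pd.DataFrame,
    stage_of_sample: dict[str, str],
    expressed=None,
    specs: list[ComparisonSpec] | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 0.58,
    n_perm: int = 10000,
    seed: int | None = 0,
    mr_null: str = "pooled",
) -> pd.DataFrame:
    """Run all stage comparisons over the expressed genes.

    Returns a tidy table with one row per expressed gene per comparison:
    gene, comparison, log2fc, p_t, p_mr, p_combined, p_adjusted, call.
    Adjustment is applied per comparison across genes; calls use
    p_adjusted < alpha together with |log2fc| > fc_threshold. ``mr_null``
    selects the median-ratio permutation null ("pooled" across genes,
    the default, or "per-gene"; see _median_ratio_p_matrix).
    """
    if specs is None:
        specs = canonical_specs()
    if expressed is not None:
        members = expressed.members if hasattr(expressed, "members") else list(expressed)
        matrix = matrix.loc[[g for g in matrix.index if g in set(members)]]
    samples_by_stage: dict[str, list[str]] = {}
    for sample in matrix.columns:
        stage = stage_of_sample.get(sample)
        if stage is None:
            raise ValueError(f"sample {sample!r} missing from the stage map")
        samples_by_stage.setdefault(stage, []).append(sample)
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        for stage in (spec.baseline, spec.contrast):
            n_reps = len(samples_by_stage.get(stage, []))
            if n_reps < 2:
                raise ValueError(
                    f"stage {stage!r} has {n_reps} replicate(s); comparisons need >= 2 — "
                    "check the stage map or drop this comparison"
                )
        a = matrix[samples_by_stage[spec.baseline]].to_numpy(dtype=float)
        b = matrix[samples_by_stage[spec.contrast]].to_numpy(dtype=float)
        p_t = _welch_p_matrix(a, b)
        log2fc, p_mr = _median_ratio_p_matrix(a, b, n_perm, rng, null=mr_null)
        p_comb = _combine_p_vector(p_t, p_mr)
        p_adj = bh_adjust(p_comb)
        call = np.where(
            (p_adj < alpha) & (np.abs(log2fc) > fc_threshold),
            np.sign(log2fc).astype(int),
            0,
        ).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "gene": matrix.index,
                    "comparison": spec.name,
                    "log2fc": log2fc,
                    "p_t": p_t,
                    "p_mr": p_mr,
                    "p_combined": p_comb,
                    "p_adjusted": p_adj,
                    "call": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def deg_union(results: pd.DataFrame) -> list[str]:
    """Genes called in at least one comparison (the DEG union)."""
    hit = results.loc[results["call"] != 0, "gene"].unique()
    return sorted(hit)
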