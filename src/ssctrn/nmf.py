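"""Consensus pluripotency / differentiation signatures from time courses.

Per-line log2 fold-change courses (each time point versus the line's
undifferentiated baseline) are harmonized by joint quantile normalization of
the vectorized matrices, combined over the shared gene identifiers, embedded
into non-negative form by splitting each column x into its positive parts
[x]+ and [-x]+, and factorized by rank-k non-negative matrix factorization
(multiplicative updates minimizing Frobenius error; k defaults to 40).
Cluster membership is decided by a permutation p-value on the gene loadings
(null: loadings refit on row-permuted data with the coefficient matrix held
fixed). Clusters whose mean trajectory is consistently up (down) across all
lines yield the differentiation-related (pluripotency-related) signature;
member genes must additionally reach a |log2 fold change| of log2(fc_min)
in the consistent direction at >= 1 time point in every line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import quantile_normalize

logger = logging.getLogger(__name__)

_EPS = 1e-10


def build_fc_matrix(timecourse: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Log2 fold-change matrix: each column minus the baseline column.

    The baseline column itself is dropped (its fold change is identically 0).
    """
    if baseline not in timecourse.columns:
        raise ValueError(f"baseline column {baseline!r} not in time course")
    fc = timecourse.drop(columns=[baseline]).sub(timecourse[baseline], axis=0)
    return fc


def harmonize_lines(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Quantile-harmonize per-line fold-change matrices and combine them.

    Each matrix is restricted to the shared gene intersection, vectorized
    row-major, the vectors are quantile-normalized jointly (removing bias
    toward lines with large fold changes), reshaped back, and the per-line
    matrices are column-concatenated with line-prefixed column names.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize_lines needs >= 2 lines")
    shared = list(matrices[0].index)
    for m in matrices[1:]:
        present = set(m.index)
        shared = [g for g in shared if g in present]
    if not shared:
        raise ValueError("empty gene intersection across lines")
    mats = [m.loc[shared] for m in matrices]
    t = mats[0].shape[1]
    if any(m.shape[1] != t for m in mats):
        raise ValueError("all lines must share the number of time points")
    vectors = pd.DataFrame(
        np.column_stack([m.to_numpy().ravel(order="C") for m in mats]),
        columns=[f"line{i+1}" for i in range(len(mats))],
    )
    normalized = quantile_normalize(vectors).to_numpy()
    frames = []
    for i, m in enumerate(mats):
        back = normalized[:, i].reshape(len(shared), t)
        frames.append(
            pd.DataFrame(back, index=shared, columns=[f"line{i+1}:{c}" for c in m.columns])
        )
    return pd.concat(frames, axis=1)


def embed_signed(matrix: pd.DataFrame) -> pd.DataFrame:
    """Non-negative embedding: each column x becomes [x]+ and [-x]+."""
    pos = matrix.clip(lower=0.0)
    neg = (-matrix).clip(lower=0.0)
    pos.columns = [f"{c}+" for c in matrix.columns]
    neg.columns = [f"{c}-" for c in matrix.columns]
    return pd.concat([pos, neg], axis=1)


@dataclass
class NMFModel:
    """Fitted rank-k factorization X ~ W H with the iteration error trace."""

    W: np.ndarray                 # genes x k, non-negative loadings
    H: np.ndarray                 # k x columns, non-negative coefficients
    k: int
    gene_ids: list[str]
    column_ids: list[str]
    error_trace: list[float] = field(default_factory=list)

    @property
    def reconstruction_error(self) -> float:
        return self.error_trace[-1] if self.error_trace else float("nan")

    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.W, index=self.gene_ids, columns=[f"c{c+1}" for c in range(self.k)]
        )


def _mu_update_h(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    return H * (W.T @ X) / (W.T @ W @ H + _EPS)


def _mu_update_w(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    return W * (X @ H.T) / (W @ (H @ H.T) + _EPS)


def nmf_factorize(
    matrix: pd.DataFrame,
    k: int = 40,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFModel:
    """Multiplicative-update NMF minimizing the Frobenius error.

    Stops when the relative change of the error drops below ``tol`` or after
    ``max_iter`` iterations; the per-iteration error trace is recorded (it is
    non-increasing, the multiplicative-update guarantee). Fixed seeds give
    bit-identical factorizations.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative (use embed_signed first)")
    m, n = X.shape
    if k > min(m, n):
        raise ValueError(f"rank k={k} exceeds min(matrix dimensions)={min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.random((m, k)) * scale + _EPS
    H = rng.random((k, n)) * scale + _EPS
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H = _mu_update_h(X, W, H)
        W = _mu_update_w(X, W, H)
        err = float(np.linalg.norm(X - W @ H))
        trace.append(err)
        if prev < np.inf and prev - err < tol * max(prev, _EPS):
            break
        prev = err
    return NMFModel(
        W=W, H=H, k=k, gene_ids=list(matrix.index), column_ids=list(matrix.columns),
        error_trace=trace,
    )


def _refit_loadings(
    X: np.ndarray, H: np.ndarray, rng: np.random.Generator, n_iter: int = 50
) -> np.ndarray:
    """Refit W with H fixed by multiplicative updates from a random start."""
    k = H.shape[0]
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.random((X.shape[0], k)) * scale + _EPS
    HHt = H @ H.T
    XHt = X @ H.T
    for _ in range(n_iter):
        W = W * XHt / (W @ HHt + _EPS)
    return W


def assign_membership(
    model: NMFModel,
    matrix: pd.DataFrame,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_iter_refit: int = 50,
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Per-cluster gene memberships by a loading permutation test.

    The observed loadings are refit (H fixed) through the identical procedure
    used for the null, in which each gene row's entries are permuted
    independently before refitting; per gene and cluster,
    p = (#{null loading >= observed} + 1) / (n_perm + 1), and genes with
    p < alpha belong to the cluster. Returns (cluster -> genes, p-values).
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 makes the p-value floor coarser than alpha=0.05")
    X = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    observed = _refit_loadings(X, model.H, rng, n_iter_refit)
    exceed = np.zeros_like(observed, dtype=int)
    for _ in range(n_perm):
        perm = rng.permuted(X, axis=1)
        null_W = _refit_loadings(perm, model.H, rng, n_iter_refit)
        exceed += null_W >= observed
    pvals = (exceed + 1) / (n_perm + 1)
    pval_df = pd.DataFrame(
        pvals, index=model.gene_ids, columns=[f"c{c+1}" for c in range(model.k)]
    )
    clusters: dict[int, list[str]] = {}
    genes = np.asarray(model.gene_ids)
    for c in range(model.k):
        members = genes[pvals[:, c] < alpha]
        clusters[c + 1] = sorted(members)
    return clusters, pval_df


@dataclass
class SignatureSets:
    """Disjoint pluripotency-related (down) and differentiation (up) sets."""

    pluripotency: list[str]
    differentiation: list[str]
    max_abs_fc: pd.Series

    def __post_init__(self) -> None:
        if set(self.pluripotency) & set(self.differentiation):
            raise ValueError("signature sets must be disjoint")

    def as_gene_sets(self) -> dict[str, list[str]]:
        return {
            "pluripotency_related": list(self.pluripotency),
            "differentiation_related": list(self.differentiation),
        }


def _cluster_direction(
    members: list[str], fc_matrices: list[pd.DataFrame], sign_tol: float
) -> int:
    """+1 (up), -1 (down) or 0 (inconsistent) for a cluster's mean trajectory.

    The direction is the common sign of the terminal mean in every line;
    the whole mean trajectory must stay on that sign (violations smaller
    than ``sign_tol`` in magnitude are ignored).
    """
    signs = []
    for fc in fc_matrices:
        present = [g for g in members if g in fc.index]
        if not present:
            return 0
        traj = fc.loc[present].mean(axis=0).to_numpy()
        s = np.sign(traj[-1])
        if s == 0:
            return 0
        if np.any((np.sign(traj) == -s) & (np.abs(traj) > sign_tol)):
            return 0
        signs.append(int(s))
    return signs[0] if len(set(signs)) == 1 else 0


def select_signatures(
    clusters: dict[int, list[str]],
    fc_matrices: list[pd.DataFrame],
    fc_min: float = 1.5,
    sign_tol: float = 0.1,
) -> SignatureSets:
    """Signature sets from directionally consistent clusters.

    ``fc_min`` is a linear-scale fold change; a member gene must reach
    sign-consistent |log2 FC| >= log2(fc_min) at >= 1 time point in every
    line. Genes qualifying in both directions (possible only for erratic
    trajectories) are resolved by the sign of their own mean terminal fold
    change across lines.
    """
    threshold = float(np.log2(fc_min))
    up: set[str] = set()
    down: set[str] = set()
    for members in clusters.values():
        if not members:
            continue
        direction = _cluster_direction(members, fc_matrices, sign_tol)
        if direction == 0:
            continue
        for g in members:
            ok = all(
                g in fc.index and (direction * fc.loc[g]).max() >= threshold
                for fc in fc_matrices
            )
            if ok:
                (up if direction > 0 else down).add(g)
    both = up & down
    if both:
        logger.info("resolving %d genes qualifying in both directions", len(both))
        for g in sorted(both):
            terminal = np.mean([fc.loc[g].iloc[-1] for fc in fc_matrices])
            if terminal > 0:
                down.discard(g)
            elif terminal < 0:
                up.discard(g)
            else:
                up.discard(g)
                down.discard(g)
    shared = sorted(set.intersection(*(set(fc.index) for fc in fc_matrices)))
    max_abs = pd.Series(
        {
            g: float(max(fc.loc[g].abs().max() for fc in fc_matrices))
            for g in shared
        },
        name="max_abs_log2fc",
    )
    return SignatureSets(sorted(down), sorted(up), max_abs)


def extract_signatures(
    fc_matrices: list[pd.DataFrame],
    k: int = 40,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    n_perm: int = 99,
    seed: int | None = 0,
    max_iter: int = 500,
) -> tuple[SignatureSets, NMFModel, dict[int, list[str]]]:
    """Full extraction: harmonize -> embed -> factorize -> members -> select."""
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seed_fact, seed_memb = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    combined = harmonize_lines(fc_matrices)
    embedded = embed_signed(combined)
    k_eff = min(k, min(embedded.shape))
    if k_eff < k:
        logger.warning("rank reduced from %d to %d to fit the matrix", k, k_eff)
    model = nmf_factorize(embedded, k=k_eff, seed=seed_fact, max_iter=max_iter)
    clusters, _ = assign_membership(model, embedded, n_perm=n_perm, alpha=alpha, seed=seed_memb)
    sets = select_signatures(clusters, fc_matrices, fc_min=fc_min)
    return sets, model, clusters
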