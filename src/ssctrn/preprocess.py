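"""Normalization and expressed-gene detection.

Quantile normalization forces every sample (column) to share the common
empirical distribution given by the row-wise mean of the sorted columns.
Expressed genes are detected by fitting a two-component Gaussian mixture to
the per-gene mean log2 intensity pooled over all samples: genes assigned to
the higher-mean component (posterior >= 0.5) are called expressed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a genes x samples matrix.

    Every output column has the identical sorted value vector: the row-wise
    mean of the input's sorted columns. Ties within a column receive the mean
    of the reference values at their tied ranks, so the transform is a pure
    function of within-column ranks.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single-sample input, returning unchanged")
        return matrix.copy()
    if matrix.shape[0] < 2:
        raise ValueError("quantile_normalize needs at least 2 genes")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        # ties: average the reference values over each tied run
        sorted_col = col[order]
        ties = pd.Series(reference).groupby(sorted_col).transform("mean").to_numpy()
        ranked = np.empty_like(reference)
        ranked[order] = ties
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class ExpressedGeneSet:
    """Expressed genes with per-gene posterior of the expressed component."""

    members: list[str]
    posterior: pd.Series  # P(expressed component) for every gene in the matrix
    degenerate: bool = False

    def __post_init__(self) -> None:
        post = self.posterior.to_numpy()
        if ((post < 0) | (post > 1)).any():
            raise ValueError("posteriors must lie in [0, 1]")
        if not set(self.members) <= set(self.posterior.index):
            raise ValueError("members must be a subset of scored genes")

    def __contains__(self, gene: str) -> bool:
        return gene in self._member_set

    @property
    def _member_set(self) -> frozenset:
        return frozenset(self.members)


def detect_expressed(
    matrix: pd.DataFrame, n_components: int = 2, seed: int | None = 0
) -> ExpressedGeneSet:
    """Split genes into expressed / unexpressed by a 1-D Gaussian mixture.

    The mixture is fitted to per-gene mean log2 intensity pooled over all
    samples. If the fitted component means collapse (|mu1 - mu2| below
    0.1 x pooled SD) the fit is degenerate: a warning is emitted and all
    genes are marked expressed with posterior 1.
    """
    mean_intensity = matrix.mean(axis=1)
    x = mean_intensity.to_numpy().reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        init_params="kmeans",
        n_init=1,
        random_state=seed,
    ).fit(x)
    means = gm.means_.ravel()
    pooled_sd = float(np.std(x))
    hi = int(np.argmax(means))
    if pooled_sd == 0 or abs(means.max() - means.min()) < 0.1 * pooled_sd:
        warnings.warn("detect_expressed: degenerate mixture fit; marking all genes expressed")
        posterior = pd.Series(1.0, index=matrix.index)
        return ExpressedGeneSet(list(matrix.index), posterior, degenerate=True)
    resp = gm.predict_proba(x)[:, hi]
    posterior = pd.Series(resp, index=matrix.index)
    members = list(matrix.index[resp >= 0.5])
    return ExpressedGeneSet(members, posterior)
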