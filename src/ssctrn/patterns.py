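"""Temporal pattern codes and their merger into DEG groups.

Each DEG receives a ternary pattern code over the three stage comparisons,
in the fixed order (iSSC-vs-SSC, mSSC-vs-iSSC, mSSC-vs-SSC), written with
U (+1), D (-1) and 0 — e.g. "U0U". The discrete codes cannot see marginal
changes, so codes are merged into k groups (default 12) by agglomerative
clustering (Euclidean distance, average linkage) of the codes' auto-scaled
mean expression profiles over the samples, and the resulting groups are
relabelled 1..k deterministically by descending overall stage slope, then
descending size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

#: comparison order that defines the pattern code
CODE_ORDER = ("iSSC-vs-SSC", "mSSC-vs-iSSC", "mSSC-vs-SSC")

_CALL_TO_CHAR = {1: "U", -1: "D", 0: "0"}
_CHAR_TO_CALL = {v: k for k, v in _CALL_TO_CHAR.items()}


class NotADEGError(ValueError):
    """Raised when a gene's calls are all zero (not a DEG)."""


def assign_pattern(calls) -> str:
    """Encode a (iSSC-vs-SSC, mSSC-vs-iSSC, mSSC-vs-SSC) call triple."""
    calls = tuple(int(c) for c in calls)
    if len(calls) != 3 or any(c not in (-1, 0, 1) for c in calls):
        raise ValueError(f"calls must be a triple over {{-1, 0, +1}}: {calls}")
    if all(c == 0 for c in calls):
        raise NotADEGError("all-zero call triple: gene is not a DEG")
    return "".join(_CALL_TO_CHAR[c] for c in calls)


def decode_pattern(code: str) -> tuple[int, int, int]:
    if len(code) != 3 or any(ch not in _CHAR_TO_CALL for ch in code):
        raise ValueError(f"malformed pattern code: {code!r}")
    return tuple(_CHAR_TO_CALL[ch] for ch in code)  # type: ignore[return-value]


def autoscale(values: np.ndarray, axis: int = -1, eps: float = 0.0) -> np.ndarray:
    """Scale to zero mean and unit SD along ``axis`` (constant rows -> 0)."""
    mean = values.mean(axis=axis, keepdims=True)
    sd = values.std(axis=axis, keepdims=True)
    sd = np.where(sd <= eps, 1.0, sd)
    return (values - mean) / sd


def pattern_table(results: pd.DataFrame) -> pd.Series:
    """Per-DEG pattern code from a deg_test results table.

    Genes with all-zero calls (non-DEGs) are excluded.
    """
    calls = results.pivot(index="gene", columns="comparison", values="call")
    missing = [c for c in CODE_ORDER if c not in calls.columns]
    if missing:
        raise ValueError(f"results lack comparisons {missing}")
    calls = calls[list(CODE_ORDER)].fillna(0).astype(int)
    nonzero = calls.ne(0).any(axis=1)
    calls = calls.loc[nonzero]
    codes = [assign_pattern(tuple(row)) for row in calls.itertuples(index=False)]
    return pd.Series(codes, index=calls.index, name="pattern")


def code_profiles(matrix: pd.DataFrame, patterns: pd.Series) -> pd.DataFrame:
    """Auto-scaled mean expression profile (over samples) of each code."""
    genes = patterns.index
    scaled = pd.DataFrame(
        autoscale(matrix.loc[genes].to_numpy(), axis=1),
        index=genes,
        columns=matrix.columns,
    )
    return scaled.groupby(patterns).mean()


def average_linkage(profiles: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage matrix) on Euclidean distance."""
    return linkage(profiles, method="average", metric="euclidean")


def cluster_patterns(
    profiles: pd.DataFrame,
    k: int = 12,
    stage_of_sample: dict[str, str] | None = None,
) -> dict[str, int]:
    """Merge pattern codes into k groups; returns code -> group id (1..k).

    The agglomerative tree is cut to exactly k clusters. If fewer codes than
    k are present each code becomes its own group (warned). Group ids are
    assigned by descending mean first-to-last slope of the member codes'
    profiles, ties broken by descending member count then code order, so the
    labelling is deterministic.
    """
    codes = list(profiles.index)
    if len(codes) == 0:
        raise ValueError("no pattern codes to cluster")
    if len(codes) < k:
        warnings.warn(
            f"only {len(codes)} codes for k={k}: using one group per code"
        )
        labels = np.arange(1, len(codes) + 1)
    elif len(codes) == 1:
        labels = np.array([1])
    else:
        tree = average_linkage(profiles.to_numpy())
        labels = fcluster(tree, t=k, criterion="maxclust")
    return _relabel(profiles, labels, stage_of_sample)


def _slope(profile: np.ndarray, columns, stage_of_sample: dict[str, str] | None) -> float:
    """First-stage-to-last-stage slope of a profile (falls back to end-to-end)."""
    if stage_of_sample:
        stages = [stage_of_sample.get(c) for c in columns]
        order = list(dict.fromkeys(stages))
        first = [i for i, s in enumerate(stages) if s == order[0]]
        last = [i for i, s in enumerate(stages) if s == order[-1]]
        return float(profile[last].mean() - profile[first].mean())
    return float(profile[-1] - profile[0])


def _relabel(
    profiles: pd.DataFrame, labels: np.ndarray, stage_of_sample: dict[str, str] | None
) -> dict[str, int]:
    codes = list(profiles.index)
    values = profiles.to_numpy()
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    keyed = []
    for lab, idx in clusters.items():
        mean_profile = values[idx].mean(axis=0)
        slope = _slope(mean_profile, profiles.columns, stage_of_sample)
        keyed.append((-slope, -len(idx), min(idx), lab))
    keyed.sort()
    new_id = {lab: rank + 1 for rank, (_, _, _, lab) in enumerate(keyed)}
    return {codes[i]: new_id[int(labels[i])] for i in range(len(codes))}


@dataclass
class DEGGroupTable:
    """The temporal DEG groups: membership, codes, and scaled profiles."""

    group_of_gene: pd.Series          # gene -> group id
    codes_of_group: dict[int, list[str]]
    mean_profiles: pd.DataFrame       # group x samples, auto-scaled means
    median_profiles: pd.DataFrame     # group x samples, auto-scaled medians

    @property
    def groups(self) -> list[int]:
        return sorted(self.codes_of_group)

    def members(self, group: int) -> list[str]:
        return sorted(self.group_of_gene.index[self.group_of_gene == group])

    def sizes(self) -> dict[int, int]:
        return {g: int((self.group_of_gene == g).sum()) for g in self.groups}

    def as_gene_sets(self) -> dict[str, list[str]]:
        return {f"group_{g}": self.members(g) for g in self.groups}


def summarize_groups(
    matrix: pd.DataFrame,
    patterns: pd.Series,
    code_to_group: dict[str, int],
) -> DEGGroupTable:
    """Assemble the per-group membership and auto-scaled profile table."""
    unknown = sorted(set(patterns.unique()) - set(code_to_group))
    if unknown:
        raise ValueError(f"codes without a group assignment: {unknown}")
    group_of_gene = patterns.map(code_to_group).rename("group")
    codes_of_group: dict[int, list[str]] = {}
    for code, grp in code_to_group.items():
        if code in set(patterns.unique()):
            codes_of_group.setdefault(grp, []).append(code)
    codes_of_group = {g: sorted(cs) for g, cs in codes_of_group.items()}
    scaled = pd.DataFrame(
        autoscale(matrix.loc[patterns.index].to_numpy(), axis=1),
        index=patterns.index,
        columns=matrix.columns,
    )
    mean_profiles = scaled.groupby(group_of_gene).mean()
    median_profiles = scaled.groupby(group_of_gene).median()
    return DEGGroupTable(group_of_gene, codes_of_group, mean_profiles, median_profiles)


def group_degs(
    matrix: pd.DataFrame,
    results: pd.DataFrame,
    k: int = 12,
    stage_of_sample: dict[str, str] | None = None,
) -> DEGGroupTable:
    """End-to-end: pattern codes -> code clustering -> group table."""
    patterns = pattern_table(results)
    profiles = code_profiles(matrix, patterns)
    mapping = cluster_patterns(profiles, k=k, stage_of_sample=stage_of_sample)
    return summarize_groups(matrix, patterns, mapping)
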