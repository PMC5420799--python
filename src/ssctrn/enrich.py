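"""Over-representation statistics, major-TF selection and overlap testing.

The core statistic is the hypergeometric upper tail P(X >= k) for the
overlap k between a query gene group and an annotated set, with BH FDR
across the sets tested against one query. Two threshold modes mirror common
practice: term mode (raw p < 0.1 and count >= 3) and TF mode (FDR < 0.05 and
count >= 5, defining "major TFs" per group). TFs significant in almost all
groups are treated as promiscuous (non-specific targets) and removed. The
gene-set overlap test draws random query-sized sets from the universe and
reports the resampled upper-tail p of the observed overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust

logger = logging.getLogger(__name__)

#: (significance mode, p-or-fdr threshold, minimum overlap count)
TERM_MODE = ("p", 0.1, 3)
TF_MODE = ("fdr", 0.05, 5)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. TF→targets or term→genes) with provenance."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Intersect every set with the universe, dropping emptied sets."""
        uni = set(universe)
        kept = {
            name: [g for g in members if g in uni]
            for name, members in self.sets.items()
        }
        kept = {name: m for name, m in kept.items() if m}
        return GeneSetCollection(kept, self.provenance)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


def hypergeom_p(k: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(universe, set, query draws)."""
    if not (0 <= k <= min(set_size, query_size) <= universe_size):
        raise ValueError(
            f"inconsistent counts: k={k}, K={set_size}, n={query_size}, N={universe_size}"
        )
    if max(set_size, query_size) > universe_size:
        raise ValueError("set or query larger than the universe")
    return float(stats.hypergeom.sf(k - 1, universe_size, set_size, query_size))


def enrich_collection(
    query,
    collection: GeneSetCollection,
    universe,
    min_count: int = 5,
    alpha: float = 0.05,
    mode: str = "fdr",
) -> pd.DataFrame:
    """Hypergeometric enrichment of every set against one query group.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe. FDR is BH across the sets tested for this
    query. ``mode`` selects the significance column the pass flag uses:
    "fdr" (TF mode) or "p" (term mode).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    restricted = collection.restricted_to(universe)
    names = sorted(restricted.sets)
    rows = []
    for name in names:
        members = set(restricted.sets[name])
        k = len(members & query)
        p = hypergeom_p(k, len(members), len(query), len(universe))
        rows.append((name, k, len(members), len(query), len(universe), p))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    sig = df["fdr"] if mode == "fdr" else df["p"]
    df["passed"] = (sig < alpha) & (df["overlap"] >= min_count)
    return df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)


def enrich_groups(
    group_members: dict[int, list[str]],
    collection: GeneSetCollection,
    universe,
    min_count: int = 5,
    alpha: float = 0.05,
    mode: str = "fdr",
) -> pd.DataFrame:
    """Per-group enrichment: concatenated rows with a ``group`` column."""
    frames = []
    for grp in sorted(group_members):
        members = [g for g in group_members[grp] if g in set(universe)]
        if not members:
            continue
        df = enrich_collection(members, collection, universe, min_count, alpha, mode)
        df.insert(0, "group", grp)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["group", "set", "overlap", "set_size", "query_size",
                     "universe_size", "p", "fdr", "passed"]
        )
    return pd.concat(frames, ignore_index=True)


def filter_promiscuous(
    per_group_rows: pd.DataFrame, max_group_fraction: float = 0.8
) -> list[str]:
    """Retained set names after removing promiscuous regulators.

    A set significant (pass flag) in more than ``max_group_fraction`` of the
    non-empty groups has non-specific targets nearly everywhere and is
    removed (logged).
    """
    if per_group_rows.empty:
        return []
    n_groups = per_group_rows["group"].nunique()
    passed = per_group_rows[per_group_rows["passed"]]
    if n_groups < 2:  # specificity across groups is undefined for one group
        return sorted(set(passed["set"]))
    hits_per_set = passed.groupby("set")["group"].nunique()
    promiscuous = sorted(hits_per_set[hits_per_set > max_group_fraction * n_groups].index)
    if promiscuous:
        logger.info("removing promiscuous sets: %s", ", ".join(promiscuous))
    retained = sorted(set(passed["set"]) - set(promiscuous))
    return retained


def major_tfs(
    group_members: dict[int, list[str]],
    tf_collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    min_count: int = 5,
    max_group_fraction: float = 0.8,
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Major TFs per group (FDR < alpha, count >= min_count, non-promiscuous).

    Returns (group -> major TF names, the full per-group enrichment table).
    """
    rows = enrich_groups(group_members, tf_collection, universe, min_count, alpha, "fdr")
    retained = set(filter_promiscuous(rows, max_group_fraction))
    per_group: dict[int, list[str]] = {}
    for grp in sorted(group_members):
        hits = rows[(rows["group"] == grp) & rows["passed"] & rows["set"].isin(retained)]
        per_group[grp] = sorted(hits["set"])
    return per_group, rows


@dataclass
class TFCatalog:
    """Three-way partition of major TFs and differentially expressed TFs."""

    major: list[str]
    detf: list[str]
    non_de_mtf: list[str] = field(init=False)
    de_mtf: list[str] = field(init=False)
    de_tf: list[str] = field(init=False)

    def __post_init__(self) -> None:
        major, detf = set(self.major), set(self.detf)
        self.non_de_mtf = sorted(major - detf)
        self.de_mtf = sorted(major & detf)
        self.de_tf = sorted(detf - major)

    def counts(self) -> dict[str, int]:
        return {
            "non_de_mtf": len(self.non_de_mtf),
            "de_mtf": len(self.de_mtf),
            "de_tf": len(self.de_tf),
        }


def categorize_tfs(
    major_tf_names, deg_union, tf_universe
) -> TFCatalog:
    """Partition TFs into non-DE-mTFs, DE-mTFs and DE-TFs.

    DETFs are the TFs of the collection whose own gene id is in the DEG
    union; major TFs come from the per-group enrichment.
    """
    degs = set(deg_union)
    detf = sorted(t for t in tf_universe if t in degs)
    return TFCatalog(major=sorted(set(major_tf_names)), detf=detf)


def overlap_permutation_p(
    query,
    signature,
    universe,
    n_samples: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Resampled upper-tail p of the overlap between query and signature.

    Draws ``n_samples`` random sets of the query's size from the universe
    (signature fixed) and reports
    p = (#{draws with overlap >= observed} + 1) / (n_samples + 1).
    """
    if n_samples < 99:
        raise ValueError("n_samples must be >= 99 for a usable p-value floor")
    universe = sorted(set(universe))
    query = set(query)
    signature = set(signature)
    if not query <= set(universe) or not signature <= set(universe):
        raise ValueError("query and signature must be contained in the universe")
    observed = len(query & signature)
    n, N = len(query), len(universe)
    if n == 0:
        return 1.0
    in_sig = np.array([g in signature for g in universe])
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_samples, int(2e7 // max(N, 1))))
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        count += int((in_sig[idx].sum(axis=1) >= observed).sum())
        done += m
    return (count + 1) / (n_samples + 1)
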