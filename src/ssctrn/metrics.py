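"""Recovery metrics against recorded simulation truth.

Recovered temporal-group labels are arbitrary relabelings of the planted
ones, so planted-vs-recovered agreement is measured after a one-to-one
best-overlap matching between planted and recovered group ids.
"""

from __future__ import annotations

import pandas as pd


def match_groups(
    planted: dict[str, int], recovered: pd.Series
) -> tuple[dict[int, int], float]:
    """Greedy one-to-one matching of planted to recovered group ids.

    Returns (planted id -> recovered id, fraction of planted genes whose
    recovered group is the matched one). Planted genes absent from the
    recovered partition count as misassigned.
    """
    overlap: dict[tuple[int, int], int] = {}
    planted_sizes: dict[int, int] = {}
    for gene, p_grp in planted.items():
        if p_grp == 0:
            continue
        planted_sizes[p_grp] = planted_sizes.get(p_grp, 0) + 1
        if gene in recovered.index:
            r_grp = int(recovered.loc[gene])
            overlap[(p_grp, r_grp)] = overlap.get((p_grp, r_grp), 0) + 1
    pairs = sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for (p_grp, r_grp), _count in pairs:
        if p_grp not in mapping and r_grp not in used:
            mapping[p_grp] = r_grp
            used.add(r_grp)
    n_total = sum(planted_sizes.values())
    n_correct = sum(
        count for (p_grp, r_grp), count in overlap.items()
        if mapping.get(p_grp) == r_grp
    )
    rate = n_correct / n_total if n_total else float("nan")
    return mapping, rate


def precision_recall(recovered, truth) -> tuple[float, float]:
    """Precision and recall of a recovered gene set against the planted one."""
    rec, tru = set(recovered), set(truth)
    precision = len(rec & tru) / len(rec) if rec else float("nan")
    recall = len(rec & tru) / len(tru) if tru else float("nan")
    return precision, recall
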