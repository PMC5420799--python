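"""Synthetic data with recorded ground truth for every pipeline input.

Three generators emulate the study design end to end:

* ``simulate_expression`` — a three-stage (SSC / iSSC / mSSC) log2 expression
  matrix with 3/2/3 replicates, genes planted into any of 12 temporal
  patterns (gradual, early, late, and partially / completely / excessively
  restored changes, up and down), null genes flat across stages, and an
  unexpressed baseline mode so the mixture-model filter has work to do.
* ``simulate_timecourses`` — per-line embryoid-body differentiation
  fold-change courses (10 time points, 3 lines by default) with planted
  pluripotency (down) and differentiation (up) signature genes.
* ``simulate_tf_network`` — TF→target collections with planted enrichment of
  chosen TFs' targets inside chosen temporal groups.

The noise model is independent Gaussian on the log2 scale per gene × sample,
keeping every planted expectation closed-form. A single master seed
deterministically derives per-component substreams, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection

STAGES = ("SSC", "iSSC", "mSSC")

#: per-stage expected offsets of each temporal group, in units of effect_size.
#: Odd rows 1..6 are up-patterns; 7..12 mirror them down. "Partial" and
#: "excessive" restoration move half an effect back / past the baseline.
GROUP_STAGE_OFFSETS: dict[int, tuple[float, float, float]] = {
    1: (0.0, 0.5, 1.0),    # gradual increase
    2: (0.0, 1.0, 1.0),    # early increase, maintained
    3: (0.0, 0.0, 1.0),    # late increase
    4: (0.0, 1.0, 0.5),    # early increase, partially restored
    5: (0.0, 1.0, 0.0),    # early increase, completely restored
    6: (0.0, 1.0, -0.5),   # early increase, excessively restored
    7: (0.0, -0.5, -1.0),  # gradual decrease
    8: (0.0, -1.0, -1.0),  # early decrease, maintained
    9: (0.0, 0.0, -1.0),   # late decrease
    10: (0.0, -1.0, -0.5),  # early decrease, partially restored
    11: (0.0, -1.0, 0.0),   # early decrease, completely restored
    12: (0.0, -1.0, 0.5),   # early decrease, excessively restored
}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the three-stage expression simulation.

    noise_sd is the within-replicate SD of log2 intensity; effect_size the
    mean log2 shift of a fully changed stage; baseline_mean/expressed_mean
    are the centers of the unexpressed and expressed intensity modes, and
    between_gene_sd spreads per-gene baselines around their mode — real
    log-intensity distributions span several log2 units, and without that
    spread rank-based normalization would distort planted changes far more
    than it does on real arrays.
    """

    n_genes: int = 2000
    replicates_per_stage: tuple[int, int, int] = (3, 2, 3)
    group_fractions: dict[int, float] = field(default_factory=dict)
    effect_size: float = 1.5
    noise_sd: float = 0.3
    baseline_mean: float = 6.0
    expressed_mean: float = 10.0
    between_gene_sd: float = 1.0
    unexpressed_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be positive")
        if len(self.replicates_per_stage) != 3 or any(
            r < 1 for r in self.replicates_per_stage
        ):
            raise InvalidConfigError("replicates_per_stage must be three positive counts")
        for g, f in self.group_fractions.items():
            if g not in GROUP_STAGE_OFFSETS:
                raise InvalidConfigError(f"unknown temporal group id {g}")
            if not (0.0 <= f <= 1.0):
                raise InvalidConfigError(f"group fraction out of [0,1]: {f}")
        if sum(self.group_fractions.values()) > 1.0 + 1e-12:
            raise InvalidConfigError("group fractions must sum to <= 1")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if self.expressed_mean <= self.baseline_mean:
            raise InvalidConfigError("expressed_mean must exceed baseline_mean")
        if self.between_gene_sd < 0:
            raise InvalidConfigError("between_gene_sd must be >= 0")
        if not (0.0 <= self.unexpressed_fraction <= 1.0):
            raise InvalidConfigError("unexpressed_fraction must lie in [0,1]")


@dataclass
class SimulationTruth:
    """Recorded planted structure; the reference for every recovery test."""

    group_of_gene: dict[str, int] = field(default_factory=dict)  # 0 = null gene
    expressed: dict[str, bool] = field(default_factory=dict)
    tf_targets: dict[str, list[str]] = field(default_factory=dict)
    planted_tfs: list[str] = field(default_factory=list)
    signature_of_gene: dict[str, str] = field(default_factory=dict)  # pluripotency/differentiation/none

    def planted_genes(self, group: int | None = None) -> list[str]:
        if group is None:
            return sorted(g for g, grp in self.group_of_gene.items() if grp != 0)
        return sorted(g for g, grp in self.group_of_gene.items() if grp == group)

    def signature_genes(self, which: str) -> list[str]:
        return sorted(g for g, s in self.signature_of_gene.items() if s == which)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.group_of_gene) | set(self.expressed) | set(self.signature_of_gene))
        return pd.DataFrame(
            {
                "gene": genes,
                "group": [self.group_of_gene.get(g, 0) for g in genes],
                "expressed": [int(self.expressed.get(g, True)) for g in genes],
                "signature": [self.signature_of_gene.get(g, "none") for g in genes],
            }
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(replicates_per_stage) -> tuple[list[str], dict[str, str]]:
    samples, stage_map = [], {}
    for stage, n_rep in zip(STAGES, replicates_per_stage):
        for r in range(1, n_rep + 1):
            name = f"{stage}_{r}"
            samples.append(name)
            stage_map[name] = stage
    return samples, stage_map


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], SimulationTruth]:
    """Generate the three-stage log2 expression matrix.

    Returns (matrix, stage_of_sample, truth). Genes planted in group g follow
    that group's expected stage offsets scaled by effect_size; null genes are
    flat; unexpressed genes sit at the baseline mode in all stages.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_base, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    genes = _gene_ids(config.n_genes)
    samples, stage_map = _sample_ids(config.replicates_per_stage)

    order = rng_assign.permutation(config.n_genes)
    group_of_gene = {g: 0 for g in genes}
    cursor = 0
    for grp in sorted(config.group_fractions):
        count = int(round(config.group_fractions[grp] * config.n_genes))
        for idx in order[cursor : cursor + count]:
            group_of_gene[genes[idx]] = grp
        cursor += count
    null_idx = order[cursor:]
    n_unexpressed = int(round(config.unexpressed_fraction * len(null_idx)))
    unexpressed = {genes[i] for i in null_idx[:n_unexpressed]}
    expressed = {g: g not in unexpressed for g in genes}

    stage_index = np.array([STAGES.index(stage_map[s]) for s in samples])
    base = np.array(
        [config.expressed_mean if expressed[g] else config.baseline_mean for g in genes]
    )
    base = base + rng_base.normal(0.0, config.between_gene_sd, size=base.shape)
    offsets = np.zeros((config.n_genes, len(STAGES)))
    for i, g in enumerate(genes):
        grp = group_of_gene[g]
        if grp:
            offsets[i] = np.asarray(GROUP_STAGE_OFFSETS[grp]) * config.effect_size
    mean = base[:, None] + offsets[:, stage_index]
    values = mean + rng_noise.normal(0.0, config.noise_sd, size=mean.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    truth = SimulationTruth(group_of_gene=group_of_gene, expressed=expressed)
    return matrix, stage_map, truth


@dataclass
class SignatureSpec:
    """Planted signature composition of a differentiation time course."""

    frac_pluripotency: float = 0.1
    frac_differentiation: float = 0.1
    terminal_log2fc: float = 2.0

    def __post_init__(self) -> None:
        for f in (self.frac_pluripotency, self.frac_differentiation):
            if not (0.0 <= f <= 1.0):
                raise InvalidConfigError(f"signature fraction out of [0,1]: {f}")
        if self.frac_pluripotency + self.frac_differentiation > 1.0 + 1e-12:
            raise InvalidConfigError("signature fractions must sum to <= 1")
        if self.terminal_log2fc <= 0:
            raise InvalidConfigError("terminal_log2fc must be positive")


def simulate_timecourses(
    n_genes: int,
    n_lines: int = 3,
    timepoints: int = 10,
    signature_spec: SignatureSpec | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    pluripotency_genes: list[str] | None = None,
    differentiation_genes: list[str] | None = None,
) -> tuple[list[pd.DataFrame], SimulationTruth]:
    """Generate per-line log2 fold-change courses with planted signatures.

    Planted pluripotency genes ramp down linearly to -terminal_log2fc by the
    last time point in every line; differentiation genes mirror upward; null
    genes fluctuate around zero. All lines share gene identifiers. Explicit
    ``pluripotency_genes`` / ``differentiation_genes`` lists (must be among
    the generated gene ids and disjoint) override the random fraction-based
    assignment — this lets planted signatures coincide with planted temporal
    groups of a matched expression simulation.
    """
    if timepoints < 2:
        raise InvalidConfigError("timepoints must be >= 2")
    if n_lines < 1:
        raise InvalidConfigError("n_lines must be >= 1")
    if noise_sd <= 0:
        raise InvalidConfigError("noise_sd must be > 0")
    spec = signature_spec or SignatureSpec()
    ss = np.random.SeedSequence(seed)
    rng_assign, *rng_lines = (np.random.default_rng(s) for s in ss.spawn(1 + n_lines))
    genes = _gene_ids(n_genes)
    signature_of_gene = {g: "none" for g in genes}
    if pluripotency_genes is not None or differentiation_genes is not None:
        down = list(pluripotency_genes or [])
        up = list(differentiation_genes or [])
        unknown = (set(down) | set(up)) - set(genes)
        if unknown:
            raise InvalidConfigError(f"planted genes not among generated ids: {sorted(unknown)[:5]}")
        if set(down) & set(up):
            raise InvalidConfigError("planted signature lists must be disjoint")
        for g in down:
            signature_of_gene[g] = "pluripotency"
        for g in up:
            signature_of_gene[g] = "differentiation"
    else:
        order = rng_assign.permutation(n_genes)
        n_down = int(round(spec.frac_pluripotency * n_genes))
        n_up = int(round(spec.frac_differentiation * n_genes))
        for idx in order[:n_down]:
            signature_of_gene[genes[idx]] = "pluripotency"
        for idx in order[n_down : n_down + n_up]:
            signature_of_gene[genes[idx]] = "differentiation"

    ramp = np.arange(1, timepoints + 1) / timepoints  # reaches 1 at the terminal point
    sign = np.array(
        [
            {"none": 0.0, "pluripotency": -1.0, "differentiation": 1.0}[signature_of_gene[g]]
            for g in genes
        ]
    )
    expectation = sign[:, None] * spec.terminal_log2fc * ramp[None, :]
    columns = [f"t{t}" for t in range(1, timepoints + 1)]
    matrices = [
        pd.DataFrame(
            expectation + rng.normal(0.0, noise_sd, size=expectation.shape),
            index=genes,
            columns=columns,
        )
        for rng in rng_lines
    ]
    truth = SimulationTruth(signature_of_gene=signature_of_gene)
    return matrices, truth


def simulate_tf_network(
    n_tfs: int,
    targets_per_tf: int,
    planted_enrichment: dict[str, tuple[int, float]],
    universe: list[str],
    group_members: dict[int, list[str]] | None = None,
    seed: int = 0,
    tf_names: list[str] | None = None,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Generate a TF→target collection with planted group enrichment.

    ``planted_enrichment`` maps a TF name (must be among the TF names) to
    (group id, fraction of its targets drawn from that group's genes, per
    ``group_members``); all remaining targets are drawn uniformly from the
    rest of the universe. By default TFs are named TF01..TFnn; passing
    ``tf_names`` (length n_tfs, unique — e.g. gene ids from the expression
    matrix) lets TFs be differentially expressed genes themselves.
    """
    if targets_per_tf > len(universe):
        raise InvalidConfigError("requested targets exceed the universe size")
    group_members = group_members or {}
    if tf_names is None:
        width = max(2, len(str(n_tfs)))
        tf_names = [f"TF{i:0{width}d}" for i in range(1, n_tfs + 1)]
    if len(tf_names) != n_tfs or len(set(tf_names)) != n_tfs:
        raise InvalidConfigError("tf_names must be n_tfs unique names")
    for tf, (grp, frac) in planted_enrichment.items():
        if tf not in tf_names:
            raise InvalidConfigError(f"planted TF {tf!r} not among generated TFs")
        if grp not in group_members:
            raise InvalidConfigError(f"planted group {grp} has no member list")
        if not (0.0 <= frac <= 1.0):
            raise InvalidConfigError(f"planted fraction out of [0,1]: {frac}")
        if int(round(frac * targets_per_tf)) > len(group_members[grp]):
            raise InvalidConfigError("requested group targets exceed the group size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    for tf in tf_names:
        if tf in planted_enrichment:
            grp, frac = planted_enrichment[tf]
            n_in = int(round(frac * targets_per_tf))
            pool_in = list(group_members[grp])
            chosen = list(rng.choice(pool_in, size=n_in, replace=False))
            pool_out = [g for g in universe if g not in set(chosen)]
            chosen += list(rng.choice(pool_out, size=targets_per_tf - n_in, replace=False))
        else:
            chosen = list(rng.choice(universe, size=targets_per_tf, replace=False))
        sets[tf] = sorted(chosen)
    collection = GeneSetCollection(sets=sets, provenance="simulated TF targets")
    truth = SimulationTruth(
        tf_targets={tf: list(m) for tf, m in sets.items()},
        planted_tfs=sorted(planted_enrichment),
    )
    return collection, truth
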