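"""Synthetic expression data with planted regulator -> target structure.

The generator emulates a two-group perturbation experiment: one (or more)
"planted" regulator is shifted upward by beta expression units in the case
samples, and each of its targets follows the regulator linearly
(target = gamma * regulator + noise), which induces both differential
expression of the targets and a regulator-target correlation of about
gamma * sd_r / sqrt(gamma^2 sd_r^2 + noise_sd^2).  Decoy regulators are
pure independent noise and draw their target sets from the same gene
universe as the planted ones, so neither the case/control split nor the
interaction structure alone can single a regulator out.  All draws are
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, RTICollection

__all__ = ["SimulationConfig", "GroundTruth", "simulate"]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror a modest two-group microarray-scale experiment: 2000
    genes, 100 regulators with 25 targets each, 10 case vs 10 control
    samples, one planted regulator with a case shift of beta = 2 expression
    units and linear coupling gamma = 2 at unit noise.
    """

    n_genes: int = 2000
    n_regulators: int = 100
    targets_per_regulator: int = 25
    n_case: int = 10
    n_control: int = 10
    n_planted: int = 1
    beta: float = 2.0
    gamma: float = 2.0
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_regulators, self.targets_per_regulator) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_planted <= self.n_regulators:
            raise ValueError("n_planted must lie in [0, n_regulators]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted * self.targets_per_regulator > self.n_genes:
            raise ValueError(
                "planted target sets (drawn disjointly without replacement) "
                "exceed the gene universe"
            )
        if self.targets_per_regulator > self.n_genes:
            raise ValueError("target sets cannot be drawn without replacement")


@dataclass
class GroundTruth:
    """What was planted: regulator ids, their targets and the expected
    case-minus-control shift of every affected row."""

    planted_regulators: list[str]
    target_sets: dict[str, list[str]]
    expected_shift: dict[str, float] = field(default_factory=dict)


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, RTICollection, GroundTruth]:
    """Generate (expression matrix, RTI collection, ground truth).

    The matrix holds one row per gene plus one per regulator; case columns
    come first.  Null rows are i.i.d. Normal(0, noise_sd).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    regs = [f"R{i:04d}" for i in range(1, config.n_regulators + 1)]
    planted = regs[: config.n_planted]
    m = config.n_case + config.n_control
    case_idx = np.arange(config.n_case)

    # target sets: planted sets mutually disjoint (clean ground-truth
    # attribution); decoys draw without replacement within each set from the
    # full gene universe, so target-set structure cannot single out the
    # planted regulator
    planted_pool = rng.choice(
        config.n_genes, size=config.n_planted * config.targets_per_regulator, replace=False
    )
    target_sets: dict[str, list[str]] = {}
    for i, reg in enumerate(planted):
        sel = planted_pool[i * config.targets_per_regulator : (i + 1) * config.targets_per_regulator]
        target_sets[reg] = [genes[j] for j in sorted(sel)]
    for reg in regs[config.n_planted :]:
        sel = rng.choice(config.n_genes, size=config.targets_per_regulator, replace=False)
        target_sets[reg] = [genes[j] for j in sorted(sel)]

    gene_rows = rng.normal(0.0, config.noise_sd, size=(config.n_genes, m))
    reg_rows = rng.normal(0.0, config.noise_sd, size=(config.n_regulators, m))
    expected: dict[str, float] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    for i, reg in enumerate(regs):
        if reg in planted:
            reg_rows[i, case_idx] += config.beta
            expected[reg] = config.beta
            for g in target_sets[reg]:
                gene_rows[gene_index[g]] = (
                    config.gamma * reg_rows[i]
                    + rng.normal(0.0, config.noise_sd, size=m)
                )
                expected[g] = config.gamma * config.beta

    values = np.vstack([gene_rows, reg_rows])
    sample_ids = [f"case{i + 1}" for i in range(config.n_case)] + [
        f"ctrl{i + 1}" for i in range(config.n_control)
    ]
    groups = {s: ("case" if i < config.n_case else "control") for i, s in enumerate(sample_ids)}
    expr = ExpressionMatrix(
        gene_ids=genes + regs,
        sample_ids=sample_ids,
        values=values,
        groups=groups,
        case_group="case",
    )
    rti = RTICollection(forward={r: list(t) for r, t in target_sets.items()})
    truth = GroundTruth(
        planted_regulators=list(planted),
        target_sets={r: list(target_sets[r]) for r in planted},
        expected_shift=expected,
    )
    return expr, rti, truth


def write_simulation(prefix, expr: ExpressionMatrix, rti: RTICollection, truth: GroundTruth) -> dict:
    """Write expression TSV, groups TSV, RTI GMT and truth TSV under a prefix;
    returns the path map."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": prefix.with_suffix(".expression.tsv"),
        "groups": prefix.with_suffix(".groups.tsv"),
        "rti": prefix.with_suffix(".rti.gmt"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    expr.to_dataframe().to_csv(paths["expression"], sep="\t", index_label="gene")
    with paths["groups"].open("w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.groups[s]}\n")
    with paths["rti"].open("w") as fh:
        for reg in rti.regulators:
            fh.write("\t".join([reg, "na", *rti.targets_of(reg)]) + "\n")
    with paths["truth"].open("w") as fh:
        fh.write("regulator\ttargets\n")
        for reg in truth.planted_regulators:
            fh.write(f"{reg}\t{','.join(truth.target_sets[reg])}\n")
    return paths
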