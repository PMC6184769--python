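"""Model/Results facade over the full analysis pipeline.

``ReggaeModel`` couples an expression matrix with an RTI collection and the
analysis options; ``fit`` runs differential-expression scoring, the
correlation-ranked enrichment analysis (with bootstrap) for one or several
gene-list sizes, and the multi-list aggregation, returning a
``ReggaeResults`` object that carries the per-size tables, the consensus
ranking, swap traces and a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregation as agg
from .data import ExpressionMatrix, ResultTable, RTICollection, read_expression, read_rti, write_results
from .diffexp import score_genes, select_gene_list
from .enrichment import ReggaeConfig
from .uncertainty import bootstrap_reggae

__all__ = ["ReggaeModel", "ReggaeResults"]


class ReggaeModel:
    """Regulator prioritisation from two-group expression data.

    Parameters
    ----------
    expression : ExpressionMatrix
    rti : RTICollection
    de_method : differential-expression scoring method (Step 1).
    direction : analyse "up"- or "down"-regulated genes.
    correlation, sort_mode : Step 2 options (Pearson/Spearman; absolute or
        signed correlation sort).
    test : "wrs" or "ks" (Step 4).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        rti: RTICollection,
        *,
        de_method: str = "shrinkage_t",
        direction: str = "up",
        correlation: str = "pearson",
        sort_mode: str = "absolute",
        test: str = "wrs",
        min_occurrences: int = 1,
        exact_threshold: int = 1_000_000,
    ) -> None:
        self.expression = expression
        self.rti = rti
        self.de_method = de_method
        self.direction = direction
        self.config = ReggaeConfig(
            test=test,
            correlation=correlation,
            sort_mode=sort_mode,
            min_occurrences=min_occurrences,
            exact_threshold=exact_threshold,
        )

    @classmethod
    def from_files(
        cls,
        matrix_path,
        groups_path,
        rti_path,
        rti_format: str = "gmt",
        case_group: str | None = None,
        **kwargs,
    ) -> "ReggaeModel":
        expr = read_expression(matrix_path, groups_path, case_group=case_group)
        rti = read_rti(rti_path, format=rti_format)
        return cls(expr, rti, **kwargs)

    def fit(
        self,
        top_k: int | tuple[int, ...] | list[int] | None = (250, 500, 750, 1000),
        p_threshold: float | None = None,
        bootstrap: int = 100,
        seed: int | None = None,
        ci_level: float = 0.95,
        ci_method: str | None = "bca",
        swap_trace: bool = False,
        aggregate: bool = True,
    ) -> "ReggaeResults":
        """Run the full analysis; one table per requested list size.

        ``top_k`` may be a single size or a sequence (the recommended
        size sweep); ``p_threshold`` adds one more list of all genes with
        p below the threshold.  With >= 2 lists and ``aggregate=True`` the
        consensus ranking is computed as well.
        """
        scores = score_genes(self.expression, method=self.de_method)
        sizes: list[int] = []
        if top_k is not None:
            sizes = [top_k] if isinstance(top_k, int) else list(top_k)
        selectors: list[tuple[str, dict]] = [
            (f"top{k}", {"top_k": k}) for k in sizes
        ]
        if p_threshold is not None:
            selectors.append((f"p<{p_threshold:g}", {"p_threshold": p_threshold}))
        if not selectors:
            raise ValueError("no gene list requested (top_k and p_threshold both empty)")

        tables: dict[str, ResultTable] = {}
        for i, (label, sel) in enumerate(selectors):
            gene_list = select_gene_list(
                scores, direction=self.direction, method=self.de_method, **sel
            )
            sub_seed = None if seed is None else (seed + i) % (2**31)
            tables[label] = bootstrap_reggae(
                self.expression,
                gene_list,
                self.rti,
                config=self.config,
                B=bootstrap,
                seed=sub_seed,
                alpha=1.0 - ci_level,
                ci_method=ci_method,
                swap_trace=swap_trace,
            )
        aggregated = None
        if aggregate and len(tables) >= 2:
            aggregated = agg.aggregate(list(tables.values()))
        return ReggaeResults(model=self, scores=scores, tables=tables, aggregated=aggregated)


@dataclass
class ReggaeResults:
    """Fitted results: per-size tables, optional consensus, diagnostics."""

    model: ReggaeModel
    scores: pd.DataFrame
    tables: dict[str, ResultTable]
    aggregated: pd.DataFrame | None = None
    _swap_traces: dict[str, list[int]] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        for label, t in self.tables.items():
            if "swap_trace" in t.metadata:
                self._swap_traces[label] = t.metadata["swap_trace"]

    @property
    def swap_traces(self) -> dict[str, list[int]]:
        return self._swap_traces

    def table(self, label: str | None = None) -> ResultTable:
        if label is None:
            label = next(iter(self.tables))
        return self.tables[label]

    def top_regulators(self, n: int = 10, label: str | None = None) -> pd.DataFrame:
        if self.aggregated is not None and label is None:
            return self.aggregated.head(n)
        return self.table(label).table.head(n)

    def summary(self, n: int = 10) -> str:
        """Human-readable report of the run and its top regulators."""
        lines = ["Regulator-gene association enrichment", "=" * 38]
        cfg = self.model.config
        first = next(iter(self.tables.values()))
        lines.append(
            f"test: {cfg.test}   correlation: {cfg.correlation} ({cfg.sort_mode})   "
            f"DE method: {self.model.de_method} ({self.model.direction})"
        )
        lines.append(
            f"samples: {self.model.expression.n_samples}   "
            f"bootstrap replicates: {first.metadata.get('B')}"
        )
        for label, t in self.tables.items():
            lines.append(
                f"\n[{label}] {len(t)} regulators tested "
                f"(N={t.metadata.get('N')}, untested={t.metadata.get('n_untested')})"
            )
            sub = t.table.head(n)[
                ["rank", "regulator", "n_occurrences", "p_median", "mean_signed_correlation", "direction"]
            ]
            lines.append(sub.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        if self.aggregated is not None:
            lines.append(f"\n[aggregated over {len(self.tables)} lists]")
            cols = ["rank", "regulator", "rank_sum", "p_max", "p_max_adjusted", "n_lists_present"]
            lines.append(
                self.aggregated.head(n)[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}")
            )
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, Path]:
        """Write each per-size table (and the aggregate) as TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for label, t in self.tables.items():
            safe = label.replace("<", "lt")
            path = out_dir / f"results_{safe}.tsv"
            write_results(t, path)
            paths[label] = path
        if self.aggregated is not None:
            path = out_dir / "results_aggregated.tsv"
            self.aggregated.to_csv(path, sep="\t", index=False, float_format="%.8g")
            paths["aggregated"] = path
        return paths
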