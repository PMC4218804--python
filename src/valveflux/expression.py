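"""Differential expression on log2 data and the gene→reaction fold-change map.

Inputs are already log2-normalized gene-level values (microarray-style);
per gene a two-sided two-sample t-test compares mutant to wild-type samples
and the fold change is ``mean(MUT) − mean(WT)`` on the log2 scale, so a
negative value means down-regulated in the mutant.  Significance is a raw
p-value threshold (default 0.01) — no multiple-testing correction by
default, though a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import MetabolicModel, genes_to_reactions

logger = logging.getLogger(__name__)

WT = "WT"
MUT = "MUT"
DEFAULT_ALPHA = 0.01


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with WT/MUT group labels."""

    values: pd.DataFrame  # rows: genes, columns: samples
    groups: pd.Series  # sample -> "WT" | "MUT"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group labels: {missing}")
        bad = set(self.groups.unique()) - {WT, MUT}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected WT/MUT")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_expression_tsv(expression_path: str, samples_path: str) -> ExpressionMatrix:
    """Read the expression TSV (first column gene id, rest samples) and the
    two-column sample sheet (sample id, group)."""
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(sheet.iloc[:, 1].values, index=sheet.iloc[:, 0].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, expression_path: str, samples_path: str) -> None:
    matrix.values.to_csv(expression_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": matrix.groups.index, "group": matrix.groups.values}).to_csv(
        samples_path, sep="\t", index=False
    )


@dataclass
class DEResult:
    """One gene's differential-expression call."""

    gene: str
    fold_change: float  # log2(MUT mean) - log2(WT mean)
    p_value: float
    significant_down: bool
    degenerate: bool = False  # zero pooled variance


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    fdr: bool = False,
) -> list[DEResult]:
    """Per-gene two-sided two-sample t-test of MUT vs WT log2 values.

    Student's pooled-variance test by default (the classic microarray-era
    choice); ``welch=True`` switches to the unequal-variance form.  Genes
    with zero pooled variance get p = 0 if the group means differ and p = 1
    otherwise, flagged ``degenerate``.  ``fdr=True`` applies
    Benjamini-Hochberg to the p-values before thresholding.
    """
    wt_cols = matrix.samples_in(WT)
    mut_cols = matrix.samples_in(MUT)
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError(
            f"need >=2 samples per group for testing, got WT={len(wt_cols)}, MUT={len(mut_cols)}"
        )
    wt = matrix.values[wt_cols].to_numpy()
    mut = matrix.values[mut_cols].to_numpy()
    fc = mut.mean(axis=1) - wt.mean(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        tres = stats.ttest_ind(mut, wt, axis=1, equal_var=not welch)
    p = np.asarray(tres.pvalue, dtype=float)
    degenerate = (wt.var(axis=1) + mut.var(axis=1)) == 0
    p = np.where(degenerate, np.where(np.abs(fc) > 0, 0.0, 1.0), p)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    return [
        DEResult(
            gene=g,
            fold_change=float(fc[i]),
            p_value=float(p[i]),
            significant_down=bool(p[i] < alpha and fc[i] < 0),
            degenerate=bool(degenerate[i]),
        )
        for i, g in enumerate(matrix.values.index)
    ]


def significant_down(results: list[DEResult], alpha: float = DEFAULT_ALPHA) -> set[str]:
    """Genes with p < alpha (strict) and negative fold change."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return {r.gene for r in results if r.p_value < alpha and r.fold_change < 0}


def assign_reaction_fold_changes(
    model: MetabolicModel,
    results: list[DEResult],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, float]:
    """Down-regulated gene set → per-reaction log2 fold change.

    Every reaction touched (via GPR leaves) by at least one significant down
    gene receives the most negative fold change among those genes — the
    conservative valve when several down genes share a reaction.  Reactions
    untouched are absent from the map.
    """
    down = significant_down(results, alpha)
    fc_by_gene = {r.gene: r.fold_change for r in results}
    mapping = genes_to_reactions(model, sorted(down))
    out: dict[str, float] = {}
    for gene, rxns in mapping.items():
        for rid in rxns:
            fc = fc_by_gene[gene]
            out[rid] = min(out.get(rid, 0.0), fc)
    return out


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "log2FC": r.fold_change,
                "p": r.p_value,
                "significant_down": r.significant_down,
            }
            for r in results
        ]
    ).set_index("gene")
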