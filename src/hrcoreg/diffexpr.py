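"""Rank-based Welch differential expression with Bonferroni correction.

Per gene, counts are rank-transformed across *all* samples pooled (average
ranks for ties), then a two-tailed Welch t-test compares the two groups'
rank subsets. P-values are Bonferroni-corrected over the number of genes
tested; a gene is called significant when the corrected p is below 0.05.
The log2 fold change is the ratio of group arithmetic means of the
normalized counts (tumor over normal). Pathway labels merge the Homologous
Recombination and Fanconi Anemia pathways into one HR group.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (
    ENDOGENOUS, FALLOPIAN_TUBE, HOUSEKEEPING, TUMOR, CountMatrix,
)

HR_PATHWAY_TOKENS = ("Homologous Recombination", "Fanconi Anemia")


class DiffExprError(ValueError):
    pass


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with average ranks for ties."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DiffExprError("need >= 2 values to rank")
    return stats.rankdata(values, method="average")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    flag: str = ""


def welch_on_ranks(
    group_a: Sequence[float], group_b: Sequence[float]
) -> WelchResult:
    """Welch's unequal-variance t-test on (already ranked) values.

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch–Satterthwaite degrees of freedom and a two-tailed Student-t
    p-value. Degenerate cases: zero variance in both groups with equal
    means gives p = 1 by convention; zero variance with unequal means gives
    the p = 0 limit, flagged ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DiffExprError("each group needs >= 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        return WelchResult(
            t=float(np.copysign(np.inf, diff)),
            df=float(a.size + b.size - 2), p=0.0, flag="degenerate",
        )
    se2 = va / a.size + vb / b.size
    t = diff / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def differential_expression(
    matrix: CountMatrix,
    samples: pd.DataFrame,
    group_col: str = "group",
    test_group: str = TUMOR,
    reference_group: str = FALLOPIAN_TUBE,
    alpha: float = 0.05,
    probe_classes: tuple[str, ...] = (ENDOGENOUS, HOUSEKEEPING),
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene rank-based Welch test between two sample groups.

    Housekeeping genes are tested (and corrected) alongside the endogenous
    genes by default; the Bonferroni multiplier is the number of genes
    actually tested unless ``bonferroni_m`` overrides it. Returns a table
    sorted by corrected p with columns gene, pathway, log2fc, t, df, p,
    p_bonferroni, significant, direction, flag. A gene whose group mean is
    nonpositive has an undefined log2fc, recorded as NaN with a flag.
    """
    test_ids = samples.index[samples[group_col] == test_group]
    ref_ids = samples.index[samples[group_col] == reference_group]
    test_ids = matrix.values.columns.intersection(test_ids)
    ref_ids = matrix.values.columns.intersection(ref_ids)
    if len(test_ids) == 0 or len(ref_ids) == 0:
        raise DiffExprError("both groups must be nonempty")

    genes = matrix.values.index[matrix.probe_class.isin(probe_classes)]
    m = bonferroni_m if bonferroni_m is not None else len(genes)
    sub = matrix.values.loc[genes, list(test_ids) + list(ref_ids)]
    n_test = len(test_ids)

    records = []
    for gene, row in sub.iterrows():
        ranks = rank_transform(row.to_numpy())
        res = welch_on_ranks(ranks[:n_test], ranks[n_test:])
        mean_t = row.iloc[:n_test].mean()
        mean_r = row.iloc[n_test:].mean()
        flag = res.flag
        if mean_t > 0 and mean_r > 0:
            log2fc = float(np.log2(mean_t / mean_r))
        else:
            log2fc = float("nan")
            flag = (flag + ";" if flag else "") + "nonpositive_group_mean"
        p_bonf = min(1.0, res.p * m)
        records.append({
            "gene": gene,
            "pathway": matrix.annotation.loc[gene].get("pathway", ""),
            "log2fc": log2fc,
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "p_bonferroni": p_bonf,
            "significant": bool(p_bonf < alpha),
            # direction follows the fold change so the two columns agree
            "direction": (
                "up" if log2fc > 0 else ("down" if log2fc < 0 else "")
            ) if np.isfinite(log2fc) else "",
            "flag": flag,
        })
    out = pd.DataFrame(records).sort_values(
        ["p_bonferroni", "p", "gene"], kind="mergesort"
    )
    return out.reset_index(drop=True)


# -- pathway classification ------------------------------------------------

def is_hr_pathway(label: str) -> bool:
    return any(tok in str(label) for tok in HR_PATHWAY_TOKENS)


class PathwayMap:
    """Gene -> pathway label(s), with the merged HR + Fanconi Anemia group.

    Labels containing either "Homologous Recombination" or "Fanconi Anemia"
    classify the gene into the HR group.
    """

    def __init__(self, mapping: dict[str, tuple[str, ...]]):
        self._map = {g: tuple(labels) for g, labels in mapping.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_col="gene",
                   pathway_col="pathway") -> "PathwayMap":
        mapping: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row[gene_col]), []).append(
                str(row[pathway_col])
            )
        return cls({g: tuple(v) for g, v in mapping.items()})

    @classmethod
    def from_csv(cls, path) -> "PathwayMap":
        return cls.from_frame(pd.read_csv(path))

    def classify(self, gene: str) -> tuple[tuple[str, ...], bool]:
        """Return ``(labels, is_hr)``; unknown genes raise KeyError."""
        if gene not in self._map:
            raise KeyError(f"gene {gene!r} not in pathway map")
        labels = self._map[gene]
        return labels, any(is_hr_pathway(lb) for lb in labels)

    def __contains__(self, gene: str) -> bool:
        return gene in self._map


def load_de_gene_table() -> pd.DataFrame:
    """The packaged differential-expression gene table (72 genes).

    Transcribed from the published pathway-by-gene listing: columns
    direction (up/down), pathway, gene, symbol_note. Combined probe entries
    (CHEK1/2) are expanded to one row per gene; apparent typographical
    symbols (RM12, SF3FA3) are preserved verbatim with a note.
    """
    ref = importlib.resources.files("hrcoreg.data") / "de_genes_table.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False)
    return df


def upregulated_hr_genes(table: Optional[pd.DataFrame] = None) -> list[str]:
    """HR-pathway genes upregulated in tumors, from the packaged table."""
    t = table if table is not None else load_de_gene_table()
    mask = (t["direction"] == "up") & t["pathway"].map(is_hr_pathway)
    return list(t.loc[mask, "gene"])
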