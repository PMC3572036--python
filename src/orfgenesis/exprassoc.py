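"""Expression-matrix association screens for a focal gene.

Given a genes x samples expression matrix, this module correlates a focal
gene's profile against every other gene (with percentile ranking of a chosen
partner among all correlates), compares expression between sample groups
with one-tailed Welch t-tests, and fits 2x2 factorial ANOVAs (type-II sums
of squares) for paired-treatment designs.  Percentiles rank by descending
signed correlation, so a partner at the 1st percentile is among the focal
gene's strongest positive correlates; no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with per-sample annotations.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``annotations``: DataFrame indexed by sample id (group labels and/or
    binary treatment factors); optional for correlation-only analyses.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()][:3]
            raise ValueError(f"duplicate gene ids: {list(dupes)}")
        if self.annotations is not None:
            missing = set(self.values.columns) - set(self.annotations.index)
            if missing:
                raise ValueError(f"unannotated samples: {sorted(missing)[:3]}")

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, matrix_path, annotations_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        ann = (pd.read_csv(annotations_path, sep="\t", index_col=0)
               if annotations_path else None)
        return cls(values, ann)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p-value.

    p follows t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(matrix: ExpressionMatrix, focal_gene: str) -> pd.DataFrame:
    """Correlate the focal gene against every other gene.

    Returns a DataFrame (index: gene) with columns r, p, percentile, sorted
    by descending r.  Constant genes get r = 0 (no linear association is
    measurable) and p = 1.
    """
    focal = matrix.gene(focal_gene)
    rows = []
    for gene_id in matrix.values.index:
        if gene_id == focal_gene:
            continue
        y = matrix.values.loc[gene_id].to_numpy(dtype=float)
        if np.std(y) == 0:
            rows.append((gene_id, 0.0, 1.0))
        else:
            r, p = pearson_with_p(focal, y)
            rows.append((gene_id, r, p))
    df = pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")
    df = df.sort_values("r", ascending=False)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["percentile"] = 100.0 * df["rank"] / n
    return df


def correlation_percentile(
    matrix: ExpressionMatrix, focal_gene: str, partner_gene: str
) -> float:
    """Percentile rank of a partner among all focal-gene correlates.

    Rank 1 (strongest positive r) maps to the lowest percentile.
    Self-correlation is rejected.
    """
    if partner_gene == focal_gene:
        raise ValueError("partner must differ from the focal gene")
    screen = correlation_screen(matrix, focal_gene)
    if partner_gene not in screen.index:
        raise KeyError(f"gene {partner_gene!r} not in matrix")
    return float(screen.loc[partner_gene, "percentile"])


def one_tailed_ttest(group_a, group_b, direction: str = "a>b") -> tuple[float, float]:
    """One-tailed Welch t-test between two sample groups.

    ``direction`` states the alternative hypothesis: "a>b" tests whether
    group_a's mean exceeds group_b's, "b>a" the reverse.  Returns (t, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if direction not in ("a>b", "b>a"):
        raise ValueError(f"direction must be 'a>b' or 'b>a', got {direction!r}")
    alternative = "greater" if direction == "a>b" else "less"
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(t), float(p)


def two_way_anova(values, factor1, factor2) -> dict:
    """2x2 factorial ANOVA with type-II sums of squares.

    ``values`` is the response; ``factor1``/``factor2`` are the two binary
    treatment labels per observation.  Returns per-term F and p for both
    main effects and the interaction.  Type II handles unbalanced designs
    without order dependence.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "f1": pd.Categorical(factor1),
        "f2": pd.Categorical(factor2),
    })
    if df["f1"].nunique() != 2 or df["f2"].nunique() != 2:
        raise ValueError("both factors must have exactly two levels")
    cells = df.groupby(["f1", "f2"], observed=False).size()
    if (cells == 0).any():
        raise ValueError("empty design cell: every factor combination needs data")
    model = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for term, key in [("C(f1)", "factor1"), ("C(f2)", "factor2"),
                      ("C(f1):C(f2)", "interaction")]:
        out[key] = {
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
        }
    out["sums_of_squares"] = "type II"
    return out
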