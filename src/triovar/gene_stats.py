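"""Cohort-level gene mutation frequencies and differential-mutation testing.

Genes are compared between tissues with Fisher's exact test on per-gene 2x2
mutated/not-mutated tables, Benjamini-Hochberg control of the FDR, Cramer's V
effect sizes, and log odds ratios (Haldane-Anscombe +0.5 correction when a
cell is empty — applied to the log-OR only, never to the exact p).  Mutation
burden is variants per megabase of gene, correlated with patient age by
Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_gene_matrix",
    "fisher_gene_test",
    "bh_adjust",
    "cramers_v",
    "log_odds_ratio",
    "mutation_burden",
    "burden_age_correlation",
    "top_frequent_genes",
    "CorrelationResult",
]


def build_gene_matrix(
    classified: Mapping[str, pd.DataFrame],
    tissue: str,
    variant_class_filter: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary patients x genes matrix from per-patient origin tables.

    ``classified`` maps patient id -> OriginTable.  A cell is 1 iff the
    patient carries >= 1 variant of the requested origin class(es) in that
    gene with presence in ``tissue``; ``None`` accepts any class present in
    the tissue.
    """
    if tissue not in ("blood", "normal", "tumor"):
        raise ValueError(f"unknown tissue {tissue!r}")
    classes = set(variant_class_filter) if variant_class_filter is not None else None
    per_patient: dict[str, set[str]] = {}
    for pid, table in classified.items():
        sel = table[table[f"in_{tissue}"]]
        if classes is not None:
            sel = sel[sel["origin_class"].isin(classes)]
        per_patient[pid] = set(sel["gene"])
    genes = sorted(set().union(*per_patient.values())) if per_patient else []
    mat = pd.DataFrame(0, index=sorted(per_patient), columns=genes, dtype=int)
    for pid, gset in per_patient.items():
        if gset:
            mat.loc[pid, sorted(gset)] = 1
    return mat


def log_odds_ratio(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """log OR of a [k_a, n_a-k_a; k_b, n_b-k_b] table; +0.5 when any cell is 0."""
    cells = np.array([k_a, n_a - k_a, k_b, n_b - k_b], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell in 2x2 table")
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    return float(np.log((a * d) / (b * c)))


def cramers_v(table: Sequence[Sequence[float]]) -> float:
    """Cramer's V for a 2x2 table: sqrt(chi^2/n), chi^2 without continuity
    correction.  Degenerate margins give 0.0."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    n = t.sum()
    if n <= 0:
        raise ValueError("grand total must be > 0")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    a, b = t[0]
    c, d = t[1]
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(np.sqrt(chi2 / n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_test_2x2(k_a: int, n_a: int, k_b: int, n_b: int) -> tuple[float, float]:
    """(odds ratio, two-sided exact p) for [k_a, n_a-k_a; k_b, n_b-k_b].

    Two-sided by the conventional "minlike" rule: sum of hypergeometric
    probabilities of all tables no more likely than the observed one.
    """
    odds, p = stats.fisher_exact(
        [[k_a, n_a - k_a], [k_b, n_b - k_b]], alternative="two-sided"
    )
    return float(odds), float(p)


def fisher_gene_test(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-sided Fisher's exact test between two tissue matrices.

    Genes absent from one matrix count as unmutated there.  Returns one row
    per gene in either matrix: counts, odds ratio, log-OR, exact p, BH q and
    Cramer's V.
    """
    n_a, n_b = len(matrix_a), len(matrix_b)
    genes = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    rows = []
    for gene in genes:
        k_a = int(matrix_a[gene].sum()) if gene in matrix_a else 0
        k_b = int(matrix_b[gene].sum()) if gene in matrix_b else 0
        table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
        odds, p = fisher_test_2x2(k_a, n_a, k_b, n_b)
        rows.append(
            {
                "gene": gene,
                "mutated_a": k_a,
                "n_a": n_a,
                "mutated_b": k_b,
                "n_b": n_b,
                "odds_ratio": float(odds),
                "log_or": log_odds_ratio(k_a, n_a, k_b, n_b),
                "p": float(p),
                "cramers_v": cramers_v(table),
            }
        )
    result = pd.DataFrame(
        rows, columns=["gene", "mutated_a", "n_a", "mutated_b", "n_b",
                       "odds_ratio", "log_or", "p", "cramers_v"],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    return result.set_index("gene")


def mutation_burden(n_variants: int, gene_length_bp: float) -> float:
    """Variants per megabase of gene length."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    return n_variants / (gene_length_bp / 1e6)


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p: float | None
    n: int
    defined: bool = True


def burden_age_correlation(
    per_patient_burden: Sequence[float], ages: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between per-patient mutation burden and age."""
    x = np.asarray(per_patient_burden, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=None, p=None, n=x.size, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=x.size)


def top_frequent_genes(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Genes ranked by mutation frequency (column mean), ties alphabetical."""
    if matrix.shape[1] == 0:
        raise ValueError("empty gene matrix")
    freq = matrix.mean(axis=0)
    df = pd.DataFrame(
        {"gene": freq.index, "n_mutated": matrix.sum(axis=0).to_numpy(),
         "frequency": freq.to_numpy()}
    )
    df["frequency_pct"] = 100 * df["frequency"]
    df = df.sort_values(["frequency", "gene"], ascending=[False, True],
                        kind="stable")
    return df.head(k).reset_index(drop=True)
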