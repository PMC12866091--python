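"""Pathway-level alteration mapping, germline/somatic attribution and
preranked gene-set enrichment analysis (GSEA).

Genes are ranked by the log odds ratio of mutation frequency between a pair
of tissues; enrichment of a gene set is the classic weighted
Kolmogorov-Smirnov running-sum statistic (ES), normalized against a
gene-label permutation null (NES) with a +1-smoothed permutation p-value and
BH FDR across sets.

Germline-versus-somatic pathway attribution supports the two origin
definitions used for triplet designs:

* definition ``A``: somatic = tumor-private variants; germline = variants
  shared by all three tissues;
* definition ``B``: somatic = normal-private plus shared normal/tumor
  variants; germline = shared-by-all plus blood∩normal variants.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gene_stats import bh_adjust, log_odds_ratio
from .variant_io import PathwayCatalog

__all__ = [
    "CONTRIBUTION_DEFINITIONS",
    "pathway_alteration_matrix",
    "germline_somatic_contribution",
    "rank_genes_log_or",
    "enrichment_score",
    "gsea_preranked",
]

CONTRIBUTION_DEFINITIONS = {
    "A": {"germline": {"germline_all"}, "somatic": {"tumor_private"}},
    "B": {
        "germline": {"germline_all", "blood_normal"},
        "somatic": {"normal_private", "shared_somatic"},
    },
}


def pathway_alteration_matrix(
    classified: Mapping[str, pd.DataFrame],
    catalog: PathwayCatalog,
    variant_classes: Iterable[str],
) -> pd.DataFrame:
    """Binary patients x pathways matrix.

    A cell is 1 iff >= 1 member gene of the pathway carries >= 1 variant of
    the selected origin classes in that patient.
    """
    classes = set(variant_classes)
    pathways = sorted(catalog)
    patients = sorted(classified)
    mat = pd.DataFrame(0, index=patients, columns=pathways, dtype=int)
    for pid, table in classified.items():
        hit_genes = set(table.loc[table["origin_class"].isin(classes), "gene"])
        hit_genes = {g.upper() for g in hit_genes}
        for pw in pathways:
            if hit_genes & catalog[pw]:
                mat.loc[pid, pw] = 1
    return mat


def germline_somatic_contribution(
    classified: Mapping[str, pd.DataFrame],
    catalog: PathwayCatalog,
    definition: str = "A",
) -> pd.DataFrame:
    """Average percent of pathway member genes hit by germline vs somatic
    variants, per pathway, across patients.

    The per-patient percent uses the full pathway size as denominator.  A
    gene hit by both origins in one patient counts once in each percent.
    Pathways with no member gene ever observed in the cohort's annotations
    are excluded and flagged (``observed_genes`` = 0, percents NaN).
    """
    if definition not in CONTRIBUTION_DEFINITIONS:
        raise ValueError(f"definition must be 'A' or 'B', got {definition!r}")
    defn = CONTRIBUTION_DEFINITIONS[definition]
    universe = set()
    per_patient_hits = {}
    for pid, table in classified.items():
        universe |= {g.upper() for g in table["gene"]}
        per_patient_hits[pid] = {
            origin: {g.upper() for g in table.loc[
                table["origin_class"].isin(classes), "gene"]}
            for origin, classes in defn.items()
        }
    rows = []
    for pw in sorted(catalog):
        members = catalog[pw]
        observed = len(members & universe)
        row = {"pathway": pw, "n_genes": len(members), "observed_genes": observed,
               "definition": definition}
        if observed == 0:
            row["germline_pct"] = np.nan
            row["somatic_pct"] = np.nan
        else:
            for origin in ("germline", "somatic"):
                pcts = [
                    100.0 * len(hits[origin] & members) / len(members)
                    for hits in per_patient_hits.values()
                ]
                row[f"{origin}_pct"] = float(np.mean(pcts)) if pcts else np.nan
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["pathway", "n_genes", "observed_genes", "definition",
                       "germline_pct", "somatic_pct"],
    ).set_index("pathway")


def rank_genes_log_or(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> pd.Series:
    """Genes scored by log OR of mutation frequency (a vs b), sorted
    descending; +0.5 correction on empty cells; ties alphabetical."""
    n_a, n_b = len(matrix_a), len(matrix_b)
    genes = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    scores = {
        g: log_odds_ratio(
            int(matrix_a[g].sum()) if g in matrix_a else 0, n_a,
            int(matrix_b[g].sum()) if g in matrix_b else 0, n_b,
        )
        for g in genes
    }
    s = pd.Series(scores, name="log_or")
    return s.sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(
    scores: np.ndarray, in_set: np.ndarray, weight_p: float = 1.0
) -> float:
    """Weighted KS enrichment score of a membership mask over a ranked list.

    ``scores`` must already be in ranked (descending) order.  Hits advance
    the running sum by |score|^p normalized over in-set genes; misses retreat
    by 1/(N - n_set).  The ES is the running-sum value of largest magnitude;
    a set spanning the whole list has ES 1 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = len(scores)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        return 1.0
    w = np.abs(scores[in_set]) ** weight_p
    total = w.sum()
    steps = np.empty(n)
    if total > 0:
        steps[in_set] = np.abs(scores[in_set]) ** weight_p / total
    else:  # all-zero hit scores: fall back to equal hit weights
        steps[in_set] = 1.0 / n_hit
    steps[~in_set] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return float(np.clip(es, -1.0, 1.0))  # guard float drift in the cumsum


def _permutation_es(
    scores: np.ndarray, n_hit: int, weight_p: float, n_perm: int, rng
) -> np.ndarray:
    """ES values for random gene-label permutations (vectorized)."""
    n = len(scores)
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hit]
    mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(mask, order, True, axis=1)
    absw = np.abs(scores)[None, :] ** weight_p
    hit_w = np.where(mask, absw, 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    zero_tot = totals[:, 0] == 0
    steps = np.divide(hit_w, totals, out=np.zeros_like(hit_w), where=totals > 0)
    if zero_tot.any():
        steps[zero_tot] = mask[zero_tot] / n_hit
    steps[~mask] = 0.0
    steps = steps - (~mask) * (1.0 / (n - n_hit))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: PathwayCatalog | Mapping[str, Iterable[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    ``ranked`` is a gene -> score series, sorted descending (it is re-sorted
    defensively).  For each set: ES; NES = ES / mean(|same-sign permutation
    ES|); permutation p with +1 smoothing on the same-sign tail; BH FDR
    across testable sets.  Sets with no genes in the list are reported as
    not testable.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = ranked.sort_values(ascending=False, kind="stable")
    genes = np.array([g.upper() for g in ranked.index])
    scores = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x65EA)))
    items = gene_sets.items() if hasattr(gene_sets, "items") else gene_sets
    perm_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in items:
        members = {m.upper() for m in members}
        in_set = np.isin(genes, sorted(members))
        n_hit = int(in_set.sum())
        if n_hit < min_size or n_hit == len(genes):
            testable = n_hit == len(genes)  # whole-list sets still get ES=1
            if not testable:
                rows.append({"set": name, "size": n_hit, "es": np.nan,
                             "nes": np.nan, "p": np.nan, "tested": False})
                continue
        es = enrichment_score(scores, in_set, weight_p)
        if n_hit == len(genes):
            rows.append({"set": name, "size": n_hit, "es": es, "nes": np.nan,
                         "p": np.nan, "tested": False})
            continue
        if n_hit not in perm_cache:
            perm_cache[n_hit] = _permutation_es(scores, n_hit, weight_p, n_perm, rng)
        perm = perm_cache[n_hit]
        same_sign = perm > 0 if es >= 0 else perm < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(perm[same_sign]).mean()
            n_ge = int((np.abs(perm[same_sign]) >= abs(es)).sum())
            p = (1 + n_ge) / (1 + n_same)
        rows.append({"set": name, "size": n_hit, "es": float(es),
                     "nes": float(nes), "p": float(p), "tested": True})
    result = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "tested"])
    result["q"] = np.nan
    tested = result["tested"] & result["p"].notna()
    if tested.any():
        result.loc[tested, "q"] = bh_adjust(result.loc[tested, "p"].to_numpy())
    return result.set_index("set")
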