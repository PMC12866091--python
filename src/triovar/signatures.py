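"""SBS-96 mutational spectra: context matrices, signature refitting, de novo
extraction, and cohort comparisons.

The 96 channels are the pyrimidine-centered single-base substitutions with
their 5' and 3' flanking bases; purine-reference SNVs are mapped through the
reverse complement, so spectra are strand-invariant.  Refitting against a
known catalog is nonnegative least squares (the primary decomposition path);
fixed-rank NMF with random restarts is provided for de novo extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variant_io import SBS96_CHANNELS, SignatureCatalog, TissueSample

__all__ = [
    "trinucleotide_context",
    "build_sbs_matrix",
    "refit_signatures",
    "extract_denovo",
    "signature_percent_contribution",
    "wilcoxon_signed_rank",
    "largest_remainder_round",
    "ReferenceMismatchError",
    "ContigEdgeError",
    "WilcoxonResult",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = ("C", "T")


class ReferenceMismatchError(ValueError):
    """The reference base at a variant position does not match the record."""


class ContigEdgeError(ValueError):
    """The position has no 5' or 3' flanking base on its contig."""


def _fetch_triplet(reference, chrom: str, pos: int) -> str:
    """1-based pos; returns the pos-1..pos+1 triplet, uppercased."""
    seq = reference[chrom]
    length = len(seq)
    if pos < 2 or pos > length - 1:
        raise ContigEdgeError(f"{chrom}:{pos} lacks a flanking base")
    return str(seq[pos - 2: pos + 1]).upper()


def trinucleotide_context(reference, chrom: str, pos: int, ref: str, alt: str) -> str:
    """SBS-96 channel label ("A[C>T]G") of an SNV against a reference.

    ``reference`` is any mapping of contig -> sliceable sequence (a
    pyfaidx.Fasta, or a plain dict of strings).  Purine-reference calls are
    reverse-complemented onto the pyrimidine strand.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not an SNV: {ref}>{alt}")
    chrom_lookup = chrom if chrom in _contig_names(reference) else f"chr{chrom}"
    triplet = _fetch_triplet(reference, chrom_lookup, pos)
    if triplet[1] != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} reference has {triplet[1]}, record says {ref}"
        )
    if ref in _PYRIMIDINES:
        five, three = triplet[0], triplet[2]
        sub_ref, sub_alt = ref, alt
    else:
        five, three = _COMP[triplet[2]], _COMP[triplet[0]]
        sub_ref, sub_alt = _COMP[ref], _COMP[alt]
    return f"{five}[{sub_ref}>{sub_alt}]{three}"


def _contig_names(reference) -> Iterable[str]:
    try:
        return reference.keys()
    except AttributeError:  # pragma: no cover - pyfaidx exposes keys()
        return []


def build_sbs_matrix(
    samples: Iterable[TissueSample], reference
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """96 x samples context-count matrix.

    Non-SNV records and contig-edge positions are excluded and tallied per
    sample in the returned skip dictionary; a reference-base mismatch raises
    (it signals corrupted inputs, not noise).
    """
    columns = {}
    skipped: dict[str, dict[str, int]] = {}
    for sample in samples:
        name = f"{sample.patient_id}_{sample.tissue}"
        counts = dict.fromkeys(SBS96_CHANNELS, 0)
        skip = {"non_snv": 0, "contig_edge": 0}
        for rec in sample.variants:
            if not rec.is_snv:
                skip["non_snv"] += 1
                continue
            try:
                channel = trinucleotide_context(
                    reference, rec.chrom, rec.pos, rec.ref, rec.alt
                )
            except ContigEdgeError:
                skip["contig_edge"] += 1
                continue
            counts[channel] += 1
        columns[name] = counts
        skipped[name] = skip
    mat = pd.DataFrame(columns, index=list(SBS96_CHANNELS), dtype=int)
    return mat, skipped


@dataclass
class ExposureTable:
    """Per-sample signature exposures from a refit.

    ``fractions``: samples x signatures, rows summing to 1 for samples with
    >= 1 mutation; ``counts``: largest-remainder integer attribution summing
    to each sample's SNV total; ``cosine``: similarity between observed and
    reconstructed spectra (NaN for empty samples).
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame
    cosine: pd.Series
    totals: pd.Series


def largest_remainder_round(values: Sequence[float], total: int) -> np.ndarray:
    """Round nonnegative values to integers that sum exactly to ``total``."""
    v = np.asarray(values, dtype=float)
    if v.sum() == 0:
        return np.zeros(len(v), dtype=int)
    scaled = v / v.sum() * total
    floors = np.floor(scaled).astype(int)
    remainder = int(total - floors.sum())
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors


def refit_signatures(
    sbs_matrix: pd.DataFrame,
    catalog: SignatureCatalog,
    signature_subset: Sequence[str] | None = None,
) -> ExposureTable:
    """Nonnegative least-squares refit of each sample onto catalog columns."""
    names = list(signature_subset) if signature_subset is not None else list(catalog.names)
    if not names:
        raise ValueError("signature subset must be nonempty")
    basis = catalog.matrix[names].to_numpy()
    fractions, counts, cosines, totals = {}, {}, {}, {}
    for sample in sbs_matrix.columns:
        v = sbs_matrix[sample].to_numpy(dtype=float)
        total = int(v.sum())
        totals[sample] = total
        if total == 0:
            fractions[sample] = np.zeros(len(names))
            counts[sample] = np.zeros(len(names), dtype=int)
            cosines[sample] = np.nan
            continue
        x, _ = optimize.nnls(basis, v)
        recon = basis @ x
        denom = np.linalg.norm(v) * np.linalg.norm(recon)
        cosines[sample] = float(v @ recon / denom) if denom > 0 else np.nan
        frac = x / x.sum() if x.sum() > 0 else x
        fractions[sample] = frac
        counts[sample] = largest_remainder_round(frac, total)
    idx = list(sbs_matrix.columns)
    return ExposureTable(
        fractions=pd.DataFrame(fractions, index=names).T.loc[idx],
        counts=pd.DataFrame(counts, index=names).T.loc[idx],
        cosine=pd.Series(cosines).loc[idx],
        totals=pd.Series(totals).loc[idx],
    )


def extract_denovo(
    sbs_matrix: pd.DataFrame, k: int, n_restarts: int = 10, seed: int = 0,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-k NMF of the 96 x samples matrix, best of ``n_restarts`` random
    initializations by Frobenius reconstruction error.

    Returns (signatures 96 x k, column-stochastic; exposures k x samples).
    Deterministic for a fixed seed.
    """
    from sklearn.decomposition import NMF

    x = sbs_matrix.to_numpy(dtype=float)
    if k < 1 or k > min(96, x.shape[1]):
        raise ValueError(f"k={k} out of range for a {x.shape} matrix")
    if x.sum() == 0:
        raise ValueError("matrix is all zero")
    seeds = np.random.SeedSequence((seed, k)).generate_state(n_restarts) % (2**31)
    best = None
    for s in seeds:
        model = NMF(n_components=k, init="random", random_state=int(s),
                    max_iter=max_iter, tol=1e-6)
        w = model.fit_transform(x)
        err = model.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, w, model.components_)
    _, w, h = best
    scale = w.sum(axis=0)
    scale[scale == 0] = 1.0
    w = w / scale
    h = h * scale[:, None]
    sig_names = [f"DENOVO{i + 1}" for i in range(k)]
    signatures = pd.DataFrame(w, index=sbs_matrix.index, columns=sig_names)
    exposures = pd.DataFrame(h, index=sig_names, columns=sbs_matrix.columns)
    return signatures, exposures


def signature_percent_contribution(
    exposures: ExposureTable, sample_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Attributed mutation counts and percents per signature per group.

    Per sample, attributed counts are the largest-remainder rounding of
    exposure fractions times the sample's SNV total, so group counts sum
    exactly to the group's mutation total.
    """
    rows = []
    for group, samples in sample_groups.items():
        counts = exposures.counts.loc[list(samples)].sum(axis=0)
        total = int(exposures.totals.loc[list(samples)].sum())
        for sig, n in counts.items():
            rows.append(
                {
                    "group": group,
                    "signature": sig,
                    "n_attributed": int(n),
                    "group_total": total,
                    "percent": 100.0 * n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["group", "signature", "n_attributed",
                                       "group_total", "percent"])


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float | None
    p: float | None
    n: int
    testable: bool = True


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 (no ties in |differences|), a tie-corrected normal approximation
    otherwise.  All-zero differences (or < 5 informative pairs) are reported
    as not testable rather than as a p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    nz = d[d != 0]
    if len(nz) < 5:
        return WilcoxonResult(None, None, len(nz), testable=False)
    res = stats.wilcoxon(nz, alternative="two-sided", mode="auto")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), len(nz))
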