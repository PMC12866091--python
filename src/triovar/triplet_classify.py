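"""Origin classification of variants across the blood/normal/tumor triplet.

Blood is the germline reference: a variant present in all three tissues is
germline; one present in normal and/or tumor but absent from blood is
somatic.  The three presence bits (B, A, T) partition variants into seven
mutually exclusive classes; the two biologically central ones are
``germline_all`` (B∩A∩T) and ``shared_somatic`` (A∩T only — evidence of
clonal seeding of histologically normal tissue).

"Present" means the variant survived whatever filtering was applied to the
sample handed in; there is no read-level rescue here except through
:func:`revalidate_presence`, an optional second pass that re-tests sub-
threshold support against a sequencing-error binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import PatientTriplet

__all__ = [
    "ORIGIN_CLASSES",
    "OriginTable",
    "VafSummary",
    "classify_origin",
    "venn_counts",
    "jaccard",
    "vaf_summary",
    "shared_somatic_vaf_ratio",
    "min_detectable_vaf",
    "revalidate_presence",
    "PresenceCall",
]

# presence bits (blood, normal, tumor) -> class name
ORIGIN_CLASSES: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "germline_all",
    (True, True, False): "blood_normal",
    (True, False, True): "blood_tumor",
    (False, True, True): "shared_somatic",
    (False, False, True): "tumor_private",
    (False, True, False): "normal_private",
    (True, False, False): "blood_private",
}

SOMATIC_CLASSES = ("shared_somatic", "tumor_private", "normal_private")

#: An OriginTable is a DataFrame with one row per item (variant key or gene)
#: and columns: in_blood, in_normal, in_tumor, origin_class, gene,
#: vaf_blood, vaf_normal, vaf_tumor.
OriginTable = pd.DataFrame


def classify_origin(triplet: PatientTriplet, level: str = "variant") -> OriginTable:
    """Partition a patient's variants (or genes) by tissue presence.

    At ``variant`` level membership is by canonical allele key; at ``gene``
    level a gene is present in a tissue when any of its variants is, and the
    reported per-tissue VAF is the maximum over the gene's variants there.
    """
    if level not in ("variant", "gene"):
        raise ValueError(f"level must be 'variant' or 'gene', got {level!r}")
    for tissue in ("blood", "normal", "tumor"):
        if triplet.sample(tissue) is None:  # pragma: no cover - dataclass forbids
            raise ValueError(f"incomplete triplet: missing {tissue}")

    maps = {t: triplet.sample(t).by_key() for t in ("blood", "normal", "tumor")}
    if level == "variant":
        items = sorted(set().union(*(m.keys() for m in maps.values())))
        rows = []
        for key in items:
            present = tuple(key in maps[t] for t in ("blood", "normal", "tumor"))
            recs = {t: maps[t].get(key) for t in ("blood", "normal", "tumor")}
            gene = next(r.gene for r in recs.values() if r is not None)
            rows.append(
                {
                    "item": f"{key[0]}:{key[1]}:{key[2]}>{key[3]}",
                    "gene": gene,
                    "in_blood": present[0],
                    "in_normal": present[1],
                    "in_tumor": present[2],
                    "origin_class": ORIGIN_CLASSES[present],
                    "vaf_blood": _vaf(recs["blood"]),
                    "vaf_normal": _vaf(recs["normal"]),
                    "vaf_tumor": _vaf(recs["tumor"]),
                }
            )
    else:
        genes: dict[str, dict] = {}
        for t in ("blood", "normal", "tumor"):
            for rec in maps[t].values():
                entry = genes.setdefault(
                    rec.gene,
                    {"in_blood": False, "in_normal": False, "in_tumor": False,
                     "vaf_blood": np.nan, "vaf_normal": np.nan, "vaf_tumor": np.nan},
                )
                entry[f"in_{t}"] = True
                v = _vaf(rec)
                if not np.isnan(v):
                    entry[f"vaf_{t}"] = np.nanmax([entry[f"vaf_{t}"], v])
        rows = [
            {
                "item": gene,
                "gene": gene,
                **entry,
                "origin_class": ORIGIN_CLASSES[
                    (entry["in_blood"], entry["in_normal"], entry["in_tumor"])
                ],
            }
            for gene, entry in sorted(genes.items())
        ]
    cols = ["item", "gene", "in_blood", "in_normal", "in_tumor", "origin_class",
            "vaf_blood", "vaf_normal", "vaf_tumor"]
    table = pd.DataFrame(rows, columns=cols)
    return table.set_index("item")


def _vaf(rec) -> float:
    if rec is None or rec.vaf is None:
        return np.nan
    return rec.vaf


def venn_counts(origin_table: OriginTable) -> dict[str, int]:
    """Counts of the 7 presence regions; they sum to the item count."""
    counts = {name: 0 for name in ORIGIN_CLASSES.values()}
    if len(origin_table):
        observed = origin_table["origin_class"].value_counts()
        for name, n in observed.items():
            counts[name] = int(n)
    assert sum(counts.values()) == len(origin_table)
    return counts


def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B|; 0.0 when both sets are empty (logged convention)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class VafSummary:
    n: int
    min: float | None = None
    max: float | None = None
    median: float | None = None
    iqr: float | None = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def vaf_summary(origin_table: OriginTable, origin_class: str, tissue: str) -> VafSummary:
    """Order-statistic summary (type-7 quartiles) of VAFs in one class/tissue."""
    if tissue not in ("blood", "normal", "tumor"):
        raise ValueError(f"unknown tissue {tissue!r}")
    sel = origin_table.loc[
        origin_table["origin_class"] == origin_class, f"vaf_{tissue}"
    ].dropna()
    if sel.empty:
        return VafSummary(n=0)
    v = sel.to_numpy(dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation = type 7
    return VafSummary(n=len(v), min=float(v.min()), max=float(v.max()),
                      median=float(med), iqr=float(q3 - q1))


@dataclass
class VafRatioResult:
    """Per-variant tumor/normal VAF ratios of shared-somatic variants."""

    ratios: pd.Series
    mean: float | None
    min: float | None
    max: float | None
    n_excluded_zero_normal: int


def shared_somatic_vaf_ratio(origin_table: OriginTable) -> VafRatioResult:
    """Tumor-over-normal VAF ratio per shared-somatic variant, with mean/range."""
    shared = origin_table[origin_table["origin_class"] == "shared_somatic"]
    both = shared.dropna(subset=["vaf_normal", "vaf_tumor"])
    zero_normal = both["vaf_normal"] == 0
    usable = both[~zero_normal]
    ratios = usable["vaf_tumor"] / usable["vaf_normal"]
    if ratios.empty:
        return VafRatioResult(ratios, None, None, None, int(zero_normal.sum()))
    return VafRatioResult(
        ratios=ratios,
        mean=float(ratios.mean()),
        min=float(ratios.min()),
        max=float(ratios.max()),
        n_excluded_zero_normal=int(zero_normal.sum()),
    )


def min_detectable_vaf(min_reads: int, coverage: float) -> float:
    """Detection limit implied by a minimum-supporting-reads rule.

    With a requirement of ``min_reads`` alt reads at ``coverage`` total depth
    the smallest reliably callable allele fraction is ``min_reads/coverage``
    (e.g. 10 reads at 100x -> 0.10; at 200x -> 0.05).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    return min_reads / coverage


@dataclass(frozen=True)
class PresenceCall:
    call: str  # "present" | "absent" | "no_call"
    p_value: float | None

    def __bool__(self) -> bool:
        return self.call == "present"


def revalidate_presence(
    alt_count: int, depth: int, error_rate: float = 0.01, alpha: float = 0.05
) -> PresenceCall:
    """Re-test weak variant support against the sequencing-error binomial.

    One-sided exact test of ``alt_count`` against Binomial(depth, error_rate);
    "present" when the upper-tail p falls below ``alpha``.  Zero depth yields
    a no-call, never "absent".
    """
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    if depth == 0:
        return PresenceCall("no_call", None)
    if not (0 <= alt_count <= depth):
        raise ValueError("need 0 <= alt_count <= depth")
    p = stats.binomtest(alt_count, depth, error_rate, alternative="greater").pvalue
    return PresenceCall("present" if p < alpha else "absent", float(p))
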