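"""Quality hard-filters and the high-functional-impact (HFI) variant definition.

A variant enters the analysis-ready set when it survives three conjunctive
gates: (1) GATK-style site hard filters with separate SNV and indel
thresholds, plus a genotype-quality floor; (2) an exonic, non-silent
functional category; (3) predicted high functional impact — deleterious by
the MetaSVM ensemble or pathogenic in ClinVar.  Thresholds use strict
inequalities exactly as conventionally printed: DP < 4 fails, DP = 4 passes.

A missing QC metric skips that rule rather than failing the record, so
annotation-poor inputs degrade gracefully instead of being discarded
wholesale.  Every drop is attributed to the first violated rule, making the
report counts additive: input = passed + sum of per-rule drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variant_io import MISSING, TissueSample, VariantRecord

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "FilterResult",
    "DEFAULT_POLICY",
    "NONSILENT_CLASSES",
    "apply_hard_filters",
    "is_exonic_nonsilent",
    "is_high_impact",
    "filter_sample",
]

#: Exonic categories retained as non-silent (ANNOVAR vocabulary).
NONSILENT_CLASSES = frozenset(
    {
        "nonsynonymous SNV",
        "stopgain",
        "stoploss",
        "frameshift insertion",
        "frameshift deletion",
        "nonframeshift insertion",
        "nonframeshift deletion",
        "splicing",
    }
)

_SILENT_KNOWN = frozenset({"synonymous SNV", "intronic", "UTR3", "UTR5",
                           "intergenic", "ncRNA_exonic", "ncRNA_intronic",
                           "upstream", "downstream", MISSING})


@dataclass(frozen=True)
class FilterPolicy:
    """Immutable per-run filter thresholds and category rules."""

    # SNV site filters
    snv_dp_min: float = 4.0
    snv_qd_min: float = 2.0
    snv_fs_max: float = 60.0
    snv_mq_min: float = 35.0
    snv_mqrs_min: float = -12.5
    snv_rprs_min: float = -8.0
    # indel site filters (no MQRankSum rule)
    indel_dp_min: float = 4.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_mq_min: float = 35.0
    indel_rprs_min: float = -20.0
    gq_min: float = 20.0
    nonsilent_classes: frozenset[str] = NONSILENT_CLASSES
    include_splicing: bool = True
    clinvar_pathogenic: frozenset[str] = frozenset({"pathogenic", "likely_pathogenic"})

    def effective_nonsilent(self) -> frozenset[str]:
        if self.include_splicing:
            return self.nonsilent_classes | {"splicing"}
        return self.nonsilent_classes - {"splicing"}


DEFAULT_POLICY = FilterPolicy()


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None  # first violated rule, e.g. "DP<4"

    def __bool__(self) -> bool:
        return self.passed


def _variant_kind(record: VariantRecord) -> str:
    return "snv" if record.is_snv else "indel"


def apply_hard_filters(
    record: VariantRecord, kind: str | None = None, policy: FilterPolicy = DEFAULT_POLICY
) -> FilterResult:
    """Site/genotype hard filters; fail reason names the first violated rule."""
    kind = kind or _variant_kind(record)
    if kind not in ("snv", "indel"):
        raise ValueError(f"kind must be 'snv' or 'indel', got {kind!r}")
    p = policy
    if kind == "snv":
        rules = [
            (record.dp, lambda v: v < p.snv_dp_min, f"DP<{p.snv_dp_min:g}"),
            (record.qd, lambda v: v < p.snv_qd_min, f"QD<{p.snv_qd_min:g}"),
            (record.fs, lambda v: v > p.snv_fs_max, f"FS>{p.snv_fs_max:g}"),
            (record.mq, lambda v: v < p.snv_mq_min, f"MQ<{p.snv_mq_min:g}"),
            (record.mq_rank_sum, lambda v: v < p.snv_mqrs_min,
             f"MQRankSum<{p.snv_mqrs_min:g}"),
            (record.read_pos_rank_sum, lambda v: v < p.snv_rprs_min,
             f"ReadPosRankSum<{p.snv_rprs_min:g}"),
        ]
    else:
        rules = [
            (record.dp, lambda v: v < p.indel_dp_min, f"DP<{p.indel_dp_min:g}"),
            (record.qd, lambda v: v < p.indel_qd_min, f"QD<{p.indel_qd_min:g}"),
            (record.fs, lambda v: v > p.indel_fs_max, f"FS>{p.indel_fs_max:g}"),
            (record.mq, lambda v: v < p.indel_mq_min, f"MQ<{p.indel_mq_min:g}"),
            (record.read_pos_rank_sum, lambda v: v < p.indel_rprs_min,
             f"ReadPosRankSum<{p.indel_rprs_min:g}"),
        ]
    rules.append((record.gq, lambda v: v < p.gq_min, f"GQ<{p.gq_min:g}"))
    for value, violates, name in rules:
        if value is None:
            continue  # unannotated metric: rule skipped
        if violates(float(value)):
            return FilterResult(False, name)
    return FilterResult(True)


def is_exonic_nonsilent(record: VariantRecord, policy: FilterPolicy = DEFAULT_POLICY) -> bool:
    """True iff the functional category is exonic and changes the protein."""
    func = record.exonic_function
    nonsilent = policy.effective_nonsilent()
    if func in nonsilent:
        return True
    if func not in _SILENT_KNOWN:
        import warnings

        warnings.warn(f"unknown exonic function category {func!r}; treated as silent")
    return False


def is_high_impact(record: VariantRecord, policy: FilterPolicy = DEFAULT_POLICY) -> bool:
    """MetaSVM deleterious OR ClinVar (likely) pathogenic.

    Missing annotations never qualify a record.
    """
    if record.metasvm == "D":
        return True
    return record.clinvar.lower().replace(" ", "_") in policy.clinvar_pathogenic


@dataclass
class FilterReport:
    """Additive per-rule drop counts; input = passed + sum(drops)."""

    n_input: int = 0
    n_passed: int = 0
    drops: dict[str, int] = field(default_factory=dict)

    def record_drop(self, rule: str) -> None:
        self.drops[rule] = self.drops.get(rule, 0) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": rule, "n_failed": n} for rule, n in sorted(self.drops.items())]
        rows.append({"rule": "PASS", "n_failed": 0})
        df = pd.DataFrame(rows, columns=["rule", "n_failed"])
        df["n_passed"] = self.n_passed
        df["n_input"] = self.n_input
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_sample(
    sample: TissueSample, policy: FilterPolicy = DEFAULT_POLICY
) -> tuple[TissueSample, FilterReport]:
    """Apply hard filters, the non-silent gate and the HFI rule in sequence."""
    report = FilterReport(n_input=len(sample.variants))
    kept: list[VariantRecord] = []
    for rec in sample.variants:
        hard = apply_hard_filters(rec, policy=policy)
        if not hard:
            report.record_drop(hard.reason)
            continue
        if not is_exonic_nonsilent(rec, policy):
            report.record_drop("not_exonic_nonsilent")
            continue
        if not is_high_impact(rec, policy):
            report.record_drop("not_high_impact")
            continue
        kept.append(rec)
    report.n_passed = len(kept)
    assert report.n_input == report.n_passed + sum(report.drops.values())
    return (
        TissueSample(patient_id=sample.patient_id, tissue=sample.tissue, variants=kept),
        report,
    )


def filter_triplet(triplet, policy: FilterPolicy = DEFAULT_POLICY):
    """Filter all three tissues; returns (filtered triplet, {tissue: report})."""
    from .variant_io import PatientTriplet

    filtered = {}
    reports = {}
    for tissue in ("blood", "normal", "tumor"):
        filtered[tissue], reports[tissue] = filter_sample(triplet.sample(tissue), policy)
    return (
        PatientTriplet(
            patient_id=triplet.patient_id,
            blood=filtered["blood"],
            normal=filtered["normal"],
            tumor=filtered["tumor"],
            age=triplet.age,
            cohort=triplet.cohort,
        ),
        reports,
    )
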