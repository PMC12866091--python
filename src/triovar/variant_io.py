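"""Reading, writing and normalization of the standard formats the pipeline touches.

All internal positions are 1-based (VCF convention); gene models are read from
BED (0-based half-open) and converted on load.  Chromosome names are
normalized by stripping any ``chr`` prefix.  Multi-allelic VCF sites are split
into one :class:`VariantRecord` per ALT allele before any set logic, so that
"shared between tissues" is well defined at the allele level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SBS96_CHANNELS",
    "SUBSTITUTIONS",
    "VariantRecord",
    "TissueSample",
    "PatientTriplet",
    "PathwayCatalog",
    "SignatureCatalog",
    "VcfFormatError",
    "CatalogFormatError",
    "variant_key",
    "normalize_variant",
    "read_annotated_vcf",
    "write_vcf",
    "read_gene_sets",
    "read_signature_catalog",
    "write_signature_catalog",
    "read_gene_model",
    "write_gene_model",
]

TISSUES = ("blood", "normal", "tumor")

#: The six pyrimidine-centered substitution classes, COSMIC order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical SBS-96 channel order: six substitution blocks, 16 flanking
#: contexts each, alphabetical within a block (COSMIC v3 file layout).
SBS96_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

MISSING = "missing"


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed into the internal model."""


class CatalogFormatError(ValueError):
    """Raised when a signature catalog violates the 96-channel contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one sample.

    ``vaf`` is ``ad_alt / dp`` and is ``None`` when depth is zero or the AD
    field was absent (the record is then flagged unusable for VAF analyses).
    Site QC metrics that were not annotated are ``None`` and the corresponding
    hard-filter rule is skipped.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = MISSING
    exonic_function: str = MISSING
    metasvm: str = MISSING
    clinvar: str = MISSING
    cadd: float | None = None
    dp: int = 0
    ad_alt: int = 0
    gq: float | None = None
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not (0 <= self.ad_alt <= max(self.dp, 0)):
            raise ValueError(
                f"AD/DP inconsistent at {self.chrom}:{self.pos}: "
                f"ad_alt={self.ad_alt}, dp={self.dp}"
            )

    @property
    def vaf(self) -> float | None:
        return self.ad_alt / self.dp if self.dp > 0 else None

    @property
    def usable_vaf(self) -> bool:
        return self.dp > 0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonicalize an allele pair: trim shared suffix, then shared prefix.

    Identical biological events map to identical keys, e.g. (100, AT, GT)
    becomes (100, A, G).  Chromosome names lose any ``chr`` prefix.
    """
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def variant_key(record: VariantRecord) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt) key of a record; pure function."""
    return normalize_variant(record.chrom, record.pos, record.ref, record.alt)


@dataclass
class TissueSample:
    """All variant calls of one tissue of one patient."""

    patient_id: str
    tissue: str
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate variant keys in sample {self.patient_id}/{self.tissue}"
            )

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def by_key(self) -> dict[tuple[str, int, str, str], VariantRecord]:
        return {v.key: v for v in self.variants}


@dataclass
class PatientTriplet:
    """Matched blood / adjacent-normal / tumor samples of one patient."""

    patient_id: str
    blood: TissueSample
    normal: TissueSample
    tumor: TissueSample
    age: float | None = None
    cohort: str = ""

    def __post_init__(self):
        for s in (self.blood, self.normal, self.tumor):
            if s.patient_id != self.patient_id:
                raise ValueError(
                    f"tissue sample patient id {s.patient_id!r} does not match "
                    f"triplet {self.patient_id!r}"
                )
        if self.age is not None and not (0 < self.age < 120):
            raise ValueError(f"implausible age {self.age}")

    def sample(self, tissue: str) -> TissueSample:
        return {"blood": self.blood, "normal": self.normal, "tumor": self.tumor}[tissue]


class PathwayCatalog:
    """Named gene sets (Hallmark / KEGG / curated collections)."""

    def __init__(self, sets: Mapping[str, Iterable[str]], label: str = ""):
        self.label = label
        self.sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            gs = frozenset(g.upper() for g in genes)
            if not gs:
                raise ValueError(f"empty gene set {name!r}")
            if name in self.sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            self.sets[name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


class SignatureCatalog:
    """96-channel x K column-stochastic signature probability matrix."""

    def __init__(self, matrix: pd.DataFrame):
        if matrix.shape[0] != 96:
            raise CatalogFormatError(f"expected 96 channel rows, got {matrix.shape[0]}")
        missing = set(SBS96_CHANNELS) - set(matrix.index)
        if missing:
            raise CatalogFormatError(f"missing channels, e.g. {sorted(missing)[:3]}")
        matrix = matrix.loc[list(SBS96_CHANNELS)].astype(float)
        if (matrix.values < 0).any():
            raise CatalogFormatError("negative signature entries")
        sums = matrix.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 1e-3).any():
            bad = sums[off > 1e-3]
            raise CatalogFormatError(
                f"columns must sum to 1 within 1e-3: {dict(bad.round(4))}"
            )
        self.matrix = matrix / sums  # renormalize small drift
        self.names = list(matrix.columns)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values

    def __getitem__(self, name: str) -> pd.Series:
        return self.matrix[name]

    def subset(self, names: Iterable[str]) -> "SignatureCatalog":
        return SignatureCatalog(self.matrix[list(names)])

    def mixture(self, weights: Mapping[str, float]) -> np.ndarray:
        """Channel probability vector of a convex signature mixture."""
        w = pd.Series(weights, dtype=float)
        unknown = set(w.index) - set(self.names)
        if unknown:
            raise KeyError(f"unknown signatures {sorted(unknown)}")
        p = self.matrix[w.index].values @ w.values
        return p / p.sum()


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_INFO_FIELDS = {
    "Gene": "gene",
    "ExonicFunc": "exonic_function",
    "MetaSVM": "metasvm",
    "CLNSIG": "clinvar",
}
# multi-word ANNOVAR categories are serialized with underscores in VCF INFO
_EXONIC_DECODE = {
    c.replace(" ", "_"): c
    for c in (
        "nonsynonymous SNV",
        "synonymous SNV",
        "frameshift insertion",
        "frameshift deletion",
        "nonframeshift insertion",
        "nonframeshift deletion",
    )
}

_QC_FIELDS = {
    "QD": "qd",
    "FS": "fs",
    "MQ": "mq",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
}


def _info_str(info, key) -> str:
    try:
        val = info.get(key)
    except (KeyError, ValueError):  # key absent from the VCF header
        val = None
    if val is None:
        return MISSING
    if isinstance(val, tuple):
        val = val[0]
    if isinstance(val, bytes):
        val = val.decode()
    return str(val) if str(val) not in (".", "") else MISSING


def _info_float(info, key) -> float | None:
    try:
        val = info.get(key)
    except (KeyError, ValueError):
        val = None
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[0]
    try:
        return float(val)
    except (TypeError, ValueError):
        return None


def read_annotated_vcf(
    path: str | Path, patient_id: str | None = None, tissue: str | None = None
) -> TissueSample:
    """Read an annotated single-sample VCF into a :class:`TissueSample`.

    Multi-allelic sites are split into one record per ALT allele.  Missing
    annotation keys become ``"missing"``; missing AD/DP leaves the record with
    dp=0 (flagged unusable for VAF analyses) rather than raising.
    """
    path = Path(path)
    if patient_id is None or tissue is None:
        # convention of the synthetic writer: <patient>_<tissue>.vcf
        stem = path.name
        for suffix in (".vcf.gz", ".vcf"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        if "_" in stem:
            pid, _, tis = stem.rpartition("_")
            patient_id = patient_id or pid
            tissue = tissue or tis
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc

    variants: list[VariantRecord] = []
    with vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            if not rec.alts:
                continue
            fmt = rec.samples[sample_names[0]] if sample_names else None
            ad = None
            dp = 0
            gq = None
            if fmt is not None:
                ad = fmt.get("AD")
                dp_val = fmt.get("DP")
                dp = int(dp_val) if dp_val is not None else 0
                gq_val = fmt.get("GQ")
                gq = float(gq_val) if gq_val is not None else None
            info_kwargs = {attr: _info_str(rec.info, key) for key, attr in _INFO_FIELDS.items()}
            info_kwargs["exonic_function"] = _EXONIC_DECODE.get(
                info_kwargs["exonic_function"], info_kwargs["exonic_function"]
            )
            qc_kwargs = {attr: _info_float(rec.info, key) for key, attr in _QC_FIELDS.items()}
            cadd = _info_float(rec.info, "CADD")
            for i, alt in enumerate(rec.alts):
                if alt in (None, "*", "<NON_REF>"):
                    continue
                ad_alt = 0
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    ad_alt = int(ad[i + 1])
                if dp == 0 and ad is not None:
                    dp = int(sum(a for a in ad if a is not None))
                variants.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        cadd=cadd,
                        dp=dp,
                        ad_alt=min(ad_alt, dp) if dp else ad_alt,
                        gq=gq,
                        **info_kwargs,
                        **qc_kwargs,
                    )
                )
    return TissueSample(patient_id=patient_id or "unknown", tissue=tissue or "blood",
                        variants=variants)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=Gene,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=ExonicFunc,Number=1,Type=String,Description="Exonic functional category">
##INFO=<ID=MetaSVM,Number=1,Type=String,Description="MetaSVM ensemble call (D/T)">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar clinical significance">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def _fmt(x, nd=2) -> str:
    return "." if x is None else f"{float(x):.{nd}f}".rstrip("0").rstrip(".")


def write_vcf(sample: TissueSample, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> Path:
    """Write a sample to a VCF 4.2 text file (FORMAT GT:AD:DP:GQ)."""
    path = Path(path)
    lines = [_VCF_HEADER.rstrip("\n")]
    contigs = dict(contig_lengths or {})
    for v in sample.variants:
        contigs.setdefault(v.chrom, 0)
    for chrom, length in contigs.items():
        entry = f"##contig=<ID={chrom}" + (f",length={length}" if length else "") + ">"
        lines.append(entry)
    sample_col = f"{sample.patient_id}_{sample.tissue}"
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_col)
    for v in sorted(sample.variants, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info = [
            f"Gene={v.gene}",
            f"ExonicFunc={v.exonic_function.replace(' ', '_')}",
            f"MetaSVM={v.metasvm}",
            f"CLNSIG={v.clinvar}",
        ]
        if v.cadd is not None:
            info.append(f"CADD={_fmt(v.cadd)}")
        for key, attr in _QC_FIELDS.items():
            val = getattr(v, attr)
            if val is not None:
                info.append(f"{key}={_fmt(val, 3)}")
        gt = "1/1" if v.dp > 0 and v.ad_alt == v.dp else "0/1"
        gq = int(v.gq) if v.gq is not None else "."
        fmt = f"{gt}:{v.dp - v.ad_alt},{v.ad_alt}:{v.dp}:{gq}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info)
            + "\tGT:AD:DP:GQ\t"
            + fmt
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(gmt_path: str | Path, label: str = "") -> PathwayCatalog:
    """Read a tab-delimited GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{gmt_path}:{lineno}: GMT line has <3 fields")
        name, _desc, *genes = fields
        genes = {g.strip().upper() for g in genes if g.strip()}
        if not genes:
            warnings.warn(f"{gmt_path}:{lineno}: empty gene set {name!r} skipped")
            continue
        sets[name] = genes
    return PathwayCatalog(sets, label=label or Path(gmt_path).stem)


# ---------------------------------------------------------------------------
# Signature catalogs
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a tab-delimited 96 x K signature matrix (COSMIC SBS layout).

    Rows are reordered to the canonical channel order; columns off 1 by more
    than 1e-3 are rejected, smaller drift is renormalized.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return SignatureCatalog(df)
    except CatalogFormatError as exc:
        raise CatalogFormatError(f"{path}: {exc}") from exc


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> Path:
    path = Path(path)
    out = catalog.matrix.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t", float_format="%.8g")
    return path


# ---------------------------------------------------------------------------
# Gene models (BED)
# ---------------------------------------------------------------------------

def read_gene_model(bed_path: str | Path) -> pd.DataFrame:
    """Read genes from BED (0-based half-open) into 1-based inclusive intervals."""
    rows = []
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{bed_path}:{lineno}: BED gene line needs 4 columns")
        chrom, start, end, name = fields[:4]
        chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
        rows.append({"chrom": chrom, "start": int(start) + 1, "end": int(end),
                     "gene": name})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    df["length_bp"] = df["end"] - df["start"] + 1
    return df


def write_gene_model(genes: pd.DataFrame, bed_path: str | Path) -> Path:
    """Write the 1-based inclusive gene table as BED (0-based half-open)."""
    bed_path = Path(bed_path)
    with bed_path.open("w") as fh:
        for row in genes.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")
    return bed_path
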