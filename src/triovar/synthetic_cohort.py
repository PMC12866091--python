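"""Synthetic triplet-cohort generator with known ground truth.

Emulates a matched blood / cancer-adjacent-normal / tumor exome cohort at the
variant-call level (no reads): a dominant shared-germline fraction, somatic
variants private to tumor or normal or shared between them, Poisson exome
depth around ~100x (blood, normal) and ~200x (tumor), binomial allele
sampling at each locus, and substitution contexts drawn from a configurable
SBS signature mixture against a real reference sequence.  A variant is
*emitted* into a tissue's call set only when it gathers at least
``min_supporting_reads`` alt reads there — the same detection-limit censoring
a minimum-supporting-reads calling rule imposes on real data.

Every emitted (and censored) variant is recorded in a truth table, so
downstream origin classification, gene statistics, pathway attribution and
signature refitting can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import (
    SBS96_CHANNELS,
    PatientTriplet,
    SignatureCatalog,
    TissueSample,
    VariantRecord,
    read_annotated_vcf,
    write_gene_model,
    write_signature_catalog,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "Cohort",
    "TRUTH_TO_OBSERVED",
    "simulate_reference",
    "sample_read_support",
    "simulate_cohort",
    "synthetic_signature_catalog",
    "synthetic_pathway_catalog",
    "write_cohort",
    "read_cohort",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: intended truth class -> origin class observed when nothing is censored
TRUTH_TO_OBSERVED = {
    "germline": "germline_all",
    "shared_somatic": "shared_somatic",
    "tumor_private": "tumor_private",
    "normal_private": "normal_private",
}

_CLASS_TISSUES = {
    "germline": ("blood", "normal", "tumor"),
    "shared_somatic": ("normal", "tumor"),
    "tumor_private": ("tumor",),
    "normal_private": ("normal",),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a small triplet breast-cancer cohort: 24 patients, exome
    coverage ~100x in blood and adjacent normal and ~200x in tumor, a 10
    supporting-read calling floor, a large inherited (germline) variant load
    against a much smaller somatic one, heterozygous/homozygous germline
    allele fractions of 0.5/1.0 in an 85/15 mix, somatic clonal fractions
    Beta-distributed around a median VAF of 0.216, and substitution contexts
    drawn from an SBS1/SBS5/SBS54-style mixture at roughly 19/59/22 percent.
    """

    n_patients: int = 24
    n_genes: int = 500
    gene_length_bp: int = 1500
    n_germline_per_patient: int = 200
    n_tumor_private: int = 30
    n_normal_private: int = 15
    n_shared_somatic: int = 15
    coverage_blood: float = 100.0
    coverage_normal: float = 100.0
    coverage_tumor: float = 200.0
    min_supporting_reads: int = 10
    germline_vaf_levels: dict = field(default_factory=lambda: {0.5: 0.85, 1.0: 0.15})
    somatic_vaf_median: float = 0.216
    somatic_vaf_shape: float = 2.0
    somatic_vaf_fixed: float | None = None
    somatic_vaf_min: float = 0.0
    signature_mix: dict = field(
        default_factory=lambda: {"SBS1": 0.191, "SBS5": 0.584, "SBS54": 0.225}
    )
    hfi_fraction: float = 0.6  # fraction of variants built to pass the impact filter
    age_range: tuple = (23, 49)
    gc_fraction: float = 0.41
    cohort_label: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_patients", "n_genes", "gene_length_bp",
                     "n_germline_per_patient"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("n_tumor_private", "n_normal_private", "n_shared_somatic",
                     "min_supporting_reads"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("coverage_blood", "coverage_normal", "coverage_tumor"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        mix = self.signature_mix
        if any(v < 0 for v in mix.values()):
            problems.append("signature_mix fractions must be nonnegative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            problems.append(f"signature_mix must sum to 1, got {sum(mix.values())}")
        if not (0 < self.gc_fraction < 1):
            problems.append("gc_fraction must be in (0, 1)")
        if not (0 <= self.hfi_fraction <= 1):
            problems.append("hfi_fraction must be in [0, 1]")
        levels = self.germline_vaf_levels
        if abs(sum(levels.values()) - 1.0) > 1e-9 or any(
            not (0 < lv <= 1) for lv in levels
        ):
            problems.append("germline_vaf_levels must be fractions in (0,1] "
                            "with weights summing to 1")
        if self.somatic_vaf_fixed is not None and not (
            0 <= self.somatic_vaf_fixed <= 1
        ):
            problems.append("somatic_vaf_fixed must be in [0, 1]")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def somatic_vaf_beta(self) -> tuple[float, float]:
        """Beta(a, b) with the configured shape and target median.

        Uses the median approximation (a - 1/3) / (a + b - 2/3) for a, b > 1.
        """
        a = self.somatic_vaf_shape
        m = self.somatic_vaf_median
        b = (a - 1 / 3) / m - a + 2 / 3
        return a, b

    def to_json(self) -> str:
        d = asdict(self)
        d["germline_vaf_levels"] = {str(k): v for k, v in d["germline_vaf_levels"].items()}
        d["age_range"] = list(d["age_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "germline_vaf_levels" in d:
            d["germline_vaf_levels"] = {
                float(k): v for k, v in d["germline_vaf_levels"].items()
            }
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    length_bp: int, gc_fraction: float, n_genes: int, seed: int,
    chrom: str = "1",
) -> tuple[str, pd.DataFrame]:
    """Random reference sequence plus a non-overlapping gene model.

    Genes are evenly spaced intervals (1-based inclusive in the returned
    table) covering ~80% of each slot.  Deterministic for a fixed seed.
    """
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    if length_bp < n_genes * 100:
        raise ValueError(
            f"length_bp={length_bp} too small for {n_genes} genes (need >= {n_genes * 100})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
                  (1 - gc_fraction) / 2])
    seq = "".join(np.array(list(_BASE))[rng.choice(4, size=length_bp, p=p)])
    slot = length_bp // n_genes
    gene_len = max(int(slot * 0.8), 50)
    rows = []
    for i in range(n_genes):
        start0 = i * slot + (slot - gene_len) // 2  # 0-based
        rows.append(
            {"chrom": chrom, "start": start0 + 1, "end": start0 + gene_len,
             "gene": f"G{i + 1:04d}"}
        )
    genes = pd.DataFrame(rows)
    genes["length_bp"] = genes["end"] - genes["start"] + 1
    return seq, genes


def _context_index(seq: str, genes: pd.DataFrame):
    """Index genome positions by pyrimidine-centered trinucleotide context.

    Returns {context_code: (positions 1-based, plus_strand_is_pyrimidine)}.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for base, c in _CODE.items():
        code[arr == ord(base)] = c
    left = code[:-2]
    center = code[1:-1]
    right = code[2:]
    trin = left * 16 + center * 4 + right
    comp = 3 - code
    rc_trin = comp[2:] * 16 + comp[1:-1] * 4 + comp[:-2]
    is_pyr = (center == 1) | (center == 3)
    canonical = np.where(is_pyr, trin, rc_trin)
    pos = np.arange(2, len(seq))  # 1-based position of the central base

    gene_mask = np.zeros(len(seq) + 1, dtype=bool)
    for row in genes.itertuples():
        gene_mask[row.start: row.end + 1] = True
    keep = gene_mask[pos]

    index = {}
    canon_k, pos_k, pyr_k = canonical[keep], pos[keep], is_pyr[keep]
    order = np.argsort(canon_k, kind="stable")
    canon_k, pos_k, pyr_k = canon_k[order], pos_k[order], pyr_k[order]
    bounds = np.searchsorted(canon_k, np.arange(65))
    for ctx in range(64):
        lo, hi = bounds[ctx], bounds[ctx + 1]
        if hi > lo:
            index[ctx] = (pos_k[lo:hi], pyr_k[lo:hi])
    return index


def _channel_context_code(channel: str) -> tuple[int, str, str]:
    """(context code, ref pyrimidine, alt) of an SBS-96 channel label."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    ctx = _CODE[five] * 16 + _CODE[ref] * 4 + _CODE[three]
    return ctx, ref, alt


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def sample_read_support(true_vaf: float, mean_depth: float, seed_or_rng) -> tuple[int, int]:
    """(alt_count, total_depth): Poisson depth, binomial allele sampling."""
    if not (0 <= true_vaf <= 1):
        raise ValueError(f"true_vaf must be in [0, 1], got {true_vaf}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    depth = int(rng.poisson(mean_depth))
    alt = int(rng.binomial(depth, true_vaf)) if depth > 0 else 0
    return alt, depth


# ---------------------------------------------------------------------------
# Synthetic catalogs (labelled synthetic: stand-ins for user-supplied files)
# ---------------------------------------------------------------------------

def synthetic_signature_catalog(
    names=("SBS1", "SBS5", "SBS54"), seed: int = 0, concentration: float = 0.08,
    disjoint: bool = False,
) -> SignatureCatalog:
    """Synthetic column-stochastic signature catalog (not real COSMIC data).

    ``disjoint=True`` gives signatures uniform over disjoint channel blocks
    (orthogonal support), handy for exact-recovery checks; otherwise sparse
    Dirichlet draws produce realistically peaked, overlapping spectra.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 96)))
    k = len(names)
    if disjoint:
        mat = np.zeros((96, k))
        blocks = np.array_split(np.arange(96), k)
        for j, block in enumerate(blocks):
            mat[block, j] = 1.0 / len(block)
    else:
        mat = rng.dirichlet(np.full(96, concentration), size=k).T
    df = pd.DataFrame(mat, index=list(SBS96_CHANNELS), columns=list(names))
    return SignatureCatalog(df)


def synthetic_pathway_catalog(
    genes, n_sets: int = 15, size_range=(8, 30), seed: int = 0, label: str = "synthetic",
):
    """Synthetic gene-set collection drawn from the simulated gene universe."""
    from .variant_io import PathwayCatalog

    rng = np.random.default_rng(np.random.SeedSequence((seed, 21)))
    genes = list(genes)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"PATHWAY_{i + 1:02d}"] = set(members)
    return PathwayCatalog(sets, label=label)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: SimConfig
    reference: str
    genes: pd.DataFrame
    catalog: SignatureCatalog
    patients: list
    truth: pd.DataFrame

    def triplet(self, patient_id: str) -> PatientTriplet:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


_NONSILENT_POOL = ["nonsynonymous SNV", "stopgain", "stoploss"]
_SILENT_POOL = ["synonymous SNV", "intronic"]


def _draw_vafs(cls: str, cfg: SimConfig, rng) -> dict[str, float]:
    if cls == "germline":
        levels = sorted(cfg.germline_vaf_levels)
        weights = [cfg.germline_vaf_levels[lv] for lv in levels]
        v = float(rng.choice(levels, p=np.asarray(weights) / np.sum(weights)))
        return {t: v for t in _CLASS_TISSUES[cls]}
    if cfg.somatic_vaf_fixed is not None:
        v = cfg.somatic_vaf_fixed
    else:
        a, b = cfg.somatic_vaf_beta
        v = float(np.clip(rng.beta(a, b), cfg.somatic_vaf_min, 1.0))
    # one clonal fraction per somatic variant, shared by all carrying tissues
    return {t: v for t in _CLASS_TISSUES[cls]}


def simulate_cohort(config: SimConfig, catalog: SignatureCatalog | None = None) -> Cohort:
    """Generate a full triplet cohort plus its ground-truth table.

    Pre-censoring class counts equal the configured counts exactly; a variant
    reaches a tissue's emitted call set only when its sampled alt-read count
    meets the supporting-read floor there.
    """
    config.validate()
    if catalog is None:
        catalog = synthetic_signature_catalog(
            names=tuple(config.signature_mix), seed=config.seed
        )
    ref_seed = int(np.random.SeedSequence((config.seed, 0)).generate_state(1)[0] % (2**31))
    length_bp = config.n_genes * (config.gene_length_bp + 200)
    reference, genes = simulate_reference(
        length_bp, config.gc_fraction, config.n_genes, ref_seed
    )
    index = _context_index(reference, genes)
    channel_p = catalog.mixture(config.signature_mix)
    # gene lookup by position
    gene_starts = genes["start"].to_numpy()
    gene_names = genes["gene"].to_numpy()

    coverages = {
        "blood": config.coverage_blood,
        "normal": config.coverage_normal,
        "tumor": config.coverage_tumor,
    }
    patients = []
    truth_rows = []
    for pi in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, pi)))
        pid = f"P{pi + 1:03d}"
        age = float(rng.integers(config.age_range[0], config.age_range[1] + 1))
        used: set[int] = set()
        tissue_variants = {t: [] for t in ("blood", "normal", "tumor")}
        plan = (
            [("germline", None)] * config.n_germline_per_patient
            + [("shared_somatic", None)] * config.n_shared_somatic
            + [("tumor_private", None)] * config.n_tumor_private
            + [("normal_private", None)] * config.n_normal_private
        )
        for cls, _ in plan:
            channel_i = int(rng.choice(96, p=channel_p))
            channel = SBS96_CHANNELS[channel_i]
            ctx, pyr_ref, pyr_alt = _channel_context_code(channel)
            positions, plus_is_pyr = index.get(ctx, (np.array([], dtype=int), None))
            if len(positions) == 0:  # pragma: no cover - dense random genomes
                continue
            for _attempt in range(200):
                j = int(rng.integers(len(positions)))
                pos = int(positions[j])
                if pos not in used:
                    break
            else:  # pragma: no cover
                continue
            used.add(pos)
            if plus_is_pyr[j]:
                ref, alt = pyr_ref, pyr_alt
            else:
                ref, alt = _COMP[pyr_ref], _COMP[pyr_alt]
            gi = int(np.searchsorted(gene_starts, pos, side="right") - 1)
            gene = str(gene_names[gi])
            vafs = _draw_vafs(cls, config, rng)
            # annotations are a property of the variant, identical across tissues
            if rng.random() < config.hfi_fraction:
                func = str(rng.choice(_NONSILENT_POOL))
                if rng.random() < 0.7:
                    metasvm, clinvar = "D", str(rng.choice(["benign", "missing"]))
                else:
                    metasvm, clinvar = "T", "pathogenic"
            else:
                if rng.random() < 0.5:
                    func = str(rng.choice(_SILENT_POOL))
                    metasvm, clinvar = "D", "missing"
                else:
                    func = str(rng.choice(_NONSILENT_POOL))
                    metasvm, clinvar = "T", str(rng.choice(["benign", "missing"]))
            cadd = float(np.round(rng.uniform(0, 45), 1))
            qc = {
                "qd": float(np.round(rng.uniform(10, 30), 2)),
                "fs": float(np.round(rng.uniform(0, 20), 2)),
                "mq": 60.0,
                "mq_rank_sum": float(np.round(rng.normal(0, 1), 2)),
                "read_pos_rank_sum": float(np.round(rng.normal(0, 1), 2)),
            }
            row = {
                "patient_id": pid,
                "chrom": "1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "channel": channel,
                "true_class": cls,
                "exonic_function": func,
                "metasvm": metasvm,
                "clinvar": clinvar,
            }
            for tissue in ("blood", "normal", "tumor"):
                v = vafs.get(tissue)
                row[f"vaf_{tissue}"] = v if v is not None else np.nan
                if v is None:
                    row[f"emitted_{tissue}"] = False
                    row[f"ad_{tissue}"] = 0
                    row[f"dp_{tissue}"] = 0
                    continue
                alt_n, dp = sample_read_support(v, coverages[tissue], rng)
                emitted = alt_n >= config.min_supporting_reads and dp > 0
                row[f"emitted_{tissue}"] = emitted
                row[f"ad_{tissue}"] = alt_n
                row[f"dp_{tissue}"] = dp
                if emitted:
                    tissue_variants[tissue].append(
                        VariantRecord(
                            chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                            exonic_function=func, metasvm=metasvm, clinvar=clinvar,
                            cadd=cadd, dp=dp, ad_alt=alt_n, gq=99.0, **qc,
                        )
                    )
            truth_rows.append(row)
        patients.append(
            PatientTriplet(
                patient_id=pid,
                blood=TissueSample(pid, "blood", tissue_variants["blood"]),
                normal=TissueSample(pid, "normal", tissue_variants["normal"]),
                tumor=TissueSample(pid, "tumor", tissue_variants["tumor"]),
                age=age,
                cohort=config.cohort_label,
            )
        )
    truth = pd.DataFrame(truth_rows)
    return Cohort(config=config, reference=reference, genes=genes,
                  catalog=catalog, patients=patients, truth=truth)


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write VCFs, reference FASTA (+.fai), gene BED, truth TSV and config."""
    import pyfaidx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fa"
    with fasta.open("w") as fh:
        fh.write(">1\n")
        for i in range(0, len(cohort.reference), 70):
            fh.write(cohort.reference[i: i + 70] + "\n")
    pyfaidx.Faidx(str(fasta))  # writes reference.fa.fai
    write_gene_model(cohort.genes, outdir / "genes.bed")
    truth = cohort.truth.copy()
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    write_signature_catalog(cohort.catalog, outdir / "signatures.tsv")
    (outdir / "sim_config.json").write_text(cohort.config.to_json() + "\n")
    meta = pd.DataFrame(
        [{"patient_id": p.patient_id, "age": p.age, "cohort": p.cohort}
         for p in cohort.patients]
    )
    meta.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    contigs = {"1": len(cohort.reference)}
    for p in cohort.patients:
        for tissue in ("blood", "normal", "tumor"):
            write_vcf(p.sample(tissue), outdir / f"{p.patient_id}_{tissue}.vcf", contigs)
    return outdir


def read_cohort(outdir: str | Path) -> list[PatientTriplet]:
    """Reconstruct patient triplets from a written cohort directory."""
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / "patients.tsv", sep="\t")
    patients = []
    for row in meta.itertuples():
        samples = {
            tissue: read_annotated_vcf(
                outdir / f"{row.patient_id}_{tissue}.vcf", row.patient_id, tissue
            )
            for tissue in ("blood", "normal", "tumor")
        }
        patients.append(
            PatientTriplet(
                patient_id=row.patient_id,
                age=float(row.age) if pd.notna(row.age) else None,
                cohort=str(row.cohort),
                **samples,
            )
        )
    return patients
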