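"""Domain types and VCF/phenotype-table I/O for annotated cohort variant data.

This module is the shared vocabulary of the pipeline: annotated alternate
alleles (:class:`VariantAnnotation`), per-individual genotype records
(:class:`IndividualRecord`), and readers/writers for the on-disk cohort
representation (a multi-sample VCF 4.2 plus a tab-separated phenotype table).

Conventions
-----------
* Coordinates are 1-based inclusive, as in VCF.
* One :class:`VariantAnnotation` describes exactly one alternate allele;
  multi-allelic VCF sites are split into per-allele records on read.
* Protein/cDNA labels are opaque strings; variants are matched only by
  ``(chrom, pos, ref, alt)``.
* A frequency source absent from ``freq_sources`` means *no evidence*, not
  frequency zero. Policy about missing evidence belongs to the filter layer.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Consequence",
    "Sex",
    "EXCLUSION_FLAGS",
    "VariantAnnotation",
    "Genotype",
    "IndividualRecord",
    "AnnotationSpec",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "read_phenotypes",
    "write_phenotypes",
]


class Consequence(str, enum.Enum):
    """Functional consequence class of a coding/splice variant."""

    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


#: Secondary-cause flags that disqualify a hypouricemia case.
EXCLUSION_FLAGS = frozenset(
    {"ckd", "hypertension", "diabetes", "metabolic_disease", "smoker", "malnutrition"}
)

#: Default chromosome labels treated as X-linked.
X_CHROM_LABELS = frozenset({"X", "chrX"})


class CohortError(ValueError):
    """Raised on structurally invalid cohort data (I/O level)."""


@dataclass
class VariantAnnotation:
    """One annotated alternate allele at a genomic site.

    Parameters
    ----------
    chrom, pos, ref, alt
        Site identity; ``pos`` is 1-based, ``ref != alt``.
    gene
        Gene symbol, e.g. ``"SLC22A12"``.
    consequence
        One of :class:`Consequence`.
    protein_change, cdna_change
        Optional HGVS-style labels, never parsed.
    freq_sources
        Mapping of population-database name to allele frequency in [0, 1].
        Absent source == no evidence.
    inhouse_hom
        True if the allele was seen homozygous/hemizygous in the in-house
        control panel.
    known_pathogenic
        True if previously reported disease-causing (curated-database flag).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    protein_change: str | None = None
    cdna_change: str | None = None
    freq_sources: dict[str, float] = field(default_factory=dict)
    inhouse_hom: bool = False
    known_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multi-allelic alt {self.alt!r}; split sites before constructing"
            )
        self.consequence = Consequence(self.consequence)
        for source, af in self.freq_sources.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"frequency {af} for source {source!r} not in [0,1]")

    @property
    def key(self) -> str:
        """Canonical variant identifier ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def is_x_linked(self, x_labels: frozenset[str] = X_CHROM_LABELS) -> bool:
        return self.chrom in x_labels


@dataclass
class Genotype:
    """Non-reference call of one individual at one annotated allele."""

    variant_key: str
    alt_count: int
    hemizygous: bool = False

    def __post_init__(self) -> None:
        if self.alt_count not in (0, 1, 2):
            raise ValueError(f"alt_count must be 0/1/2, got {self.alt_count}")
        if self.hemizygous and self.alt_count == 2:
            raise ValueError("hemizygous genotype cannot carry two alleles")


@dataclass
class IndividualRecord:
    """One subject: sex, serum urate, exclusion flags and non-ref genotypes."""

    individual_id: str
    sex: Sex
    serum_ua: float
    exclusion_flags: frozenset[str] = frozenset()
    genotypes: list[Genotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.serum_ua < 0:
            raise ValueError(f"serum_ua must be non-negative, got {self.serum_ua}")
        self.exclusion_flags = frozenset(self.exclusion_flags)
        unknown = self.exclusion_flags - EXCLUSION_FLAGS
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        keys = [g.variant_key for g in self.genotypes]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate variant_key in genotypes of {self.individual_id}"
            )
        # canonical order so records compare equal regardless of build order
        self.genotypes.sort(key=lambda g: g.variant_key)

    def genotype_map(self) -> dict[str, Genotype]:
        return {g.variant_key: g for g in self.genotypes}


@dataclass(frozen=True)
class AnnotationSpec:
    """Names of the INFO subfields carrying the annotation payload."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    protein_change: str = "PCH"
    cdna_change: str = "CDNA"
    af_prefix: str = "AF_"
    inhouse_hom: str = "IHH"
    known_pathogenic: str = "KP"


DEFAULT_ANNOTATION_SPEC = AnnotationSpec()


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

def write_phenotypes(individuals: Sequence[IndividualRecord], path: str | Path) -> None:
    """Write the tab-separated phenotype table (``id sex ua flags``)."""
    rows = []
    for ind in sorted(individuals, key=lambda i: i.individual_id):
        flags = ",".join(sorted(ind.exclusion_flags)) or "."
        rows.append(
            {"id": ind.individual_id, "sex": ind.sex.value,
             "ua": repr(float(ind.serum_ua)), "flags": flags}
        )
    pd.DataFrame(rows, columns=["id", "sex", "ua", "flags"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> dict[str, dict]:
    """Read the phenotype table into ``{id: {sex, ua, flags}}``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "sex", "ua", "flags"]
    if list(df.columns) != expected:
        raise CohortError(
            f"phenotype table {path} must have columns {expected}, got {list(df.columns)}"
        )
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        if row.id in out:
            raise CohortError(f"duplicate individual id {row.id!r} in {path}")
        try:
            sex = Sex(row.sex)
        except ValueError as exc:
            raise CohortError(f"unknown sex {row.sex!r} for {row.id!r}") from exc
        flags = frozenset() if row.flags == "." else frozenset(row.flags.split(","))
        out[row.id] = {"sex": sex, "ua": float(row.ua), "flags": flags}
    return out


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

def _build_header(
    variants: Sequence[VariantAnnotation],
    sample_ids: Sequence[str],
    spec: AnnotationSpec,
    extra_meta: Mapping[str, str] | None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for key, value in (extra_meta or {}).items():
        header.add_line(f"##{key}={value}")
    for chrom in sorted({v.chrom for v in variants}):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        f'##INFO=<ID={spec.gene},Number=1,Type=String,Description="Gene symbol">'
    )
    header.add_line(
        f'##INFO=<ID={spec.consequence},Number=1,Type=String,Description="Consequence class">'
    )
    header.add_line(
        f'##INFO=<ID={spec.protein_change},Number=1,Type=String,Description="Protein change (HGVS-p)">'
    )
    header.add_line(
        f'##INFO=<ID={spec.cdna_change},Number=1,Type=String,Description="cDNA change (HGVS-c)">'
    )
    # AF subfields are typed String so that decimal representations round-trip
    # exactly (VCF Float is 32-bit in htslib).
    sources = sorted({s for v in variants for s in v.freq_sources})
    for source in sources:
        header.add_line(
            f'##INFO=<ID={spec.af_prefix}{source},Number=1,Type=String,'
            f'Description="Allele frequency in {source}">'
        )
    header.add_line(
        f'##INFO=<ID={spec.inhouse_hom},Number=0,Type=Flag,'
        'Description="Homozygous/hemizygous in in-house control panel">'
    )
    header.add_line(
        f'##INFO=<ID={spec.known_pathogenic},Number=0,Type=Flag,'
        'Description="Previously reported pathogenic">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_cohort(
    individuals: Sequence[IndividualRecord],
    variants: Sequence[VariantAnnotation],
    vcf_path: str | Path,
    phenotype_path: str | Path,
    annotation_spec: AnnotationSpec = DEFAULT_ANNOTATION_SPEC,
    x_chrom_labels: frozenset[str] = X_CHROM_LABELS,
    extra_meta: Mapping[str, str] | None = None,
) -> None:
    """Write a cohort as VCF 4.2 + phenotype TSV.

    Records are ordered by ``(chrom, pos, alt)`` lexicographically and samples
    by individual id, so output is deterministic for a given cohort.

    Raises
    ------
    CohortError
        If any genotype references a variant_key not present in ``variants``.
    """
    spec = annotation_spec
    known_keys = {v.key for v in variants}
    for ind in individuals:
        for g in ind.genotypes:
            if g.variant_key not in known_keys:
                raise CohortError(
                    f"individual {ind.individual_id} references unknown "
                    f"variant_key {g.variant_key}"
                )

    individuals = sorted(individuals, key=lambda i: i.individual_id)
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    sample_ids = [i.individual_id for i in individuals]
    genotype_maps = [i.genotype_map() for i in individuals]
    header = _build_header(variants, sample_ids, spec, extra_meta)

    with pysam.VariantFile(str(vcf_path), mode="w", header=header) as vcf:
        for var in variants:
            rec = vcf.new_record(
                contig=var.chrom, start=var.pos - 1, alleles=(var.ref, var.alt)
            )
            rec.info[spec.gene] = var.gene
            rec.info[spec.consequence] = var.consequence.value
            if var.protein_change is not None:
                rec.info[spec.protein_change] = var.protein_change
            if var.cdna_change is not None:
                rec.info[spec.cdna_change] = var.cdna_change
            for source, af in sorted(var.freq_sources.items()):
                rec.info[f"{spec.af_prefix}{source}"] = repr(float(af))
            if var.inhouse_hom:
                rec.info[spec.inhouse_hom] = True
            if var.known_pathogenic:
                rec.info[spec.known_pathogenic] = True
            on_x = var.chrom in x_chrom_labels
            for ind, gmap in zip(individuals, genotype_maps):
                g = gmap.get(var.key)
                haploid = (g.hemizygous if g is not None
                           else on_x and ind.sex is Sex.MALE)
                if g is None:
                    alleles = (0,) if haploid else (0, 0)
                elif haploid:
                    alleles = (g.alt_count,)
                elif g.alt_count == 2:
                    alleles = (1, 1)
                else:
                    alleles = (0, 1)
                rec.samples[ind.individual_id]["GT"] = alleles
            vcf.write(rec)

    write_phenotypes(individuals, phenotype_path)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _info_str(rec: pysam.VariantRecord, field_name: str) -> str | None:
    value = rec.info.get(field_name)
    if value is None:
        return None
    if isinstance(value, tuple):
        value = value[0]
    return str(value)


def _parse_consequence(token: str | None, site: str) -> Consequence:
    if token is None:
        warnings.warn(f"{site}: missing consequence, using 'other'", stacklevel=3)
        return Consequence.OTHER
    try:
        return Consequence(token)
    except ValueError:
        warnings.warn(
            f"{site}: unparseable consequence {token!r}, using 'other'", stacklevel=3
        )
        return Consequence.OTHER


def read_cohort(
    vcf_path: str | Path,
    phenotype_path: str | Path,
    annotation_spec: AnnotationSpec = DEFAULT_ANNOTATION_SPEC,
) -> tuple[list[IndividualRecord], list[VariantAnnotation]]:
    """Read a cohort from VCF + phenotype table.

    Multi-allelic sites are split into one :class:`VariantAnnotation` per
    alternate allele; per-sample alt counts are apportioned per allele.
    Genotypes with ``alt_count == 0`` are dropped.

    Raises
    ------
    CohortError
        If the VCF sample set and the phenotype id set differ (the symmetric
        difference is listed in the message).
    """
    spec = annotation_spec
    phenotypes = read_phenotypes(phenotype_path)

    variants: dict[str, VariantAnnotation] = {}
    sample_genotypes: dict[str, list[Genotype]] = {}

    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        vcf_set, pheno_set = set(vcf_samples), set(phenotypes)
        if vcf_set != pheno_set:
            missing = sorted(vcf_set ^ pheno_set)
            raise CohortError(
                f"VCF/phenotype sample sets differ; symmetric difference: {missing}"
            )
        sample_genotypes = {s: [] for s in vcf_samples}
        af_fields = [
            k for k in vcf.header.info if k.startswith(spec.af_prefix)
        ]
        for rec in vcf:
            site = f"{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            freq_sources = {}
            for field_name in af_fields:
                raw = _info_str(rec, field_name)
                if raw is not None:
                    freq_sources[field_name[len(spec.af_prefix):]] = float(raw)
            consequence = _parse_consequence(_info_str(rec, spec.consequence), site)
            gene = _info_str(rec, spec.gene) or ""
            for alt_index, alt in enumerate(alts, start=1):
                var = VariantAnnotation(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=gene,
                    consequence=consequence,
                    protein_change=_info_str(rec, spec.protein_change),
                    cdna_change=_info_str(rec, spec.cdna_change),
                    freq_sources=dict(freq_sources),
                    inhouse_hom=bool(rec.info.get(spec.inhouse_hom, False)),
                    known_pathogenic=bool(rec.info.get(spec.known_pathogenic, False)),
                )
                variants.setdefault(var.key, var)
                for sid in vcf_samples:
                    alleles = rec.samples[sid]["GT"]
                    called = [a for a in alleles if a is not None]
                    if not called:
                        continue
                    count = sum(1 for a in called if a == alt_index)
                    if count == 0:
                        continue
                    sample_genotypes[sid].append(
                        Genotype(
                            variant_key=var.key,
                            alt_count=count,
                            hemizygous=len(called) == 1,
                        )
                    )

    individuals = [
        IndividualRecord(
            individual_id=sid,
            sex=phenotypes[sid]["sex"],
            serum_ua=phenotypes[sid]["ua"],
            exclusion_flags=phenotypes[sid]["flags"],
            genotypes=sample_genotypes[sid],
        )
        for sid in sorted(phenotypes)
    ]
    variant_list = sorted(variants.values(), key=lambda v: (v.chrom, v.pos, v.alt))
    return individuals, variant_list
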