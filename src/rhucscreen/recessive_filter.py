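"""Four-step variant-filtering cascade under a recessive inheritance model.

The cascade removes, in order: (1) variants too common in any populated
population-frequency source, (2) variants seen homozygous/hemizygous in the
in-house control panel, (3) variants outside the kept consequence classes,
and finally (4) single heterozygous genotypes, so that only bi-allelic
configurations (homozygous, compound heterozygous, or hemizygous males on X)
remain as candidate molecular diagnoses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variant_model import (
    Consequence,
    IndividualRecord,
    Sex,
    VariantAnnotation,
    X_CHROM_LABELS,
)

__all__ = [
    "FilterConfig",
    "ZygosityClass",
    "DiagnosisResult",
    "CascadeCounts",
    "filter_by_maf",
    "filter_inhouse",
    "filter_consequence",
    "collect_biallelic",
    "run_cascade",
]

DEFAULT_CONSEQUENCE_KEEP = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Tuning knobs of the filtering cascade.

    ``maf_policy`` decides how multiple frequency sources are aggregated:
    ``any_source_exceeds`` drops a variant as soon as one populated source is
    above the threshold; ``max_across_sources`` compares only the maximum.
    Sources absent from a variant contribute no evidence under either policy,
    so fully unobserved variants always survive the frequency step.
    """

    maf_threshold: float = 0.01
    consequence_keep: frozenset[Consequence] = DEFAULT_CONSEQUENCE_KEEP
    maf_policy: str = "any_source_exceeds"
    x_chrom_labels: frozenset[str] = X_CHROM_LABELS

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold must be in (0,1), got {self.maf_threshold}")
        if self.maf_policy not in ("any_source_exceeds", "max_across_sources"):
            raise ValueError(f"unknown maf_policy {self.maf_policy!r}")
        object.__setattr__(
            self,
            "consequence_keep",
            frozenset(Consequence(c) for c in self.consequence_keep),
        )


class ZygosityClass(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    COMPOUND_HET = "compound_het"
    HEMIZYGOUS = "hemizygous"
    NONE = "none"


@dataclass
class DiagnosisResult:
    """Per-individual outcome of the recessive cascade.

    ``gene`` is the top-ranked qualifying gene (ranking: higher fraction of
    previously-reported alleles first, then lexicographic); ``gene_alleles``
    retains the qualifying allele sets of *all* qualifying genes.
    ``phase_resolved`` is always False for compound heterozygotes called from
    unphased genotypes — the two variants may lie in cis.
    """

    individual_id: str
    gene: str | None
    zygosity_class: ZygosityClass
    qualifying_alleles: list[tuple[str, int]] = field(default_factory=list)
    phase_resolved: bool = True
    gene_alleles: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def diagnosed(self) -> bool:
        return self.zygosity_class is not ZygosityClass.NONE


@dataclass
class CascadeCounts:
    """Per-step variant survival counts plus the diagnosed-individual tally."""

    n_variants_input: int
    after_maf: int
    after_inhouse: int
    after_consequence: int
    n_individuals: int
    n_diagnosed: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# variant-level steps (1-3)
# ---------------------------------------------------------------------------

def filter_by_maf(
    variants: Iterable[VariantAnnotation], config: FilterConfig = FilterConfig()
) -> list[VariantAnnotation]:
    """Step 1: drop variants whose population frequency exceeds the threshold."""
    kept = []
    for v in variants:
        afs = list(v.freq_sources.values())
        if config.maf_policy == "max_across_sources":
            exceeds = bool(afs) and max(afs) > config.maf_threshold
        else:
            exceeds = any(af > config.maf_threshold for af in afs)
        if not exceeds:
            kept.append(v)
    return kept


def filter_inhouse(variants: Iterable[VariantAnnotation]) -> list[VariantAnnotation]:
    """Step 2: drop variants seen hom/hemizygous in the in-house control panel.

    Heterozygous presence in controls does not disqualify a variant.
    """
    return [v for v in variants if not v.inhouse_hom]


def filter_consequence(
    variants: Iterable[VariantAnnotation], config: FilterConfig = FilterConfig()
) -> list[VariantAnnotation]:
    """Step 3: keep protein-altering / splice consequences only."""
    return [v for v in variants if v.consequence in config.consequence_keep]


# ---------------------------------------------------------------------------
# step 4: bi-allelic collection per individual
# ---------------------------------------------------------------------------

def _gene_zygosity(
    entries: list[tuple[VariantAnnotation, int]],
    male: bool,
    x_linked: bool,
) -> ZygosityClass | None:
    if any(count == 2 for _, count in entries):
        return ZygosityClass.HOMOZYGOUS
    if male and x_linked:
        # one qualifying allele on the single X suffices
        return ZygosityClass.HEMIZYGOUS
    if len(entries) >= 2:
        return ZygosityClass.COMPOUND_HET
    return None


def collect_biallelic(
    individual: IndividualRecord,
    surviving_variants: Sequence[VariantAnnotation],
    config: FilterConfig = FilterConfig(),
) -> DiagnosisResult:
    """Step 4: group an individual's surviving genotypes by gene and call
    the bi-allelic zygosity class, excluding single heterozygotes.

    Homozygous dominates within a gene even when extra heterozygous alleles
    are present; females require bi-allelic configurations on X exactly as on
    autosomes, while one qualifying X allele diagnoses a male (hemizygous).
    """
    by_key = {v.key: v for v in surviving_variants}
    male = individual.sex is Sex.MALE

    per_gene: dict[str, list[tuple[VariantAnnotation, int]]] = {}
    for g in individual.genotypes:
        var = by_key.get(g.variant_key)
        if var is None or g.alt_count == 0:
            continue
        per_gene.setdefault(var.gene, []).append((var, g.alt_count))

    qualifying: dict[str, tuple[ZygosityClass, list[tuple[VariantAnnotation, int]]]] = {}
    for gene, entries in per_gene.items():
        x_linked = all(v.is_x_linked(config.x_chrom_labels) for v, _ in entries)
        zyg = _gene_zygosity(entries, male, x_linked)
        if zyg is not None:
            qualifying[gene] = (zyg, entries)

    if not qualifying:
        return DiagnosisResult(
            individual_id=individual.individual_id,
            gene=None,
            zygosity_class=ZygosityClass.NONE,
        )

    def rank(gene: str) -> tuple[float, str]:
        entries = qualifying[gene][1]
        known_fraction = sum(v.known_pathogenic for v, _ in entries) / len(entries)
        return (-known_fraction, gene)

    ordered = sorted(qualifying, key=rank)
    top = ordered[0]
    top_zyg, top_entries = qualifying[top]
    return DiagnosisResult(
        individual_id=individual.individual_id,
        gene=top,
        zygosity_class=top_zyg,
        qualifying_alleles=[(v.key, c) for v, c in top_entries],
        phase_resolved=top_zyg is not ZygosityClass.COMPOUND_HET,
        gene_alleles={
            g: [(v.key, c) for v, c in qualifying[g][1]] for g in ordered
        },
    )


def run_cascade(
    cases: Sequence[IndividualRecord],
    variants: Sequence[VariantAnnotation],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[DiagnosisResult], CascadeCounts]:
    """Apply the four filter steps in order and diagnose every case.

    Returns the per-individual :class:`DiagnosisResult` list (input order)
    and the per-step survival counts.
    """
    step1 = filter_by_maf(variants, config)
    step2 = filter_inhouse(step1)
    step3 = filter_consequence(step2, config)
    results = [collect_biallelic(ind, step3, config) for ind in cases]
    counts = CascadeCounts(
        n_variants_input=len(variants),
        after_maf=len(step1),
        after_inhouse=len(step2),
        after_consequence=len(step3),
        n_individuals=len(cases),
        n_diagnosed=sum(r.diagnosed for r in results),
    )
    return results, counts
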