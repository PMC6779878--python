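"""Two-variant founder-panel classification and diagnostic-yield statistics.

Emulates single-base-extension genotyping of the two Korean founder alleles
in *SLC22A12* — p.Trp258* (rs121907892) and p.Arg90His (rs121907896) — as a
direct genotype lookup at the panel sites, tabulates the per-category
distribution of panel/other allele configurations, and computes the two
yield metrics:

* ``screening_yield`` — subjects carrying at least one allele of either
  panel variant (this deliberately counts single heterozygotes as screen
  positive, the permissive definition used when quoting panel utility);
* ``biallelic_yield`` — subjects with a bona-fide bi-allelic molecular
  diagnosis in a given gene from the recessive cascade.

Both are exposed because they answer different questions; the single-het
contribution to the screening yield is explicit in the category table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .recessive_filter import DiagnosisResult, ZygosityClass
from .variant_model import IndividualRecord, VariantAnnotation

__all__ = [
    "PanelVariant",
    "PanelDefinition",
    "Category",
    "PanelClassification",
    "CohortSummary",
    "default_panel",
    "read_panel",
    "write_panel",
    "classify_panel",
    "categorize",
    "tabulate_distribution",
    "screening_yield",
    "biallelic_yield",
    "compare_percent_strings",
]


@dataclass(frozen=True)
class PanelVariant:
    """Identity of one screening-panel site."""

    gene: str
    cdna: str
    protein: str
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class PanelDefinition:
    panel_variants: tuple[PanelVariant, ...]
    panel_gene: str

    def __post_init__(self) -> None:
        keys = [v.key for v in self.panel_variants]
        if len(keys) != len(set(keys)):
            raise ValueError("panel variants must be distinct")
        if any(v.gene != self.panel_gene for v in self.panel_variants):
            raise ValueError("all panel variants must lie in the panel gene")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(v.key for v in self.panel_variants)


def default_panel() -> PanelDefinition:
    """The two-founder-allele *SLC22A12* screening panel."""
    return PanelDefinition(
        panel_variants=(
            PanelVariant(
                gene="SLC22A12", cdna="c.774G>A", protein="p.Trp258*",
                rsid="rs121907892", chrom="11", pos=64361219, ref="G", alt="A",
            ),
            PanelVariant(
                gene="SLC22A12", cdna="c.269G>A", protein="p.Arg90His",
                rsid="rs121907896", chrom="11", pos=64358955, ref="G", alt="A",
            ),
        ),
        panel_gene="SLC22A12",
    )


PANEL_COLUMNS = ["gene", "cdna", "protein", "rsid", "chrom", "pos", "ref", "alt"]


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    pd.DataFrame(
        [
            {c: getattr(v, c) for c in PANEL_COLUMNS}
            for v in panel.panel_variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> PanelDefinition:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns {sorted(missing)}")
    variants = tuple(
        PanelVariant(
            gene=row.gene, cdna=row.cdna, protein=row.protein, rsid=row.rsid,
            chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
        )
        for row in df.itertuples(index=False)
    )
    genes = {v.gene for v in variants}
    if len(genes) != 1:
        raise ValueError(f"panel spans multiple genes: {sorted(genes)}")
    return PanelDefinition(panel_variants=variants, panel_gene=variants[0].gene)


class Category(str, enum.Enum):
    """Panel-allele configuration category (A = first panel variant, B = second)."""

    HOM_A = "homA"
    HOM_B = "homB"
    COMPOUND_AB = "compound_AB"
    HET_A_PLUS_OTHER = "hetA_plus_other"
    HET_B_PLUS_OTHER = "hetB_plus_other"
    HET_A_ONLY = "hetA_only"
    HET_B_ONLY = "hetB_only"
    OTHERS_ONLY = "others_only"
    NONE = "none"


@dataclass
class PanelClassification:
    individual_id: str
    alleles_per_panel_variant: tuple[int, ...]
    other_qualifying_alleles: int
    category: Category
    #: False in genotyping-only mode, where non-panel alleles were not
    #: assayed and ``other_qualifying_alleles`` is reported as 0-by-ignorance.
    others_assayed: bool = True

    @property
    def panel_positive(self) -> bool:
        return any(a >= 1 for a in self.alleles_per_panel_variant)


def categorize(a1: int, a2: int, others: int) -> Category:
    """Pure category function of (panel-A count, panel-B count, other count)."""
    if a1 == 2:
        return Category.HOM_A
    if a2 == 2:
        return Category.HOM_B
    if a1 == 1 and a2 == 1:
        return Category.COMPOUND_AB
    if a1 == 1 and others >= 1:
        return Category.HET_A_PLUS_OTHER
    if a2 == 1 and others >= 1:
        return Category.HET_B_PLUS_OTHER
    if a1 == 1:
        return Category.HET_A_ONLY
    if a2 == 1:
        return Category.HET_B_ONLY
    if others >= 1:
        return Category.OTHERS_ONLY
    return Category.NONE


def classify_panel(
    individual: IndividualRecord,
    panel: PanelDefinition,
    variants: Sequence[VariantAnnotation],
    qualifying_variants: Sequence[VariantAnnotation] | None = None,
) -> PanelClassification:
    """Classify one individual over the panel sites.

    ``qualifying_variants`` is the post-cascade survivor set used to count
    non-panel qualifying alleles in the panel gene ("others"). Pass ``None``
    for genotyping-only mode (only the panel sites were assayed, as in a
    replication cohort typed by single-base extension): the other-allele
    count is then reported as 0 with ``others_assayed=False``.

    Raises
    ------
    ValueError
        If a panel variant is absent from the cohort variant collection.
    """
    variant_keys = {v.key for v in variants}
    for pv in panel.panel_variants:
        if pv.key not in variant_keys:
            raise ValueError(
                f"panel variant {pv.protein} ({pv.key}) absent from variant collection"
            )
    gmap = individual.genotype_map()
    alleles = tuple(
        gmap[pv.key].alt_count if pv.key in gmap else 0
        for pv in panel.panel_variants
    )
    genotyping_only = qualifying_variants is None
    if genotyping_only:
        others = 0
    else:
        qualifying_keys = {
            v.key
            for v in qualifying_variants
            if v.gene == panel.panel_gene and v.key not in panel.keys
        }
        others = sum(
            g.alt_count for g in individual.genotypes if g.variant_key in qualifying_keys
        )
    if len(alleles) != 2:
        raise ValueError("categorization is defined for two-variant panels")
    return PanelClassification(
        individual_id=individual.individual_id,
        alleles_per_panel_variant=alleles,
        other_qualifying_alleles=others,
        category=categorize(alleles[0], alleles[1], others),
        others_assayed=not genotyping_only,
    )


# ---------------------------------------------------------------------------
# cohort summaries and yields
# ---------------------------------------------------------------------------

def _pct(count: int, n: int) -> str:
    return f"{100 * count / n:.1f}%"


@dataclass
class CohortSummary:
    """Category counts, rounded percent strings, and the two-row roll-up
    (any panel-gene qualifying allele vs none)."""

    n: int
    counts: dict[Category, int]
    percents: dict[Category, str]
    n_panel_gene: int
    n_other: int
    percent_panel_gene: str
    percent_other: str

    def to_rows(self) -> list[dict]:
        rows = []
        for cat in Category:
            c = self.counts.get(cat, 0)
            if c:
                rows.append(
                    {"category": cat.value, "count": c, "percent": self.percents[cat]}
                )
        return rows

    def to_markdown(self, panel: PanelDefinition | None = None) -> str:
        head_a = panel.panel_variants[0].protein if panel else "panel A"
        head_b = panel.panel_variants[1].protein if panel else "panel B"
        alleles = {
            Category.HOM_A: (2, 0, "0"), Category.HOM_B: (0, 2, "0"),
            Category.COMPOUND_AB: (1, 1, "0"),
            Category.HET_A_PLUS_OTHER: (1, 0, ">=1"),
            Category.HET_B_PLUS_OTHER: (0, 1, ">=1"),
            Category.HET_A_ONLY: (1, 0, "0"), Category.HET_B_ONLY: (0, 1, "0"),
            Category.OTHERS_ONLY: (0, 0, ">=1"), Category.NONE: (0, 0, "0"),
        }
        lines = [
            f"| Subjects (%) | {head_a} | {head_b} | Others | Category |",
            "|---|---|---|---|---|",
        ]
        for cat in Category:
            c = self.counts.get(cat, 0)
            if not c:
                continue
            a1, a2, oth = alleles[cat]
            lines.append(
                f"| {c} ({self.percents[cat]}) | {a1} | {a2} | {oth} | {cat.value} |"
            )
        lines.append(
            f"| {self.n_panel_gene} ({self.percent_panel_gene}) "
            f"| any qualifying allele in panel gene | | | |"
        )
        lines.append(
            f"| {self.n_other} ({self.percent_other}) | other than panel gene | | | |"
        )
        return "\n".join(lines)


def tabulate_distribution(
    classifications: Sequence[PanelClassification],
) -> CohortSummary:
    """Count classifications per category with 1-decimal percent strings."""
    if not classifications:
        raise ValueError("cannot tabulate an empty classification list")
    n = len(classifications)
    counts = {cat: 0 for cat in Category}
    for cl in classifications:
        counts[cl.category] += 1
    n_other = counts[Category.NONE]
    n_panel_gene = n - n_other
    return CohortSummary(
        n=n,
        counts=counts,
        percents={cat: _pct(c, n) for cat, c in counts.items()},
        n_panel_gene=n_panel_gene,
        n_other=n_other,
        percent_panel_gene=_pct(n_panel_gene, n),
        percent_other=_pct(n_other, n),
    )


def screening_yield(
    classifications: Sequence[PanelClassification],
) -> tuple[Fraction, str]:
    """Fraction of subjects carrying >=1 allele of either panel variant.

    Single heterozygotes count as screen-positive.
    """
    if not classifications:
        raise ValueError("cannot compute a yield over an empty cohort")
    num = sum(cl.panel_positive for cl in classifications)
    return Fraction(num, len(classifications)), f"{num}/{len(classifications)}"


def biallelic_yield(
    diagnoses: Sequence[DiagnosisResult], gene: str
) -> tuple[Fraction, str]:
    """Fraction of individuals with a bi-allelic diagnosis in ``gene``."""
    if not diagnoses:
        raise ValueError("cannot compute a yield over an empty diagnosis list")
    num = sum(
        d.zygosity_class is not ZygosityClass.NONE and gene in d.gene_alleles
        for d in diagnoses
    )
    return Fraction(num, len(diagnoses)), f"{num}/{len(diagnoses)}"


def compare_percent_strings(
    summary: CohortSummary, published: Mapping[str, str]
) -> list[str]:
    """Flag cells where a published percent string disagrees with the
    computed rounding (e.g. a typo in a printed table).

    ``published`` maps category values (or ``panel_gene`` / ``other``) to the
    percent strings as printed.
    """
    computed = {cat.value: pct for cat, pct in summary.percents.items()}
    computed["panel_gene"] = summary.percent_panel_gene
    computed["other"] = summary.percent_other
    notes = []
    for key, printed in published.items():
        ours = computed.get(key)
        if ours is not None and ours != printed:
            notes.append(
                f"published percent for {key!r} is {printed} but computed "
                f"rounding gives {ours}"
            )
    return notes
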