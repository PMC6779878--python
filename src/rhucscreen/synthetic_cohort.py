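"""Synthetic cohort generation for end-to-end testing of the pipeline.

Two generators live here:

``simulate_cohort``
    A configurable stochastic cohort: genotypes at rare pathogenic
    *SLC22A12* sites drawn under Hardy-Weinberg equilibrium, class-
    conditional Gaussian serum urate (truncated at 0), optional
    non-*SLC22A12* bi-allelic cases, transient (non-genetic) hypouricemia
    mimics, and common benign decoy variants that the frequency filter must
    remove. A truth table records each individual's generative class so
    downstream recovery can be scored without leaking truth into the VCF.

``make_reference_cohort``
    Deterministic reconstruction of the published Korean screening study's
    two cohorts (31 whole-exome discovery subjects, 50 genotyping-only
    replication subjects) from their per-category founder-allele
    configurations, for exact reproduction of the reported distribution and
    yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .founder_screen import default_panel
from .variant_model import (
    EXCLUSION_FLAGS,
    Consequence,
    Genotype,
    IndividualRecord,
    Sex,
    VariantAnnotation,
)

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "make_reference_cohort",
    "reference_variant",
    "PUBLISHED_CATEGORY_STRINGS",
    "TRUTH_COLUMNS",
    "write_truth_table",
]

TRUTH_COLUMNS = ["id", "class", "causal_gene", "allele1", "allele2"]

# ---------------------------------------------------------------------------
# reference variant catalog (panel gene NM_144585.2 numbering; labels opaque)
# ---------------------------------------------------------------------------

def _v(chrom, pos, ref, alt, gene, csq, protein, cdna, freqs, known):
    return VariantAnnotation(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=csq, protein_change=protein, cdna_change=cdna,
        freq_sources=dict(freqs), known_pathogenic=known,
    )


def _catalog() -> dict[str, VariantAnnotation]:
    """Rare pathogenic alleles used by both generators, keyed by protein label."""
    panel = default_panel()
    a, b = panel.panel_variants
    msn = Consequence.MISSENSE
    entries = [
        _v(a.chrom, a.pos, a.ref, a.alt, a.gene, Consequence.STOP_GAINED,
           a.protein, a.cdna, {"gnomad": 0.00025}, True),
        _v(b.chrom, b.pos, b.ref, b.alt, b.gene, msn,
           b.protein, b.cdna, {"gnomad": 0.00013}, True),
        # non-panel qualifying alleles in the panel gene
        _v("11", 64360256, "C", "A", "SLC22A12", msn, "p.Asn136Lys", "c.408C>A",
           {"gnomad": 0.000004}, False),
        _v("11", 64361095, "C", "T", "SLC22A12", msn, "p.Thr217Met", "c.650C>T",
           {"gnomad": 0.00007}, True),
        _v("11", 64361119, "C", "A", "SLC22A12", msn, "p.Thr225Lys", "c.674C>A",
           {}, False),
        _v("11", 64366008, "G", "A", "SLC22A12", msn, "p.Arg284Gln", "c.851G>A",
           {"gnomad": 0.000019}, False),
        _v("11", 64367222, "A", "T", "SLC22A12", msn, "p.Gln382Leu", "c.1145A>T",
           {"gnomad": 0.00003}, True),
        _v("11", 64367330, "T", "G", "SLC22A12", msn, "p.Leu418Arg", "c.1253T>G",
           {"gnomad": 0.00005}, True),
        _v("11", 64367362, "G", "A", "SLC22A12", msn, "p.Glu429Lys", "c.1285G>A",
           {"dbsnp": 0.00005, "go_esp": 0.00008, "gnomad": 0.000044}, False),
        _v("11", 64368297, "G", "A", "SLC22A12", msn, "p.Arg477His", "c.1430G>A",
           {"gnomad": 0.00006}, True),
        # urate transporter gene on chromosome 4 (second recessive locus)
        _v("4", 9922167, "C", "T", "SLC2A9", msn, "p.Arg198Cys", "c.592C>T",
           {"gnomad": 0.00002}, True),
        _v("4", 9998300, "C", "T", "SLC2A9", msn, "p.Arg380Trp", "c.1138C>T",
           {"gnomad": 0.00001}, True),
        # rare candidate alleles in other urate-pathway genes
        _v("2", 31580000, "G", "A", "XDH", msn, "p.Gly172Arg", "c.514G>A",
           {"gnomad": 0.00001}, False),
        _v("18", 36190000, "C", "T", "MOCOS", msn, "p.Arg187Cys", "c.559C>T",
           {"gnomad": 0.00002}, False),
        _v("18", 36220000, "G", "A", "MOCOS", msn, "p.Ala510Thr", "c.1528G>A",
           {"gnomad": 0.00001}, False),
        _v("14", 20469000, "T", "C", "PNP", msn, "p.Tyr192His", "c.574T>C",
           {"gnomad": 0.00001}, False),
    ]
    return {v.protein_change: v for v in entries}


#: Non-panel qualifying alleles in the panel gene, in genomic order.
_OTHER_SLC22A12 = [
    "p.Asn136Lys", "p.Thr217Met", "p.Thr225Lys", "p.Arg284Gln",
    "p.Gln382Leu", "p.Leu418Arg", "p.Glu429Lys", "p.Arg477His",
]


def reference_variant(protein_change: str) -> VariantAnnotation:
    """Look up a catalog variant by its protein label (a fresh copy)."""
    cat = _catalog()
    if protein_change not in cat:
        raise KeyError(f"unknown catalog variant {protein_change!r}")
    return cat[protein_change]


def _decoy_variants(include_x: bool) -> list[VariantAnnotation]:
    """Common benign variants the frequency filter must remove (MAF > 1%)."""
    decoys = []
    mafs = [0.02, 0.05, 0.08, 0.11, 0.15, 0.19, 0.24, 0.28, 0.33, 0.38,
            0.42, 0.45, 0.03, 0.07, 0.12, 0.21, 0.31, 0.44]
    for i, maf in enumerate(mafs):
        chrom = str(1 + (i % 9))
        csq = Consequence.SYNONYMOUS if i % 3 == 2 else Consequence.MISSENSE
        decoys.append(
            VariantAnnotation(
                chrom=chrom, pos=1_000_000 + 50_000 * i, ref="A", alt="G",
                gene=f"DECOY{i % 6 + 1}", consequence=csq,
                protein_change=None, cdna_change=None,
                freq_sources={"gnomad": maf, "kg1000p3": min(1.0, maf * 1.1)},
            )
        )
    if include_x:
        for j, maf in enumerate([0.06, 0.18, 0.35]):
            decoys.append(
                VariantAnnotation(
                    chrom="X", pos=2_000_000 + 80_000 * j, ref="C", alt="T",
                    gene="DECOYX", consequence=Consequence.MISSENSE,
                    freq_sources={"gnomad": maf},
                )
            )
    return decoys


# ---------------------------------------------------------------------------
# stochastic simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the stochastic cohort generator.

    ``panel_freqs`` gives population allele frequencies for the two founder
    alleles; defaults are illustrative, not measured values.
    ``ua_params`` maps generative class to ``(mean, sd)`` of serum urate in
    mg/dL; means must be ordered ``biallelic_carrier < single_het <=
    noncarrier``. ``transient_rate`` is the probability that a noncarrier
    nevertheless presents hypouricemic (urate drawn from the carrier
    distribution; a non-genetic mimic). ``plant_cis_pairs`` plants that many
    noncarriers with two pathogenic alleles on the *same* haplotype — the
    known failure mode of unphased compound-het calling.
    """

    n_individuals: int
    seed: int = 0
    panel_freqs: dict[str, float] = field(
        default_factory=lambda: {"trp258_stop": 0.004, "arg90_his": 0.002}
    )
    other_pathogenic_freq: float = 0.001
    other_gene_fraction: float = 0.0
    benign_variant_rate: float = 2.0
    ua_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "biallelic_carrier": (0.77, 0.25),
            "single_het": (4.6, 0.5),
            "noncarrier": (5.5, 0.6),
        }
    )
    transient_rate: float = 0.0
    exclusion_flag_rate: float = 0.0
    include_x_decoys: bool = True
    plant_cis_pairs: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        probs = [
            *self.panel_freqs.values(), self.other_pathogenic_freq,
            self.other_gene_fraction, self.transient_rate, self.exclusion_flag_rate,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        q1 = self.panel_freqs.get("trp258_stop", 0.0)
        q2 = self.panel_freqs.get("arg90_his", 0.0)
        if q1 + q2 + self.other_pathogenic_freq > 1.0:
            raise ValueError("summed pathogenic allele frequencies exceed 1")
        means = {k: v[0] for k, v in self.ua_params.items()}
        if not (
            means["biallelic_carrier"] < means["single_het"] <= means["noncarrier"]
        ):
            raise ValueError(
                "ua means must satisfy biallelic_carrier < single_het <= noncarrier"
            )
        if self.plant_cis_pairs < 0:
            raise ValueError("plant_cis_pairs must be >= 0")


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[IndividualRecord], list[VariantAnnotation], pd.DataFrame]:
    """Draw a cohort under the configured generative model.

    Returns ``(individuals, variants, truth_table)``; the truth table has
    columns ``id class causal_gene allele1 allele2`` and classes in
    ``{biallelic_carrier, single_het, noncarrier, transient, cis_pair}``.
    Identical configs (including seed) produce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    cat = _catalog()
    panel = default_panel()

    # pathogenic sites in the panel gene, with per-site allele frequencies
    site_labels = [panel.panel_variants[0].protein, panel.panel_variants[1].protein]
    site_freqs = [
        config.panel_freqs.get("trp258_stop", 0.0),
        config.panel_freqs.get("arg90_his", 0.0),
    ]
    others = [p for p in _OTHER_SLC22A12]
    per_other = config.other_pathogenic_freq / len(others)
    site_labels += others
    site_freqs += [per_other] * len(others)

    # Hardy-Weinberg genotype draws: alt count ~ Binomial(2, q) per site
    geno = np.stack(
        [rng.binomial(2, q, size=n) for q in site_freqs], axis=0
    ) if n else np.zeros((len(site_freqs), 0), dtype=int)

    male = rng.random(n) < 0.5

    hom_any = (geno == 2).any(axis=0)
    n_het_sites = (geno == 1).sum(axis=0)
    biallelic_panel_gene = hom_any | (n_het_sites >= 2)

    eligible_other = ~biallelic_panel_gene
    other_gene = eligible_other & (rng.random(n) < config.other_gene_fraction)

    classes = np.full(n, "noncarrier", dtype=object)
    classes[n_het_sites == 1] = "single_het"
    classes[biallelic_panel_gene | other_gene] = "biallelic_carrier"

    noncarrier = classes == "noncarrier"
    transient = noncarrier & (rng.random(n) < config.transient_rate)
    classes[transient] = "transient"

    cis_indices = np.flatnonzero(classes == "noncarrier")[: config.plant_cis_pairs]
    classes[cis_indices] = "cis_pair"

    # class-conditional serum urate (transient and cis mimic their hosts)
    ua = np.zeros(n)
    draw_class = {
        "biallelic_carrier": "biallelic_carrier",
        "single_het": "single_het",
        "noncarrier": "noncarrier",
        "transient": "biallelic_carrier",
        "cis_pair": "noncarrier",
    }
    for cls in ["biallelic_carrier", "single_het", "noncarrier", "transient",
                "cis_pair"]:
        mask = classes == cls
        mean, sd = config.ua_params[draw_class[cls]]
        ua[mask] = _truncated_normal(rng, mean, sd, int(mask.sum()))

    flags_matrix = {
        flag: rng.random(n) < config.exclusion_flag_rate
        for flag in sorted(EXCLUSION_FLAGS)
    }

    # benign decoys: per-site Bernoulli with p = rate / n_sites, so the
    # per-individual decoy count is Binomial(n_sites, rate/n_sites) with
    # mean benign_variant_rate
    decoys = _decoy_variants(config.include_x_decoys)
    p_decoy = min(1.0, config.benign_variant_rate / len(decoys))
    decoy_mask = rng.random((len(decoys), n)) < p_decoy

    slc2a9_pair = [cat["p.Arg198Cys"], cat["p.Arg380Trp"]]
    cis_pair = [cat[site_labels[0]], cat[others[0]]]

    width = max(5, len(str(max(n - 1, 1))))
    individuals: list[IndividualRecord] = []
    truth_rows = []
    for i in range(n):
        genotypes: list[Genotype] = []
        carried = []
        for s, label in enumerate(site_labels):
            count = int(geno[s, i])
            if count:
                genotypes.append(Genotype(cat[label].key, count))
                carried.append((label, count))
        if other_gene[i]:
            for v in slc2a9_pair:
                genotypes.append(Genotype(v.key, 1))
        if classes[i] == "cis_pair":
            for v in cis_pair:
                genotypes.append(Genotype(v.key, 1))
        for d in np.flatnonzero(decoy_mask[:, i]):
            dv = decoys[int(d)]
            hemi = dv.chrom == "X" and bool(male[i])
            genotypes.append(Genotype(dv.key, 1, hemizygous=hemi))

        flags = frozenset(f for f, m in flags_matrix.items() if m[i])
        ind_id = f"S{i:0{width}d}"
        individuals.append(
            IndividualRecord(
                individual_id=ind_id,
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                serum_ua=float(ua[i]),
                exclusion_flags=flags,
                genotypes=genotypes,
            )
        )

        causal_gene, a1, a2 = ".", ".", "."
        cls = classes[i]
        if cls == "biallelic_carrier" and other_gene[i]:
            causal_gene = "SLC2A9"
            a1, a2 = "p.Arg198Cys", "p.Arg380Trp"
        elif cls == "biallelic_carrier":
            causal_gene = "SLC22A12"
            hom_sites = [lbl for lbl, c in carried if c == 2]
            if hom_sites:
                a1 = a2 = hom_sites[0]
            else:
                hets = [lbl for lbl, c in carried if c == 1]
                a1, a2 = hets[0], hets[1]
        elif cls == "single_het":
            causal_gene = "."
            a1 = carried[0][0] if carried else "."
        elif cls == "cis_pair":
            a1, a2 = cis_pair[0].protein_change, cis_pair[1].protein_change
        truth_rows.append(
            {"id": ind_id, "class": cls, "causal_gene": causal_gene,
             "allele1": a1, "allele2": a2}
        )

    variants = [cat[lbl] for lbl in site_labels] + slc2a9_pair + decoys
    # unique by key, deterministic order
    seen: dict[str, VariantAnnotation] = {}
    for v in variants:
        seen.setdefault(v.key, v)
    variant_list = sorted(seen.values(), key=lambda v: (v.chrom, v.pos, v.alt))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return individuals, variant_list, truth


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# deterministic reconstruction of the published cohorts
# ---------------------------------------------------------------------------

#: Percent strings as printed in the published distribution table, keyed by
#: category; used to flag rounding discrepancies (the replication
#: "other" cell prints 6.6% where 3/50 rounds to 6.0%).
PUBLISHED_CATEGORY_STRINGS = {
    "discovery": {
        "homA": "32.3%", "compound_AB": "22.6%", "homB": "6.5%",
        "hetA_plus_other": "16.1%", "others_only": "9.7%",
        "panel_gene": "87.1%", "other": "12.9%",
    },
    "replication": {
        "homA": "20.0%", "compound_AB": "44.0%", "homB": "2.0%",
        "hetA_only": "20.0%", "hetB_only": "8.0%",
        "panel_gene": "94.0%", "other": "6.6%",
    },
}

_UA_CYCLE = [0.45, 0.62, 0.78, 0.91, 1.05, 1.12, 0.55, 0.70, 0.85, 0.98]

# Discovery subjects: (id, [(protein label, alt count), ...]).
# Ids of the three subjects carrying novel (not-previously-reported) alleles
# follow the published subject labels.
_DISCOVERY_LAYOUT: list[tuple[str, list[tuple[str, int]]]] = (
    [(f"D{i:03d}", [("p.Trp258*", 2)]) for i in range(1, 11)]
    + [(f"D{i:03d}", [("p.Trp258*", 1), ("p.Arg90His", 1)]) for i in range(11, 18)]
    + [(f"D{i:03d}", [("p.Arg90His", 2)]) for i in range(18, 20)]
    + [
        ("D020", [("p.Trp258*", 1), ("p.Thr217Met", 1)]),
        ("D021", [("p.Trp258*", 1), ("p.Gln382Leu", 1)]),
        ("D022", [("p.Trp258*", 1), ("p.Leu418Arg", 1)]),
        ("D023", [("p.Trp258*", 1), ("p.Arg477His", 1)]),
        ("NIH17A8865148", [("p.Trp258*", 1), ("p.Glu429Lys", 1)]),
        ("NIH17A8798528", [("p.Thr225Lys", 1), ("p.Arg284Gln", 1)]),
        ("NIH17K4930892", [("p.Asn136Lys", 1), ("p.Leu418Arg", 1)]),
        ("D027", [("p.Thr217Met", 1), ("p.Gln382Leu", 1)]),
        ("D028", [("p.Arg198Cys", 1), ("p.Arg380Trp", 1)]),
        ("D029", [("p.Gly172Arg", 2)]),
        ("D030", [("p.Arg187Cys", 1), ("p.Ala510Thr", 1)]),
        ("D031", [("p.Tyr192His", 2)]),
    ]
)

_REPLICATION_LAYOUT: list[tuple[int, int]] = (
    [(2, 0)] * 10 + [(1, 1)] * 22 + [(0, 2)] * 1 + [(1, 0)] * 10
    + [(0, 1)] * 4 + [(0, 0)] * 3
)


def make_reference_cohort(
    cohort_name: str,
) -> tuple[list[IndividualRecord], list[VariantAnnotation]]:
    """Deterministically reconstruct one of the two published cohorts.

    ``discovery`` yields the 31 whole-exome cases (11 male, 20 female) with
    their per-category founder/other allele configurations; ``replication``
    yields the 50 genotyping-only cases typed at the two panel sites. All
    serum urate values are below the 1.3 mg/dL case threshold and no
    exclusion flags are set.
    """
    if cohort_name not in ("discovery", "replication"):
        raise ValueError(
            f"cohort_name must be 'discovery' or 'replication', got {cohort_name!r}"
        )
    cat = _catalog()
    panel = default_panel()

    individuals: list[IndividualRecord] = []
    if cohort_name == "discovery":
        used: set[str] = set()
        for i, (ind_id, alleles) in enumerate(_DISCOVERY_LAYOUT):
            genotypes = [Genotype(cat[p].key, c) for p, c in alleles]
            used.update(p for p, _ in alleles)
            individuals.append(
                IndividualRecord(
                    individual_id=ind_id,
                    sex=Sex.MALE if i < 11 else Sex.FEMALE,
                    serum_ua=_UA_CYCLE[i % len(_UA_CYCLE)],
                    genotypes=genotypes,
                )
            )
        variants = sorted(
            (cat[p] for p in used), key=lambda v: (v.chrom, v.pos, v.alt)
        )
    else:
        key_a, key_b = panel.keys
        for i, (a1, a2) in enumerate(_REPLICATION_LAYOUT):
            genotypes = []
            if a1:
                genotypes.append(Genotype(key_a, a1))
            if a2:
                genotypes.append(Genotype(key_b, a2))
            individuals.append(
                IndividualRecord(
                    individual_id=f"R{i + 1:03d}",
                    sex=Sex.MALE if i % 2 else Sex.FEMALE,
                    serum_ua=_UA_CYCLE[i % len(_UA_CYCLE)],
                    genotypes=genotypes,
                )
            )
        variants = sorted(
            (cat[pv.protein] for pv in panel.panel_variants),
            key=lambda v: (v.chrom, v.pos, v.alt),
        )
    return individuals, variants
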