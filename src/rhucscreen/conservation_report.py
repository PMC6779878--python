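"""Ortholog residue-conservation profiling, external-prediction aggregation,
and the final per-individual / per-variant evidence report.

External pathogenicity predictors are never executed here — their printed
verdicts are inputs. Residues are accepted in one- or three-letter code and
normalized internally (Asn vs Asp must survive normalization, hence the
strict alphabet check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import protein_letters, protein_letters_3to1

from .founder_screen import PanelClassification, compare_percent_strings
from .recessive_filter import DiagnosisResult, ZygosityClass

__all__ = [
    "DEFAULT_SPECIES",
    "OrthologPanel",
    "ConservationProfile",
    "VerdictSummary",
    "normalize_residue",
    "conservation_profile",
    "aggregate_verdicts",
    "default_ortholog_panel",
    "default_verdicts",
    "read_ortholog_panel",
    "read_verdicts",
    "build_report",
]

DEFAULT_SPECIES = (
    "Rhesus macaque",
    "Mus musculus",
    "Canis lupus familiaris",
    "Loxodonta africana",
)

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_LETTER = set(protein_letters)


def normalize_residue(residue: str) -> str:
    """Normalize a one- or three-letter amino-acid code to one-letter.

    Raises
    ------
    ValueError
        If the symbol is not a standard amino acid.
    """
    token = residue.strip()
    if len(token) == 1 and token.upper() in _ONE_LETTER:
        return token.upper()
    if len(token) == 3 and token.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[token.upper()]
    raise ValueError(f"not an amino-acid residue symbol: {residue!r}")


@dataclass
class OrthologPanel:
    """Residues of candidate variants across an ordered ortholog species list."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    human_residue: dict[str, str] = field(default_factory=dict)
    residues: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for variant, row in self.residues.items():
            if len(row) != len(self.species):
                raise ValueError(
                    f"{variant}: {len(row)} residues for {len(self.species)} species"
                )


@dataclass
class ConservationProfile:
    n_conserved: int
    fraction: float
    matches: tuple[bool, ...]


def conservation_profile(
    human_residue: str, ortholog_residues: Sequence[str]
) -> ConservationProfile:
    """Count orthologs whose residue is identical to the human reference.

    >>> conservation_profile("Glu", ["Glu", "Gly", "Glu", "Glu"]).n_conserved
    3
    """
    if not ortholog_residues:
        raise ValueError("ortholog residue list must be non-empty")
    human = normalize_residue(human_residue)
    matches = tuple(normalize_residue(r) == human for r in ortholog_residues)
    n = sum(matches)
    return ConservationProfile(
        n_conserved=n, fraction=n / len(matches), matches=matches
    )


# ---------------------------------------------------------------------------
# external prediction verdicts
# ---------------------------------------------------------------------------

#: Mapping from each tool's printed vocabulary onto the common three-way
#: scale. Covers every token used by the four tools' outputs: DC (disease
#: causing) / PM (polymorphism) for the mutation-effect classifier, Dam /
#: Bn for the structure-based score, Del / Tol for the alignment-based
#: score, Del / Neu for the consensus score.
VERDICT_VOCABULARY = {
    "DC": "deleterious",
    "PM": "benign",
    "DAM": "deleterious",
    "BN": "benign",
    "DEL": "deleterious",
    "TOL": "benign",
    "NEU": "benign",
}


@dataclass
class VerdictSummary:
    consensus: str
    n_deleterious: int
    n_benign: int
    n_ambiguous: int
    tally: str
    per_tool: dict[str, str]

    @property
    def n_tools(self) -> int:
        return self.n_deleterious + self.n_benign + self.n_ambiguous


def _parse_token(raw: str) -> tuple[str, float | None]:
    """Split a verdict cell like ``Dam(0.998)`` into token and score."""
    raw = raw.strip()
    score = None
    if "(" in raw and raw.endswith(")"):
        token, rest = raw.split("(", 1)
        try:
            score = float(rest[:-1])
        except ValueError:
            token = raw
        return token.strip(), score
    return raw, score


def aggregate_verdicts(verdicts: Mapping[str, str]) -> VerdictSummary:
    """Map per-tool verdict strings to a consensus label.

    Each tool's token is looked up in :data:`VERDICT_VOCABULARY`; unknown
    tokens count as ambiguous (with a warning). Consensus is the majority of
    deleterious vs benign calls; ties are ambiguous.
    """
    import warnings

    if not verdicts:
        raise ValueError("at least one tool verdict is required")
    per_tool = {}
    tallies = {"deleterious": 0, "benign": 0, "ambiguous": 0}
    for tool, raw in verdicts.items():
        token, _score = _parse_token(str(raw))
        label = VERDICT_VOCABULARY.get(token.upper())
        if label is None:
            warnings.warn(
                f"unknown verdict token {token!r} from tool {tool!r}; "
                "treating as ambiguous",
                stacklevel=2,
            )
            label = "ambiguous"
        per_tool[tool] = label
        tallies[label] += 1
    if tallies["deleterious"] > tallies["benign"]:
        consensus = "deleterious"
    elif tallies["benign"] > tallies["deleterious"]:
        consensus = "benign"
    else:
        consensus = "ambiguous"
    return VerdictSummary(
        consensus=consensus,
        n_deleterious=tallies["deleterious"],
        n_benign=tallies["benign"],
        n_ambiguous=tallies["ambiguous"],
        tally=f"{tallies['deleterious']}:{tallies['benign']}",
        per_tool=per_tool,
    )


# ---------------------------------------------------------------------------
# bundled reference data for the four novel panel-gene missense variants
# ---------------------------------------------------------------------------

def default_ortholog_panel() -> OrthologPanel:
    """Ortholog residues of the four novel missense variants."""
    return OrthologPanel(
        species=DEFAULT_SPECIES,
        human_residue={
            "p.Glu429Lys": "Glu",
            "p.Thr225Lys": "Thr",
            "p.Arg284Gln": "Arg",
            "p.Asn136Lys": "Asn",
        },
        residues={
            "p.Glu429Lys": ["Glu", "Gly", "Glu", "Glu"],
            "p.Thr225Lys": ["Thr", "Thr", "Thr", "Thr"],
            "p.Arg284Gln": ["Arg", "Arg", "Arg", "Arg"],
            "p.Asn136Lys": ["Asn", "Asp", "Asp", "Asp"],
        },
    )


def default_verdicts() -> dict[str, dict[str, str]]:
    """Published predictor verdicts for the four novel missense variants."""
    return {
        "p.Glu429Lys": {
            "MutationTaster": "DC", "PolyPhen2": "Bn(0.37)",
            "SIFT": "Tol(0.05)", "Condel": "Neu(0.463)",
        },
        "p.Thr225Lys": {
            "MutationTaster": "DC", "PolyPhen2": "Dam(0.998)",
            "SIFT": "Del(0)", "Condel": "Del(0.919)",
        },
        "p.Arg284Gln": {
            "MutationTaster": "DC", "PolyPhen2": "Dam(0.527)",
            "SIFT": "Del(0.03)", "Condel": "Del(0.542)",
        },
        "p.Asn136Lys": {
            "MutationTaster": "PM", "PolyPhen2": "Bn(0.345)",
            "SIFT": "Del(0)", "Condel": "Del(0.553)",
        },
    }


def read_ortholog_panel(path: str | Path) -> OrthologPanel:
    """Read an ortholog panel TSV: ``variant human <species columns...>``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["variant", "human"]:
        raise ValueError(
            f"ortholog panel {path} must start with columns 'variant', 'human'"
        )
    species = tuple(df.columns[2:])
    if not species:
        raise ValueError(f"ortholog panel {path} has no species columns")
    return OrthologPanel(
        species=species,
        human_residue={r.variant: r.human for r in df.itertuples(index=False)},
        residues={
            row[0]: list(row[2:]) for row in df.itertuples(index=False)
        },
    )


def read_verdicts(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a verdicts TSV: ``variant <tool columns...>``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "variant":
        raise ValueError(f"verdicts file {path} must start with column 'variant'")
    tools = list(df.columns[1:])
    if not tools:
        raise ValueError(f"verdicts file {path} has no tool columns")
    return {
        row[0]: dict(zip(tools, row[1:])) for row in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    per_individual: pd.DataFrame
    per_variant: pd.DataFrame
    notes: list[str]

    def to_markdown(self) -> str:
        parts = ["# Cohort diagnostic report", "", "## Per-individual findings", ""]
        parts.append(self.per_individual.to_markdown(index=False))
        parts += ["", "## Per-variant evidence", ""]
        parts.append(self.per_variant.to_markdown(index=False))
        if self.notes:
            parts += ["", "## Notes", ""]
            parts += [f"- {n}" for n in self.notes]
        parts.append("")
        return "\n".join(parts)

    def write_tsv(self, individuals_path: str | Path, variants_path: str | Path) -> None:
        self.per_individual.to_csv(individuals_path, sep="\t", index=False)
        self.per_variant.to_csv(variants_path, sep="\t", index=False)


def build_report(
    diagnoses: Sequence[DiagnosisResult],
    classifications: Sequence[PanelClassification],
    conservation: Mapping[str, ConservationProfile] | None = None,
    verdicts: Mapping[str, VerdictSummary] | None = None,
    published_percents: Mapping[str, str] | None = None,
) -> ReportBundle:
    """Join diagnoses, panel classifications and per-variant evidence into a
    deterministic report.

    Raises
    ------
    ValueError
        If the diagnosis and classification id sets differ.
    """
    diag_ids = {d.individual_id for d in diagnoses}
    class_ids = {c.individual_id for c in classifications}
    if diag_ids != class_ids:
        raise ValueError(
            "diagnosis/classification id mismatch; symmetric difference: "
            f"{sorted(diag_ids ^ class_ids)}"
        )
    by_class = {c.individual_id: c for c in classifications}

    ind_rows = []
    for d in sorted(diagnoses, key=lambda d: d.individual_id):
        cl = by_class[d.individual_id]
        caveats = []
        if d.zygosity_class is ZygosityClass.COMPOUND_HET and not d.phase_resolved:
            caveats.append("phase unresolved (cis/trans unknown)")
        if not cl.others_assayed:
            caveats.append("non-panel alleles not assayed")
        ind_rows.append(
            {
                "individual_id": d.individual_id,
                "gene": d.gene or ".",
                "zygosity": d.zygosity_class.value,
                "qualifying_alleles": ";".join(
                    f"{k}x{c}" for k, c in d.qualifying_alleles
                ) or ".",
                "panel_category": cl.category.value,
                "panel_alleles": "/".join(map(str, cl.alleles_per_panel_variant)),
                "caveats": "; ".join(caveats) or ".",
            }
        )
    per_individual = pd.DataFrame(
        ind_rows,
        columns=["individual_id", "gene", "zygosity", "qualifying_alleles",
                 "panel_category", "panel_alleles", "caveats"],
    )

    var_rows = []
    variant_labels = sorted(
        set(conservation or {}) | set(verdicts or {})
    )
    for label in variant_labels:
        row: dict = {"variant": label}
        prof = (conservation or {}).get(label)
        row["n_conserved"] = prof.n_conserved if prof else "."
        row["conservation_fraction"] = (
            f"{prof.fraction:.2f}" if prof else "."
        )
        vs = (verdicts or {}).get(label)
        row["prediction_consensus"] = vs.consensus if vs else "."
        row["prediction_tally"] = vs.tally if vs else "."
        var_rows.append(row)
    per_variant = pd.DataFrame(
        var_rows,
        columns=["variant", "n_conserved", "conservation_fraction",
                 "prediction_consensus", "prediction_tally"],
    )

    notes: list[str] = []
    if published_percents:
        from .founder_screen import tabulate_distribution

        summary = tabulate_distribution(list(classifications))
        notes.extend(compare_percent_strings(summary, published_percents))
    return ReportBundle(
        per_individual=per_individual, per_variant=per_variant, notes=notes
    )
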