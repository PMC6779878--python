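"""Case ascertainment and prevalence for extreme hypouricemia.

Cases are subjects with serum uric acid strictly below the threshold
(default 1.3 mg/dL) and no secondary-cause exclusion flag. The strict
``<`` comparison matters: a subject at exactly the threshold is *not*
hypouricemic. The selection returns both the total hypouricemic count in
the screening frame and the flag-free case subset, because prevalence is
computed over the former while genetic testing operates on the latter.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .variant_model import EXCLUSION_FLAGS, IndividualRecord

__all__ = ["SelectionCriteria", "select_cases", "prevalence"]


@dataclass(frozen=True)
class SelectionCriteria:
    ua_threshold: float = 1.3
    excluded_flags: frozenset[str] = EXCLUSION_FLAGS

    def __post_init__(self) -> None:
        if self.ua_threshold <= 0:
            raise ValueError(f"ua_threshold must be > 0, got {self.ua_threshold}")
        unknown = frozenset(self.excluded_flags) - EXCLUSION_FLAGS
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        object.__setattr__(self, "excluded_flags", frozenset(self.excluded_flags))


def select_cases(
    individuals: Sequence[IndividualRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[IndividualRecord], int]:
    """Select flag-free hypouricemia cases.

    Returns ``(cases, n_hypouricemic_total)`` where the total counts every
    subject with ``serum_ua < ua_threshold`` regardless of flags, and cases
    are the subset with no excluded flag, sorted by individual id.
    """
    hypo = [i for i in individuals if i.serum_ua < criteria.ua_threshold]
    cases = [i for i in hypo if not (i.exclusion_flags & criteria.excluded_flags)]
    cases.sort(key=lambda i: i.individual_id)
    return cases, len(hypo)


def prevalence(n_hypouricemic_total: int, n_screened: int) -> tuple[Fraction, str]:
    """Exact prevalence ratio plus a percent string rounded to 3 decimals.

    >>> prevalence(148, 179318)[1]
    '0.083%'
    """
    if n_screened <= 0:
        raise ValueError(f"n_screened must be > 0, got {n_screened}")
    if not 0 <= n_hypouricemic_total <= n_screened:
        raise ValueError(
            f"need 0 <= n_hypouricemic_total <= n_screened, got "
            f"{n_hypouricemic_total}/{n_screened}"
        )
    ratio = Fraction(n_hypouricemic_total, n_screened)
    return ratio, f"{100 * float(ratio):.3f}%"
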