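"""Staged allele-sharing exclusion against escalating wild-chromosome panels.

A polymorphism can only be the causal mutation if its mutant-haplotype
allele is absent from every wild (+) chromosome: any wild chromosome
carrying the L-associated allele proves the allele predates the mutation
and excludes the site. Markers are screened in stages against panels of
increasing size and decreasing relatedness to the carrier population;
screening stops at the first stage that observes sharing, so the
cumulative counts ``k/n`` reflect only the panels actually run.

The module also provides the Haldane map function and the probability of
observing at least one recombinant in ``n`` meioses over a physical
interval, the argument used to judge whether further recombinants could
split two fully associated markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

#: Wild-chromosome panel escalation used for marker screening: an initial
#: handful of non-carrier ewes, the carrier-breed genetic family, two
#: related populations, then nine unrelated breeds (10 animals each).
DEFAULT_PANEL_SIZES = (
    ("initial", 5),
    ("Lacaune family", 103),
    ("GEBRO", 173),
    ("BMC", 148),
    ("unrelated breeds", 180),
)


@dataclass(frozen=True)
class ShareRecord:
    """Cumulative allele sharing of one polymorphism: k of n wild
    chromosomes carry the L-associated allele; ``stage`` is the last
    panel stage actually run (1-based)."""

    poly_id: str
    k: int
    n: int
    stage: int
    excluded: bool
    is_border: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got {self.k}/{self.n}")
        if self.excluded != (self.k > 0):
            raise ValueError("excluded flag must equal (k > 0)")

    @property
    def sharing(self) -> str:
        return f"{self.k}/{self.n}"


@dataclass(frozen=True)
class Panel:
    """A stage of wild chromosomes genotyped at the candidate sites.

    ``alleles`` is an ``(n_chromosomes, n_sites)`` integer matrix; use
    :data:`MISSING` (-1) for failed genotypes, which reduce ``n`` for
    that site instead of erroring.
    """

    label: str
    alleles: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles)
        if a.ndim != 2:
            raise ValueError("panel alleles must be a 2-D matrix")
        object.__setattr__(self, "alleles", a)

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]


def share_count(site_alleles: Sequence[int], l_allele: int) -> tuple[int, int]:
    """Count wild chromosomes carrying the L allele at one site.

    Returns ``(k, n)`` where ``n`` excludes missing genotypes. An empty
    panel yields ``(0, 0)`` with a warning rather than an error.
    """
    a = np.asarray(site_alleles)
    typed = a != MISSING
    n = int(typed.sum())
    if n == 0:
        warnings.warn("empty panel: no typed wild chromosomes", stacklevel=2)
        return 0, 0
    k = int((a[typed] == l_allele).sum())
    return k, n


def staged_screen(
    poly_id: str,
    site_index: int,
    l_allele: int,
    panels: Sequence[Panel],
    is_border: bool = False,
) -> ShareRecord:
    """Screen one polymorphism through ordered panels, stopping at the
    first stage where any wild chromosome shares the L allele."""
    if not panels:
        raise ValueError("staged screen requires at least one panel")
    k_tot = n_tot = 0
    stage = 0
    for stage, panel in enumerate(panels, start=1):
        k, n = share_count(panel.alleles[:, site_index], l_allele)
        k_tot += k
        n_tot += n
        if k_tot > 0:
            break
    return ShareRecord(
        poly_id=poly_id,
        k=k_tot,
        n=n_tot,
        stage=stage,
        excluded=k_tot > 0,
        is_border=is_border,
    )


def fully_associated(records: Iterable[ShareRecord]) -> list[ShareRecord]:
    """Polymorphisms still fully associated with the mutation after
    screening: never shared (k = 0) and not an interval border (border
    markers bound the minimal locus but lie outside it)."""
    return [r for r in records if not r.excluded and not r.is_border]


def haldane_r(d_morgans: float) -> float:
    """Haldane map function r = (1 - exp(-2d))/2, no crossover interference."""
    if d_morgans < 0:
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


def morgans(length_bp: float, cM_per_Mb: float = 1.0) -> float:
    """Physical length to genetic length: 1 cM/Mb = 1e-8 Morgan/bp."""
    if length_bp < 0 or cM_per_Mb < 0:
        raise ValueError("lengths and rates must be non-negative")
    return length_bp * cM_per_Mb * 1e-8


def prob_recombinant(
    length_bp: float, n_meioses: int, cM_per_Mb: float = 1.0
) -> float:
    """Probability of observing >= 1 recombinant gamete within an interval
    of ``length_bp`` over ``n_meioses`` independent meioses."""
    if n_meioses < 0:
        raise ValueError("n_meioses must be non-negative")
    r = haldane_r(morgans(length_bp, cM_per_Mb))
    return 1.0 - (1.0 - r) ** n_meioses
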