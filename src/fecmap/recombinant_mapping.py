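"""Carrier classification, pedigree phasing, recombinant detection and
reduction of the candidate interval to the zero-recombinant zone.

The logic mirrors classical within-family fine mapping: every phased
chromosome whose mutant-lineage (L) segment switches to wild lineage
between two informative markers is a recombinant; a chromosome known to
carry the causal allele places it inside its L segment, a chromosome
known not to carry it places it outside. The minimal interval is the
intersection of those constraints, reported between the two closest
recombinant (border) markers, which themselves lie outside the minimal
locus.

Phasing is pedigree-certain only: allele transmissions are assigned
where one parent is homozygous or the offspring is homozygous, and
ambiguous sites are flagged rather than guessed. Double crossovers
inside one inter-marker gap are unobservable and therefore undetected;
lineage between concordant informative markers is imputed under the
minimal-recombination assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import GenomicInterval, MarkerMap
from .synthetic_data import GENOTYPE_CLASSES, L_LINEAGE, Animal, Pedigree

UNKNOWN = -1
WILD = 0
L = 1

_COPIES = {"+/+": 0, "L/+": 1, "L/L": 2}


# ---------------------------------------------------------------------------
# carrier classification from proxy markers
# ---------------------------------------------------------------------------


def classify_genotype_from_markers(
    proxy_pat: Sequence[int], proxy_mat: Sequence[int]
) -> str | None:
    """Genotype class from phased proxy-marker alleles (1 = L-defining).

    A haplotype is called L when every typed proxy allele is the
    L-defining allele. Returns None (flagged unknown) when either
    haplotype has no typed proxy marker.
    """
    classes = []
    for hap in (np.asarray(proxy_pat), np.asarray(proxy_mat)):
        typed = hap[hap != UNKNOWN]
        if typed.size == 0:
            return None
        classes.append(bool((typed == 1).all()))
    return GENOTYPE_CLASSES[sum(classes)]


def classification_accuracy(observed: Sequence[str], truth: Sequence[str]) -> float:
    obs, tru = list(observed), list(truth)
    if len(obs) != len(tru) or not obs:
        raise ValueError("need equal-length, non-empty class lists")
    return sum(o == t for o, t in zip(obs, tru)) / len(obs)


# ---------------------------------------------------------------------------
# pedigree-certain phasing
# ---------------------------------------------------------------------------


@dataclass
class PhasedChromosome:
    """One transmitted chromosome: phased alleles (-1 where ambiguous),
    inferred L-lineage per marker (1 / 0 / -1 unknown), and per-site
    Mendelian-error flags (flagged sites are excluded from inference)."""

    animal_id: str
    parent: str  # "pat" or "mat"
    alleles: np.ndarray
    l_lineage: np.ndarray
    mendel_error: np.ndarray
    carries_causal: bool | None = None


def phase_by_descent(
    pedigree: Pedigree, l_founders: set[str] | None = None
) -> dict[tuple[str, str], PhasedChromosome]:
    """Phase every animal's chromosomes from genotype dosages and parent
    links, propagating L-lineage labels down from the mutant founder(s).

    Only transmission-certain assignments are made: a site is phased when
    the offspring is homozygous or one parent is homozygous; an offspring
    allele not producible by the recorded parents raises a per-site
    Mendelian-error flag and the site is excluded.
    """
    if l_founders is None:
        l_founders = {
            a.id
            for a in pedigree.animals
            if a.generation == "founder" and a.observed_class == "L/L"
        }
    n = len(pedigree.marker_map)
    dosage = {a.id: a.dosage for a in pedigree.animals}
    phased: dict[tuple[str, str], PhasedChromosome] = {}

    def founder_chromosomes(a: Animal) -> None:
        g = dosage[a.id]
        is_l = a.id in l_founders
        for side in ("pat", "mat"):
            al = np.where(g == 0, 0, np.where(g == 2, 1, UNKNOWN)).astype(np.int8)
            lin = np.full(n, L if is_l else WILD, dtype=np.int8)
            phased[(a.id, side)] = PhasedChromosome(
                a.id, side, al, lin, np.zeros(n, dtype=bool)
            )

    def transmitted_lineage(
        parent_id: str, child_allele: np.ndarray
    ) -> np.ndarray:
        """Lineage of the gamete received from ``parent_id``."""
        p1 = phased[(parent_id, "pat")]
        p2 = phased[(parent_id, "mat")]
        lin = np.full(n, UNKNOWN, dtype=np.int8)
        same = (p1.l_lineage == p2.l_lineage) & (p1.l_lineage != UNKNOWN)
        lin[same] = p1.l_lineage[same]
        # parent heterozygous with phase known: the transmitted allele
        # identifies which parental haplotype (hence lineage) was copied
        informative = (
            (p1.alleles != UNKNOWN)
            & (p2.alleles != UNKNOWN)
            & (p1.alleles != p2.alleles)
            & (child_allele != UNKNOWN)
        )
        from_p1 = informative & (child_allele == p1.alleles)
        from_p2 = informative & (child_allele == p2.alleles)
        lin[from_p1 & (p1.l_lineage != UNKNOWN)] = p1.l_lineage[
            from_p1 & (p1.l_lineage != UNKNOWN)
        ]
        lin[from_p2 & (p2.l_lineage != UNKNOWN)] = p2.l_lineage[
            from_p2 & (p2.l_lineage != UNKNOWN)
        ]
        return lin

    for a in pedigree.animals:
        if a.generation == "founder":
            founder_chromosomes(a)
            continue
        g = dosage[a.id]
        gs = dosage[a.sire]
        gd = dosage[a.dam]
        pat = np.full(n, UNKNOWN, dtype=np.int8)
        mat = np.full(n, UNKNOWN, dtype=np.int8)
        err = np.zeros(n, dtype=bool)
        hom = g != 1
        pat[hom] = (g[hom] // 2).astype(np.int8)
        mat[hom] = pat[hom]
        het = ~hom
        sire_hom = het & (gs != 1)
        pat[sire_hom] = (gs[sire_hom] // 2).astype(np.int8)
        mat[sire_hom] = 1 - pat[sire_hom]
        dam_hom = het & (gs == 1) & (gd != 1)
        mat[dam_hom] = (gd[dam_hom] // 2).astype(np.int8)
        pat[dam_hom] = 1 - mat[dam_hom]
        # Mendelian consistency: each transmitted allele must exist in
        # its parent's genotype
        for child_al, parent_g in ((pat, gs), (mat, gd)):
            known = child_al != UNKNOWN
            bad = known & (
                ((child_al == 1) & (parent_g == 0))
                | ((child_al == 0) & (parent_g == 2))
            )
            err |= bad
        pat[err] = UNKNOWN
        mat[err] = UNKNOWN
        lin_pat = transmitted_lineage(a.sire, pat)
        lin_mat = transmitted_lineage(a.dam, mat)
        lin_pat[err] = UNKNOWN
        lin_mat[err] = UNKNOWN
        phased[(a.id, "pat")] = PhasedChromosome(a.id, "pat", pat, lin_pat, err)
        phased[(a.id, "mat")] = PhasedChromosome(a.id, "mat", mat, lin_mat, err)
    return phased


def assign_carrier_chromosomes(
    phased: Mapping[tuple[str, str], PhasedChromosome],
    pedigree: Pedigree,
) -> list[PhasedChromosome]:
    """Decide, per chromosome, whether it carries the causal allele, from
    the animal's genotype class and the pair's L-segment content.

    Ambiguous pairs (one mutant copy, both chromosomes showing L
    segments) are skipped rather than guessed.
    """
    out: list[PhasedChromosome] = []
    for a in pedigree.non_founders:
        if a.observed_class not in _COPIES:
            continue
        copies = _COPIES[a.observed_class]
        pair = [phased[(a.id, "pat")], phased[(a.id, "mat")]]
        if copies == 0:
            flags: list[bool | None] = [False, False]
        elif copies == 2:
            flags = [True, True]
        else:
            has_l = [bool((c.l_lineage == L).any()) for c in pair]
            known = [bool((c.l_lineage != UNKNOWN).any()) for c in pair]
            if has_l == [True, False] and known[1]:
                flags = [True, False]
            elif has_l == [False, True] and known[0]:
                flags = [False, True]
            else:
                flags = [None, None]
        for c, f in zip(pair, flags):
            if f is None:
                continue
            c.carries_causal = f
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# recombinant detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinantChromosome:
    """A chromosome whose lineage switches between two adjacent
    informative markers; the crossover lies in the open interval."""

    animal_id: str
    parent: str
    lo_pos: int
    hi_pos: int
    lo_marker: str
    hi_marker: str
    from_lineage: int  # lineage left of the breakpoint (L or WILD)
    to_lineage: int
    side: str = "unknown"  # which flank of the locus this trims


def detect_recombinants(
    chromosomes: Iterable[PhasedChromosome], marker_map: MarkerMap
) -> list[RecombinantChromosome]:
    """Breakpoints between adjacent informative markers with discordant
    lineage. A fully L or fully wild chromosome yields none; two
    crossovers inside one inter-marker gap are invisible here."""
    positions = marker_map.positions
    ids = marker_map.ids
    out = []
    for c in chromosomes:
        info = np.flatnonzero(c.l_lineage != UNKNOWN)
        for i, j in zip(info, info[1:]):
            if c.l_lineage[i] != c.l_lineage[j]:
                if c.carries_causal is None:
                    side = "unknown"
                else:
                    # the discordant flank is wild on a carrier, L on a
                    # non-carrier; that flank is the one trimmed
                    wild_right = c.l_lineage[j] == WILD
                    trims_distal = wild_right if c.carries_causal else not wild_right
                    side = "distal" if trims_distal else "proximal"
                out.append(
                    RecombinantChromosome(
                        c.animal_id, c.parent,
                        int(positions[i]), int(positions[j]),
                        ids[i], ids[j],
                        int(c.l_lineage[i]), int(c.l_lineage[j]),
                        side,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# interval reduction
# ---------------------------------------------------------------------------


@dataclass
class ZoneClassification:
    """Recombinant counts over the region's atoms.

    Atoms alternate: open segment, marker, open segment, ..., marker,
    open segment (2 * n_markers + 1 entries). ``counts[i]`` is the number
    of constraint chromosomes excluding atom i; the zero-count atoms form
    the zero-recombinant zone."""

    marker_map: MarkerMap
    region: tuple[int, int]
    counts: np.ndarray

    def category(self) -> np.ndarray:
        """Counts collapsed to the conventional 0 / 1 / >=2 classes."""
        return np.minimum(self.counts, 2)


def _imputed_lineage_atoms(
    c: PhasedChromosome, n_markers: int
) -> np.ndarray:
    """Per-atom lineage under minimal recombination: markers keep their
    known lineage; a gap takes the shared lineage of its flanking
    informative markers, else UNKNOWN."""
    lin = c.l_lineage
    atoms = np.full(2 * n_markers + 1, UNKNOWN, dtype=np.int8)
    info = np.flatnonzero(lin != UNKNOWN)
    if info.size == 0:
        return atoms
    for k in info:
        atoms[2 * k + 1] = lin[k]
    # terminal gaps inherit the nearest informative marker's lineage
    first, last = info[0], info[-1]
    atoms[: 2 * first + 1] = lin[first]
    atoms[2 * last + 2 :] = lin[last]
    # interior gaps: filled when flanking informative markers agree
    for a, b in zip(info, info[1:]):
        if lin[a] == lin[b]:
            atoms[2 * a + 2 : 2 * b + 1] = lin[a]
    return atoms


def reduce_interval(
    chromosomes: Sequence[PhasedChromosome],
    marker_map: MarkerMap,
    region: tuple[int, int],
) -> tuple[GenomicInterval, ZoneClassification]:
    """Intersect all carrier-segment constraints into the minimal interval.

    A carrier chromosome excludes atoms imputed wild; a non-carrier
    chromosome excludes atoms imputed L. The reported interval runs
    between the closest excluded (recombinant border) markers, which
    bound but do not belong to the minimal locus; a side with no
    excluding marker falls back to the region bound with a warning.

    If the constraints are jointly unsatisfiable (no atom left), the
    cause is a mislabelled carrier status (e.g. a proxy-marker
    misclassification), not a recombination pattern: the offending
    constraints are dropped greedily — most-excluding chromosome first,
    i.e. the one most discordant with the consensus — with a warning,
    until a zero-recombinant zone reappears.
    """
    n = len(marker_map)
    masks: list[tuple[np.ndarray, PhasedChromosome]] = []
    for c in chromosomes:
        if c.carries_causal is None:
            continue
        atoms = _imputed_lineage_atoms(c, n)
        excluded = atoms == (WILD if c.carries_causal else L)
        masks.append((excluded, c))
    counts = np.zeros(2 * n + 1, dtype=int)
    for m, _ in masks:
        counts += m
    while masks and not (counts == 0).any():
        worst = max(range(len(masks)), key=lambda i: masks[i][0].sum())
        mask, c = masks.pop(worst)
        counts -= mask
        warnings.warn(
            f"dropping inconsistent constraint chromosome {c.animal_id}/"
            f"{c.parent} (conflicting carrier classification?)",
            stacklevel=2,
        )
    zones = ZoneClassification(marker_map, region, counts)

    zero = counts == 0
    runs: list[tuple[int, int]] = []
    start = None
    for i, z in enumerate(zero):
        if z and start is None:
            start = i
        elif not z and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(zero) - 1))
    if not runs:
        raise ValueError("no zero-recombinant zone and no constraints to drop")
    if len(runs) > 1:
        warnings.warn(
            "zero-recombinant zone is not contiguous; keeping the widest run",
            stacklevel=2,
        )
    positions = marker_map.positions

    def atom_lo(i: int) -> int:
        # left boundary position of atom i
        return region[0] if i == 0 else positions[(i - 1) // 2]

    def atom_hi(i: int) -> int:
        return region[1] if i == 2 * n else positions[i // 2]

    lo_a, hi_a = max(runs, key=lambda r: atom_hi(r[1]) - atom_lo(r[0]))
    if lo_a == 0:
        warnings.warn("no proximal recombinant: interval open at region start",
                      stacklevel=2)
        start_bp, prox_id = region[0], None
    else:
        # the atom left of the run is an excluded marker (imputation makes
        # excluded blocks end on informative markers); snap to it
        k = (lo_a - 1) // 2
        start_bp, prox_id = int(positions[k]), marker_map.ids[k]
    if hi_a == 2 * n:
        warnings.warn("no distal recombinant: interval open at region end",
                      stacklevel=2)
        end_bp, dist_id = region[1], None
    else:
        k = hi_a // 2
        end_bp, dist_id = int(positions[k]), marker_map.ids[k]
    interval = GenomicInterval("sim", start_bp, end_bp, prox_id, dist_id)
    return interval, zones
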