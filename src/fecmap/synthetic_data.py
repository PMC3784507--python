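"""Forward simulation of every input the fine-mapping pipeline consumes.

The generator emulates the study design around a livestock fecundity
locus: a single mutant haplotype (the L haplotype) carrying one causal
variant inside a ~488 kb region, an experimental F1 / backcross /
intercross pedigree segregating that haplotype, staged panels of wild
chromosomes from increasingly unrelated populations, additive
ovulation-rate phenotypes (+1.5 ova per mutant copy), efficiency-aware
qPCR Ct tables, and replicate-structured protein-identification tables.

Randomness is fully reproducible: one master seed, one named substream
per stage (:func:`substream`), so re-running any stage with the same
configuration is bit-identical regardless of what ran before it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_screen import DEFAULT_PANEL_SIZES, Panel, morgans
from .genome_model import MarkerMap, marker_map_from_positions

GENOTYPE_CLASSES = ("+/+", "L/+", "L/L")
L_LINEAGE = 0  # lineage code of the mutant founder haplotype

OVARIAN_TISSUES = ("GC-SF", "GC-LF", "TC-LF")
NON_OVARIAN_TISSUES = ("pituitary", "hypothalamus", "intestine")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of the master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeDesign:
    """Counts of non-founder animals per generation; the default split of
    the 189 experimental animals across F1, backcross and intercross."""

    n_f1: int = 20
    n_bc: int = 100
    n_f1xbc: int = 69

    @property
    def total(self) -> int:
        return self.n_f1 + self.n_bc + self.n_f1xbc


@dataclass(frozen=True)
class ORModel:
    """Additive ovulation-rate model: OR = base + effect * copies + noise."""

    base_mean: float = 1.2
    per_copy_effect: float = 1.5
    residual_sd: float = 0.8


@dataclass(frozen=True)
class PanelSpec:
    """One wild-chromosome screening stage.

    ``share_rate`` is the chance a wild chromosome carries the
    L-associated allele at the sites closest to the causal one;
    sharing decays with distance as exp(-d / decay_length_bp).
    ``decay_length_bp = 0`` means no sharing anywhere.
    """

    label: str
    n_chromosomes: int
    share_rate: float = 0.25
    decay_length_bp: float = 200_000.0


def default_panels() -> tuple[PanelSpec, ...]:
    rates = {"initial": 0.30, "Lacaune family": 0.30, "GEBRO": 0.20,
             "BMC": 0.20, "unrelated breeds": 0.10}
    return tuple(
        PanelSpec(label, n, share_rate=rates[label])
        for label, n in DEFAULT_PANEL_SIZES
    )


@dataclass(frozen=True)
class ExpressionDesign:
    """True per-gene, per-tissue fold changes (L/L over +/+) driving the
    qPCR simulation; any (gene, tissue) not listed has fold 1."""

    fold_changes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "B4GALNT2": {"GC-SF": 1000.0, "GC-LF": 1000.0, "TC-LF": 1000.0},
            "IGF2BP1": {"GC-SF": 6.0, "GC-LF": 6.0},
        }
    )
    tissues: tuple[str, ...] = OVARIAN_TISSUES + NON_OVARIAN_TISSUES
    reference_gene: str = "RPL19"
    n_per_group: int = 5
    ct_base: float = 20.0
    ct_noise_sd: float = 0.25

    def fold(self, gene: str, tissue: str) -> float:
        return float(self.fold_changes.get(gene, {}).get(tissue, 1.0))


@dataclass(frozen=True)
class MsDesign:
    """Shape of the simulated protein-identification tables."""

    n_background: int = 20
    n_exclusive: int = 10
    replicates: int = 2
    min_exclusive_peptides: int = 4
    mean_extra_peptides: float = 5.0
    probability_low: float = 0.96
    shared_peptide_rate: float = 0.0
    mw_range_kda: tuple[float, float] = (39.0, 613.0)


@dataclass(frozen=True)
class SimulationConfig:
    region_length: int = 488_195
    n_variant_sites: int = 49
    causal_index: int | None = None  # default: middle site
    cM_per_Mb: float = 1.0
    pedigree: PedigreeDesign = field(default_factory=PedigreeDesign)
    n_wild_founders: int = 60
    panels: tuple[PanelSpec, ...] = field(default_factory=default_panels)
    or_model: ORModel = field(default_factory=ORModel)
    proxy_misclassification: float = 0.005
    n_proxy_markers: int = 4
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)
    ms: MsDesign = field(default_factory=MsDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0 or self.n_variant_sites < 1:
            raise ValueError("region and site counts must be positive")
        ci = self.causal_index
        if ci is not None and not 0 <= ci < self.n_variant_sites:
            raise ValueError("causal site outside the region's site list")
        if not 0.0 <= self.proxy_misclassification <= 1.0:
            raise ValueError("misclassification rate must be in [0, 1]")
        if self.or_model.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        if self.cM_per_Mb < 0:
            raise ValueError("recombination rate must be non-negative")

    @property
    def causal(self) -> int:
        return (
            self.n_variant_sites // 2
            if self.causal_index is None
            else self.causal_index
        )


# ---------------------------------------------------------------------------
# haplotypes and founders
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """Allele vector aligned to a marker map, plus the per-site lineage of
    origin (ground truth for recombination analysis)."""

    alleles: np.ndarray
    lineage: np.ndarray  # per-site founder lineage code; L_LINEAGE is mutant

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.lineage = np.asarray(self.lineage, dtype=np.int32)
        if self.alleles.shape != self.lineage.shape:
            raise ValueError("allele and lineage vectors differ in length")

    def copy(self) -> "Haplotype":
        return Haplotype(self.alleles.copy(), self.lineage.copy())


def _uniform_lineage(code: int, n: int) -> np.ndarray:
    return np.full(n, code, dtype=np.int32)


@dataclass
class FounderPool:
    """The mutant haplotype plus wild founder haplotypes, with the
    per-site probability that a fresh wild chromosome carries the
    L-associated allele."""

    marker_map: MarkerMap
    causal_index: int
    l_haplotype: Haplotype
    wild_haplotypes: list[Haplotype]
    wild_share_probs: np.ndarray
    _next_lineage: int = field(init=False)

    def __post_init__(self) -> None:
        self._next_lineage = 1 + len(self.wild_haplotypes)

    def draw_wild(self, rng: np.random.Generator) -> Haplotype:
        """A fresh wild haplotype with a new lineage code."""
        alleles = (
            rng.random(len(self.wild_share_probs)) < self.wild_share_probs
        ).astype(np.int8)
        hap = Haplotype(alleles, _uniform_lineage(self._next_lineage, alleles.size))
        self._next_lineage += 1
        return hap


def share_probabilities(
    positions: np.ndarray,
    causal_index: int,
    share_rate: float,
    decay_length_bp: float,
) -> np.ndarray:
    """Per-site probability that a wild chromosome carries the L allele.

    Sharing is highest near the causal site (old flanking variation
    travels with related haplotypes) and always exactly zero at the
    causal site itself: the mutation is unique to the L lineage.
    """
    d = np.abs(positions - positions[causal_index]).astype(float)
    if decay_length_bp == 0:
        p = np.zeros_like(d)
    else:
        p = share_rate * np.exp(-d / decay_length_bp)
    p[causal_index] = 0.0
    return p


def simulate_founders(
    config: SimulationConfig,
    rng: np.random.Generator,
    site_share_probs: Sequence[float] | None = None,
) -> FounderPool:
    """Build the founder haplotype pool: one L haplotype carrying the
    causal allele at the causal site plus ``n_wild_founders`` wild
    haplotypes that may share L alleles at non-causal sites.

    ``site_share_probs`` overrides the distance-decay sharing model with
    explicit per-site probabilities (causal site is forced to zero).
    """
    if config.n_wild_founders < 1:
        raise ValueError("at least one wild founder haplotype is required")
    n = config.n_variant_sites
    positions = np.sort(
        rng.choice(np.arange(1, config.region_length + 1), size=n, replace=False)
    )
    mmap = marker_map_from_positions("sim", positions)
    causal = config.causal
    if site_share_probs is None:
        base = config.panels[0] if config.panels else PanelSpec("wild", 0)
        probs = share_probabilities(
            positions, causal, base.share_rate, base.decay_length_bp
        )
    else:
        probs = np.asarray(site_share_probs, dtype=float).copy()
        if probs.shape != (n,):
            raise ValueError("need one share probability per site")
        probs[causal] = 0.0
    l_hap = Haplotype(np.ones(n, dtype=np.int8), _uniform_lineage(L_LINEAGE, n))
    wild = [
        Haplotype(
            (rng.random(n) < probs).astype(np.int8), _uniform_lineage(i + 1, n)
        )
        for i in range(config.n_wild_founders)
    ]
    return FounderPool(mmap, causal, l_hap, wild, probs)


def simulate_panels(
    config: SimulationConfig,
    pool: FounderPool,
    rng: np.random.Generator,
) -> list[Panel]:
    """Wild-chromosome genotype panels for the staged allele screen."""
    positions = np.asarray(pool.marker_map.positions)
    out = []
    for spec in config.panels:
        probs = share_probabilities(
            positions, pool.causal_index, spec.share_rate, spec.decay_length_bp
        )
        alleles = (
            rng.random((spec.n_chromosomes, positions.size)) < probs
        ).astype(np.int8)
        out.append(Panel(spec.label, alleles))
    return out


# ---------------------------------------------------------------------------
# meiosis and pedigree
# ---------------------------------------------------------------------------


def simulate_meiosis(
    hap_a: Haplotype,
    hap_b: Haplotype,
    positions: Sequence[int],
    cM_per_Mb: float,
    rng: np.random.Generator,
    region: tuple[int, int] | None = None,
) -> tuple[Haplotype, list[float]]:
    """One gamete from a parental haplotype pair.

    Crossovers follow a Poisson process without interference on the
    genetic map (``cM_per_Mb`` uniform over the region), so the
    recombination fraction between two markers equals the Haldane value
    for their genetic distance. Returns the gamete and the crossover
    positions in bp.
    """
    positions = np.asarray(positions)
    lo, hi = region if region is not None else (positions[0], positions[-1])
    length_m = morgans(max(hi - lo, 0), cM_per_Mb)
    n_x = rng.poisson(length_m) if length_m > 0 else 0
    crossovers = np.sort(rng.uniform(lo, hi, size=n_x)) if n_x else np.empty(0)
    start = int(rng.integers(2))
    # phase at each site = start flipped once per crossover to its left
    phase = (start + np.searchsorted(crossovers, positions)) % 2
    parents = (hap_a, hap_b)
    alleles = np.where(phase == 0, parents[0].alleles, parents[1].alleles)
    lineage = np.where(phase == 0, parents[0].lineage, parents[1].lineage)
    return Haplotype(alleles, lineage), [float(x) for x in crossovers]


@dataclass
class Animal:
    id: str
    sire: str | None
    dam: str | None
    generation: str  # founder, F1, BC, F1xBC
    hap_pat: Haplotype
    hap_mat: Haplotype
    true_class: str = "+/+"
    observed_class: str = "+/+"

    def l_copies(self, causal_index: int) -> int:
        return int(self.hap_pat.lineage[causal_index] == L_LINEAGE) + int(
            self.hap_mat.lineage[causal_index] == L_LINEAGE
        )

    @property
    def dosage(self) -> np.ndarray:
        return (self.hap_pat.alleles + self.hap_mat.alleles).astype(np.int8)


@dataclass
class Pedigree:
    marker_map: MarkerMap
    causal_index: int
    animals: list[Animal]  # founders first, then F1, BC, F1xBC in order

    @property
    def non_founders(self) -> list[Animal]:
        return [a for a in self.animals if a.generation != "founder"]

    def by_id(self, animal_id: str) -> Animal:
        for a in self.animals:
            if a.id == animal_id:
                return a
        raise KeyError(animal_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [a.id for a in self.animals],
                "sire": [a.sire or "" for a in self.animals],
                "dam": [a.dam or "" for a in self.animals],
                "generation": [a.generation for a in self.animals],
                "true_class": [a.true_class for a in self.animals],
                "observed_class": [a.observed_class for a in self.animals],
            }
        )

    def genotype_frame(self) -> pd.DataFrame:
        mat = np.vstack([a.dosage for a in self.animals])
        return pd.DataFrame(
            mat, index=[a.id for a in self.animals], columns=self.marker_map.ids
        )


def _classify(copies: int) -> str:
    return GENOTYPE_CLASSES[copies]


def simulate_pedigree(
    config: SimulationConfig,
    pool: FounderPool,
    rng: np.random.Generator,
) -> Pedigree:
    """Forward-simulate the experimental pedigree.

    An L/L founder ram is mated to wild founder ewes to produce the F1;
    backcross (BC) animals are F1 x fresh wild ewes; intercross (F1xBC)
    animals are F1 x BC. Proxy genotype classification is corrupted at
    the configured per-animal misclassification rate.
    """
    design = config.pedigree
    if design.n_f1 > 0 and config.n_wild_founders < 1:
        raise ValueError("F1 animals requested but no wild founders available")
    if design.n_bc > 0 and design.n_f1 == 0:
        raise ValueError("backcross animals require F1 parents")
    if design.n_f1xbc > 0 and (design.n_f1 == 0 or design.n_bc == 0):
        raise ValueError("intercross animals require both F1 and BC parents")

    positions = pool.marker_map.positions
    n_sites = len(positions)
    causal = pool.causal_index
    animals: list[Animal] = []

    ram = Animal(
        "ram0", None, None, "founder", pool.l_haplotype.copy(),
        pool.l_haplotype.copy(), "L/L", "L/L",
    )
    animals.append(ram)

    ewes: list[Animal] = []

    def fresh_ewe() -> Animal:
        ewe = Animal(
            f"ewe{len(ewes)}", None, None, "founder",
            pool.draw_wild(rng), pool.draw_wild(rng), "+/+", "+/+",
        )
        ewes.append(ewe)
        animals.append(ewe)
        return ewe

    def child(ident: str, sire: Animal, dam: Animal, gen: str) -> Animal:
        pat, _ = simulate_meiosis(
            sire.hap_pat, sire.hap_mat, positions, config.cM_per_Mb, rng
        )
        mat, _ = simulate_meiosis(
            dam.hap_pat, dam.hap_mat, positions, config.cM_per_Mb, rng
        )
        a = Animal(ident, sire.id, dam.id, gen, pat, mat)
        a.true_class = _classify(a.l_copies(causal))
        if rng.random() < config.proxy_misclassification:
            others = [c for c in GENOTYPE_CLASSES if c != a.true_class]
            a.observed_class = others[int(rng.integers(len(others)))]
        else:
            a.observed_class = a.true_class
        animals.append(a)
        return a

    f1 = [child(f"f1_{i}", ram, fresh_ewe(), "F1") for i in range(design.n_f1)]
    bc = [
        child(
            f"bc_{i}", f1[int(rng.integers(len(f1)))], fresh_ewe(), "BC"
        )
        for i in range(design.n_bc)
    ]
    for i in range(design.n_f1xbc):
        child(
            f"ic_{i}",
            f1[int(rng.integers(len(f1)))],
            bc[int(rng.integers(len(bc)))],
            "F1xBC",
        )
    return Pedigree(pool.marker_map, causal, animals)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    l_copies: Sequence[int],
    or_model: ORModel,
    rng: np.random.Generator,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Additive ovulation-rate phenotypes for animals with the given
    mutant-copy counts: OR = base + effect * copies + N(0, sd)."""
    if or_model.residual_sd < 0:
        raise ValueError("residual sd must be non-negative")
    copies = np.asarray(l_copies, dtype=int)
    noise = (
        rng.normal(0.0, or_model.residual_sd, size=copies.size)
        if or_model.residual_sd > 0
        else np.zeros(copies.size)
    )
    ovulation = or_model.base_mean + or_model.per_copy_effect * copies + noise
    return pd.DataFrame(
        {
            "id": list(ids) if ids is not None else [f"a{i}" for i in range(copies.size)],
            "l_copies": copies,
            "genotype": [_classify(int(c)) for c in copies],
            "ovulation_rate": ovulation,
        }
    )


def pedigree_phenotypes(
    pedigree: Pedigree, or_model: ORModel, rng: np.random.Generator
) -> pd.DataFrame:
    animals = pedigree.non_founders
    return simulate_phenotypes(
        [a.l_copies(pedigree.causal_index) for a in animals],
        or_model,
        rng,
        ids=[a.id for a in animals],
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    design: ExpressionDesign,
    efficiencies: Mapping[str, float],
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Ct table for target and reference genes across tissues/genotypes.

    Ct = ct_base - log_E(relative abundance) + N(0, noise); wild-type
    abundance is 1, mutant abundance is the configured fold change, and
    the reference gene is unregulated. With zero noise the downstream
    efficiency-corrected ratio recovers each fold change exactly.
    """
    sd = design.ct_noise_sd if noise_sd is None else noise_sd
    if sd < 0:
        raise ValueError("Ct noise sd must be non-negative")
    genes = list(design.fold_changes) + [design.reference_gene]
    for g in genes:
        if g not in efficiencies:
            raise KeyError(f"no amplification efficiency for gene {g!r}")
        if efficiencies[g] <= 1.0:
            raise ValueError(f"amplification efficiency must exceed 1 ({g})")
    rows = []
    for tissue in design.tissues:
        for genotype in ("+/+", "L/L"):
            for i in range(design.n_per_group):
                sample = f"{tissue}:{genotype}:{i}"
                for gene in genes:
                    if gene == design.reference_gene:
                        abundance = 1.0
                    else:
                        abundance = (
                            design.fold(gene, tissue) if genotype == "L/L" else 1.0
                        )
                    e = efficiencies[gene]
                    ct = design.ct_base - math.log(abundance) / math.log(e)
                    if sd > 0:
                        ct += rng.normal(0.0, sd)
                    rows.append((sample, tissue, genotype, gene, ct))
    return pd.DataFrame(
        rows, columns=["sample", "tissue", "genotype", "gene", "ct"]
    )


# ---------------------------------------------------------------------------
# mass spectrometry
# ---------------------------------------------------------------------------


def simulate_ms_table(
    design: MsDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Replicate-structured protein identification table.

    The configured exclusive proteins are identified in every mutant
    replicate (with peptide counts and probabilities clearing the
    downstream thresholds) and in no wild-type replicate; background
    proteins are identified everywhere. A fraction of background
    peptides may be shared between two proteins to exercise
    shared-peptide removal.
    """
    if design.n_exclusive < 0 or design.n_background < 0:
        raise ValueError("protein counts must be non-negative")
    lo, hi = design.mw_range_kda
    rows = []

    def peptide_ids(name: str, n: int) -> list[str]:
        return [f"{name}_p{j}" for j in range(n)]

    shared_donors: list[str] = []
    for i in range(design.n_background):
        name = f"BG{i}"
        npep = design.min_exclusive_peptides + rng.poisson(
            design.mean_extra_peptides
        )
        peps = peptide_ids(name, npep)
        # optionally share one peptide with the previous background protein
        if shared_donors and rng.random() < design.shared_peptide_rate:
            peps[-1] = shared_donors[-1]
        shared_donors.extend(peps)
        mw = float(rng.uniform(lo, hi))
        for genotype in ("+/+", "L/L"):
            for rep in range(1, design.replicates + 1):
                sc = float(npep * 3 + rng.integers(-2, 3))
                rows.append(
                    (name, name, rep, genotype, len(set(peps)),
                     float(rng.uniform(design.probability_low, 1.0)), sc, mw,
                     ";".join(peps))
                )
    exclusive_mws = np.sort(rng.uniform(lo, hi, size=design.n_exclusive))[::-1]
    if design.n_exclusive:  # pin the configured MW range exactly
        exclusive_mws[0], exclusive_mws[-1] = hi, lo
    for i in range(design.n_exclusive):
        name = f"EXCL{i}"
        npep = design.min_exclusive_peptides + rng.poisson(
            design.mean_extra_peptides
        )
        peps = peptide_ids(name, npep)
        for rep in range(1, design.replicates + 1):
            sc = float(npep * 3 + rng.integers(-2, 3))
            rows.append(
                (name, name, rep, "L/L", npep,
                 float(rng.uniform(design.probability_low, 1.0)), sc,
                 float(exclusive_mws[i]), ";".join(peps))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "gene_symbol", "replicate", "genotype", "n_peptides",
            "probability", "spectral_count", "mw_kda", "peptides",
        ],
    )


# ---------------------------------------------------------------------------
# haplotype sequences with planted variants
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one planted sequence difference (wild coordinates,
    1-based, first differing base; insertions use the first wild base
    after the insertion point)."""

    pos: int
    ptype: str  # SNP / MICROSAT / INDEL
    wild: str
    mutant: str
    motif: str | None = None
    wild_repeats: int | None = None
    mutant_repeats: int | None = None


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _derepeat(seq: str) -> str:
    """Break accidental >=5x tandem 2-6 bp repeats so planted microsats
    are the only ones present (keeps oracle comparisons exact)."""
    s = list(seq)
    for k in range(2, 7):
        i = 0
        while i + 5 * k <= len(s):
            unit = s[i : i + k]
            run = 1
            while (
                i + (run + 1) * k <= len(s)
                and s[i + run * k : i + (run + 1) * k] == unit
            ):
                run += 1
            if run >= 5:
                j = i + 4 * k  # mutate one base inside the 5th copy
                s[j] = "A" if s[j] != "A" else "C"
            i += max(1, (run - 4)) if run >= 5 else 1
    return "".join(s)


def plant_variants(
    wild: str, variants: Sequence[PlantedVariant]
) -> str:
    """Apply planted edits (sorted, non-overlapping) to the wild sequence."""
    out = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        start = v.pos - 1
        out.append(wild[cursor:start])
        out.append(v.mutant)
        cursor = start + len(v.wild)
    out.append(wild[cursor:])
    return "".join(out)


def simulate_sequence_pair(
    length: int,
    rng: np.random.Generator,
    n_snp: int = 3,
    n_microsat: int = 1,
    n_indel: int = 1,
    spacing: int = 40,
) -> tuple[str, str, list[PlantedVariant]]:
    """A wild/mutant sequence pair with planted, well-separated variants.

    Variants are spaced at least ``spacing`` bp apart inside a
    repeat-free wild sequence, so the planted list is exactly what an
    ideal variant caller must report.
    """
    wild = _derepeat(random_sequence(length, rng))
    n_total = n_snp + n_microsat + n_indel
    if n_total == 0:
        return wild, wild, []
    usable = length - 2 * spacing
    if usable < n_total * spacing:
        raise ValueError("sequence too short for the requested variants")
    anchors = np.sort(
        rng.choice(np.arange(spacing, length - spacing), size=n_total, replace=False)
    )
    while np.any(np.diff(anchors) < spacing):
        anchors = np.sort(
            rng.choice(
                np.arange(spacing, length - spacing), size=n_total, replace=False
            )
        )
    kinds = ["SNP"] * n_snp + ["MICROSAT"] * n_microsat + ["INDEL"] * n_indel
    rng.shuffle(kinds)
    variants: list[PlantedVariant] = []
    wild_list = list(wild)
    for pos0, kind in zip(anchors, kinds):
        pos = int(pos0) + 1  # 1-based
        if kind == "SNP":
            ref = wild_list[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(PlantedVariant(pos, "SNP", ref, alt))
        elif kind == "MICROSAT":
            motif = "".join(rng.choice(_BASES, size=2))
            while motif[0] == motif[1]:
                motif = "".join(rng.choice(_BASES, size=2))
            n_rep = int(rng.integers(5, 9))
            run = motif * n_rep
            # install the run into the wild sequence at pos, and break the
            # repeat at both flanks so the planted run is maximal
            wild_list[pos - 1 : pos - 1 + len(run)] = list(run)
            non_motif = [b for b in "ACGT" if b not in motif]
            wild_list[pos - 2] = str(rng.choice(non_motif))
            wild_list[pos - 1 + len(run)] = str(rng.choice(non_motif))
            variants.append(
                PlantedVariant(
                    pos, "MICROSAT", run, motif * (n_rep + 1),
                    motif=motif, wild_repeats=n_rep, mutant_repeats=n_rep + 1,
                )
            )
        else:  # INDEL: delete 2-4 bases or insert 2-4 bases
            # keep the planted placement the unique minimal alignment:
            # indel bases drawn from {A, C}, local flanks from {G, T}, so
            # no alternative equal-cost alignment or left-shift exists
            k = int(rng.integers(2, 5))
            flank = lambda m: [str(b) for b in rng.choice(["G", "T"], size=m)]
            body = "".join(rng.choice(["A", "C"], size=k))
            wild_list[pos - 2 : pos - 1] = flank(1)
            if rng.random() < 0.5:
                wild_list[pos - 1 : pos - 1 + k] = list(body)
                wild_list[pos - 1 + k : pos + k + 4] = flank(5)
                variants.append(PlantedVariant(pos, "INDEL", body, ""))
            else:
                wild_list[pos - 1 : pos + 4] = flank(5)
                variants.append(PlantedVariant(pos, "INDEL", "", body))
    wild_seq = "".join(wild_list)
    wild_seq = _derepeat_except(wild_seq, variants)
    mutant_seq = plant_variants(wild_seq, variants)
    return wild_seq, mutant_seq, variants


def _derepeat_except(seq: str, variants: Sequence[PlantedVariant]) -> str:
    """Re-run repeat breaking outside planted microsat runs (installing a
    run can create flanking repeats)."""
    protected = set()
    for v in variants:
        margin = 7 if v.ptype == "MICROSAT" else 2
        protected.update(
            range(v.pos - margin, v.pos + max(len(v.wild), len(v.mutant)) + margin)
        )
    s = list(seq)
    for k in range(2, 7):
        i = 0
        while i + 5 * k <= len(s):
            unit = s[i : i + k]
            run = 1
            while (
                i + (run + 1) * k <= len(s)
                and s[i + run * k : i + (run + 1) * k] == unit
            ):
                run += 1
            if run >= 5 and not any(
                j in protected for j in range(i, i + run * k)
            ):
                j = i + 4 * k
                s[j] = "A" if s[j] != "A" else "C"
            i += max(1, (run - 4)) if run >= 5 else 1
    return "".join(s)
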