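"""Core coordinate and variant data model shared by every pipeline stage.

Conventions
-----------
All genomic positions are 1-based base pairs, matching g.-style variant
nomenclature. Interval length is the simple difference ``end - start``,
which is the convention under which the locus landmarks round to their
conventional kb figures (e.g. 488195 bp -> "488 kb"). Reference-vs-locus
coordinate conversion is piecewise (exact alignment blocks), because a
sequenced locus generally differs from the reference assembly by indels,
so no single constant offset exists.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence


class InvalidIntervalError(ValueError):
    """Raised when an interval's start is not strictly before its end."""


class UnmappableError(KeyError):
    """Raised when a position falls in a gap between alignment blocks."""


class VariantType(str, Enum):
    SNP = "SNP"
    MICROSAT = "MICROSAT"
    INDEL = "INDEL"


def interval_span(a: int, b: int) -> int:
    """Length in bp of the interval between marker positions ``a`` and ``b``.

    Uses the difference convention ``b - a``; raises
    :class:`InvalidIntervalError` unless ``a < b``.
    """
    if a >= b:
        raise InvalidIntervalError(f"invalid interval: start {a} >= end {b}")
    return b - a


def format_kb(span_bp: int, precision: int = 0) -> str:
    """Report a bp span in kb, round-half-up at ``precision`` decimals."""
    q = Decimal(1).scaleb(-precision)
    kb = (Decimal(span_bp) / 1000).quantize(q, rounding=ROUND_HALF_UP)
    return f"{kb} kb"


@dataclass(frozen=True)
class GenomicInterval:
    """Closed marker-bounded interval; flanking markers border the region."""

    chrom: str
    start_bp: int
    end_bp: int
    proximal_marker: str | None = None
    distal_marker: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise InvalidIntervalError(
                f"invalid interval: {self.start_bp} >= {self.end_bp}"
            )

    @property
    def span(self) -> int:
        return interval_span(self.start_bp, self.end_bp)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker scaffold of a chromosome region.

    ``markers`` is a sequence of ``(id, ref_pos, alleles)`` with strictly
    increasing 1-based positions and unique ids.
    """

    chrom: str
    markers: tuple[tuple[str, int, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        pos = [m[1] for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        ids = [m[0] for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m[1] for m in self.markers)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def index_of(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m[0] == marker_id:
                return i
        raise KeyError(marker_id)


@dataclass(frozen=True)
class Polymorphism:
    """A single sequence difference between the wild and mutant haplotypes.

    ``ref_pos``/``locus_pos`` are the dual coordinates (either may be
    absent). For SNPs and indels the alleles are the literal wild and
    mutant sequences (empty string = deletion on that side). For
    microsatellites the variant is a repeat-count change of ``motif``;
    ``mutant_repeats`` may be None when the repeat variation was typed
    but not sized.
    """

    id: str
    ptype: VariantType
    ref_pos: int | None = None
    locus_pos: int | None = None
    wild_allele: str = ""
    mutant_allele: str = ""
    motif: str | None = None
    wild_repeats: int | None = None
    mutant_repeats: int | None = None

    def __post_init__(self) -> None:
        if self.ref_pos is None and self.locus_pos is None:
            raise ValueError("polymorphism needs at least one coordinate")
        if self.ptype is VariantType.SNP:
            if len(self.wild_allele) != 1 or len(self.mutant_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.wild_allele == self.mutant_allele:
                raise ValueError("SNP alleles must differ")
        elif self.ptype is VariantType.MICROSAT:
            if self.motif is None or not (2 <= len(self.motif) <= 6):
                raise ValueError("microsatellite motif must be 2-6 bp")
            if self.wild_repeats is None or self.wild_repeats < 1:
                raise ValueError("microsatellite needs a wild repeat count")
        elif self.ptype is VariantType.INDEL:
            if self.wild_allele == self.mutant_allele:
                raise ValueError("indel alleles must differ")
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown polymorphism type: {self.ptype!r}")

    @property
    def position(self) -> int:
        """Preferred display coordinate: reference if known, else locus."""
        return self.ref_pos if self.ref_pos is not None else self.locus_pos  # type: ignore[return-value]

    @property
    def label(self) -> str:
        return format_variant(self)


def format_variant(p: Polymorphism) -> str:
    """Deterministic HGVS-like label for a polymorphism.

    SNP -> ``g.<pos><wild>><mut>``; microsatellite ->
    ``Ms <motif>(<n_wild>_<n_mut>)`` with ``?`` for an unsized mutant
    repeat; indels -> ``<start>_<end>del<seq>`` / ``<pos>_<pos+1>ins<seq>``
    / ``<start>_<end>delins<seq>`` using the locus coordinate when
    available (indels are sized on the sequenced locus).
    """
    if p.ptype is VariantType.SNP:
        return f"g.{p.position}{p.wild_allele}>{p.mutant_allele}"
    if p.ptype is VariantType.MICROSAT:
        mut = "?" if p.mutant_repeats is None else str(p.mutant_repeats)
        return f"Ms {p.motif}({p.wild_repeats}_{mut})"
    if p.ptype is VariantType.INDEL:
        pos = p.locus_pos if p.locus_pos is not None else p.ref_pos
        w, m = p.wild_allele, p.mutant_allele
        if m == "":  # pure deletion
            return f"{pos}_{pos + len(w) - 1}del{w}"
        if w == "":  # pure insertion, between pos and pos+1
            return f"{pos}_{pos + 1}ins{m}"
        return f"{pos}_{pos + len(w) - 1}delins{m}"
    raise ValueError(f"unknown polymorphism type: {p.ptype!r}")


@dataclass(frozen=True)
class CoordinateLift:
    """Piecewise-exact mapping between reference and locus coordinates.

    ``blocks`` are half-open 1-based ``(ref_start, ref_end, locus_start,
    locus_end)`` tuples, non-overlapping, strictly increasing in both
    coordinate systems, with matching lengths within each block.
    Positions between blocks are unmappable and raise
    :class:`UnmappableError` rather than being silently interpolated.
    """

    blocks: tuple[tuple[int, int, int, int], ...]
    _ref_starts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        blocks = tuple(sorted(self.blocks))
        for rs, re, ls, le in blocks:
            if not (rs < re and ls < le):
                raise ValueError(f"degenerate block {(rs, re, ls, le)}")
            if re - rs != le - ls:
                raise ValueError("block lengths differ between coordinates")
        for a, b in zip(blocks, blocks[1:]):
            if b[0] < a[1] or b[2] < a[3]:
                raise ValueError("blocks overlap or are non-monotone")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "_ref_starts", tuple(b[0] for b in blocks))

    def lift(self, ref_pos: int) -> int:
        i = bisect.bisect_right(self._ref_starts, ref_pos) - 1
        if i >= 0:
            rs, re, ls, _ = self.blocks[i]
            if ref_pos < re:
                return ls + (ref_pos - rs)
        raise UnmappableError(
            f"position {ref_pos} falls outside every alignment block"
        )

    def inverse(self) -> "CoordinateLift":
        return CoordinateLift(
            tuple((ls, le, rs, re) for rs, re, ls, le in self.blocks)
        )

    @classmethod
    def identity(cls, start: int, end: int) -> "CoordinateLift":
        return cls(((start, end, start, end),))

    @classmethod
    def single_block(
        cls, ref_start: int, ref_end: int, locus_start: int
    ) -> "CoordinateLift":
        """One block anchoring ``ref_start`` at ``locus_start``."""
        return cls(
            ((ref_start, ref_end, locus_start, locus_start + ref_end - ref_start),)
        )


def lift_coordinate(ref_pos: int, lift: CoordinateLift) -> int:
    """Map a reference position onto the locus sequence (see CoordinateLift)."""
    return lift.lift(ref_pos)


def marker_map_from_positions(
    chrom: str, positions: Sequence[int], prefix: str = "m"
) -> MarkerMap:
    """Build an anonymous biallelic marker map from sorted positions."""
    return MarkerMap(
        chrom,
        tuple((f"{prefix}{i}", int(p), ("0", "1")) for i, p in enumerate(positions)),
    )
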