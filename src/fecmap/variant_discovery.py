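"""Polymorphism discovery by comparing two homozygous haplotype sequences.

The two inputs are the assembled mutant-homozygote and wild-homozygote
sequences over the candidate interval, so every difference is a
homozygous-vs-homozygous call: there are no read-level qualities and no
heterozygous genotypes. The pair is globally aligned with edlib and the
alignment path is post-processed here: adjacent non-match operations
merge into one event, indel fragments split around short re-matches are
coalesced, pure insertions/deletions are left-normalized, and a pure
length change inside a tandem-repeat run is reported as a
microsatellite repeat-count change rather than a generic indel.

Positions are 1-based on the wild sequence, at the first differing
base; a pure insertion is anchored at the first wild base after the
insertion point; a microsatellite is anchored at the start of its
repeat run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import edlib

from .genome_model import Polymorphism, VariantType


@dataclass(frozen=True)
class RepeatCall:
    """Result of tandem-repeat classification around a position."""

    is_microsat: bool
    motif: str | None = None  # canonical: lexicographically minimal rotation
    copies: int | None = None
    run_start: int | None = None  # 1-based start of the repeat run
    leading_motif: str | None = None  # motif as it appears at run start


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def classify_repeat(
    context: str,
    position: int,
    min_copies: int = 5,
    motif_lengths: tuple[int, int] = (2, 6),
) -> RepeatCall:
    """Detect a tandem repeat of a 2-6 bp motif covering ``position``
    (1-based) with at least ``min_copies`` copies in the wild sequence.

    The smallest motif length producing a qualifying run wins, so a
    dinucleotide run is never reported as its own doubled motif.
    """
    i = position - 1
    if not 0 <= i < len(context):
        return RepeatCall(False)
    for k in range(motif_lengths[0], motif_lengths[1] + 1):
        # maximal run of period k containing i: indices x with
        # context[x] == context[x + k] form the run's match set
        a = i
        while a - 1 >= 0 and a - 1 + k < len(context) and context[a - 1] == context[a - 1 + k]:
            a -= 1
        b = i
        while b + k < len(context) and context[b] == context[b + k]:
            b += 1
        run_len = (b + k) - a
        copies = run_len // k
        if copies >= min_copies and a <= i < a + run_len:
            leading = context[a : a + k]
            return RepeatCall(
                True,
                motif=_canonical_rotation(leading),
                copies=copies,
                run_start=a + 1,
                leading_motif=leading,
            )
    return RepeatCall(False)


@dataclass
class _Event:
    pos: int  # 1-based on wild, first differing base (ins: base after site)
    wild: str
    mutant: str


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def _events_from_alignment(wild: str, mutant: str) -> list[_Event]:
    res = edlib.align(mutant, wild, mode="NW", task="path")
    events: list[_Event] = []
    wi = mi = 0  # 0-based cursors
    cur: _Event | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            events.append(cur)
            cur = None

    for n, op in _parse_cigar(res["cigar"]):
        if op in ("=", "M"):
            # edlib 'M' can hide mismatches; split by direct comparison
            for j in range(n):
                if wild[wi + j] == mutant[mi + j]:
                    flush()
                else:
                    if cur is None:
                        cur = _Event(wi + j + 1, "", "")
                    cur.wild += wild[wi + j]
                    cur.mutant += mutant[mi + j]
            wi += n
            mi += n
            if op == "=" or wild[wi - 1] == mutant[mi - 1]:
                flush()
        elif op == "X":
            if cur is None:
                cur = _Event(wi + 1, "", "")
            cur.wild += wild[wi : wi + n]
            cur.mutant += mutant[mi : mi + n]
            wi += n
            mi += n
        elif op == "D":  # in edlib NW(query=mutant, target=wild): extra wild
            if cur is None:
                cur = _Event(wi + 1, "", "")
            cur.wild += wild[wi : wi + n]
            wi += n
        elif op == "I":  # extra mutant bases
            if cur is None:
                cur = _Event(wi + 1, "", "")
            cur.mutant += mutant[mi : mi + n]
            mi += n
        else:  # pragma: no cover - edlib emits only =XIDM
            raise ValueError(f"unexpected cigar op {op!r}")
    flush()
    return events


def _merge_nearby_indels(events: list[_Event], wild: str, max_gap: int = 6) -> list[_Event]:
    """Coalesce events separated by a short match when one is an indel.

    A single insertion/deletion inside a repeat run admits several
    equal-cost alignments and may come out of the aligner split into
    fragments around one-base matches; rejoining the fragments (and
    trimming the re-matched prefix/suffix) restores the single event.
    Pure substitution neighbours are left alone: adjacent SNPs are
    distinct variants unless their mismatch runs touch.
    """
    changed = True
    while changed:
        changed = False
        out: list[_Event] = []
        i = 0
        while i < len(events):
            a = events[i]
            if i + 1 < len(events):
                b = events[i + 1]
                gap = b.pos - (a.pos + len(a.wild))
                has_indel = len(a.wild) != len(a.mutant) or len(b.wild) != len(
                    b.mutant
                )
                if 0 <= gap <= max_gap and has_indel:
                    gap_seq = wild[a.pos - 1 + len(a.wild) : b.pos - 1]
                    w = a.wild + gap_seq + b.wild
                    m = a.mutant + gap_seq + b.mutant
                    pos = a.pos
                    while w and m and w[0] == m[0]:
                        w, m, pos = w[1:], m[1:], pos + 1
                    while w and m and w[-1] == m[-1]:
                        w, m = w[:-1], m[:-1]
                    events[i + 1] = _Event(pos, w, m)
                    changed = True
                    i += 1
                    continue
            out.append(a)
            i += 1
        events = out
    return events


def _split_equal_length(events: list[_Event]) -> list[_Event]:
    """Decompose equal-length events into positional mismatch runs.

    The aligner may represent separated substitutions as an equal-cost
    insertion/deletion pair; once re-merged the event has equal-length
    alleles and the positional character walk is the canonical reading
    (each contiguous mismatch run is one variant)."""
    out: list[_Event] = []
    for ev in events:
        if len(ev.wild) != len(ev.mutant):
            out.append(ev)
            continue
        start = None
        for i, (w, m) in enumerate(zip(ev.wild, ev.mutant)):
            if w != m:
                if start is None:
                    start = i
            elif start is not None:
                out.append(
                    _Event(ev.pos + start, ev.wild[start:i], ev.mutant[start:i])
                )
                start = None
        if start is not None:
            out.append(
                _Event(ev.pos + start, ev.wild[start:], ev.mutant[start:])
            )
    return out


def _left_normalize(ev: _Event, wild: str) -> _Event:
    """Shift a pure insertion/deletion to its leftmost equivalent placement."""
    if ev.wild and ev.mutant:
        return ev
    seq = ev.wild or ev.mutant
    pos = ev.pos
    while pos > 1 and seq and wild[pos - 2] == seq[-1]:
        seq = wild[pos - 2] + seq[:-1]
        pos -= 1
    if ev.wild:
        return _Event(pos, seq, "")
    return _Event(pos, "", seq)


def _classify_event(
    ev: _Event, wild: str, offset: int, min_repeat_copies: int
) -> Polymorphism:
    pos = ev.pos + offset
    if len(ev.wild) == 1 and len(ev.mutant) == 1:
        return Polymorphism(
            id=f"g.{pos}{ev.wild}>{ev.mutant}",
            ptype=VariantType.SNP,
            locus_pos=pos,
            wild_allele=ev.wild,
            mutant_allele=ev.mutant,
        )
    pure_indel = not ev.wild or not ev.mutant
    if pure_indel:
        rep = classify_repeat(wild, ev.pos, min_copies=min_repeat_copies)
        delta = ev.mutant or ev.wild
        if (
            rep.is_microsat
            and len(delta) % len(rep.leading_motif) == 0
            and delta == rep.leading_motif * (len(delta) // len(rep.leading_motif))
        ):
            k = len(rep.leading_motif)
            change = len(delta) // k
            wild_n = rep.copies
            mut_n = wild_n + change if ev.mutant else wild_n - change
            run_pos = rep.run_start + offset
            return Polymorphism(
                id=f"locus:{run_pos}Ms{rep.leading_motif}",
                ptype=VariantType.MICROSAT,
                locus_pos=run_pos,
                wild_allele=rep.leading_motif * wild_n,
                mutant_allele=rep.leading_motif * mut_n,
                motif=rep.leading_motif,
                wild_repeats=wild_n,
                mutant_repeats=mut_n,
            )
    p = Polymorphism(
        id=f"locus:{pos}indel",
        ptype=VariantType.INDEL,
        locus_pos=pos,
        wild_allele=ev.wild,
        mutant_allele=ev.mutant,
    )
    return p


def diff_haplotypes(
    wild: str,
    mutant: str,
    offset: int = 0,
    min_repeat_copies: int = 5,
) -> list[Polymorphism]:
    """All polymorphisms between two haplotype sequences.

    ``offset`` shifts reported 1-based positions (e.g. to place a
    sub-interval back onto locus coordinates). Each maximal mismatch run
    is one event: single-base substitutions become SNPs, repeat-count
    changes inside a >= ``min_repeat_copies`` tandem run become
    microsatellites, everything else an indel/delins.
    """
    if not wild or not mutant:
        raise ValueError("haplotype sequences must be non-empty")
    events = _merge_nearby_indels(_events_from_alignment(wild, mutant), wild)
    events = _split_equal_length(events)
    events = [_left_normalize(e, wild) for e in events]
    return [
        _classify_event(e, wild, offset, min_repeat_copies) for e in events
    ]


def summarize_variants(polys: Iterable[Polymorphism]) -> dict[str, int]:
    """Total and per-type polymorphism counts."""
    counts = {"total": 0, "SNP": 0, "MICROSAT": 0, "INDEL": 0}
    for p in polys:
        counts["total"] += 1
        counts[p.ptype.value] += 1
    return counts


def write_vcf(
    polys: Sequence[Polymorphism],
    handle: TextIO,
    chrom: str = "locus",
    wild_seq: str | None = None,
) -> None:
    """Minimal VCF 4.2 serialization of homozygous haplotype differences.

    Indels are anchored on the preceding wild base when ``wild_seq`` is
    supplied (positions interpreted as locus coordinates into it);
    otherwise an ``N`` anchor is used. Microsatellites with an unsized
    mutant repeat get a ``.`` ALT.
    """
    handle.write("##fileformat=VCFv4.2\n")
    handle.write(f"##contig=<ID={chrom}>\n")
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for p in sorted(polys, key=lambda p: p.position):
        pos = p.position
        if p.ptype is VariantType.SNP:
            ref, alt = p.wild_allele, p.mutant_allele
        elif p.ptype is VariantType.MICROSAT:
            ref = p.motif * p.wild_repeats
            alt = "." if p.mutant_repeats is None else p.motif * p.mutant_repeats
        else:
            if p.wild_allele and p.mutant_allele:
                ref, alt = p.wild_allele, p.mutant_allele
            else:
                anchor = (
                    wild_seq[pos - 2]
                    if wild_seq is not None and pos >= 2
                    else "N"
                )
                pos = pos - 1
                ref = anchor + p.wild_allele
                alt = anchor + p.mutant_allele
        handle.write(
            f"{chrom}\t{pos}\t{p.id}\t{ref}\t{alt}\t.\tPASS\tTYPE={p.ptype.value}\n"
        )
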