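"""Genome scanning for candidate p53 REs.

Matching is set-membership per position against the 20-symbol consensus
expansion (no PWM scoring); a spacer of 0-13 background bases may separate
the two half-sites.  Ambiguity base N in the genome never matches any
symbol.  The consensus is its own reverse complement, so a hit and its
strand mirror describe one site; dedupe() collapses them to a canonical
plus-strand record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import (
    RE_LENGTH,
    ConsensusPattern,
    IUPAC_SETS,
    MismatchReport,
    ResponseElement,
    count_mismatches,
)

DEFAULT_MAX_MISMATCHES = 3

_GENOME_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class MatchResult:
    """One scanner hit: 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str
    spacer: int
    mismatch_report: MismatchReport
    matched_re: ResponseElement

    def __post_init__(self) -> None:
        if self.end - self.start != RE_LENGTH + self.spacer:
            raise ValueError("interval length must be 20 + spacer")


def _encode(sequence: str) -> np.ndarray:
    """Map a genome string to uint8 codes; unknown characters -> N."""
    seq = sequence.upper()
    lut = np.full(256, _GENOME_ALPHABET.index("N"), dtype=np.uint8)
    for i, b in enumerate(_GENOME_ALPHABET):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mismatch_table(pattern: ConsensusPattern) -> np.ndarray:
    """(20, 5) boolean: does pattern position p REJECT genome code c?"""
    tab = np.ones((RE_LENGTH, len(_GENOME_ALPHABET)), dtype=bool)
    for p, sym in enumerate(pattern.full_site):
        for c, base in enumerate(_GENOME_ALPHABET):
            if base != "N" and base in IUPAC_SETS[sym]:
                tab[p, c] = False
    return tab


def _half_mismatches(codes: np.ndarray, tab: np.ndarray, half: int) -> np.ndarray:
    """mismatches[o] of 10-mer starting at o against half-site ``half`` (0/1)."""
    n = len(codes) - 9
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    out = np.zeros(n, dtype=np.int16)
    base = 10 * half
    for p in range(10):
        out += tab[base + p][codes[p : p + n]]
    return out


def scan(
    sequence: str,
    *,
    contig: str = "seq",
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    spacer_min: int = 0,
    spacer_max: int = 0,
    both_strands: bool = True,
    pattern: ConsensusPattern | None = None,
) -> list[MatchResult]:
    """All (offset, spacer, strand) windows with <= max_mismatches.

    Results are deduped (strand mirrors collapsed to '+') and sorted by
    (contig, start, spacer).  Genomic N counts as a mismatch at every
    pattern position.
    """
    if not (0 <= spacer_min <= spacer_max <= 13):
        raise ValueError("require 0 <= spacer_min <= spacer_max <= 13")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    pattern = pattern or ConsensusPattern()
    if not sequence:
        return []

    hits: list[MatchResult] = []
    strands = ("+", "-") if both_strands else ("+",)
    L = len(sequence)
    for strand in strands:
        seq = sequence.upper() if strand == "+" else _genome_rc(sequence)
        codes = _encode(seq)
        tab = _mismatch_table(pattern)
        m1 = _half_mismatches(codes, tab, 0)
        m2 = _half_mismatches(codes, tab, 1)
        for spacer in range(spacer_min, spacer_max + 1):
            span = RE_LENGTH + spacer
            n = L - span + 1
            if n <= 0:
                continue
            total = m1[:n] + m2[10 + spacer : 10 + spacer + n]
            for off in np.flatnonzero(total <= max_mismatches):
                off = int(off)
                mer = seq[off : off + 10] + seq[off + 10 + spacer : off + span]
                start = off if strand == "+" else L - off - span
                re = ResponseElement(
                    name=f"{contig}:{start}:{spacer}:{strand}",
                    sequence=mer,
                    spacer=spacer,
                    source="scan",
                )
                hits.append(
                    MatchResult(
                        contig=contig,
                        start=start,
                        end=start + span,
                        strand=strand,
                        spacer=spacer,
                        mismatch_report=count_mismatches(re, pattern),
                        matched_re=re,
                    )
                )
    return dedupe(hits)


def _genome_rc(sequence: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return sequence.upper().translate(comp)[::-1]


def dedupe(matches: list[MatchResult]) -> list[MatchResult]:
    """Collapse strand-mirror hits on one interval; sort deterministically.

    A '+' and '-' hit with identical (contig, start, end, spacer) become one
    canonical '+' record.  Distinct offsets are all kept.
    """
    by_key: dict[tuple[str, int, int, int], MatchResult] = {}
    for m in matches:
        key = (m.contig, m.start, m.end, m.spacer)
        prev = by_key.get(key)
        if prev is None or (prev.strand == "-" and m.strand == "+"):
            by_key[key] = m
    return sorted(by_key.values(), key=lambda m: (m.contig, m.start, m.spacer))


def scan_contigs(
    contigs: dict[str, str], **kwargs
) -> list[MatchResult]:
    """scan() over a multi-contig genome, concatenating results."""
    out: list[MatchResult] = []
    for name, seq in contigs.items():
        out.extend(scan(seq, contig=name, **kwargs))
    return out
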