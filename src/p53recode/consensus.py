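"""Degenerate p53 consensus, response elements, and mismatch accounting.

The p53 response element (RE) is two RRRCWWGYYY decamer half-sites,
optionally separated by a 0-13 bp spacer.  Positions are numbered 1-20
across the concatenated half-sites; spacer bases are excluded from the
numbering, so positions 13 and 18 keep their meaning for spacered REs.
Inosine (I) is allowed in RE sequences: it presents a G-like major-groove
face, so pattern matching admits it wherever G is admitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RE_LENGTH = 20
HALF_SITE = "RRRCWWGYYY"
CORE_POSITIONS = frozenset({4, 5, 6, 7, 14, 15, 16, 17})
INVARIANT_POSITIONS = frozenset({4, 7, 14, 17})
CODE_POSITIONS = (3, 8, 13, 18)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "Y": frozenset("CT"),
    "N": frozenset("ACGT"),
}

# I pairs with C; its complement is written C, and complement(I) = C.
_COMPLEMENT = str.maketrans("ACGTIN", "TGCACN")

RE_ALPHABET = frozenset("ACGTIN")


class AlphabetError(ValueError):
    """Unknown base or degenerate symbol."""


def iupac_admits(symbol: str, base: str) -> bool:
    """True iff ``base`` is admitted by degenerate ``symbol``.

    Inosine is admitted exactly where G is admitted (G-like major groove).
    The ambiguity base N, which genome scans may carry into an RE, is
    admitted by no symbol.
    """
    try:
        admitted = IUPAC_SETS[symbol]
    except KeyError:
        raise AlphabetError(f"unknown pattern symbol {symbol!r}") from None
    if base not in RE_ALPHABET:
        raise AlphabetError(f"unknown base {base!r}")
    if base == "I":
        return "G" in admitted
    if base == "N":
        return False
    return base in admitted


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,I}; complement(I) = C (its pairing partner)."""
    seq = sequence.upper()
    bad = set(seq) - RE_ALPHABET
    if bad:
        raise AlphabetError(f"cannot complement {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusPattern:
    """The degenerate RE consensus: two half-sites with a bounded spacer."""

    half_site: str = HALF_SITE
    spacer_min: int = 0
    spacer_max: int = 13

    def __post_init__(self) -> None:
        if len(self.half_site) != 10:
            raise ValueError("half_site must be 10 symbols")
        for s in self.half_site:
            if s not in IUPAC_SETS:
                raise AlphabetError(f"unknown pattern symbol {s!r}")
        if not (0 <= self.spacer_min <= self.spacer_max <= 13):
            raise ValueError("require 0 <= spacer_min <= spacer_max <= 13")

    @property
    def full_site(self) -> str:
        """20-symbol expansion: both half-sites concatenated."""
        return self.half_site * 2

    def admits(self, position: int, base: str) -> bool:
        """Does 1-based RE ``position`` admit ``base``?"""
        return iupac_admits(self.full_site[position - 1], base)


@dataclass(frozen=True)
class ResponseElement:
    """A named 20-bp RE; the spacer (if any) is stored separately."""

    name: str
    sequence: str
    spacer: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != RE_LENGTH:
            raise ValueError(
                f"RE {self.name!r}: sequence must be {RE_LENGTH} bp, got {len(seq)}"
            )
        bad = set(seq) - RE_ALPHABET
        if bad:
            raise AlphabetError(f"RE {self.name!r}: invalid bases {sorted(bad)}")
        if not (0 <= self.spacer <= 13):
            raise ValueError("spacer must be in 0..13")

    def base(self, position: int) -> str:
        """Base at 1-based position (1-20)."""
        if not (1 <= position <= RE_LENGTH):
            raise IndexError(f"position {position} outside 1..{RE_LENGTH}")
        return self.sequence[position - 1]

    def reverse_complement(self) -> "ResponseElement":
        return ResponseElement(
            name=f"{self.name}_rc",
            sequence=reverse_complement(self.sequence),
            spacer=self.spacer,
            source=self.source,
        )


@dataclass(frozen=True)
class MismatchReport:
    """Per-position mismatches of an RE against the consensus."""

    positions: tuple[int, ...]
    core_mismatches: int
    invariant_position_mismatches: int

    @property
    def total(self) -> int:
        return len(self.positions)


def count_mismatches(
    re: ResponseElement, pattern: ConsensusPattern | None = None
) -> MismatchReport:
    """Compare an RE against the 20-symbol consensus expansion."""
    pattern = pattern or ConsensusPattern()
    positions = tuple(
        p for p in range(1, RE_LENGTH + 1) if not pattern.admits(p, re.base(p))
    )
    return MismatchReport(
        positions=positions,
        core_mismatches=sum(1 for p in positions if p in CORE_POSITIONS),
        invariant_position_mismatches=sum(
            1 for p in positions if p in INVARIANT_POSITIONS
        ),
    )


@dataclass(frozen=True)
class CoreReport:
    """The two CWWG core quadruples of an RE with per-core match flags."""

    core1: str  # positions 4-7
    core2: str  # positions 14-17
    core1_matches: bool
    core2_matches: bool
    mismatch_positions: tuple[int, ...]


def locate_core(re: ResponseElement) -> CoreReport:
    """Extract the CWWG cores (positions 4-7 and 14-17) and flag mismatches."""
    pattern = ConsensusPattern()
    core1 = re.sequence[3:7]
    core2 = re.sequence[13:17]
    mism = tuple(
        p for p in sorted(CORE_POSITIONS) if not pattern.admits(p, re.base(p))
    )
    return CoreReport(
        core1=core1,
        core2=core2,
        core1_matches=not any(4 <= p <= 7 for p in mism),
        core2_matches=not any(14 <= p <= 17 for p in mism),
        mismatch_positions=mism,
    )


@dataclass(frozen=True)
class MechanismAnnotation:
    """DNA-contact role of a key p53 residue."""

    residue: str
    contacted_positions: frozenset[int]
    groove: str
    interaction_class: str


MECHANISM_ANNOTATIONS: dict[str, MechanismAnnotation] = {
    "Arg280": MechanismAnnotation(
        "Arg280", frozenset({4, 7, 14, 17}), "major", "base-specific"
    ),
    "Lys120": MechanismAnnotation(
        "Lys120", frozenset({2, 3, 12, 13}), "major", "base-specific"
    ),
    "Arg248": MechanismAnnotation(
        "Arg248", frozenset({8, 9, 18, 19}), "minor", "backbone/shape-readout"
    ),
}
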