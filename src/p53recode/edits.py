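"""Design of minimal RE edits that interconvert predicted binding modes.

Two edit families mirror the designed variants characterised in vitro:

* G/C <-> A/T substitutions at the code positions {3, 8, 13, 18}, which move
  both channels together (BAX_8/13, p21_8/13, NOXA_3/13 style);
* G -> I substitutions (partner C retained), which empty the minor channel
  while leaving the major channel intact (BAX_8/13 I/C style), decoupling
  predicted binding mode from predicted K120R sensitivity.

Default replacement bases follow the printed designs: transitions (G<->A,
C<->T), which also keep every code position compatible with its consensus
symbol (R at 3/13, Y at 8/18).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .classify import CodeProfile, CodeThresholds, DEFAULT_THRESHOLDS, classify
from .consensus import CODE_POSITIONS, ResponseElement


class EditConsistencyError(ValueError):
    """An edit's from-base does not match the RE (coordinate-convention guard)."""


@dataclass(frozen=True)
class Edit:
    position: int  # 1-based
    from_base: str
    to_base: str

    def __str__(self) -> str:
        return f"{self.from_base}{self.position}{self.to_base}"


@dataclass(frozen=True)
class EditPlan:
    base: ResponseElement
    edits: tuple[Edit, ...]
    profile_before: CodeProfile
    profile_after: CodeProfile

    @property
    def edit_count(self) -> int:
        return len(self.edits)

    @property
    def result(self) -> ResponseElement:
        return apply_edits(self.base, self.edits)


def apply_edits(
    re: ResponseElement, edits: tuple[Edit, ...] | list[Edit]
) -> ResponseElement:
    """New RE with substitutions applied; name suffixed with the edits."""
    seq = list(re.sequence)
    for e in edits:
        if not (1 <= e.position <= 20):
            raise IndexError(f"edit position {e.position} outside 1..20")
        if seq[e.position - 1] != e.from_base.upper():
            raise EditConsistencyError(
                f"{re.name}: position {e.position} holds {seq[e.position - 1]}, "
                f"edit expects {e.from_base}"
            )
        seq[e.position - 1] = e.to_base.upper()
    suffix = "+".join(str(e) for e in edits)
    name = f"{re.name}[{suffix}]" if edits else re.name
    return ResponseElement(name=name, sequence="".join(seq), spacer=re.spacer,
                           source=re.source)


def replace_range(
    re: ResponseElement, start: int, replacement: str
) -> ResponseElement:
    """Replace positions start..start+len(replacement)-1 (1-based, inclusive)."""
    edits = tuple(
        Edit(start + k, re.base(start + k), b)
        for k, b in enumerate(replacement.upper())
        if re.base(start + k) != b.upper()
    )
    return apply_edits(re, edits)


# printed-design replacement convention: transitions, which keep each code
# position inside its consensus symbol (R at 3/13, Y at 8/18)
_TO_AT = {"G": "A", "C": "T"}
_TO_GC = {"A": "G", "T": "C"}


def propose_mode_flip(
    re: ResponseElement,
    target_mode: str,
    allowed_positions: tuple[int, ...] = CODE_POSITIONS,
    max_edits: int = 4,
    thresholds: CodeThresholds = DEFAULT_THRESHOLDS,
) -> list[EditPlan]:
    """All minimal code-position edit sets reaching ``target_mode``.

    Plans are the minimal-size subsets of ``allowed_positions`` whose
    substitution (by the printed-design base convention) gives the target
    mode label on reclassification; ties are ordered lexicographically by
    position tuple.  Empty list (with no error) when the target is
    unreachable within ``max_edits``.
    """
    if target_mode not in ("hydrophobic", "electrostatic"):
        raise ValueError("target_mode must be hydrophobic or electrostatic")
    current = classify(re, thresholds)
    if current.mode_label == target_mode:
        raise ValueError(f"{re.name} already has mode {target_mode}")
    conv = _TO_AT if target_mode == "hydrophobic" else _TO_GC
    before = current
    plans: list[EditPlan] = []
    for k in range(1, max_edits + 1):
        for posns in combinations(sorted(allowed_positions), k):
            edits = []
            feasible = True
            for p in posns:
                b = re.base(p)
                if b not in conv:
                    feasible = False  # wrong pair class (or inosine) at p
                    break
                edits.append(Edit(p, b, conv[b]))
            if not feasible:
                continue
            new = apply_edits(re, tuple(edits))
            after = classify(new, thresholds)
            if after.mode_label == target_mode:
                plans.append(EditPlan(re, tuple(edits), before, after))
        if plans:
            break  # minimal size found
    return plans


def propose_ic_variant(
    re: ResponseElement,
    positions: tuple[int, ...],
    thresholds: CodeThresholds = DEFAULT_THRESHOLDS,
) -> EditPlan:
    """G/C -> I/C plan at the given positions (written base becomes I).

    Each selected position must currently hold a G·C pair.  The resulting
    profile drops the minor channel by one per substitution while the major
    channel is unchanged, so predicted K120R sensitivity is preserved.
    """
    edits = []
    for p in positions:
        b = re.base(p)
        if b not in "GC":
            raise EditConsistencyError(
                f"{re.name}: position {p} holds {b}, not a G·C pair"
            )
        edits.append(Edit(p, b, "I"))
    before = classify(re, thresholds)
    new = apply_edits(re, tuple(edits))
    return EditPlan(re, tuple(edits), before, classify(new, thresholds))
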