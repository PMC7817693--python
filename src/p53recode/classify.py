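"""The G/C code at RE positions 3, 8, 13, 18 and its two mechanistic channels.

The four code positions flank the CWWG cores and set local DNA shape.  Two
readout channels are distinguished:

* minor channel — base pairs bearing a minor-groove 2-amino group (G·C only;
  not I·C, not A/T).  These widen the minor groove, forcing Arg248 into its
  bent, electrostatic, salt-sensitive conformation.  Few such pairs leave the
  groove narrow, and Arg248 inserts in the extended hydrophobic mode.
* major channel — base pairs presenting a G-like major-groove face (G·C and
  I·C).  These are what the K120R arginine clashes with; a G-rich major
  channel predicts loss of K120R-p53 binding.

An inosine-free RE has identical channel counts; I·C pairs split them,
which is the in vitro trick that decouples the two readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consensus import CODE_POSITIONS, ResponseElement


@dataclass(frozen=True)
class CodeThresholds:
    """Decision bands on channel counts (0-4): <= low, ambiguous, >= high."""

    low: int = 1
    high: int = 3

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("require low < high")

    def band(self, count: int) -> str:
        if count <= self.low:
            return "low"
        if count >= self.high:
            return "high"
        return "ambiguous"


DEFAULT_THRESHOLDS = CodeThresholds()


@dataclass(frozen=True)
class CodeProfile:
    """Classifier view of one RE."""

    name: str
    gc_count: int
    minor_channel_count: int
    major_channel_count: int
    mode_label: str  # hydrophobic | electrostatic | ambiguous
    k120r_label: str  # bound | unbound | ambiguous
    fate_tendency: str  # pro-survival | pro-apoptotic | indeterminate


def gc_code_count(re: ResponseElement) -> int:
    """Number of code positions holding G or C (inosine excluded)."""
    return sum(1 for p in CODE_POSITIONS if re.base(p) in "GC")


def channel_counts(re: ResponseElement) -> tuple[int, int]:
    """(minor_channel_count, major_channel_count) at the code positions.

    Minor: G·C pairs only (2-amino group in the minor groove).
    Major: G·C plus I·C pairs (G-like major-groove face).
    """
    minor = 0
    major = 0
    for p in CODE_POSITIONS:
        b = re.base(p)
        if b in "GC":
            minor += 1
            major += 1
        elif b == "I":
            major += 1
    return minor, major


_MODE = {"low": "hydrophobic", "high": "electrostatic", "ambiguous": "ambiguous"}
_K120R = {"low": "bound", "high": "unbound", "ambiguous": "ambiguous"}
_FATE = {"low": "pro-survival", "high": "pro-apoptotic", "ambiguous": "indeterminate"}


def classify(
    re: ResponseElement, thresholds: CodeThresholds = DEFAULT_THRESHOLDS
) -> CodeProfile:
    """Predict binding mode, K120R sensitivity and fate tendency for one RE.

    mode_label depends only on the minor channel, k120r_label only on the
    major channel; fate_tendency follows the plain G/C count.
    """
    minor, major = channel_counts(re)
    gc = gc_code_count(re)
    return CodeProfile(
        name=re.name,
        gc_count=gc,
        minor_channel_count=minor,
        major_channel_count=major,
        mode_label=_MODE[thresholds.band(minor)],
        k120r_label=_K120R[thresholds.band(major)],
        fate_tendency=_FATE[thresholds.band(gc)],
    )


def code_hamming(
    re_a: ResponseElement, re_b: ResponseElement
) -> tuple[int, tuple[int, ...]]:
    """Count and locate code positions where two REs differ."""
    diff = tuple(p for p in CODE_POSITIONS if re_a.base(p) != re_b.base(p))
    return len(diff), diff


def stratify_by_code(
    res: list[ResponseElement], labels: list[str]
) -> pd.DataFrame:
    """Per-G/C-count bucket (0-4): n and fraction with label 'unbound'.

    Buckets with n = 0 get fraction NaN.  ``labels`` are observed binary
    labels ('bound'/'unbound'), one per RE.
    """
    if len(res) != len(labels):
        raise ValueError("res and labels must align")
    for lab in labels:
        if lab not in ("bound", "unbound"):
            raise ValueError(f"label must be bound/unbound, got {lab!r}")
    counts = [0] * 5
    unbound = [0] * 5
    for re, lab in zip(res, labels):
        b = gc_code_count(re)
        counts[b] += 1
        if lab == "unbound":
            unbound[b] += 1
    return pd.DataFrame(
        {
            "gc_count": range(5),
            "n": counts,
            "n_unbound": unbound,
            "fraction_unbound": [
                u / n if n else float("nan") for u, n in zip(unbound, counts)
            ],
        }
    )


def profiles_table(
    res: list[ResponseElement], thresholds: CodeThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """One CodeProfile row per RE, in input order."""
    rows = [vars(classify(re, thresholds)) for re in res]
    return pd.DataFrame(rows)
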