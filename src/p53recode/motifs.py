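"""Positional base-frequency summaries and set-vs-set composition contrasts.

Used to reproduce the style of motif comparison that distinguishes
K120R-bound from K120R-unbound RE sets: per-position base frequencies,
information content in bits, and a per-position G/C-vs-A/T enrichment test
between two RE sets.  The exact-test layer is a convenience beyond visual
motif comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import RE_LENGTH, ResponseElement

BASES = "ACGT"


@dataclass(frozen=True)
class PositionFrequencyTable:
    counts: np.ndarray  # (20, 4) int
    n: int

    @property
    def frequencies(self) -> np.ndarray:
        if self.n == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        return self.counts / self.n

    @property
    def information(self) -> np.ndarray:
        """Per-position information in bits: 2 - Shannon entropy.

        Zero-frequency terms contribute nothing; no small-sample correction.
        """
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + terms.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", range(1, RE_LENGTH + 1))
        df["information_bits"] = self.information
        return df


def build_pft(res: list[ResponseElement]) -> PositionFrequencyTable:
    """Exact base counts per position.  Inosine-bearing REs are rejected."""
    counts = np.zeros((RE_LENGTH, 4), dtype=int)
    for re in res:
        if "I" in re.sequence or "N" in re.sequence:
            raise ValueError(f"RE {re.name!r}: only A/C/G/T sequences summarised")
        for p, b in enumerate(re.sequence):
            counts[p, BASES.index(b)] += 1
    return PositionFrequencyTable(counts=counts, n=len(res))


def _gc_at(res: list[ResponseElement], position: int) -> tuple[int, int]:
    gc = sum(1 for re in res if re.base(position) in "GC")
    return gc, len(res) - gc


def compare_sets(
    set_a: list[ResponseElement],
    set_b: list[ResponseElement],
    positions: tuple[int, ...] = (3, 8, 13, 18),
) -> pd.DataFrame:
    """Per-position G/C-vs-A/T 2x2 contrast between two RE sets.

    Fisher's exact test per position, Benjamini-Hochberg adjusted across the
    requested positions.  Zero-margin tables get an undefined (NaN) odds
    ratio plus a Haldane-Anscombe continuity-corrected alternative.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    rows = []
    for pos in positions:
        a_gc, a_at = _gc_at(set_a, pos)
        b_gc, b_at = _gc_at(set_b, pos)
        table = np.array([[a_gc, a_at], [b_gc, b_at]])
        odds, p = stats.fisher_exact(table)
        if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
            odds = np.nan
        cc = (a_gc + 0.5) * (b_at + 0.5) / ((a_at + 0.5) * (b_gc + 0.5))
        rows.append(
            {
                "position": pos,
                "a_gc": a_gc,
                "a_at": a_at,
                "b_gc": b_gc,
                "b_at": b_at,
                "odds_ratio": odds,
                "odds_ratio_cc": cc,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def plot_logo(pft: PositionFrequencyTable, ax=None):
    """Cosmetic logo-style rendering: stacked per-base information bars.

    Purely visual convenience; nothing numeric depends on it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}
    info = pft.information
    freq = pft.frequencies
    for pos in range(RE_LENGTH):
        bottom = 0.0
        order = np.argsort(freq[pos])
        for b in order:
            h = freq[pos, b] * info[pos]
            if h > 0:
                ax.bar(pos + 1, h, bottom=bottom, color=colors[BASES[b]],
                       width=0.85, edgecolor="none")
                bottom += h
    ax.set_xlim(0.4, RE_LENGTH + 0.6)
    ax.set_ylim(0, 2)
    ax.set_xlabel("RE position")
    ax.set_ylabel("bits")
    return ax


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
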