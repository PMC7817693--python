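"""Seeded generators for every input class the pipeline consumes.

Each generator returns its ground truth alongside the data, so closed-loop
tests (scanner recall, classifier stratification, Kd recovery) need no
external files.  All randomness flows through a numpy Generator seeded from
the config; identical (config, seed) pairs are bit-reproducible.

The labeled-RE generator emulates the statistical structure of the in vivo
observation that K120R sensitivity rises with G/C content at the code
positions: the label model is the minimal monotone family, a logistic in
the G/C code count.  Code positions are drawn consensus-compatible (G at
3/13 or C at 8/18 for a G/C pair, A at 3/13 or T at 8/18 otherwise);
mismatches are implanted only outside the code positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import TitrationCurve, model_mP
from .consensus import (
    CODE_POSITIONS,
    ConsensusPattern,
    IUPAC_SETS,
    RE_LENGTH,
    ResponseElement,
)

_BASES = "ACGT"
# consensus-compatible base carrying a G/C (resp. A/T) pair at each code position
_CODE_GC = {3: "G", 8: "C", 13: "G", 18: "C"}
_CODE_AT = {3: "A", 8: "T", 13: "A", 18: "T"}


@dataclass(frozen=True)
class SyntheticREConfig:
    n: int = 1000
    gc_code_distribution: tuple[float, ...] = (0.13, 0.28, 0.37, 0.18, 0.04)
    mismatch_rate: float = 0.05
    label_intercept: float = -2.5
    label_slope: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.gc_code_distribution, dtype=float)
        if len(w) != 5 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("gc_code_distribution must be 5 non-negative weights summing to 1")
        if not (0 <= self.mismatch_rate <= 0.3):
            raise ValueError("mismatch_rate must be in [0, 0.3]")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def _unbound_probability(gc_count, intercept: float, slope: float):
    z = intercept + slope * np.asarray(gc_count, dtype=float)
    return 1.0 / (1.0 + np.exp(-z))


def sample_re_set(
    config: SyntheticREConfig,
) -> tuple[list[ResponseElement], "pd.DataFrame"]:
    """Labeled consensus-derived REs with known G/C code counts.

    Returns (REs, truth table) where the truth table records each RE's
    exact gc_count, its P(unbound) under the logistic label model, and the
    drawn binary label.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    pattern = ConsensusPattern()
    full = pattern.full_site
    non_code = [p for p in range(1, RE_LENGTH + 1) if p not in CODE_POSITIONS]
    res: list[ResponseElement] = []
    rows = []
    gc_counts = rng.choice(5, size=config.n, p=config.gc_code_distribution)
    for k in range(config.n):
        gc = int(gc_counts[k])
        code_gc_positions = rng.choice(4, size=gc, replace=False)
        seq = [""] * RE_LENGTH
        for idx, p in enumerate(CODE_POSITIONS):
            seq[p - 1] = _CODE_GC[p] if idx in code_gc_positions else _CODE_AT[p]
        for p in non_code:
            choices = sorted(IUPAC_SETS[full[p - 1]])
            seq[p - 1] = choices[rng.integers(len(choices))]
        # implant mismatches outside the code positions
        n_mismatched = 0
        for p in non_code:
            if rng.random() < config.mismatch_rate:
                bad = sorted(set(_BASES) - IUPAC_SETS[full[p - 1]])
                if not bad:  # N admits everything; no mismatch possible
                    continue
                seq[p - 1] = bad[rng.integers(len(bad))]
                n_mismatched += 1
        p_unbound = float(
            _unbound_probability(gc, config.label_intercept, config.label_slope)
        )
        label = "unbound" if rng.random() < p_unbound else "bound"
        re = ResponseElement(name=f"synth_{k:05d}", sequence="".join(seq),
                             source="sample_re_set")
        res.append(re)
        rows.append(
            {
                "name": re.name,
                "sequence": re.sequence,
                "gc_count": gc,
                "n_mismatches": n_mismatched,
                "p_unbound": p_unbound,
                "label": label,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["name", "sequence", "gc_count", "n_mismatches", "p_unbound", "label"],
    )
    return res, truth


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    length: int = 10_000
    gc_background: float = 0.41
    implants: tuple[tuple[ResponseElement, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_background < 1):
            raise ValueError("gc_background must be in (0, 1)")
        spans = []
        for re, offset, strand in self.implants:
            span = RE_LENGTH + re.spacer
            if strand not in "+-":
                raise ValueError("strand must be + or -")
            if not (0 <= offset and offset + span <= self.length):
                raise ValueError(f"implant at {offset} outside genome bounds")
            spans.append((offset, offset + span))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("implants overlap")


def implant_genome(
    config: SyntheticGenomeConfig,
) -> tuple[str, "pd.DataFrame"]:
    """(contig sequence, truth BED table) with implants copied verbatim.

    Background bases are i.i.d. with the stated G/C fraction.  Spacered
    implants keep their background spacer bases: only the two half-sites
    are written.  Minus-strand implants are written as the reverse
    complement of the RE.  The truth table uses scanner conventions
    (0-based half-open intervals).
    """
    import pandas as pd

    from .consensus import reverse_complement

    rng = np.random.default_rng(config.seed)
    g = config.gc_background / 2
    a = (1 - config.gc_background) / 2
    seq = list(rng.choice(list("ACGT"), size=config.length, p=[a, g, g, a]))
    rows = []
    for re, offset, strand in config.implants:
        written = re.sequence if strand == "+" else reverse_complement(re.sequence)
        half1, half2 = written[:10], written[10:]
        seq[offset : offset + 10] = half1
        start2 = offset + 10 + re.spacer
        seq[start2 : start2 + 10] = half2
        rows.append(
            {
                "contig": "synth",
                "start": offset,
                "end": offset + RE_LENGTH + re.spacer,
                "name": re.name,
                "strand": strand,
                "spacer": re.spacer,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "strand", "spacer"]
    ).sort_values(["start"]).reset_index(drop=True)
    return "".join(seq), truth


def consensus_match_probability(gc_background: float) -> float:
    """Analytic P(a random background 20-mer matches RRRCWWGYYY^2 exactly).

    Per-position admit probabilities under the i.i.d. background: R, W and
    Y admit two bases each, C and G one.
    """
    g = gc_background / 2
    a = (1 - gc_background) / 2
    per = {"R": a + g, "W": 2 * a, "Y": a + g, "C": g, "G": g, "N": 1.0}
    p = 1.0
    for sym in ConsensusPattern().full_site:
        p *= per[sym]
    return p


def simulate_titration(
    Kd: float,
    mP_max: float = 170.0,
    mP_baseline: float = 80.0,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    salt_mM: float = 275.0,
) -> TitrationCurve:
    """Noisy titration from the binding hyperbola; exact when noise_sd = 0.

    Default concentrations are 12 log-spaced points over 1 nM - 1 uM, the
    range titrated in the polarization assay.
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if concentrations is None:
        concentrations = np.logspace(-9, -6, 12)
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    mp = model_mP(conc, Kd, mP_max, mP_baseline)
    if noise_sd > 0:
        mp = mp + rng.normal(0.0, noise_sd, size=conc.shape)
    return TitrationCurve(
        concentrations=conc, mP=mp, salt_mM=salt_mM,
        name=f"sim_Kd={Kd:.3g}M_noise={noise_sd:g}",
    )
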