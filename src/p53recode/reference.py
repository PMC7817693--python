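"""Built-in reference REs: the natural and designed variants characterised
by fluorescence polarization (Kd at 200 and 275 mM NaCl, WT and K120R p53).

An I·C base pair is written as the letter I at that position of the 20-mer,
whichever strand physically carries the inosine; channel logic downstream is
pair-level, so the strand does not matter.  K120R status: ``bound`` REs keep
measurable K120R-p53 affinity at 275 mM NaCl, ``unbound`` REs lose it
(non-detectable) or are strongly impaired.
"""

from __future__ import annotations

from .consensus import ResponseElement

# name -> (sequence, K120R group used for concordance checks, note)
_TABLE: dict[str, tuple[str, str | None, str]] = {
    "p21": ("GAACATGTCCCAACATGTTG", "bound", "natural, cell-cycle arrest"),
    "MDM2": ("AGACAAGTCAGGACTTAACT", "bound", "natural"),
    "APBB2": ("AGGCATGTCCCAACATGCCC", "bound", "natural"),
    "3Q05": ("GGGCATGTCTGGGCATGTCT", "bound", "artificial, crystallized"),
    "BAX": ("GGGCAGGCCCGGGCTTGTCG", "unbound", "natural, pro-apoptotic"),
    "NOXA": ("GAGCGTGTCCGGGCAGGTCG", "unbound", "natural, pro-apoptotic"),
    "Pro-apoptotic": ("GGGCATGCCCGGGCATGCCC", "unbound", "ideal G/C-rich"),
    "6FJ5": ("AGGCATGCCTAGGCATGCCT", "unbound", "artificial, crystallized"),
    "BAX_8/13": ("GGGCAGGTCCGGACTTGTCG", "bound", "BAX with G/C->A/T at 8,13"),
    "NOXA_3/13": ("GAACGTGTCCGGACAGGTCG", "bound", "NOXA with G/C->A/T at 3,13"),
    "p21_8/13": ("GAACATGCCCCAGCATGTTG", "unbound", "p21 with A/T->G/C at 8,13"),
    "BAX_8/13 I/C": ("GGGCAGGICCGGICTTGTCG", "unbound", "BAX with G/C->I/C at 8,13"),
    "6FJ5_8/18 I/C": ("AGGCATGICTAGGCATGICT", None, "6FJ5 with G/C->I/C at 8,18"),
}

# Measured Kd in nM: (WT 200 mM, WT 275 mM, K120R 200 mM, K120R 275 mM);
# None = not available (non-detectable binding).
KD_NM: dict[str, tuple[float | None, float | None, float | None, float | None]] = {
    "p21": (26, 23, 35, 43),
    "MDM2": (20, 97, 36, 72),
    "APBB2": (10, 40, 37, 80),
    "3Q05": (6, 33, 33, 78),
    "BAX": (22, 460, 280, None),
    "NOXA": (45, 446, 68, 2900),
    "Pro-apoptotic": (15, 254, 23, 3500),
    "6FJ5": (8, 783, 140, 800),
    "BAX_8/13": (8, 40, 94, 168),
    "NOXA_3/13": (23, 60, 141, 81),
    "p21_8/13": (33, 99, 55, 479),
    "BAX_8/13 I/C": (9, 83, 150, None),
    "6FJ5_8/18 I/C": (8, 587, 26, 91),
}


def reference_res() -> list[ResponseElement]:
    """All reference REs as ResponseElement objects."""
    return [
        ResponseElement(name=name, sequence=seq, source=note)
        for name, (seq, _, note) in _TABLE.items()
    ]


def reference_re(name: str) -> ResponseElement:
    seq, _, note = _TABLE[name]
    return ResponseElement(name=name, sequence=seq, source=note)


def k120r_group(name: str) -> str | None:
    """Observed K120R binding group ('bound'/'unbound'), None if equivocal."""
    return _TABLE[name][1]
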