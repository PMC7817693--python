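"""Readers and writers shared by all pipeline stages.

Fixed dialects: FASTA wrapped at 60 columns (Biopython-backed), BED6 with
0-based half-open intervals, TSV with a header row and stable column order.
Every table writer emits columns in a documented, deterministic order so
re-runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ResponseElement
from .scanner import MatchResult


def read_re_fasta(path) -> list[ResponseElement]:
    """One RE per record; header = name, optional 'spacer=K' token."""
    res = []
    for rec in SeqIO.parse(str(path), "fasta"):
        spacer = 0
        for token in rec.description.split()[1:]:
            if token.startswith("spacer="):
                spacer = int(token.split("=", 1)[1])
        res.append(
            ResponseElement(
                name=rec.id, sequence=str(rec.seq).upper(), spacer=spacer,
                source=str(path),
            )
        )
    return res


def write_re_fasta(res: list[ResponseElement], path) -> None:
    records = [
        SeqRecord(
            Seq(re.sequence),
            id=re.name.replace(" ", "_"),
            description=f"spacer={re.spacer}" if re.spacer else "",
        )
        for re in res
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    """Multi-contig genome FASTA -> {contig: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def matches_to_bed(matches: list[MatchResult]) -> pd.DataFrame:
    """BED6: name = matched 20-mer + spacer, score = (20 - mismatches)/20 * 1000."""
    rows = [
        {
            "contig": m.contig,
            "start": m.start,
            "end": m.end,
            "name": f"{m.matched_re.sequence}|spacer={m.spacer}",
            "score": round((20 - m.mismatch_report.total) / 20 * 1000),
            "strand": m.strand,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_titrations(path) -> pd.DataFrame:
    """Titration table: concentration_M, mP, optional replicate and salt_mM."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"concentration_M", "mP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "salt_mM" not in df.columns:
        df["salt_mM"] = 275.0
    return df


def mismatch_table(res: list[ResponseElement]) -> pd.DataFrame:
    """One MismatchReport row per RE, in input order."""
    from .consensus import count_mismatches, locate_core

    rows = []
    for re in res:
        rep = count_mismatches(re)
        core = locate_core(re)
        rows.append(
            {
                "name": re.name,
                "sequence": re.sequence,
                "total": rep.total,
                "positions": ",".join(map(str, rep.positions)) or ".",
                "core_mismatches": rep.core_mismatches,
                "invariant_position_mismatches": rep.invariant_position_mismatches,
                "core1": core.core1,
                "core2": core.core2,
            }
        )
    return pd.DataFrame(rows)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
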