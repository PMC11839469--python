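"""Plain-text serialization: commented TSV tables and FASTQ."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO


def write_tsv(df: pd.DataFrame, path, comments: Mapping[str, object] | None = None) -> None:
    """Write a TSV with '# key: value' header comments (config provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            if isinstance(value, (dict, list, tuple)):
                value = json.dumps(value)
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_comments(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            out[key.strip()] = value.strip()
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> int:
    """Write (id, sequence) pairs as Phred-33 FASTQ; returns the read count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_fastq(path) -> list[tuple[str, str]]:
    """Read FASTQ into (id, sequence) pairs via Biopython."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
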