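"""Barcode -> variant lookup from long reads, and barcode counting.

Long reads sharing a barcode are collapsed to a per-position majority
consensus; the consensus is retained only if it is the wild-type coding
sequence or carries exactly one amino-acid change matching the designed
library.  Anything else — ambiguous consensus positions, indels, extra
("backbone") substitutions, undesigned changes — invalidates the barcode.
Short reads are counted by exact barcode match against the retained
lookup; 30-nt random barcodes make collisions negligible, so no error
correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .design import INVALID, WILD_TYPE, ReferenceDesign
from .simulate import BARCODE_FLANK_3, BARCODE_FLANK_5

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BarcodeExtractor:
    """Fixed-position barcode between two exact flanking anchors."""

    flank5: str = BARCODE_FLANK_5
    flank3: str = BARCODE_FLANK_3
    barcode_length: int = 30

    def extract(self, seq: str) -> tuple[str, str] | None:
        """Return (barcode, payload-after-flank3) or None if unparseable."""
        n5 = len(self.flank5)
        end = n5 + self.barcode_length
        if not seq.startswith(self.flank5):
            return None
        if seq[end : end + len(self.flank3)] != self.flank3:
            return None
        return seq[n5:end], seq[end + len(self.flank3) :]


def call_consensus(reads: Iterable[str]) -> str:
    """Per-position majority base over equal-length reads; ties become 'N'."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read bundle")
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError("reads in a bundle must have equal length")
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(
        len(reads), -1
    )
    counts = np.stack([(arr == b).sum(axis=0) for b in _ACGT])
    best = counts.max(axis=0)
    ties = (counts == best).sum(axis=0) > 1
    cons = _ACGT[counts.argmax(axis=0)].tobytes().decode()
    if ties.any():
        cons = "".join("N" if t else c for c, t in zip(cons, ties))
    return cons


def classify_consensus(consensus: str, design: ReferenceDesign) -> str:
    """Assign a consensus coding sequence to WT, a designed variant, or INVALID.

    Comparison is at the amino-acid level after in-frame translation; any
    length change, ambiguous position, second substitution or undesigned
    substitution invalidates the barcode.
    """
    if len(consensus) != 3 * len(design.protein) or "N" in consensus:
        return INVALID
    protein = str(Seq(consensus).translate())
    diffs = [
        i for i, (a, b) in enumerate(zip(protein, design.protein), start=1) if a != b
    ]
    if not diffs:
        return WILD_TYPE
    if len(diffs) > 1:
        return INVALID
    pos = diffs[0]
    vid = f"{design.protein[pos - 1]}{pos}{protein[pos - 1]}"
    return vid if vid in set(design.variant_ids) else INVALID


def _iter_reads(reads) -> Iterable[str]:
    """Yield sequences from (id, seq) pairs, SeqRecords, or a FASTQ path."""
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        reads = read_fastq(reads)
    for r in reads:
        if isinstance(r, str):
            yield r
        elif isinstance(r, tuple):
            yield r[1]
        else:  # SeqRecord
            yield str(r.seq)


def build_lookup(
    reads,
    design: ReferenceDesign,
    min_support: int = 3,
    extractor: BarcodeExtractor | None = None,
) -> pd.DataFrame:
    """Group long reads by barcode and classify each consensus.

    Returns one row per barcode with support >= ``min_support``:
    ``barcode, assignment, support, consensus``.  Summary counts (retained,
    invalid, dropped reads, low-support barcodes) are stored in
    ``DataFrame.attrs['summary']``.
    """
    extractor = extractor or BarcodeExtractor()
    bundles: dict[str, list[str]] = {}
    dropped = 0
    expected_len = 3 * len(design.protein)
    for seq in _iter_reads(reads):
        hit = extractor.extract(seq)
        if hit is None or len(hit[1]) != expected_len:
            dropped += 1
            continue
        bundles.setdefault(hit[0], []).append(hit[1])

    rows = []
    low_support = 0
    for barcode in sorted(bundles):
        bundle = bundles[barcode]
        if len(bundle) < min_support:
            low_support += 1
            continue
        consensus = call_consensus(bundle)
        rows.append(
            {
                "barcode": barcode,
                "assignment": classify_consensus(consensus, design),
                "support": len(bundle),
                "consensus": consensus,
            }
        )
    lookup = pd.DataFrame(rows, columns=["barcode", "assignment", "support", "consensus"])
    lookup.attrs["summary"] = {
        "n_barcodes": len(lookup),
        "n_retained": int((lookup["assignment"] != INVALID).sum()) if len(lookup) else 0,
        "n_invalid": int((lookup["assignment"] == INVALID).sum()) if len(lookup) else 0,
        "n_reads_dropped": dropped,
        "n_low_support": low_support,
    }
    return lookup


def count_barcodes(
    reads,
    lookup: pd.DataFrame,
    extractor: BarcodeExtractor | None = None,
) -> pd.DataFrame:
    """Exact-match barcode counts for one condition/timepoint.

    Returns one row per retained barcode (``barcode, variant_id, count``);
    reads whose barcode is unparseable or not retained are tallied into
    ``attrs['unassigned']``; ``attrs['total']`` records all reads seen.
    Retained + unassigned always equals the total exactly.
    """
    if lookup.empty:
        raise ValueError("lookup is empty")
    extractor = extractor or BarcodeExtractor()
    retained = lookup[lookup["assignment"] != INVALID]
    counts = dict.fromkeys(retained["barcode"], 0)
    unassigned = 0
    total = 0
    for seq in _iter_reads(reads):
        total += 1
        hit = extractor.extract(seq)
        if hit is None or hit[0] not in counts:
            unassigned += 1
        else:
            counts[hit[0]] += 1
    out = pd.DataFrame(
        {
            "barcode": retained["barcode"].to_numpy(),
            "variant_id": retained["assignment"].to_numpy(),
            "count": [counts[b] for b in retained["barcode"]],
        }
    )
    out.attrs["unassigned"] = unassigned
    out.attrs["total"] = total
    return out


def merge_timepoints(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Join pre/post-selection barcode counts into one enrichment-ready table.

    Inputs are :func:`count_barcodes` outputs; barcodes absent from one
    timepoint get count 0.  Unassigned totals are carried in ``attrs`` for
    the total-read normalization.
    """
    merged = pre[["barcode", "variant_id", "count"]].merge(
        post[["barcode", "count"]], on="barcode", how="outer", suffixes=("_pre", "_post")
    )
    out = pd.DataFrame(
        {
            "barcode": merged["barcode"],
            "variant_id": merged["variant_id"],
            "n_pre": merged["count_pre"].fillna(0).astype(int),
            "n_post": merged["count_post"].fillna(0).astype(int),
        }
    )
    out.attrs["pre_unassigned"] = pre.attrs.get("unassigned", 0)
    out.attrs["post_unassigned"] = post.attrs.get("unassigned", 0)
    return out


def lookup_accuracy(lookup: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of true barcodes whose lookup assignment matches the truth.

    ``truth`` has columns ``barcode, variant_id``; barcodes missing from the
    lookup or invalidated count as incorrect.
    """
    merged = truth.merge(
        lookup[["barcode", "assignment"]], on="barcode", how="left"
    )
    return float((merged["assignment"] == merged["variant_id"]).mean())
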