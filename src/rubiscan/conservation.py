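"""Per-position phylogenetic conservation from a multiple sequence alignment.

Conservation at a reference position is the maximum, over amino acids, of
the fraction of aligned sequences carrying that amino acid in the
corresponding column (a column that is 90% alanine scores 0.9).  Gaps and
non-standard residues are excluded from the denominator by default.  The
module consumes any aligned FASTA; building the alignment (e.g. an
iterative HMM search) is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from scipy import stats

from .design import AMINO_ACIDS

_GAPS = set("-.")


def _load_alignment(alignment) -> MultipleSeqAlignment:
    if isinstance(alignment, (str, Path)):
        return AlignIO.read(str(alignment), "fasta")
    return alignment


def column_conservation(
    alignment,
    reference_id: str,
    count_gaps: bool = False,
) -> pd.DataFrame:
    """Conservation profile along the ungapped reference sequence.

    Returns one row per 1-based reference position with the alignment
    column index, the reference residue, the conservation (maximum
    amino-acid fraction), the modal amino acid and the gap fraction.
    With ``count_gaps=True`` fractions are taken over all rows instead of
    non-gap rows only.
    """
    aln = _load_alignment(alignment)
    ref = next((rec for rec in aln if rec.id == reference_id), None)
    if ref is None:
        raise KeyError(f"reference id {reference_id!r} not in alignment")

    cols = np.array([list(str(rec.seq).upper()) for rec in aln])
    n_rows = len(aln)
    rows = []
    position = 0
    for j, ref_char in enumerate(str(ref.seq).upper()):
        if ref_char in _GAPS:
            continue
        position += 1
        column = cols[:, j]
        counts = {aa: int((column == aa).sum()) for aa in AMINO_ACIDS}
        n_gap = int(np.isin(column, list(_GAPS)).sum())
        denom = n_rows if count_gaps else sum(counts.values())
        if denom == 0:
            conservation, top_aa = float("nan"), ""
        else:
            top_aa = max(counts, key=counts.get)
            conservation = counts[top_aa] / denom
        rows.append(
            {
                "position": position,
                "column": j,
                "wt_aa": ref_char,
                "conservation": conservation,
                "top_aa": top_aa,
                "gap_fraction": n_gap / n_rows,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConservationFitness:
    """Per-position fitness vs conservation comparison."""

    table: pd.DataFrame  # position, conservation, mean_fitness
    rho: float  # Spearman correlation (NaN when undefined)
    pvalue: float
    conserved_tolerant: pd.DataFrame  # high conservation, high mean fitness
    variable_sensitive: pd.DataFrame  # low conservation, low mean fitness


def conservation_vs_fitness(
    profile: pd.DataFrame,
    fitness: pd.DataFrame,
    quantile: float = 0.2,
) -> ConservationFitness:
    """Relate positional conservation to mean mutational fitness.

    ``fitness`` is a per-variant table with columns ``position`` and
    ``e_norm``; the mean over the (up to 19) mutants at each position is
    compared with conservation by Spearman rank correlation.  Outlier
    panels are cut at the given quantiles of both axes.  A constant input
    makes the correlation undefined; it is reported as NaN.
    """
    per_pos = (
        fitness.groupby("position")["e_norm"].mean().rename("mean_fitness")
    )
    table = profile.merge(per_pos, left_on="position", right_index=True)
    if table.empty:
        raise ValueError("no positions shared between profile and fitness table")

    x = table["conservation"].to_numpy()
    y = table["mean_fitness"].to_numpy()
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        rho, pvalue = float("nan"), float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.spearmanr(x, y, nan_policy="omit")
        rho, pvalue = float(res.statistic), float(res.pvalue)

    hi_c, lo_c = np.nanquantile(x, [1 - quantile, quantile])
    hi_f, lo_f = np.nanquantile(y, [1 - quantile, quantile])
    conserved_tolerant = table[(x >= hi_c) & (y >= hi_f)]
    variable_sensitive = table[(x <= lo_c) & (y <= lo_f)]
    return ConservationFitness(
        table=table[["position", "wt_aa", "conservation", "mean_fitness"]],
        rho=rho,
        pvalue=pvalue,
        conserved_tolerant=conserved_tolerant,
        variable_sensitive=variable_sensitive,
    )


def synthetic_alignment(
    reference: str,
    target_conservation,
    n_sequences: int = 200,
    reference_id: str = "reference",
    seed: int = 0,
) -> MultipleSeqAlignment:
    """Synthetic ungapped alignment with per-column conservation targets.

    Each non-reference row keeps the reference residue with the column's
    target probability and otherwise draws uniformly from the other 19
    amino acids.  Useful as a test fixture with known conservation.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng([0xA1, seed])
    target = np.broadcast_to(
        np.asarray(target_conservation, dtype=float), (len(reference),)
    )
    records = [SeqRecord(Seq(reference), id=reference_id, description="")]
    others = {aa: [b for b in AMINO_ACIDS if b != aa] for aa in AMINO_ACIDS}
    for s in range(1, n_sequences):
        chars = []
        for k, ref_aa in enumerate(reference):
            if rng.random() < target[k]:
                chars.append(ref_aa)
            else:
                chars.append(others[ref_aa][rng.integers(0, 19)])
        records.append(SeqRecord(Seq("".join(chars)), id=f"seq{s}", description=""))
    return MultipleSeqAlignment(records)
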