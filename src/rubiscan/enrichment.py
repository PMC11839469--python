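"""Variant enrichment statistics for the pooled selection.

The enrichment of variant j in one condition/replicate is the median over
its barcodes i (passing a minimum-count threshold) of the total-normalized
log ratio

    e_j = median_i [ log10((N_f,i + N_f,tot * a_p) / (N_0,i + N_0,tot * a_p))
                     - log10(N_f,tot / N_0,tot) ]

where N_0/N_f are pre/post-selection read counts, N_tot the column totals
(including unassigned reads) and a_p a pseudo-count constant scaled by the
totals.  A barcode enters the median iff max(N_0,i, N_f,i) >= c_min
(observed either pre- OR post-selection).  Enrichments are then normalized
so the pooled wild-type barcodes map to 1 and the median over a panel of
catalytically dead mutants maps to 0:

    e_j,norm = (e_j - e_dead) / (e_WT - e_dead)

The two processing parameters (c_min, a_p) are chosen by a 2-D sweep that
maximizes the mean pairwise Pearson correlation between replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import WILD_TYPE


class EmptyConditionError(ValueError):
    """Raised when a count table has zero total reads on either side."""


class NoSelectionSignalError(ValueError):
    """Raised when wild-type and dead-panel enrichments coincide."""


@dataclass(frozen=True)
class EnrichmentConfig:
    """Processing parameters; defaults are the sweep-optimized values."""

    c_min: int = 5
    alpha_p: float = 3.65e-7

    def __post_init__(self) -> None:
        if self.c_min < 0:
            raise ValueError("c_min must be >= 0")
        if self.alpha_p <= 0:
            raise ValueError("alpha_p must be > 0")


#: Default dead-panel variant-id prefix positions; see design.DEFAULT_DEAD_POSITIONS.
def dead_variant_ids(variants: pd.DataFrame) -> list[str]:
    """Variant ids flagged dead in a ground-truth table."""
    return list(variants.loc[variants["is_dead"], "variant_id"])


def barcode_log_ratios(
    n_pre: np.ndarray,
    n_post: np.ndarray,
    pre_total: float,
    post_total: float,
    alpha_p: float,
) -> np.ndarray:
    """Per-barcode total-normalized log10 enrichment with pseudo-counts."""
    if pre_total <= 0 or post_total <= 0:
        raise EmptyConditionError("empty condition: zero total reads")
    return np.log10(
        (n_post + post_total * alpha_p) / (n_pre + pre_total * alpha_p)
    ) - np.log10(post_total / pre_total)


def compute_enrichment(
    counts: pd.DataFrame,
    config: EnrichmentConfig | None = None,
    pre_unassigned: int = 0,
    post_unassigned: int = 0,
) -> pd.DataFrame:
    """Raw per-variant enrichments for one condition/replicate.

    ``counts`` has columns ``barcode, variant_id, n_pre, n_post``.  Totals
    are the column sums plus any unassigned reads.  Variants whose barcodes
    all fail the count threshold are emitted with ``e_raw = NaN``
    (missing), never silently dropped.
    """
    config = config or EnrichmentConfig()
    n_pre = counts["n_pre"].to_numpy(dtype=float)
    n_post = counts["n_post"].to_numpy(dtype=float)
    pre_total = n_pre.sum() + pre_unassigned
    post_total = n_post.sum() + post_unassigned
    ratios = barcode_log_ratios(n_pre, n_post, pre_total, post_total, config.alpha_p)
    passing = np.maximum(n_pre, n_post) >= config.c_min

    vids = counts["variant_id"].to_numpy()
    e = (
        pd.Series(ratios[passing])
        .groupby(pd.Categorical(vids[passing]), observed=True)
        .median()
    )
    all_variants = pd.Index(pd.unique(vids), name="variant_id")
    out = pd.DataFrame(
        {
            "e_raw": e.reindex(all_variants),
            "n_barcodes": pd.Series(passing.astype(int))
            .groupby(pd.Categorical(vids), observed=True)
            .sum()
            .reindex(all_variants, fill_value=0),
        }
    )
    out.attrs["pre_total"] = float(pre_total)
    out.attrs["post_total"] = float(post_total)
    return out


def normalize_enrichment(
    raw: pd.DataFrame,
    dead_variants: Iterable[str],
    wt_id: str = WILD_TYPE,
) -> pd.DataFrame:
    """Rescale raw enrichments so WT -> 1 and the dead-panel median -> 0."""
    dead_variants = [d for d in dead_variants if d in raw.index]
    if not dead_variants:
        raise ValueError("dead panel absent from enrichment table")
    if wt_id not in raw.index:
        raise ValueError("wild-type entry absent from enrichment table")
    e_wt = float(raw.loc[wt_id, "e_raw"])
    e_dead = float(np.nanmedian(raw.loc[dead_variants, "e_raw"].to_numpy()))
    denom = e_wt - e_dead
    if not np.isfinite(denom) or denom == 0.0:
        raise NoSelectionSignalError("no selection signal: e_WT equals dead median")
    out = raw.copy()
    out["e_norm"] = (out["e_raw"] - e_dead) / denom
    out.attrs.update(raw.attrs)
    out.attrs["e_wt"] = e_wt
    out.attrs["e_dead"] = e_dead
    return out


def pairwise_replicate_correlation(
    tables: Mapping[int, pd.Series] | Sequence[pd.Series],
) -> float:
    """Mean Pearson correlation over all unordered replicate pairs.

    Each table is a per-variant series of (normalized) enrichments indexed
    by variant id; variants missing (NaN) in either member of a pair are
    excluded from that pair only.
    """
    series = list(tables.values()) if isinstance(tables, Mapping) else list(tables)
    if len(series) < 2:
        raise ValueError("need >= 2 replicates")
    coeffs = []
    for a, b in itertools.combinations(series, 2):
        joined = pd.concat([a, b], axis=1, join="inner").dropna()
        if len(joined) < 2:
            raise ValueError("fewer than 2 shared variants between replicates")
        x = joined.iloc[:, 0].to_numpy()
        y = joined.iloc[:, 1].to_numpy()
        coeffs.append(np.corrcoef(x, y)[0, 1])
    return float(np.mean(coeffs))


def enrichment_by_replicate(
    counts: pd.DataFrame,
    dead_variants: Iterable[str],
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Normalized enrichments for a long-form multi-condition count table.

    ``counts`` carries columns ``co2_percent, co2_um, replicate, barcode,
    variant_id, n_pre, n_post``; returns long-form rows
    ``variant_id, co2_percent, co2_um, replicate, e_raw, e_norm, n_barcodes``.
    """
    dead_variants = list(dead_variants)
    frames = []
    for (co2_percent, co2_um, rep), sub in counts.groupby(
        ["co2_percent", "co2_um", "replicate"], sort=True
    ):
        norm = normalize_enrichment(compute_enrichment(sub, config), dead_variants)
        norm = norm.reset_index()
        norm.insert(1, "co2_percent", co2_percent)
        norm.insert(2, "co2_um", co2_um)
        norm.insert(3, "replicate", rep)
        frames.append(norm)
    return pd.concat(frames, ignore_index=True)


def mean_fitness_at(
    enrichments: pd.DataFrame, co2_percent: float
) -> pd.Series:
    """Per-variant normalized enrichment at one condition, averaged over replicates."""
    sub = enrichments[enrichments["co2_percent"] == co2_percent]
    if sub.empty:
        raise ValueError(f"no condition at {co2_percent}% CO2")
    return sub.groupby("variant_id")["e_norm"].mean()


def sweep_processing_params(
    counts: pd.DataFrame,
    dead_variants: Iterable[str],
    c_min_grid: Sequence[int] = tuple(range(0, 51, 5)),
    alpha_grid: Sequence[float] = tuple(np.logspace(-9, -6, 10)),
) -> tuple[EnrichmentConfig, pd.DataFrame]:
    """2-D sweep of (c_min, alpha_p) maximizing mean replicate correlation.

    Every grid combination is evaluated; the mean pairwise Pearson
    coefficient is computed within each condition and averaged across
    conditions.  Ties break toward smaller c_min, then smaller alpha_p.
    Returns the best config and the full correlation surface.
    """
    if not len(c_min_grid) or not len(alpha_grid):
        raise ValueError("sweep grids must be non-empty")
    dead_variants = list(dead_variants)
    rows = []
    for c_min in c_min_grid:
        for alpha in alpha_grid:
            cfg = EnrichmentConfig(c_min=int(c_min), alpha_p=float(alpha))
            table = enrichment_by_replicate(counts, dead_variants, cfg)
            corrs = []
            for _, sub in table.groupby("co2_percent"):
                reps = {
                    r: s.set_index("variant_id")["e_norm"]
                    for r, s in sub.groupby("replicate")
                }
                corrs.append(pairwise_replicate_correlation(reps))
            rows.append(
                {
                    "c_min": int(c_min),
                    "alpha_p": float(alpha),
                    "mean_pearson": float(np.mean(corrs)),
                }
            )
    surface = pd.DataFrame(rows)
    # correlations within 1e-10 are treated as tied so that the stated
    # tie-break (smaller c_min, then smaller alpha_p) is numerically stable
    ranked = surface.assign(_r=surface["mean_pearson"].round(10)).sort_values(
        ["_r", "c_min", "alpha_p"], ascending=[False, True, True]
    )
    best = ranked.iloc[0]
    return EnrichmentConfig(int(best["c_min"]), float(best["alpha_p"])), surface
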