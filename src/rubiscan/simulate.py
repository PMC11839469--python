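"""Synthetic growth-coupled selection experiments with known ground truth.

The generator emulates the selection assay end to end: a barcoded
single-substitution library with per-variant Michaelis-Menten kinetics,
exponential (log-phase) growth in a rubisco-dependent host at a set CO2
concentration, and multinomial sequencing of barcode abundances before and
after selection.  Growth rate interpolates linearly between a residual
"dead" rate and the wild-type rate in proportion to carboxylation velocity,
so in expectation the normalized enrichment of a variant equals
v_mut/v_WT — the quantity the downstream ratiometric Michaelis-Menten fit
assumes.

All randomness flows from a single master seed through fixed per-operation
child streams, so identical configurations reproduce byte-identical tables
and reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ReferenceDesign, WILD_TYPE

# Henry's-law solubility of CO2 in water at 25 C [mol / (L atm)] and the
# van 't Hoff temperature-dependence coefficient [K].  5% CO2 at 37 C gives
# ~1,220 uM dissolved CO2.
HENRY_KH_25C = 0.0334
VANT_HOFF_K = 2400.0
_T0_K = 298.15

# Fixed anchors flanking the 30-nt barcode in simulated amplicons/long reads.
BARCODE_FLANK_5 = "TCGACTGAGGCT"
BARCODE_FLANK_3 = "AGCTTGCATGCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Per-operation child-stream tags (master seed is the second word).
_STREAM = {"library": 0x11, "selection": 0x22, "long_reads": 0x33, "short_reads": 0x44}


def _rng(op: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[op], seed])


def dissolved_co2(
    co2_percent: float,
    temperature_c: float = 37.0,
    kh_25c: float = HENRY_KH_25C,
    vant_hoff_k: float = VANT_HOFF_K,
) -> float:
    """Equilibrium dissolved CO2 (uM) for a gas phase at 1 atm total pressure.

    Henry's law with a van 't Hoff temperature correction:
    ``C = p_CO2 * K_H(25C) * exp[k * (1/T - 1/298.15)]``; linear in the gas
    fraction.
    """
    if co2_percent < 0 or co2_percent > 100:
        raise ValueError("co2_percent must be in [0, 100]")
    if not 0 < temperature_c < 100:
        raise ValueError("temperature_c must be in (0, 100)")
    t_k = temperature_c + 273.15
    kh = kh_25c * math.exp(vant_hoff_k * (1.0 / t_k - 1.0 / _T0_K))
    return co2_percent / 100.0 * kh * 1e6


@dataclass(frozen=True)
class SelectionCondition:
    """One growth condition of the CO2 titration."""

    co2_percent: float
    co2_um: float
    replicate_id: int
    wt_doublings: float = math.log2(100.0)  # "100-fold expansion" of the culture

    def __post_init__(self) -> None:
        if self.co2_percent > 0 and self.co2_um <= 0:
            raise ValueError("co2_um must be positive when co2_percent > 0")
        if self.wt_doublings <= 0:
            raise ValueError("wt_doublings must be positive")


def default_conditions(
    co2_percents: Sequence[float] = (0.3, 0.7, 1.5, 3.0, 5.0, 10.0),
    replicates: int = 3,
    temperature_c: float = 37.0,
    wt_doublings: float = math.log2(100.0),
) -> list[SelectionCondition]:
    """The default CO2 titration grid x biological replicates."""
    return [
        SelectionCondition(p, dissolved_co2(p, temperature_c), r, wt_doublings)
        for p in co2_percents
        for r in range(1, replicates + 1)
    ]


@dataclass(frozen=True)
class GrowthModel:
    """Linear map from relative carboxylation velocity to growth rate.

    mu(v) = mu_dead + (mu_wt - mu_dead) * v / v_WT.  The proportionality
    constant between growth-rate and velocity differences cancels in the
    normalized enrichment, so only the two endpoints matter.  Growth is
    capped at ``mu_max`` (default 1.5x wild type): in the host, factors
    other than rubisco flux limit growth well before a variant could grow
    arbitrarily faster than wild type, and without a cap a single
    high-velocity variant can swallow the whole post-selection pool.
    """

    mu_wt: float = 0.45  # 1/h
    mu_dead: float = 0.02  # 1/h
    mu_max: float = 0.675  # 1/h

    def __post_init__(self) -> None:
        if not self.mu_max >= self.mu_wt > self.mu_dead >= 0:
            raise ValueError("require mu_max >= mu_wt > mu_dead >= 0")

    def growth_rate(self, v_rel: np.ndarray) -> np.ndarray:
        mu = self.mu_dead + (self.mu_wt - self.mu_dead) * v_rel
        return np.minimum(mu, self.mu_max)

    def selection_time(self, wt_doublings: float) -> float:
        """Hours for the wild type to complete the configured doublings."""
        return wt_doublings * math.log(2.0) / self.mu_wt


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment; the seed fully determines output."""

    seed: int = 0
    barcodes_per_variant: int = 20
    barcode_length: int = 30
    read_depth: int = 1_000_000  # reads per condition per timepoint
    short_read_depth: int = 100_000
    reads_per_barcode: int = 20  # long reads
    long_read_error_rate: float = 0.0
    kcat_wt: float = 8.0  # 1/s
    kc_wt_um: float = 149.0
    # Mutant kinetics prior: mostly deleterious, bounded just above wild type
    # (gains beyond ~15% of wild-type kcat are not observed), K_C lognormal
    # around wild type truncated to the observable range, plus a null
    # fraction of near-dead (e.g. unfolded) mutants giving the bimodal
    # fitness distribution characteristic of deep mutational scans.
    kcat_log_mu: float = -0.35  # lognormal location of mutant kcat / kcat_wt
    kcat_log_sigma: float = 0.35
    kcat_ratio_max: float = 1.15
    kc_log_sigma: float = 0.6  # lognormal scale of mutant K_C around wild type
    kc_min_um: float = 30.0
    kc_max_um: float = 1500.0
    expression_log_sigma: float = 0.2
    fraction_null: float = 0.25  # near-dead mutants outside the dead panel
    null_kcat_factor: float = 0.02
    preselection_log_sigma: float = 0.5  # bottlenecked barcode abundances
    dead_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "barcodes_per_variant",
            "barcode_length",
            "read_depth",
            "short_read_depth",
            "reads_per_barcode",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.long_read_error_rate < 0.5:
            raise ValueError("long_read_error_rate must be in [0, 0.5)")
        if self.kc_wt_um <= 0 or self.kcat_wt <= 0:
            raise ValueError("wild-type kinetics must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _unique_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in _BASES[block]:
            bc = row.tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_library(
    design: ReferenceDesign, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ground-truth kinetics and barcode assignments for the library.

    Returns ``(variants, barcodes)``: one row per designed variant plus a
    wild-type entry (kcat, K_C, expression factor, dead flag), and the
    barcode -> variant assignment table with ``barcodes_per_variant`` unique
    barcodes each.
    """
    rng = _rng("library", config.seed)
    dead = set(config.dead_positions)
    missing = dead - set(design.mutable_positions)
    if missing:
        raise ValueError(f"dead positions not in design: {sorted(missing)}")

    n_mut = len(design.variants)
    kcat_ratio = np.minimum(
        rng.lognormal(config.kcat_log_mu, config.kcat_log_sigma, size=n_mut),
        config.kcat_ratio_max,
    )
    null = rng.random(n_mut) < config.fraction_null
    kcat_ratio[null] *= config.null_kcat_factor
    kcat = config.kcat_wt * kcat_ratio
    kc = np.clip(
        config.kc_wt_um * rng.lognormal(0.0, config.kc_log_sigma, size=n_mut),
        config.kc_min_um,
        config.kc_max_um,
    )
    expr = rng.lognormal(0.0, config.expression_log_sigma, size=n_mut)

    rows = [
        {
            "variant_id": WILD_TYPE,
            "position": 0,
            "wt_aa": "",
            "mut_aa": "",
            "true_kcat": config.kcat_wt,
            "true_kc_um": config.kc_wt_um,
            "expression_factor": 1.0,
            "is_dead": False,
        }
    ]
    for i, v in enumerate(design.variants):
        is_dead = v.position in dead
        rows.append(
            {
                "variant_id": v.variant_id,
                "position": v.position,
                "wt_aa": v.wt_aa,
                "mut_aa": v.mut_aa,
                "true_kcat": 0.0 if is_dead else kcat[i],
                "true_kc_um": kc[i],
                "expression_factor": expr[i],
                "is_dead": is_dead,
            }
        )
    variants = pd.DataFrame(rows)

    n_bc = len(variants) * config.barcodes_per_variant
    barcodes = pd.DataFrame(
        {
            "barcode": _unique_barcodes(n_bc, config.barcode_length, rng),
            "variant_id": np.repeat(
                variants["variant_id"].to_numpy(), config.barcodes_per_variant
            ),
        }
    )
    return variants, barcodes


def _relative_velocity(variants: pd.DataFrame, config: SimulationConfig, co2_um: float) -> np.ndarray:
    """Per-variant carboxylation velocity relative to wild type at one [CO2]."""
    v = (
        variants["expression_factor"].to_numpy()
        * variants["true_kcat"].to_numpy()
        * co2_um
        / (variants["true_kc_um"].to_numpy() + co2_um)
    )
    v_wt = config.kcat_wt * co2_um / (config.kc_wt_um + co2_um)
    return v / v_wt


def simulate_selection(
    variants: pd.DataFrame,
    barcodes: pd.DataFrame,
    conditions: Iterable[SelectionCondition],
    config: SimulationConfig,
    growth: GrowthModel | None = None,
    sampling: bool = True,
) -> pd.DataFrame:
    """Simulate pre/post-selection barcode counts for every condition.

    With ``sampling=True`` (the default) reads are drawn multinomially at
    ``config.read_depth`` per condition and timepoint, so counts sum to the
    configured depth exactly.  With ``sampling=False`` the infinite-depth
    limit is returned instead: expected cell counts with
    ``n_post = n_pre * exp(mu * t)`` per barcode and no renormalization.
    """
    growth = growth or GrowthModel()
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if config.read_depth <= 0:
        raise ValueError("zero read depth")

    rng = _rng("selection", config.seed)
    bc = barcodes.reset_index(drop=True)
    var_index = pd.Index(variants["variant_id"])
    vidx = var_index.get_indexer(bc["variant_id"])
    if (vidx < 0).any():
        raise ValueError("barcode table references unknown variants")

    replicates = sorted({c.replicate_id for c in conditions})
    abundance = {
        r: rng.lognormal(0.0, config.preselection_log_sigma, size=len(bc))
        for r in replicates
    }

    frames = []
    for cond in conditions:
        a = abundance[cond.replicate_id]
        v_rel = _relative_velocity(variants, config, cond.co2_um)
        mu = growth.growth_rate(v_rel)[vidx]
        t = growth.selection_time(cond.wt_doublings)
        log_growth = mu * t

        if sampling:
            p0 = a / a.sum()
            n_pre = rng.multinomial(config.read_depth, p0)
            logw = np.log(a) + log_growth
            w = np.exp(logw - logw.max())
            n_post = rng.multinomial(config.read_depth, w / w.sum())
        else:
            n_pre = config.read_depth * a / a.sum()
            n_post = n_pre * np.exp(log_growth)

        frames.append(
            pd.DataFrame(
                {
                    "co2_percent": cond.co2_percent,
                    "co2_um": cond.co2_um,
                    "replicate": cond.replicate_id,
                    "barcode": bc["barcode"],
                    "variant_id": bc["variant_id"],
                    "n_pre": n_pre,
                    "n_post": n_post,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _mutate(seqs: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitution errors on an array of base codes (uint8 ACGT)."""
    if rate == 0:
        return seqs
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    idx = lut[seqs]
    mask = rng.random(seqs.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    return _BASES[idx]


def simulate_reads(
    design: ReferenceDesign,
    barcodes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Synthesize long-read bundles and short barcode amplicons.

    Long reads: ``flank5 + barcode + flank3 + coding sequence`` with i.i.d.
    substitution errors on the coding region at ``long_read_error_rate``
    (the barcode region is emulated as accurately read — grouping reads by
    barcode is presumed solved upstream).  Short reads carry the barcode
    amplicon only.  Returns ``(long_reads, short_reads)`` as (id, sequence)
    pairs; FASTQ serialization lives in :mod:`rubiscan.io`.
    """
    cds_by_variant = {WILD_TYPE: design.cds}
    for v in design.variants:
        cds_by_variant[v.variant_id] = design.variant_cds(v)

    rng = _rng("long_reads", config.seed)
    long_reads: list[tuple[str, str]] = []
    for row in barcodes.itertuples(index=False):
        cds = np.frombuffer(cds_by_variant[row.variant_id].encode(), dtype=np.uint8)
        bundle = np.tile(cds, (config.reads_per_barcode, 1))
        bundle = _mutate(bundle, config.long_read_error_rate, rng)
        prefix = BARCODE_FLANK_5 + row.barcode + BARCODE_FLANK_3
        for k in range(config.reads_per_barcode):
            long_reads.append(
                (f"lr|{row.barcode}|{k}", prefix + bundle[k].tobytes().decode())
            )

    srng = _rng("short_reads", config.seed)
    counts = srng.multinomial(
        config.short_read_depth, np.full(len(barcodes), 1.0 / len(barcodes))
    )
    short_reads: list[tuple[str, str]] = []
    for (row, n) in zip(barcodes.itertuples(index=False), counts):
        amplicon = BARCODE_FLANK_5 + row.barcode + BARCODE_FLANK_3
        short_reads.extend((f"sr|{row.barcode}|{k}", amplicon) for k in range(n))
    return long_reads, short_reads
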