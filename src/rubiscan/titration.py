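"""Ratiometric Michaelis-Menten inference from the CO2 titration.

Under growth-coupled selection the normalized enrichment of a variant is,
in expectation, its carboxylation velocity relative to wild type, so as a
function of dissolved CO2 it follows

    e_norm([CO2]) = Vr * (K_C,WT + [CO2]) / (K_C,mut + [CO2])

with Vr = Vmax,mut / Vmax,WT and K_C,WT fixed to the literature value of
149 uM.  Fitting this curve across the titration yields a per-variant
Vmax ratio and apparent CO2 affinity K_C,mut.

Because the inferred affinity of weak variants is sensitive to the
enrichment processing parameters, each variant is refit across the full
(c_min, alpha_p) sweep combined with replicate subsampling — 11 x 10 x 10
= 1,100 bootstrap fits by default — and summarized by a robust
(quartile-based) coefficient of variation; variants with CV < 1 are
flagged reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .enrichment import (
    EnrichmentConfig,
    compute_enrichment,
    normalize_enrichment,
)


@dataclass(frozen=True)
class FitConfig:
    """Parameters of the titration fit and the reliability sweep."""

    kc_wt_um: float = 149.0
    vmax_bounds: tuple[float, float] = (0.0, 10.0)
    kc_bounds_um: tuple[float, float] = (1e-2, 1e4)
    c_min_grid: tuple[int, ...] = tuple(range(0, 51, 5))  # 11 values, linear 0-50
    alpha_grid: tuple[float, ...] = tuple(np.logspace(-9, -6, 10))
    n_subsamples: int = 10
    cv_threshold: float = 1.0
    cv_method: str = "quartile"  # or "sd"
    n_starts: tuple[int, int] = (5, 5)  # (Vr, K_C) log-grid multi-start
    n_refine: int = 3  # least-squares refinements from the best starts
    tol: float = 1e-14  # least-squares ftol/xtol/gtol
    missing_cell_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kc_wt_um <= 0:
            raise ValueError("kc_wt_um must be positive")
        if self.cv_method not in ("quartile", "sd"):
            raise ValueError("cv_method must be 'quartile' or 'sd'")

    @classmethod
    def reduced(cls, **kwargs) -> "FitConfig":
        """A 3 x 3 x 3 sweep for reduced-scale runs."""
        defaults = dict(
            c_min_grid=(0, 25, 50),
            alpha_grid=tuple(np.logspace(-9, -6, 3)),
            n_subsamples=3,
            n_refine=1,
            tol=1e-10,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def with_(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


def predict_enrichment(
    vmax_ratio: float,
    kc_mut_um,
    co2_um,
    config: FitConfig | None = None,
) -> np.ndarray | float:
    """Expected normalized enrichment of a variant at dissolved [CO2] (uM)."""
    kc_wt = (config or FitConfig()).kc_wt_um
    if np.any(np.asarray(kc_mut_um) <= 0):
        raise ValueError("kc_mut_um must be positive")
    return vmax_ratio * (kc_wt + co2_um) / (kc_mut_um + co2_um)


@dataclass(frozen=True)
class TitrationFit:
    vmax_ratio: float
    kc_um: float
    cost: float
    n_points: int
    pinned_vmax: bool
    pinned_kc: bool

    @property
    def pinned(self) -> bool:
        return self.pinned_vmax or self.pinned_kc


class UnfittableVariantError(ValueError):
    """Raised when fewer than two distinct CO2 levels are usable."""


def _start_grid(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    nv, nk = config.n_starts
    v_lo = max(config.vmax_bounds[0], 1e-3)
    v = np.geomspace(v_lo, config.vmax_bounds[1], nv)
    k = np.geomspace(config.kc_bounds_um[0], config.kc_bounds_um[1], nk)
    return v, k


def fit_titration(
    co2_um: Sequence[float],
    e_norm: Sequence[float],
    config: FitConfig | None = None,
) -> TitrationFit:
    """Bounded least-squares fit of the ratiometric Michaelis-Menten curve.

    All replicate points are weighted equally.  The objective is evaluated
    on a coarse multi-start grid over (Vr, K_C); bounded least squares is
    refined from the best ``n_refine`` starts (plus a data-driven start)
    and the lowest final objective wins, ties broken toward smaller K_C.
    Solutions pinned at a bound are flagged.
    """
    config = config or FitConfig()
    x = np.asarray(co2_um, dtype=float)
    y = np.asarray(e_norm, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(np.unique(x)) < 2:
        raise UnfittableVariantError("need >= 2 distinct CO2 levels")
    if np.any(x <= 0):
        raise ValueError("co2_um must be positive")

    kc_wt = config.kc_wt_um
    lo = np.array([config.vmax_bounds[0], config.kc_bounds_um[0]])
    hi = np.array([config.vmax_bounds[1], config.kc_bounds_um[1]])
    w = kc_wt + x  # fixed numerator factor

    def residuals(p):
        return p[0] * w / (p[1] + x) - y

    def jac(p):
        g = w / (p[1] + x)
        return np.column_stack([g, -p[0] * g / (p[1] + x)])

    # vectorized objective on the start grid, plus a data-driven start
    # (Vr from the highest-CO2 response assuming wild-type K_C)
    v0, k0 = _start_grid(config)
    i_max = int(np.argmax(x))
    v_guess = float(np.clip(abs(y[i_max]), lo[0] + 1e-6, hi[0]))
    cand_v = np.append(np.repeat(v0, len(k0)), v_guess)
    cand_k = np.append(np.tile(k0, len(v0)), kc_wt)
    pred = cand_v[:, None] * (w[None, :] / (cand_k[:, None] + x[None, :]))
    sse = ((pred - y[None, :]) ** 2).sum(axis=1)
    order = np.argsort(sse)
    starts = [(cand_v[i], cand_k[i]) for i in order[: max(config.n_refine, 1)]]

    best = None
    for v_s, k_s in starts:
        x0 = np.clip([v_s, k_s], lo + 1e-12, hi - 1e-12)
        sol = least_squares(
            residuals,
            x0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            x_scale=[1.0, kc_wt],
            xtol=config.tol,
            ftol=config.tol,
            gtol=config.tol,
        )
        key = (sol.cost, sol.x[1])
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    vr, kc = float(sol.x[0]), float(sol.x[1])
    rtol = 1e-6
    return TitrationFit(
        vmax_ratio=vr,
        kc_um=kc,
        cost=float(sol.cost),
        n_points=len(x),
        pinned_vmax=(vr <= lo[0] + rtol * max(1.0, lo[0]))
        or (vr >= hi[0] * (1 - rtol)),
        pinned_kc=(kc <= lo[1] * (1 + 1e-3)) or (kc >= hi[1] * (1 - 1e-3)),
    )


def robust_cv(values: Sequence[float], method: str = "quartile") -> float:
    """Coefficient of variation of bootstrap estimates.

    ``quartile``: IQR / (1.349 * |median|) — the Gaussian-consistent robust
    sigma over mu.  ``sd``: plain standard deviation over |mean|.  Scale
    invariant by construction; an identically-constant sample has CV 0.
    """
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return float("inf")
    if method == "quartile":
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        spread = (q3 - q1) / 1.349
        center = abs(med)
    elif method == "sd":
        spread = float(np.std(v))
        center = abs(float(np.mean(v)))
    else:
        raise ValueError("method must be 'quartile' or 'sd'")
    if spread == 0.0:
        return 0.0
    if center == 0.0:
        return float("inf")
    return float(spread / center)


def _enrichment_tensor(
    groups: list[tuple[float, int, pd.DataFrame]],
    var_index: pd.Index,
    dead_variants: list[str],
    co2_levels: np.ndarray,
    replicates: list[int],
    config: EnrichmentConfig,
) -> np.ndarray:
    """E[variant, co2 level, replicate] of normalized enrichments (NaN = missing)."""
    E = np.full((len(var_index), len(co2_levels), len(replicates)), np.nan)
    co2_pos = {c: i for i, c in enumerate(co2_levels)}
    rep_pos = {r: i for i, r in enumerate(replicates)}
    for co2_um, rep, sub in groups:
        norm = normalize_enrichment(compute_enrichment(sub, config), dead_variants)
        idx = var_index.get_indexer(norm.index)
        keep = idx >= 0
        E[idx[keep], co2_pos[co2_um], rep_pos[rep]] = norm["e_norm"].to_numpy()[keep]
    return E


def reliability_sweep(
    counts: pd.DataFrame,
    dead_variants: Iterable[str],
    config: FitConfig | None = None,
    variants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bootstrap the titration fit over the processing-parameter sweep.

    For every (c_min, alpha_p) grid cell the enrichments are recomputed;
    for each cell the replicates are subsampled with replacement
    ``n_subsamples`` times and the ratiometric fit repeated, giving
    ``len(c_min_grid) * len(alpha_grid) * n_subsamples`` bootstrap K_C
    values per variant (1,100 at the default grids).  Returns one row per
    variant: median Vr and K_C of the sweep, bootstrap quartiles, the
    robust CV, the reliability flag (CV < threshold) and fit bookkeeping.
    Variants usable in fewer than half the sweep cells get CV = inf.
    """
    config = config or FitConfig()
    dead_variants = list(dead_variants)
    rng = np.random.default_rng([0x77, config.seed])

    groups = [
        (co2_um, rep, sub)
        for (co2_um, rep), sub in counts.groupby(["co2_um", "replicate"], sort=True)
    ]
    co2_levels = np.array(sorted({g[0] for g in groups}))
    replicates = sorted({g[1] for g in groups})
    n_rep = len(replicates)
    var_index = pd.Index(pd.unique(counts["variant_id"]))
    if variants is None:
        variants = [v for v in var_index]
    targets = var_index.get_indexer(pd.Index(variants))
    if (targets < 0).any():
        raise ValueError("requested variants absent from counts")

    n_cells = len(config.c_min_grid) * len(config.alpha_grid)
    kc_vals = [[] for _ in variants]
    vr_vals = [[] for _ in variants]
    n_attempted = np.zeros(len(variants), dtype=int)
    n_completed = np.zeros(len(variants), dtype=int)
    cells_ok = np.zeros(len(variants), dtype=int)

    x_full = np.repeat(co2_levels, n_rep)
    for c_min in config.c_min_grid:
        for alpha in config.alpha_grid:
            ecfg = EnrichmentConfig(c_min=int(c_min), alpha_p=float(alpha))
            E = _enrichment_tensor(
                groups, var_index, dead_variants, co2_levels, replicates, ecfg
            )
            rep_draws = rng.integers(0, n_rep, size=(config.n_subsamples, n_rep))
            cell_hit = np.zeros(len(variants), dtype=bool)
            for draw in rep_draws:
                for j, vi in enumerate(targets):
                    y = E[vi][:, draw].ravel()
                    finite = np.isfinite(y)
                    if len(np.unique(x_full[finite])) < 2:
                        continue
                    n_attempted[j] += 1
                    try:
                        fit = fit_titration(x_full, y, config)
                    except UnfittableVariantError:
                        continue
                    n_completed[j] += 1
                    vr_vals[j].append(fit.vmax_ratio)
                    # a K_C pinned at an imposed bound is not an estimate;
                    # keep it out of the bootstrap sample
                    if not fit.pinned_kc:
                        kc_vals[j].append(fit.kc_um)
                        cell_hit[j] = True
            cells_ok += cell_hit

    rows = []
    for j, vid in enumerate(variants):
        kcs = np.asarray(kc_vals[j])
        if len(kcs) and cells_ok[j] > config.missing_cell_fraction * n_cells:
            q1, med, q3 = np.percentile(kcs, [25, 50, 75])
            cv = robust_cv(kcs, config.cv_method)
        else:
            q1 = med = q3 = float("nan")
            cv = float("inf")
        rows.append(
            {
                "variant_id": vid,
                "vmax_ratio": float(np.median(vr_vals[j]))
                if vr_vals[j]
                else float("nan"),
                "kc_um": float(med),
                "cv": float(cv),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "reliable": bool(cv < config.cv_threshold),
                "n_fits": int(n_completed[j]),
                "n_kc_estimates": int(len(kcs)),
                "n_attempted": int(n_attempted[j]),
                "n_cells_ok": int(cells_ok[j]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_cells"] = n_cells
    out.attrs["n_bootstrap"] = n_cells * config.n_subsamples
    return out
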