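"""In-vitro kinetics calculations for purified rubisco.

Carboxylation is followed spectrophotometrically through a coupled assay
in which each carboxylation oxidizes two NADH (A340 declines), so the
carboxylation velocity is |dA/dt| / (eps * path) / 2.  Initial rates are
taken from the best-scoring linear window of the absorbance trace.
Substrate-saturation data are fit to the Michaelis-Menten curve by
non-linear least squares; turnover numbers come from a CABP titration of
active sites (y-intercept over x-intercept of the rate line); and CO2/O2
specificity from membrane-inlet mass spectrometry velocities,
S_C/O = v_C [O2] / (v_O [DIC]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

#: NADH molecules oxidized per carboxylation in the coupled assay.
NADH_PER_CARBOXYLATION = 2.0


@dataclass(frozen=True)
class WindowSearchConfig:
    """Hyper-parameter grid for initial-rate window selection."""

    start_stride: int = 5
    length_fractions: tuple[float, ...] = (0.1, 0.2, 0.4)
    min_points: int = 5


@dataclass(frozen=True)
class InitialRate:
    velocity_um_s: float  # carboxylation velocity
    nadh_rate_um_s: float
    slope: float  # A340 per second (negative for a declining trace)
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices of the chosen window
    score: float


def extract_initial_rate(
    times_s,
    a340,
    eps_path_per_um: float,
    config: WindowSearchConfig | None = None,
    nadh_per_carboxylation: float = NADH_PER_CARBOXYLATION,
) -> InitialRate:
    """Initial carboxylation velocity (uM/s) from an absorbance trace.

    Candidate (start, length) windows are scored by linear-fit R^2 times
    the fraction of the trace's total monotonic decrease the window
    covers; the best window's slope gives the NADH oxidation rate
    |slope| / (eps * path), halved for the 2:1 NADH:carboxylation
    stoichiometry.  A non-decreasing trace yields velocity 0 with a
    warning.  Invariant to a constant absorbance baseline.
    """
    config = config or WindowSearchConfig()
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(a340, dtype=float)
    if len(t) < config.min_points:
        raise ValueError(f"need >= {config.min_points} points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if eps_path_per_um <= 0:
        raise ValueError("eps_path_per_um must be positive")

    total_drop = float(a.max() - a.min())
    if total_drop <= 0:
        warnings.warn("non-decreasing trace: velocity set to 0")
        return InitialRate(0.0, 0.0, 0.0, 0.0, (0, len(a)), 0.0)

    n = len(a)
    lengths = sorted(
        {max(config.min_points, int(round(f * n))) for f in config.length_fractions}
    )
    best: InitialRate | None = None
    for length in lengths:
        for start in range(0, n - length + 1, config.start_stride):
            stop = start + length
            tw, aw = t[start:stop], a[start:stop]
            slope, intercept = np.polyfit(tw, aw, 1)
            fitted = slope * tw + intercept
            ss_res = float(((aw - fitted) ** 2).sum())
            ss_tot = float(((aw - aw.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            drop = float(aw[0] - aw[-1])
            score = max(r2, 0.0) * max(drop, 0.0) / total_drop
            if best is None or score > best.score:
                nadh_rate = abs(min(slope, 0.0)) / eps_path_per_um
                best = InitialRate(
                    velocity_um_s=nadh_rate / nadh_per_carboxylation,
                    nadh_rate_um_s=nadh_rate,
                    slope=float(slope),
                    r_squared=r2,
                    window=(start, stop),
                    score=score,
                )
    assert best is not None
    if best.slope >= 0:
        warnings.warn("non-decreasing best window: velocity set to 0")
        return InitialRate(0.0, 0.0, best.slope, best.r_squared, best.window, best.score)
    return best


@dataclass(frozen=True)
class MMFit:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    boundary: bool  # no curvature within the sampled range


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(conc_um, rates) -> MMFit:
    """Non-linear least-squares Michaelis-Menten fit of v vs [S].

    Replicates may simply be concatenated — points are weighted equally,
    so the pooled fit is the joint fit.  Standard errors come from the
    square root of the covariance diagonal.  The fit is flagged when K_M
    falls outside the sampled concentration range (no usable curvature).
    """
    s = np.asarray(conc_um, dtype=float)
    v = np.asarray(rates, dtype=float)
    ok = np.isfinite(s) & np.isfinite(v)
    s, v = s[ok], v[ok]
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    vmax0 = max(v.max(), 1e-9)
    km0 = float(np.median(s))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = optimize.curve_fit(
            _mm,
            s,
            v,
            p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    perr = np.sqrt(np.diag(pcov))
    km = float(popt[1])
    pos = s[s > 0]
    boundary = not (pos.min() / 5 <= km <= pos.max() * 5)
    return MMFit(float(popt[0]), km, float(perr[0]), float(perr[1]), boundary)


def fit_michaelis_menten_band(conc_um, rate_median, rate_sd) -> tuple[MMFit, MMFit, MMFit]:
    """Triplicate error-band recipe: fits to median - sd, median, median + sd."""
    med = np.asarray(rate_median, dtype=float)
    sd = np.asarray(rate_sd, dtype=float)
    low = fit_michaelis_menten(conc_um, med - sd)
    mid = fit_michaelis_menten(conc_um, med)
    high = fit_michaelis_menten(conc_um, med + sd)
    return low, mid, high


def kcat_from_cabp(cabp_um, rates_um_s) -> float:
    """Turnover number (1/s) from a CABP active-site titration.

    Reaction rate declines linearly with inhibitor: rate = a - b*[CABP].
    k_cat = y-intercept / x-intercept = a / (a/b) = b, i.e. the slope
    magnitude, with rates in uM/s and CABP (= active sites) in uM.
    """
    c = np.asarray(cabp_um, dtype=float)
    v = np.asarray(rates_um_s, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 CABP concentrations")
    res = stats.linregress(c, v)
    if res.slope >= 0:
        raise ValueError("no titration signal: rates do not decline with CABP")
    return float(-res.slope)


def specificity_from_mims(
    vc: float, vo: float, o2_um: float, dic_um: float
) -> float:
    """CO2/O2 specificity S_C/O = v_C [O2] / (v_O [DIC])."""
    if vo <= 0:
        raise ValueError("no oxygenation detected")
    if dic_um <= 0:
        raise ValueError("dic_um must be positive")
    return vc * o2_um / (vo * dic_um)


def co2_from_bicarbonate(
    hco3_um: float, ph: float = 8.0, pka: float = 6.35
) -> float:
    """Dissolved CO2 (uM) in equilibrium with bicarbonate at a given pH.

    Henderson-Hasselbalch: [CO2] = [HCO3-] * 10^(pKa' - pH).  The
    effective pKa' depends on temperature and ionic strength and is
    configurable.
    """
    if hco3_um < 0:
        raise ValueError("hco3_um must be >= 0")
    return hco3_um * math.pow(10.0, pka - ph)
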