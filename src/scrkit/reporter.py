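"""Reporter-assay quantification and associated statistics.

Read-through efficiency from dual reporters: each replicate's test-reporter
signal (FLuc or GFP) is normalized to a co-transfected control reporter
(RLuc or RFP), and the normalized activity of the read-through construct is
expressed as a percentage of a construct carrying no stop codon between the
upstream ORF and the reporter,

    efficiency% = 100 * (R_test - B) / (R_nostop - B),

with B the mean ratio of a negative-control construct when background
subtraction is requested (off by default; both raw and subtracted values can
be computed). Standard errors propagate to the ratio by the first-order
delta method. Also here: the 2^-ddCt qPCR fold change, the JC-1 red/green
spectral ratio (mitochondrial membrane potential proxy), single-exponential
protein-decay half-life fitting with censoring, and Student/Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateReplicateError,
    InsufficientDataError,
    InvalidControlError,
)


@dataclass(frozen=True)
class ReporterPlate:
    """Replicate dual-reporter measurements for one construct."""

    construct: str
    replicates: tuple[tuple[float, float], ...]  # (test signal, control signal)

    def __post_init__(self):
        if not self.replicates:
            raise InsufficientDataError(f"{self.construct}: no replicates")

    @property
    def ratios(self) -> np.ndarray:
        for i, (_, ctrl) in enumerate(self.replicates):
            if ctrl <= 0:
                raise DegenerateReplicateError(
                    f"{self.construct}: control signal <= 0 in replicate {i}"
                )
        arr = np.asarray(self.replicates, dtype=float)
        return arr[:, 0] / arr[:, 1]


@dataclass(frozen=True)
class EfficiencyEstimate:
    percent: float
    se: float
    sd: float
    n: int
    background_subtracted: bool


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential decay fit; ``censored`` marks half-lives reported as > t_max."""

    half_life: float | None
    censored: bool
    t_max: float
    slope: float
    r_squared: float
    n_points: int

    def __str__(self):
        if self.censored:
            return f"t1/2 > {self.t_max:g}"
        return f"t1/2 = {self.half_life:.3g}"


def normalized_activity(plate: ReporterPlate) -> tuple[float, float]:
    """Mean and standard error of per-replicate test/control ratios."""
    r = plate.ratios
    se = float(r.std(ddof=1) / math.sqrt(len(r))) if len(r) > 1 else 0.0
    return float(r.mean()), se


def _ratio_estimate(
    test_mean, test_se, ctrl_mean, ctrl_se, background, bg_se, n, subtracted
) -> EfficiencyEstimate:
    num = test_mean - background
    den = ctrl_mean - background
    if den <= 0:
        raise InvalidControlError("no-stop control mean does not exceed background")
    ratio = num / den
    # first-order (delta method) propagation on the ratio of independent means
    var_num = test_se**2 + bg_se**2
    var_den = ctrl_se**2 + bg_se**2
    if num == 0:
        se = 100.0 * math.sqrt(var_num) / den
    else:
        se = 100.0 * abs(ratio) * math.sqrt(var_num / num**2 + var_den / den**2)
    return EfficiencyEstimate(
        percent=100.0 * ratio,
        se=se,
        sd=se * math.sqrt(n),
        n=n,
        background_subtracted=subtracted,
    )


def readthrough_efficiency(
    test: ReporterPlate,
    nostop: ReporterPlate,
    negative: ReporterPlate | None = None,
    subtract_background: bool = False,
) -> EfficiencyEstimate:
    """Read-through efficiency of ``test`` relative to the no-stop control."""
    tm, ts = normalized_activity(test)
    nm, ns = normalized_activity(nostop)
    if subtract_background:
        if negative is None:
            raise InvalidControlError("background subtraction requested without a negative plate")
        bm, bs = normalized_activity(negative)
    else:
        bm, bs = 0.0, 0.0
    return _ratio_estimate(tm, ts, nm, ns, bm, bs, len(test.replicates), subtract_background)


def gfp_efficiency(
    test_ratios, nostop_ratios, subtract_background: bool = False, negative_ratios=None
) -> EfficiencyEstimate:
    """Efficiency from pre-computed per-replicate GFP/RFP intensity ratios."""

    def plate(name, ratios):
        if ratios is None or len(ratios) == 0:
            raise InsufficientDataError(f"{name}: no replicate ratios")
        return ReporterPlate(name, tuple((float(r), 1.0) for r in ratios))

    return readthrough_efficiency(
        plate("gfp_test", test_ratios),
        plate("gfp_nostop", nostop_ratios),
        plate("gfp_negative", negative_ratios) if negative_ratios is not None else None,
        subtract_background,
    )


def fold_change_ddct(
    target_ct: dict[str, list[float]],
    ref_ct: dict[str, list[float]],
    control_cond: str,
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    dCt = mean(target Ct) - mean(reference Ct) per condition;
    ddCt = dCt(condition) - dCt(control); fold change = 2^-ddCt.
    """
    missing = (set(target_ct) ^ set(ref_ct)) | ({control_cond} - set(target_ct))
    if missing:
        raise InsufficientDataError(f"conditions missing from Ct tables: {sorted(missing)}")
    dct = {
        cond: float(np.mean(target_ct[cond])) - float(np.mean(ref_ct[cond]))
        for cond in target_ct
    }
    return {cond: 2.0 ** -(dct[cond] - dct[control_cond]) for cond in dct}


def jc1_ratio(spectrum, red_nm: float = 594.0, green_nm: float = 538.0) -> float:
    """Red/green JC-1 fluorescence ratio, interpolating the spectrum linearly.

    ``spectrum`` is a sequence of (wavelength nm, intensity) points covering
    both target wavelengths.
    """
    pts = sorted((float(w), float(i)) for w, i in spectrum)
    w = np.array([p[0] for p in pts])
    inten = np.array([p[1] for p in pts])
    if not (w[0] <= green_nm <= w[-1] and w[0] <= red_nm <= w[-1]):
        raise InsufficientDataError("spectrum does not cover both target wavelengths")
    i_green = float(np.interp(green_nm, w, inten))
    i_red = float(np.interp(red_nm, w, inten))
    if i_green == 0:
        raise DegenerateReplicateError("zero intensity at the green wavelength")
    return i_red / i_green


def estimate_half_life(times, intensities, t_max: float = 36.0) -> DecayFit:
    """Half-life from a log-linear fit of intensity vs time.

    Non-positive intensities are excluded (they carry no log information);
    at least three usable points are required. The fit is least squares of
    ln(I) on t; t1/2 = ln2 / (-slope). When the slope is non-negative or the
    fitted half-life exceeds ``t_max`` the result is censored as > t_max,
    the convention for proteins stable over the chase duration.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = y > 0
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 positive intensities for a decay fit")
    res = stats.linregress(t, np.log(y))
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    if slope >= 0:
        return DecayFit(None, True, t_max, slope, r2, len(t))
    hl = math.log(2) / (-slope)
    if hl > t_max:
        return DecayFit(None, True, t_max, slope, r2, len(t))
    return DecayFit(hl, False, t_max, slope, r2, len(t))


def welch_t_test(a, b, welch: bool = True) -> tuple[float, float, float]:
    """Two-sided two-sample t-test.

    Student's pooled-variance form when ``welch`` is off;
    Welch-Satterthwaite degrees of freedom when on. Returns (t, df, p).
    Two identical zero-variance samples give t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = float(na + nb - 2)
            return 0.0, df, 1.0
        raise DegenerateReplicateError("zero variance in both samples with unequal means")
    if welch:
        sa2, sb2 = va / na, vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
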