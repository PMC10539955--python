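"""Estimators that turn measured ion abundances into biological quantities.

Inputs are integrated GC-MS ion areas at the three monitored masses of the
glucose derivative fragment (m/z 360/361/362 = M+0/M+1/M+2).  From these the
module computes excess enrichments, fractional gluconeogenesis f(GNG), the
fasted-state PEPCK-vs-glycerol split, the [2-13C]glycerol triose-phosphate
contribution, and body-water enrichment from the acetone assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from . import mida_core
from .isotopes import (
    GLUCOSE_FRAGMENT,
    IsotopePattern,
    IsotopeTable,
    natural_isotope_pattern,
)
from .mida_core import (
    ExcessEnrichments,
    GngModel,
    TOTAL_GNG,
    GGL,
    equivalent_n,
    invert_fgng,
    invert_fgng_tabular,
    invert_subpathway,
)

__all__ = [
    "MeasuredSpectrum",
    "BaselineSpec",
    "ReplicateEnrichments",
    "EstimateResult",
    "TriosePrecursorResult",
    "StandardCurveFit",
    "spectrum_to_enrichments",
    "estimate_fgng",
    "estimate_subpathways_fasted",
    "triose_precursor_13c",
    "body_water_enrichment",
]

#: EM1 values below this are flagged: the ratio EM2/EM1 becomes unreliable.
DEFAULT_EM1_FLOOR = 1e-4


@dataclass(frozen=True)
class MeasuredSpectrum:
    """One injection's raw integrated ion areas at M+0, M+1, M+2."""

    sample_id: str
    m0: float
    m1: float
    m2: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError(f"{self.sample_id}: M+0 area must be positive")
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError(f"{self.sample_id}: negative ion area")

    def fractions(self) -> np.ndarray:
        """Fractional abundances over the three monitored ions."""
        v = np.array([self.m0, self.m1, self.m2], dtype=float)
        return v / v.sum()


@dataclass(frozen=True)
class BaselineSpec:
    """Where the unlabeled baseline comes from.

    ``theoretical`` computes natural abundance from the fragment formula.
    ``empirical`` averages the fractional abundances of unlabeled standard
    injections, which folds in the instrument's concentration effect; it takes
    precedence when standards are available.
    """

    mode: str = "theoretical"
    standards: tuple[MeasuredSpectrum, ...] = ()
    comp: dict[str, int] = field(default_factory=lambda: dict(GLUCOSE_FRAGMENT))
    isotope_table: IsotopeTable | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("theoretical", "empirical"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if self.mode == "empirical" and not self.standards:
            raise ValueError("empirical baseline requires unlabeled standard spectra")

    def fractions(self) -> np.ndarray:
        """Baseline fractional abundances over the monitored window."""
        if self.mode == "empirical":
            mat = np.stack([s.fractions() for s in self.standards])
            return mat.mean(axis=0)
        pattern = natural_isotope_pattern(self.comp, table=self.isotope_table)
        return mida_core.fractional_abundances(pattern, "three-ion")

    def pattern(self) -> IsotopePattern:
        """Full natural-abundance pattern (theoretical component only)."""
        return natural_isotope_pattern(self.comp, table=self.isotope_table)


@dataclass(frozen=True)
class ReplicateEnrichments:
    """Per-replicate excess enrichments with summary statistics.

    The ratio is computed per replicate and then averaged (matching how
    replicate SEs are reported on R); the ratio of mean EMs is also kept.
    """

    per_replicate: tuple[ExcessEnrichments, ...]
    em1_mean: float
    em2_mean: float
    em1_se: float
    em2_se: float
    em1_cv: float
    ratio_mean: float
    ratio_se: float
    ratio_of_means: float
    low_em1: bool


def _summary(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, se


def spectrum_to_enrichments(
    spectra: MeasuredSpectrum | Sequence[MeasuredSpectrum],
    baseline: BaselineSpec | None = None,
    em1_floor: float = DEFAULT_EM1_FLOOR,
) -> ReplicateEnrichments:
    """Excess enrichments EM1, EM2 (and R) from raw three-ion areas.

    Areas are normalized within each injection, so any common scale factor
    cancels; the baseline fractions are subtracted to give excesses.
    """
    if isinstance(spectra, MeasuredSpectrum):
        spectra = [spectra]
    if not spectra:
        raise ValueError("no spectra given")
    baseline = baseline if baseline is not None else BaselineSpec()
    b = baseline.fractions()
    per = []
    for s in spectra:
        a = s.fractions()
        per.append(ExcessEnrichments(em1=float(a[1] - b[1]), em2=float(a[2] - b[2])))
    em1s = [e.em1 for e in per]
    em2s = [e.em2 for e in per]
    em1_mean, em1_se = _summary(em1s)
    em2_mean, em2_se = _summary(em2s)
    low = em1_mean < em1_floor
    if not low and all(e.ratio_defined for e in per):
        ratios = [e.ratio for e in per]
        ratio_mean, ratio_se = _summary(ratios)
        ratio_of_means = em2_mean / em1_mean
    else:
        low = True
        ratio_mean = ratio_se = ratio_of_means = math.nan
    cv = em1_se * math.sqrt(len(per)) / em1_mean if (len(per) > 1 and em1_mean > 0) else 0.0
    return ReplicateEnrichments(
        per_replicate=tuple(per),
        em1_mean=em1_mean,
        em2_mean=em2_mean,
        em1_se=em1_se,
        em2_se=em2_se,
        em1_cv=cv,
        ratio_mean=ratio_mean,
        ratio_se=ratio_se,
        ratio_of_means=ratio_of_means,
        low_em1=low,
    )


@dataclass(frozen=True)
class EstimateResult:
    """An f(GNG) (or subpathway-fraction) estimate with diagnostics."""

    sample_id: str
    f: float
    f_tabular: float | None
    n_equivalent: float | None
    ratio: float
    p: float
    em1: float
    em2: float
    flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flags


def _flags_from(inv, enr: ReplicateEnrichments) -> tuple[str, ...]:
    flags = []
    if enr.low_em1:
        flags.append("low-EM1")
    if inv.out_of_range:
        flags.append("out-of-range")
    if inv.clamped:
        flags.append("clamped")
    return tuple(flags)


def estimate_fgng(
    spectra: MeasuredSpectrum | Sequence[MeasuredSpectrum],
    p: float,
    baseline: BaselineSpec | None = None,
    n_gng: GngModel = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
    isotope_table: IsotopeTable | None = None,
    tabular: bool = True,
) -> EstimateResult:
    """Fractional gluconeogenesis from measured spectra at known body-water p.

    Composes :func:`spectrum_to_enrichments` with the exact mixture inversion;
    the tabular (bracketing-rows, arithmetic-mean) estimate is reported
    alongside for cross-checking.  Noise slack for the out-of-range flag is
    2 x the replicate SE of R when replicates are available.
    """
    if not 0.0 < p <= 0.08:
        raise ValueError(f"body-water enrichment p={p} outside (0, 0.08]")
    enr = spectrum_to_enrichments(spectra, baseline)
    if enr.low_em1:
        return EstimateResult(
            sample_id=_sample_id(spectra), f=math.nan, f_tabular=None, n_equivalent=None,
            ratio=math.nan, p=p, em1=enr.em1_mean, em2=enr.em2_mean, flags=("low-EM1",),
        )
    R = enr.ratio_mean
    slack = 2.0 * enr.ratio_se if enr.ratio_se else 0.0
    inv = invert_fgng(R, p, n_gng=n_gng, n_ggl=n_ggl, table=isotope_table, slack=slack)
    f_tab = invert_fgng_tabular(R, p, table=isotope_table) if tabular else None
    try:
        neq = equivalent_n(R, p, table=isotope_table)
    except ValueError:
        neq = None
    return EstimateResult(
        sample_id=_sample_id(spectra), f=inv.f, f_tabular=f_tab, n_equivalent=neq,
        ratio=R, p=p, em1=enr.em1_mean, em2=enr.em2_mean, flags=_flags_from(inv, enr),
    )


def _sample_id(spectra) -> str:
    if isinstance(spectra, MeasuredSpectrum):
        return spectra.sample_id
    return spectra[0].sample_id


def estimate_subpathways_fasted(
    spectra: MeasuredSpectrum | Sequence[MeasuredSpectrum],
    p: float,
    baseline: BaselineSpec | None = None,
    isotope_table: IsotopeTable | None = None,
) -> EstimateResult:
    """PEPCK share of the triose-phosphate pool from a fasted-state spectrum.

    Valid when f(GNG) is essentially 1 (prolonged fast: < 5% glycogen
    contribution); any residual glycogenolysis is ignored, which the caller
    accepts by choosing this estimator.  Returns f(PEPCK->TP); the glycerol
    share is its complement.
    """
    if not 0.0 < p <= 0.08:
        raise ValueError(f"body-water enrichment p={p} outside (0, 0.08]")
    enr = spectrum_to_enrichments(spectra, baseline)
    if enr.low_em1:
        return EstimateResult(
            sample_id=_sample_id(spectra), f=math.nan, f_tabular=None, n_equivalent=None,
            ratio=math.nan, p=p, em1=enr.em1_mean, em2=enr.em2_mean, flags=("low-EM1",),
        )
    R = enr.ratio_mean
    slack = 2.0 * enr.ratio_se if enr.ratio_se else 0.0
    inv = invert_subpathway(R, p, table=isotope_table, slack=slack)
    try:
        neq = equivalent_n(R, p, table=isotope_table)
    except ValueError:
        neq = None
    return EstimateResult(
        sample_id=_sample_id(spectra), f=inv.f, f_tabular=None, n_equivalent=neq,
        ratio=R, p=p, em1=enr.em1_mean, em2=enr.em2_mean, flags=_flags_from(inv, enr),
    )


@dataclass(frozen=True)
class TriosePrecursorResult:
    """13C triose-phosphate precursor enrichment and glycerol contribution."""

    sample_id: str
    q: float
    f_glycerol_to_tp: float
    egp_contribution: float
    ratio: float
    flags: tuple[str, ...]


def triose_precursor_13c(
    spectra: MeasuredSpectrum | Sequence[MeasuredSpectrum],
    plasma_glycerol_enrichment: float,
    f_gng: float,
    baseline: BaselineSpec | None = None,
    isotope_table: IsotopeTable | None = None,
) -> TriosePrecursorResult:
    """Glycerol contribution to the triose-phosphate pool from [2-13C]glycerol.

    Glucose is a condensation product of two triose subunits; with each
    subunit carrying one 13C with probability q (the triose-phosphate pool
    enrichment), the label-count distribution is binomial(2, q).  q is solved
    from the measured EM2/EM1 with the same convolution machinery used for
    deuterium, then compared with the plasma glycerol enrichment: their ratio
    is the fractional contribution of free glycerol to the pool, and
    multiplying by f(GNG) gives the glycerol share of endogenous glucose
    production.
    """
    if not 0.0 < plasma_glycerol_enrichment < 1.0:
        raise ValueError("plasma glycerol enrichment must be in (0, 1)")
    if not 0.0 <= f_gng <= 1.0:
        raise ValueError("f_gng must be in [0, 1]")
    baseline = baseline if baseline is not None else BaselineSpec()
    enr = spectrum_to_enrichments(spectra, baseline)
    flags: list[str] = []
    if enr.low_em1:
        return TriosePrecursorResult(
            sample_id=_sample_id(spectra), q=math.nan, f_glycerol_to_tp=math.nan,
            egp_contribution=math.nan, ratio=math.nan, flags=("low-EM1",),
        )
    R = enr.ratio_mean
    base_pattern = baseline.pattern()

    def model_ratio(q: float) -> float:
        pat = mida_core.labeled_pattern(2, q, base_pattern)
        return mida_core.excess_enrichments(pat, base_pattern, "three-ion").ratio

    lo, hi = 1e-9, 0.5 - 1e-9
    r_lo, r_hi = model_ratio(lo), model_ratio(hi)
    if not (min(r_lo, r_hi) <= R <= max(r_lo, r_hi)):
        flags.append("out-of-range")
        q = 0.0 if R < min(r_lo, r_hi) else 0.5
    else:
        q = float(brentq(lambda x: model_ratio(x) - R, lo, hi, xtol=1e-12))
    f_gly = q / plasma_glycerol_enrichment
    if q > plasma_glycerol_enrichment:
        flags.append("q-exceeds-plasma")
    return TriosePrecursorResult(
        sample_id=_sample_id(spectra), q=q, f_glycerol_to_tp=f_gly,
        egp_contribution=f_gly * f_gng, ratio=R, flags=tuple(flags),
    )


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of acetone M+1 fraction against known water enrichment."""

    slope: float
    intercept: float
    one_minus_r2: float
    p_range: tuple[float, float]


def body_water_enrichment(
    curve: Sequence[tuple[float, float]],
    sample_m1_fraction: float | Sequence[float],
    max_one_minus_r2: float = 0.003,
    allow_poor_fit: bool = False,
) -> tuple[float | np.ndarray, StandardCurveFit, tuple[str, ...]]:
    """Body-water deuterium enrichment p via the acetone standard curve.

    ``curve`` holds (known p, measured fractional M+1 abundance of acetone at
    m/z 58 over 57+58+59) pairs.  An ordinary least-squares line of response
    on p is inverted at the sample response.  Curves with 1-R^2 above
    ``max_one_minus_r2`` (the assay's quality bound) are rejected unless
    overridden; sample responses outside the fitted range are flagged as
    extrapolation.
    """
    pts = [(float(p), float(y)) for p, y in curve]
    if len(pts) < 3:
        raise ValueError("standard curve needs at least 3 points")
    for p, y in pts:
        if not 0.0 <= p <= 0.3:
            raise ValueError(f"curve enrichment {p} outside [0, 0.3]")
        if not 0.0 < y < 1.0:
            raise ValueError(f"curve response {y} outside (0, 1)")
    xs = np.array([p for p, _ in pts])
    ys = np.array([y for _, y in pts])
    res = linregress(xs, ys)
    one_minus_r2 = 1.0 - res.rvalue**2
    fit = StandardCurveFit(
        slope=float(res.slope), intercept=float(res.intercept),
        one_minus_r2=float(one_minus_r2), p_range=(float(xs.min()), float(xs.max())),
    )
    if one_minus_r2 > max_one_minus_r2 and not allow_poor_fit:
        raise ValueError(
            f"standard curve quality 1-R^2 = {one_minus_r2:.4f} exceeds {max_one_minus_r2}"
        )
    resp = np.asarray(sample_m1_fraction, dtype=float)
    p_hat = (resp - res.intercept) / res.slope
    flags = []
    lo, hi = ys.min(), ys.max()
    if np.any(resp < lo) or np.any(resp > hi):
        flags.append("extrapolation")
    if one_minus_r2 > max_one_minus_r2:
        flags.append("poor-fit")
    p_out = float(p_hat) if np.isscalar(sample_m1_fraction) else p_hat
    return p_out, fit, tuple(flags)
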