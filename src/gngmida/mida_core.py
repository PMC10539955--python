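"""The generative MIDA model of deuterium labeling on glucose.

Three parameters drive mass isotopomer distribution analysis (MIDA) here:

* ``n`` — the number of C-H positions of glucose that exchange hydrogen with
  body water along a given production pathway (7 for PEPCK gluconeogenesis,
  2 for glycerol gluconeogenesis, 1 for glycogenolysis, 6 as the integer
  approximation for total gluconeogenesis);
* ``p`` — the deuterium enrichment of body water (the precursor pool), a
  fraction, typically 0.005-0.08;
* ``f`` — the fraction of the glucose population produced by the labeled
  pathway.

A pathway's label-count distribution is binomial(n, p).  Convolved with the
natural-abundance pattern of the GC-MS fragment it gives the predicted
spectrum; subtracting the unlabeled baseline gives the excess enrichments
EM1 and EM2 whose ratio R = EM2/EM1 is the method's core observable.  Because
enrichments are linear in the mixing weights, R for a pathway mixture is a
ratio of linear forms in f, which this module inverts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binom

from .isotopes import (
    DEFAULT_MAX_SHIFT,
    GLUCOSE_FRAGMENT,
    IsotopePattern,
    IsotopeTable,
    convolve,
    natural_isotope_pattern,
)

__all__ = [
    "PathwayLabelModel",
    "PEPCK_GNG",
    "GLYCEROL_GNG",
    "TOTAL_GNG",
    "GGL",
    "ExcessEnrichments",
    "GngModel",
    "composite_gng",
    "label_site_distribution",
    "labeled_pattern",
    "fractional_abundances",
    "excess_enrichments",
    "pathway_excess",
    "pathway_ratio",
    "mixture_excess",
    "mixture_ratio",
    "subpathway_mixture_ratio",
    "equivalent_n",
    "invert_fgng",
    "invert_fgng_tabular",
    "invert_subpathway",
    "generate_table",
    "table_to_long",
    "DEFAULT_P_GRID",
    "DEFAULT_F_GRID",
]

MAX_SITES = 10
DEFAULT_WINDOW = "three-ion"

#: Table 1 layout: p from 0.5% to 8% in 0.5% steps, f(GNG) from 0 to 100% in 10% steps.
DEFAULT_P_GRID = tuple(np.round(np.arange(0.005, 0.0801, 0.005), 6))
DEFAULT_F_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 6))


@dataclass(frozen=True)
class PathwayLabelModel:
    """A glucose-production pathway identified by its exchangeable-site count."""

    name: str
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= MAX_SITES):
            raise ValueError(f"site count n={self.n} outside 0..{MAX_SITES}")


PEPCK_GNG = PathwayLabelModel("PEPCK-GNG", 7)
GLYCEROL_GNG = PathwayLabelModel("glycerol-GNG", 2)
TOTAL_GNG = PathwayLabelModel("total-GNG", 6)
GGL = PathwayLabelModel("GGL", 1)

#: A GNG end-member for mixture math: an integer site count or molecule-level
#: components given as (n, weight) pairs with weights summing to 1.
GngModel = Union[int, Sequence[tuple[int, float]]]


def composite_gng(f_pepck: float = 2.0 / 3.0) -> tuple[tuple[int, float], ...]:
    """Molecule-level total-GNG components: PEPCK (n=7) and glycerol (n=2) arms."""
    if not 0.0 <= f_pepck <= 1.0:
        raise ValueError("f_pepck must be in [0, 1]")
    return ((PEPCK_GNG.n, f_pepck), (GLYCEROL_GNG.n, 1.0 - f_pepck))


def _as_components(gng: GngModel) -> tuple[tuple[int, float], ...]:
    if isinstance(gng, (int, np.integer)):
        return ((int(gng), 1.0),)
    comps = tuple((int(n), float(w)) for n, w in gng)
    total = sum(w for _, w in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights sum to {total}, not 1")
    if any(w < 0 for _, w in comps):
        raise ValueError("negative mixture weight")
    return comps


def _check_p(p: float) -> None:
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"precursor enrichment p={p} outside [0, 0.5]")


def label_site_distribution(n: int, p: float, max_shift: int = DEFAULT_MAX_SHIFT) -> IsotopePattern:
    """Binomial label-count distribution over n exchangeable sites at enrichment p."""
    _check_p(p)
    if not (0 <= n <= MAX_SITES):
        raise ValueError(f"site count n={n} outside 0..{MAX_SITES}")
    pmf = binom.pmf(np.arange(min(n, max_shift) + 1), n, p)
    vec = np.zeros(max_shift + 1)
    vec[: pmf.size] = pmf
    return IsotopePattern(vec)


def labeled_pattern(
    model: PathwayLabelModel | int,
    p: float,
    baseline: IsotopePattern,
) -> IsotopePattern:
    """Spectrum pattern of glucose produced by one pathway at enrichment p."""
    n = model.n if isinstance(model, PathwayLabelModel) else int(model)
    sites = label_site_distribution(n, p, max_shift=len(baseline) - 1)
    return convolve(baseline, sites, max_shift=len(baseline) - 1)


def fractional_abundances(pattern: IsotopePattern, window: str = DEFAULT_WINDOW) -> np.ndarray:
    """Fractional abundances under a window convention.

    ``"three-ion"`` renormalizes over the monitored shifts {0,1,2} (what the
    instrument reports when only m/z 360-362 are scanned); ``"full"`` uses the
    raw truncated pattern.
    """
    a = pattern.abundances
    if window == "three-ion":
        return a[:3] / a[:3].sum()
    if window == "full":
        return a
    raise ValueError(f"unknown window {window!r}")


@dataclass(frozen=True)
class ExcessEnrichments:
    """Baseline-subtracted enrichments of the M+1 and M+2 mass isotopomers."""

    em1: float
    em2: float

    @property
    def ratio(self) -> float:
        """R = EM2/EM1; defined only when EM1 > 0."""
        if not self.ratio_defined:
            raise ValueError("EM2/EM1 undefined: EM1 <= 0")
        return self.em2 / self.em1

    @property
    def ratio_defined(self) -> bool:
        return self.em1 > 0.0


def excess_enrichments(
    pattern: IsotopePattern,
    baseline: IsotopePattern,
    window: str = DEFAULT_WINDOW,
) -> ExcessEnrichments:
    """EM_x = fractional abundance of M+x minus the baseline fraction."""
    a = fractional_abundances(pattern, window)
    b = fractional_abundances(baseline, window)
    return ExcessEnrichments(em1=float(a[1] - b[1]), em2=float(a[2] - b[2]))


def excess_numerators(
    pattern: IsotopePattern,
    baseline: IsotopePattern,
    window: str = DEFAULT_WINDOW,
) -> tuple[float, float]:
    """Unnormalized excesses N_x = A_x - b_x * (window sum of A).

    For a pure population N2/N1 equals the excess-enrichment ratio; unlike the
    per-population normalized EM_x, the N_x of a population mixture are
    *exactly* linear in the mixing weights under the three-ion window, because
    the mixture's window normalization cancels from the ratio.  They are the
    quantity mixture math should weight when the model must agree with a
    spectrum measured on the mixed population.
    """
    a = pattern.abundances
    b = fractional_abundances(baseline, window)
    if window == "three-ion":
        s = a[:3].sum()
        return float(a[1] - b[1] * s), float(a[2] - b[2] * s)
    if window == "full":
        return float(a[1] - b[1]), float(a[2] - b[2])
    raise ValueError(f"unknown window {window!r}")


#: Mixture-weighting conventions: "pattern" mixes populations at the spectrum
#: level (self-consistent with measured mixed spectra); "tabulated" weights
#: each population's window-normalized EM_x (the published lookup-table
#: convention; differs from "pattern" by < 0.7% relative in R at p <= 8%).
MIXING_CONVENTIONS = ("pattern", "tabulated")


class _ModelContext:
    """Caches the baseline and per-n excesses for one configuration."""

    def __init__(self, window: str, table: IsotopeTable | None, comp: dict[str, int] | None,
                 mixing: str = "pattern"):
        if mixing not in MIXING_CONVENTIONS:
            raise ValueError(f"unknown mixing convention {mixing!r}")
        self.window = window
        self.mixing = mixing
        self.comp = comp if comp is not None else GLUCOSE_FRAGMENT
        self.baseline = natural_isotope_pattern(self.comp, table=table)

    def excess(self, n: int, p: float) -> tuple[float, float]:
        pat = labeled_pattern(n, p, self.baseline)
        if self.mixing == "tabulated":
            e = excess_enrichments(pat, self.baseline, self.window)
            return e.em1, e.em2
        return excess_numerators(pat, self.baseline, self.window)


def _context(
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    comp: dict[str, int] | None = None,
    mixing: str = "pattern",
) -> _ModelContext:
    return _ModelContext(window, table, comp, mixing)


def pathway_excess(
    gng: GngModel,
    p: float,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    mixing: str = "pattern",
) -> ExcessEnrichments:
    """Excess enrichments of a pure pathway or molecule-level pathway composite."""
    ctx = _context(window, table, mixing=mixing)
    e1 = e2 = 0.0
    for n, w in _as_components(gng):
        a, b = ctx.excess(n, p)
        e1 += w * a
        e2 += w * b
    return ExcessEnrichments(em1=e1, em2=e2)


def pathway_ratio(
    gng: GngModel, p: float, window: str = DEFAULT_WINDOW, table: IsotopeTable | None = None
) -> float:
    """EM2/EM1 of a fully labeled population from one pathway (f = 1)."""
    return pathway_excess(gng, p, window, table).ratio


def mixture_excess(
    f_gng: float,
    p: float,
    n_gng: GngModel = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    mixing: str = "pattern",
) -> ExcessEnrichments:
    """Excess enrichments of the GNG/GGL population mixture at fraction f(GNG).

    Enrichments are linear in the mixing weights, so each EM_x of the mixture
    is the weighted sum of the end-member EM_x values.
    """
    if not 0.0 <= f_gng <= 1.0:
        raise ValueError(f"f_gng={f_gng} outside [0, 1]")
    _check_p(p)
    g = pathway_excess(n_gng, p, window, table, mixing)
    l = pathway_excess(n_ggl, p, window, table, mixing)
    return ExcessEnrichments(
        em1=f_gng * g.em1 + (1.0 - f_gng) * l.em1,
        em2=f_gng * g.em2 + (1.0 - f_gng) * l.em2,
    )


def mixture_ratio(
    f_gng: float,
    p: float,
    n_gng: GngModel = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    mixing: str = "pattern",
) -> float:
    """R = EM2/EM1 of the f(GNG) mixture; strictly increasing in f for p > 0."""
    return mixture_excess(f_gng, p, n_gng, n_ggl, window, table, mixing).ratio


def subpathway_mixture_ratio(
    f_pepck: float,
    p: float,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    mixing: str = "pattern",
) -> float:
    """R of a molecule-level PEPCK (n=7) / glycerol (n=2) GNG mixture at f=1.

    Used in the fasted state, where glycogenolysis is negligible and the
    observable partitions total GNG between its two arms.
    """
    if not 0.0 <= f_pepck <= 1.0:
        raise ValueError(f"f_pepck={f_pepck} outside [0, 1]")
    return pathway_excess(composite_gng(f_pepck), p, window, table, mixing).ratio


def _invert_linear(
    R: float, g: ExcessEnrichments, l: ExcessEnrichments
) -> float:
    """Exact solution of R = (f*g2+(1-f)*l2)/(f*g1+(1-f)*l1) for f."""
    num = l.em2 - R * l.em1
    den = (R * g.em1 - g.em2) + (l.em2 - R * l.em1)
    if den == 0.0:
        raise ZeroDivisionError("degenerate mixture: end-members indistinguishable")
    return num / den


@dataclass(frozen=True)
class InversionResult:
    """f estimate with bookkeeping on range violations."""

    f: float
    f_raw: float
    clamped: bool
    out_of_range: bool
    valid_interval: tuple[float, float]


def invert_fgng(
    R: float,
    p: float,
    n_gng: GngModel = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    slack: float = 0.0,
    mixing: str = "pattern",
) -> InversionResult:
    """Infer f(GNG) from a measured EM2/EM1 ratio at known body-water enrichment.

    R is a ratio of linear forms in f, so the inverse is closed-form and exact;
    monotonicity of R in f guarantees uniqueness.  Ratios outside the model
    range [R(f=0), R(f=1)] are clamped to [0, 1] and flagged; a ``slack``
    (in R units, e.g. 2 x replicate SE) suppresses the out-of-range flag for
    small excursions attributable to noise.
    """
    _check_p(p)
    g = pathway_excess(n_gng, p, window, table, mixing)
    l = pathway_excess(n_ggl, p, window, table, mixing)
    r_lo, r_hi = l.ratio, g.ratio
    f_raw = _invert_linear(R, g, l)
    clamped = not (0.0 <= f_raw <= 1.0)
    f = min(max(f_raw, 0.0), 1.0)
    out = (R < r_lo - slack) or (R > r_hi + slack)
    return InversionResult(f=f, f_raw=f_raw, clamped=clamped, out_of_range=out,
                           valid_interval=(r_lo, r_hi))


def invert_subpathway(
    R: float,
    p: float,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    slack: float = 0.0,
    mixing: str = "pattern",
) -> InversionResult:
    """Infer f(PEPCK->triose-P) from R in the fasted state (f(GNG) ~ 1)."""
    _check_p(p)
    g = pathway_excess(PEPCK_GNG.n, p, window, table, mixing)
    l = pathway_excess(GLYCEROL_GNG.n, p, window, table, mixing)
    r_lo, r_hi = l.ratio, g.ratio
    f_raw = _invert_linear(R, g, l)
    clamped = not (0.0 <= f_raw <= 1.0)
    f = min(max(f_raw, 0.0), 1.0)
    out = (R < r_lo - slack) or (R > r_hi + slack)
    return InversionResult(f=f, f_raw=f_raw, clamped=clamped, out_of_range=out,
                           valid_interval=(r_lo, r_hi))


def generate_table(
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    n_gng: GngModel = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
    mixing: str = "pattern",
) -> pd.DataFrame:
    """Reference table of EM2/EM1 over a grid of p (rows) and f(GNG) (columns).

    Mirrors the published lookup-table layout: rows are body-water enrichments
    in percent, columns are f(GNG) in percent.  ``mixing="tabulated"``
    reproduces the published table's per-population EM weighting to printed
    precision; the default "pattern" convention mixes at the spectrum level
    and is the one consistent with measured mixed populations.
    """
    ctx = _context(window, table, mixing=mixing)
    ggl = [ctx.excess(n_ggl, p) for p in p_grid]
    rows = []
    comps = _as_components(n_gng)
    for i, p in enumerate(p_grid):
        e1l, e2l = ggl[i]
        e1g = sum(w * ctx.excess(n, p)[0] for n, w in comps)
        e2g = sum(w * ctx.excess(n, p)[1] for n, w in comps)
        rows.append(
            [(f * e2g + (1 - f) * e2l) / (f * e1g + (1 - f) * e1l) for f in f_grid]
        )
    df = pd.DataFrame(
        rows,
        index=pd.Index(np.round(np.asarray(p_grid) * 100, 6), name="p_percent"),
        columns=pd.Index(np.round(np.asarray(f_grid) * 100, 6), name="f_gng_percent"),
    )
    return df


def table_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Long-format (p, f, R) version of the reference table."""
    long = df.stack().rename("em2_em1").reset_index()
    return long.sort_values(["p_percent", "f_gng_percent"]).reset_index(drop=True)


def invert_fgng_tabular(
    R: float,
    p: float,
    ref: pd.DataFrame | None = None,
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
) -> float:
    """The paper-and-pencil lookup: bracketing p rows, arithmetic-mean interpolation.

    Takes the arithmetic mean of the two table rows bracketing the measured p
    (accurate in the small 0.5% windows between rows), then interpolates f
    linearly between the bracketing R columns.  Exact recomputation via
    :func:`invert_fgng` is preferred programmatically; this path exists to
    cross-check the tabular procedure.
    """
    if ref is None:
        ref = generate_table(window=window, table=table)
    p_pct = p * 100.0
    prows = ref.index.to_numpy(dtype=float)
    if not (prows.min() - 1e-9 <= p_pct <= prows.max() + 1e-9):
        raise ValueError(f"p={p} outside the table's row range")
    near = np.isclose(prows, p_pct, rtol=0, atol=1e-9)
    if near.any():
        row = ref.iloc[int(np.argmax(near))].to_numpy()
    else:
        hi = int(np.searchsorted(prows, p_pct))
        row = (ref.iloc[hi - 1].to_numpy() + ref.iloc[hi].to_numpy()) / 2.0
    fcols = ref.columns.to_numpy(dtype=float) / 100.0
    # row is strictly increasing in f; clamp outside
    if R <= row[0]:
        return 0.0
    if R >= row[-1]:
        return 1.0
    j = int(np.searchsorted(row, R)) - 1
    frac = (R - row[j]) / (row[j + 1] - row[j])
    return float(fcols[j] + frac * (fcols[j + 1] - fcols[j]))


def equivalent_n(
    R: float,
    p: float,
    fit_sites: Sequence[int] = tuple(range(1, 8)),
    window: str = DEFAULT_WINDOW,
    table: IsotopeTable | None = None,
) -> float:
    """Real-valued homogeneous site count whose pure-population ratio matches R.

    Fits an ordinary-least-squares line of n against R over integer site
    counts (default 1..7) at f = 1 and evaluates it at the given R.  Because a
    pathway mixture is not a homogeneous population, its equivalent n is a
    curvilinear, p-stable summary of the pathway contributions.
    """
    _check_p(p)
    ctx = _context(window, table)
    ns = np.asarray(fit_sites, dtype=float)
    Rs = np.array([ExcessEnrichments(*ctx.excess(int(n), p)).ratio for n in ns])
    r_lo = Rs[0]
    e = ExcessEnrichments(*ctx.excess(8, p))
    r_hi = e.ratio
    if not (r_lo - 1e-12 <= R <= r_hi + 1e-12):
        raise ValueError(
            f"R={R:.6f} outside the calibrated interval [{r_lo:.6f}, {r_hi:.6f}] at p={p}"
        )
    A = np.vstack([Rs, np.ones_like(Rs)]).T
    slope, intercept = np.linalg.lstsq(A, ns, rcond=None)[0]
    return float(slope * R + intercept)
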