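"""Deterministic sensitivity analyses of the f(GNG) model.

Three studies, all closed-form evaluations of the generative model (no random
numbers):

* how much a wrong assumption about the glycerol share of the
  triose-phosphate pool (fixed at one-third when inverting with the n=6
  total-GNG end-member) biases f(GNG);
* how much transaldolase / pentose-phosphate exchange (an extra labelable
  site on part of the population) biases f(GNG);
* the equivalent-n curve of PEPCK/glycerol subpathway mixtures.

Each bias is computed by forward-simulating the perturbed population's
EM2/EM1 and pushing it through the standard inversion.  Because the table's
rows flatten as f(GNG) approaches 1, the inversion magnifies small ratio
perturbations strongly in that region; both error surfaces therefore grow
steeply with f(GNG).  Alternative error conventions (difference against the
unperturbed calculation rather than against truth; perturbing only the
glycogen-derived population in the transaldolase study) are exposed as modes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .isotopes import GLUCOSE_FRAGMENT, IsotopePattern, IsotopeTable, natural_isotope_pattern
from . import mida_core
from .mida_core import (
    GGL,
    TOTAL_GNG,
    composite_gng,
    equivalent_n,
    invert_fgng,
    labeled_pattern,
    mixture_ratio,
    subpathway_mixture_ratio,
)

__all__ = [
    "DEFAULT_SIM_P",
    "glycerol_variation_error",
    "ta_exchange_error",
    "n_equivalence_curve",
]

#: Body-water enrichment of the labeling regime used for the sensitivity
#: studies (bolus + enriched drinking water reaches ~4-5% in mice).
DEFAULT_SIM_P = 0.045


def glycerol_variation_error(
    f_gng_grid: Sequence[float] | None = None,
    g_grid: Sequence[float] | None = None,
    p: float = DEFAULT_SIM_P,
    reference: str = "truth",
    clamp: bool = True,
    window: str = mida_core.DEFAULT_WINDOW,
    isotope_table: IsotopeTable | None = None,
) -> pd.DataFrame:
    """Bias in f(GNG) when the true glycerol->triose-P share deviates from 1/3.

    For each (true f(GNG), true glycerol share g): the labeled population is a
    molecule-level mixture of PEPCK-GNG (n=7, weight 1-g) and glycerol-GNG
    (n=2, weight g), mixed with glycogenolysis (n=1) at the true f(GNG).  Its
    EM2/EM1 is inverted assuming the standard n=6 total-GNG end-member.

    ``reference="truth"`` reports apparent minus true f(GNG) (includes the
    integer-6 approximation residual); ``reference="assumed"`` reports
    apparent minus the value the same inversion returns when g is exactly 1/3
    (isolates the effect of the deviation).  Deltas are in percentage points.
    """
    if f_gng_grid is None:
        f_gng_grid = np.round(np.arange(0.20, 0.801, 0.02), 6)
    if g_grid is None:
        g_grid = np.round(np.linspace(1.0 / 3.0 - 0.10, 1.0 / 3.0 + 0.10, 41), 6)
    if reference not in ("truth", "assumed"):
        raise ValueError(f"unknown reference {reference!r}")
    rows = []
    for g in g_grid:
        gng_true = composite_gng(1.0 - g)
        for f_true in f_gng_grid:
            r_obs = mixture_ratio(f_true, p, n_gng=gng_true, window=window, table=isotope_table)
            inv = invert_fgng(r_obs, p, n_gng=TOTAL_GNG.n, window=window, table=isotope_table)
            f_app = inv.f if clamp else inv.f_raw
            if reference == "truth":
                ref_val = f_true
            else:
                r_base = mixture_ratio(
                    f_true, p, n_gng=composite_gng(2.0 / 3.0), window=window, table=isotope_table
                )
                invb = invert_fgng(r_base, p, n_gng=TOTAL_GNG.n, window=window, table=isotope_table)
                ref_val = invb.f if clamp else invb.f_raw
            rows.append(
                {
                    "g_true": float(g),
                    "f_true": float(f_true),
                    "em2_em1": r_obs,
                    "f_apparent": f_app,
                    "delta_pp": 100.0 * (f_app - ref_val),
                }
            )
    return pd.DataFrame(rows)


def _ta_pattern(
    base_pattern: IsotopePattern,
    f_gng: float,
    p: float,
    t: float,
    scope: str,
    n_gng: int = TOTAL_GNG.n,
    n_ggl: int = GGL.n,
) -> IsotopePattern:
    """Population pattern with an extra labelable site on the exchanged fraction.

    The exchanged molecules pick up one more site (glucose C-5) occupied with
    probability 2p(1-p), the binomial chance of exactly one label over the two
    triose passes.  ``scope="population"`` applies the exchange to a fraction
    t of all glucose; ``scope="ggl"`` to a fraction t of the glycogen-derived
    molecules only (gluconeogenic glucose already carries the C-5 exchange).
    """
    q = 2.0 * p * (1.0 - p)
    bern = IsotopePattern(np.array([1.0 - q, q]))
    gng = labeled_pattern(n_gng, p, base_pattern)
    ggl = labeled_pattern(n_ggl, p, base_pattern)
    if scope == "population":
        mix = IsotopePattern(f_gng * gng.abundances + (1 - f_gng) * ggl.abundances)
        extra = mix.convolve(bern, max_shift=len(mix) - 1)
        return IsotopePattern((1.0 - t) * mix.abundances + t * extra.abundances)
    if scope == "ggl":
        extra = ggl.convolve(bern, max_shift=len(ggl) - 1)
        ggl_t = IsotopePattern((1.0 - t) * ggl.abundances + t * extra.abundances)
        return IsotopePattern(f_gng * gng.abundances + (1 - f_gng) * ggl_t.abundances)
    raise ValueError(f"unknown scope {scope!r}")


def ta_exchange_error(
    f_gng_grid: Sequence[float] | None = None,
    p: float = DEFAULT_SIM_P,
    t_grid: Sequence[float] | None = None,
    scope: str = "population",
    clamp: bool = True,
    window: str = mida_core.DEFAULT_WINDOW,
    isotope_table: IsotopeTable | None = None,
) -> pd.DataFrame:
    """Bias in f(GNG) from transaldolase / pentose-phosphate exchange.

    A fraction t of glucose (t up to ~6%, the literature ceiling for hepatic
    pentose-phosphate diversion) gains an extra labelable site at probability
    2p(1-p); the perturbed ratio is inverted with the standard model and the
    apparent-minus-true f(GNG) is reported in percentage points.  t = 0 gives
    zero error identically.
    """
    if f_gng_grid is None:
        f_gng_grid = np.round(np.arange(0.0, 1.001, 0.02), 6)
    if t_grid is None:
        t_grid = (0.0, 0.02, 0.04, 0.06)
    if any(t < 0 or t > 0.1 for t in t_grid):
        raise ValueError("exchanged fraction t must lie in [0, 0.1]")
    base = natural_isotope_pattern(GLUCOSE_FRAGMENT, table=isotope_table)
    rows = []
    for t in t_grid:
        for f_true in f_gng_grid:
            pat = _ta_pattern(base, float(f_true), p, float(t), scope)
            e = mida_core.excess_enrichments(pat, base, window)
            if not e.ratio_defined:
                continue
            inv = invert_fgng(e.ratio, p, window=window, table=isotope_table)
            f_app = inv.f if clamp else inv.f_raw
            rows.append(
                {
                    "t": float(t),
                    "f_true": float(f_true),
                    "em2_em1": e.ratio,
                    "f_apparent": f_app,
                    "delta_pp": 100.0 * (f_app - float(f_true)),
                }
            )
    return pd.DataFrame(rows)


def n_equivalence_curve(
    p: float = DEFAULT_SIM_P,
    f_pepck_grid: Sequence[float] | None = None,
    window: str = mida_core.DEFAULT_WINDOW,
    isotope_table: IsotopeTable | None = None,
) -> pd.DataFrame:
    """Equivalent homogeneous n across PEPCK/glycerol mixtures.

    Tabulates the mixture EM2/EM1 and the real-valued site count a homogeneous
    population would need to produce it.  The curve runs from n=2 (pure
    glycerol-GNG) to n=7 (pure PEPCK-GNG) and is curvilinear: enrichment-
    weighted mixing pulls the equivalent n toward the more-labeled arm.
    """
    if f_pepck_grid is None:
        f_pepck_grid = np.round(np.arange(0.0, 1.001, 0.02), 6)
    rows = []
    for fp in f_pepck_grid:
        r = subpathway_mixture_ratio(float(fp), p, window=window, table=isotope_table)
        rows.append(
            {
                "f_pepck": float(fp),
                "em2_em1": r,
                "n_equivalent": equivalent_n(r, p, window=window, table=isotope_table),
            }
        )
    return pd.DataFrame(rows)
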