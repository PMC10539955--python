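"""Shared fixtures: calibrated constants, baselines, and the published lookup table."""

import numpy as np
import pytest

from gngmida.isotopes import (
    GLUCOSE_FRAGMENT,
    IsotopeTable,
    calibrate_carbon13,
    natural_isotope_pattern,
)

# Published EM2/EM1 lookup table for the n=6 / n=1 mixture: rows are body-water
# enrichment p in percent (0.5..8 by 0.5), columns f(GNG) in percent (0..100 by 10).
REFERENCE_TABLE_TEXT = """\
0.5 0.173155 0.179123 0.182154 0.183988 0.185218 0.186099 0.186762 0.187279 0.187693 0.188032 0.188315
1 0.173155 0.184984 0.191088 0.194813 0.197324 0.19913 0.200492 0.201556 0.20241 0.203111 0.203696
1.5 0.173155 0.190738 0.199953 0.205626 0.20947 0.212246 0.214346 0.215989 0.21731 0.218395 0.219303
2 0.173155 0.196383 0.208747 0.216424 0.221654 0.225447 0.228323 0.230579 0.232395 0.23389 0.235141
2.5 0.173155 0.20192 0.217466 0.227202 0.233873 0.238729 0.242423 0.245326 0.247669 0.249599 0.251216
3 0.173155 0.207346 0.226106 0.237958 0.246125 0.252093 0.256646 0.260233 0.263133 0.265525 0.267532
3.5 0.173155 0.212663 0.234666 0.248689 0.258406 0.265537 0.270993 0.275301 0.278791 0.281674 0.284096
4 0.173155 0.217869 0.243143 0.25939 0.270714 0.279059 0.285462 0.290532 0.294645 0.298049 0.300913
4.5 0.173155 0.222964 0.251533 0.270059 0.283047 0.292657 0.300055 0.305926 0.310699 0.314655 0.317988
5 0.173155 0.227949 0.259834 0.280692 0.295401 0.30633 0.314771 0.321486 0.326956 0.331497 0.335328
5.5 0.173155 0.232823 0.268043 0.291286 0.307773 0.320076 0.329609 0.337212 0.343418 0.348579 0.352939
6 0.173155 0.237588 0.276159 0.301838 0.320161 0.333894 0.34457 0.353107 0.360089 0.365906 0.370827
6.5 0.173155 0.242242 0.28418 0.312344 0.332562 0.347782 0.359653 0.369171 0.376972 0.383483 0.388999
7 0.173155 0.246787 0.292102 0.322801 0.344973 0.361738 0.374858 0.385406 0.394071 0.401315 0.407461
7.5 0.173155 0.251223 0.299925 0.333206 0.357391 0.37576 0.390185 0.401814 0.411388 0.419407 0.426222
8 0.173155 0.255551 0.307646 0.343557 0.369813 0.389846 0.405633 0.418396 0.428927 0.437765 0.445287
"""

#: Unlabeled baseline EM2/EM1 of the glucose fragment (the table's f=0 column).
BASELINE_RATIO = 0.173155


@pytest.fixture(scope="session")
def reference_table() -> np.ndarray:
    rows = [
        [float(x) for x in line.split()]
        for line in REFERENCE_TABLE_TEXT.strip().splitlines()
    ]
    return np.asarray(rows)


@pytest.fixture(scope="session")
def reference_p_grid(reference_table) -> np.ndarray:
    return reference_table[:, 0] / 100.0


@pytest.fixture(scope="session")
def reference_cells(reference_table) -> np.ndarray:
    return reference_table[:, 1:]


@pytest.fixture(scope="session")
def calibrated_table() -> IsotopeTable:
    return calibrate_carbon13()


@pytest.fixture(scope="session")
def default_baseline():
    return natural_isotope_pattern(GLUCOSE_FRAGMENT)


@pytest.fixture(scope="session")
def calibrated_baseline(calibrated_table):
    return natural_isotope_pattern(GLUCOSE_FRAGMENT, table=calibrated_table)
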