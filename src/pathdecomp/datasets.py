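"""Packaged example data.

The wheat breeding study: 105 observations of three yield components
(y1 panicles per plant, y2 grain number per panicle, y3 1000-grain weight)
against three agronomic traits (x1 biomass per plant, x2 single-stem grass
weight, x3 economic coefficient), supplied as the published 6x6 phenotypic
correlation matrix.
"""

from __future__ import annotations

from importlib import resources

from .io_reporting import load_correlation_csv
from .model_core import CorrelationSystem

__all__ = ["wheat"]

WHEAT_N = 105
WHEAT_X = ("x1", "x2", "x3")
WHEAT_Y = ("y1", "y2", "y3")


def wheat() -> CorrelationSystem:
    """The wheat yield-component correlation system (m = p = 3, n = 105)."""
    path = resources.files("pathdecomp.data") / "wheat_correlations.csv"
    with resources.as_file(path) as fp:
        return load_correlation_csv(fp, WHEAT_N, WHEAT_X, WHEAT_Y)
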