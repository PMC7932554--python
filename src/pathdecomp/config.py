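"""Versioned numerical defaults shared across the package.

Values here are deliberate choices, not magic numbers scattered through the
code; change them in one place and every module follows.
"""

#: Relative positive-definiteness tolerance: smallest eigenvalue of a
#: correlation matrix must exceed this fraction of the largest.
PD_RTOL = 1e-10

#: Absolute symmetry tolerance for input correlation matrices; asymmetry
#: below this is repaired by averaging, above it is an error.
SYM_ATOL = 1e-8

#: Absolute tolerance for diagonal entries differing from 1.
DIAG_ATOL = 1e-8

#: Mismatch between the two determinant routes to v_xy that triggers a
#: numerical warning (block identity vs direct ratio).
VXY_ROUTE_ATOL = 1e-8

#: Condition-number ceiling for Rxx / Ryy inversion inside a fit.
MAX_CONDITION = 1e12

#: Significance levels used for star flagging: "**" below the second,
#: "*" below the first.
ALPHA_STAR = 0.05
ALPHA_DOUBLE_STAR = 0.01

#: Default significance level for decision-coefficient classification.
ALPHA_CLASSIFY = 0.05

#: Gap between tr(B) and the exact generalized determination coefficient
#: 1 - det(I - B) above which reports carry a warning (the trace-based
#: division degrades as correlations approach 1).
TRB_GAP_WARN = 0.05

#: Null-simulation preset: within-block exchangeable correlation used by
#: ``simulate.null_battery`` when constructing a block-diagonal truth with
#: independent X and Y blocks.
NULL_WITHIN_BLOCK_RHO = 0.3

#: Significance levels at which null batteries report rejection rates.
NULL_BATTERY_LEVELS = (0.05, 0.01)
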