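"""Published reference discriminant functions for the Lonicera problem.

The three-class authentication study that motivates this package reports
its final stepwise-LDA model as explicit classification functions over
seven TMS-normalized bucket integrals — V17, V31, V66, V145, V147, V184 and
V186 under the descending variable convention (V186 spans 0.675-0.725 ppm,
the saponin methyl region).  They are shipped here as an importable
coefficient table so new 7-variable bucket vectors can be scored against
the published model.
"""

from __future__ import annotations

import numpy as np

from .lda import LDAModel, model_from_functions

__all__ = [
    "REFERENCE_VARIABLES",
    "REFERENCE_CLASS_ORDER",
    "reference_classification_functions",
]

# coefficient order: V17, V31, V66, V145, V147, V184, V186
REFERENCE_VARIABLES = ["V17", "V31", "V66", "V145", "V147", "V184", "V186"]
REFERENCE_CLASS_ORDER = ["cLJF", "LF", "wLJF"]

_COEFFICIENTS = np.array([
    # cLJF
    [245.678, -321.509, 71.423, 19.730, 176.163, 471.194, -954.988],
    # LF
    [311.308, 1139.664, 472.028, -350.766, -1371.149, 8174.827, -6550.292],
    # wLJF
    [-4229.002, 1114.710, 35.912, 434.342, -452.648, 1229.008, -953.914],
])
_INTERCEPTS = np.array([-10.103, -92.660, -29.427])


def reference_classification_functions() -> LDAModel:
    """The published three-class model as a ready-to-evaluate LDAModel.

    Inputs must be the seven TMS-normalized bucket integrals in
    ``REFERENCE_VARIABLES`` order; output scores follow
    ``REFERENCE_CLASS_ORDER`` (cLJF, LF, wLJF).
    """
    v_indices = [int(v[1:]) - 1 for v in REFERENCE_VARIABLES]  # 0-based V index
    return model_from_functions(
        coefficients=_COEFFICIENTS.copy(),
        intercepts=_INTERCEPTS.copy(),
        class_order=list(REFERENCE_CLASS_ORDER),
        selected_variables=v_indices,
    )
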