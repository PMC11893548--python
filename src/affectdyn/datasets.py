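"""Small built-in reference data."""

from __future__ import annotations

import numpy as np

from .markov import TransitionMatrix

# Transition probabilities reported for a single anorexia-nervosa case,
# re-keyed from the published figure at two decimals (rows A-D = stress,
# engagement, boredom, relaxation).  Row sums are 0.99-1.00 because of the
# printed rounding; kept verbatim so computations reproduce the figure.
_AN_CASE = np.array(
    [
        [0.23, 0.22, 0.26, 0.28],
        [0.23, 0.24, 0.21, 0.32],
        [0.13, 0.58, 0.13, 0.15],
        [0.15, 0.24, 0.42, 0.19],
    ]
)


def example_patient_matrix(renormalize: bool = False) -> TransitionMatrix:
    """The example single-case transition matrix (anorexia-nervosa patient).

    With ``renormalize=False`` (default) the two-decimal printed values are
    returned as-is; with ``renormalize=True`` rows are rescaled to sum
    exactly 1.
    """
    return TransitionMatrix.from_rounded(_AN_CASE.copy(), renormalize=renormalize)
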