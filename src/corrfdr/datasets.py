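"""Small built-in example inputs."""

from __future__ import annotations

import numpy as np

from .procedures import SortedScreenInput

__all__ = ["illustration_example"]

# Eight sorted two-group test p-values and the seven Pearson correlations
# between the consecutively ranked feature columns; the standard worked
# example for comparing the six procedures at alpha = 0.1.
_EXAMPLE_P = (0.0023, 0.0098, 0.0139, 0.0221, 0.0348, 0.0421, 0.0463, 0.0520)
_EXAMPLE_R = (0.1, -0.5, 0.9, 0.7, -0.8, 0.2, 0.9)
_EXAMPLE_ALPHA = 0.1


def illustration_example() -> tuple[SortedScreenInput, float]:
    """Eight-feature worked example: (sorted input, alpha)."""
    inp = SortedScreenInput.from_pvalues(
        np.array(_EXAMPLE_P), np.array(_EXAMPLE_R)
    )
    return inp, _EXAMPLE_ALPHA
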