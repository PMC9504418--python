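"""IRRI standard-evaluation-system (SES) grain-shape classification.

Kernel length in mm determines the size class (medium: 5.0-6.0 inclusive,
long: above 6.0) and the length-to-breadth ratio the shape class (slender:
ratio strictly above 3.0, bold otherwise).  Kernels shorter than 5.0 mm
fall outside the published class table and are reported as out_of_range.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import MetstabError

LABELS = ("medium_slender", "long_slender", "medium_bold", "long_bold", "out_of_range")


@dataclass(frozen=True)
class KernelSpec:
    kernel_length: float  # mm
    lb_ratio: float       # dimensionless length / breadth

    def __post_init__(self):
        for name in ("kernel_length", "lb_ratio"):
            v = getattr(self, name)
            if not (v > 0 and v == v and v != float("inf")):
                raise MetstabError(f"{name} must be positive and finite, got {v}")


def classify_grain(spec: KernelSpec) -> str:
    """Total deterministic map from kernel dimensions to an SES class."""
    if spec.kernel_length < 5.0:
        return "out_of_range"
    size = "medium" if spec.kernel_length <= 6.0 else "long"
    shape = "slender" if spec.lb_ratio > 3.0 else "bold"
    return f"{size}_{shape}"
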