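"""Small deterministic trees used across the test suite."""

from __future__ import annotations

from .config import GeometryConfig
from .geometry import AcinarTree, build_acinus


def fixture_tree(scale: str = "tiny", seed: int = 0) -> AcinarTree:
    """Deterministic reduced trees.

    ``"tiny"``
        one generation-16 duct carrying 2 alveoli;
    ``"single_unit"``
        the TBU 16-18 alone with its standard 84 alveoli;
    ``"full"``
        the default three-unit acinus.
    """
    if scale == "tiny":
        cfg = GeometryConfig(
            seed=seed,
            alveoli_per_generation={16: 2},
        )
        return build_acinus(cfg, units=("SINGLE_16",))
    if scale == "single_unit":
        cfg = GeometryConfig(seed=seed)
        return build_acinus(cfg, units=("TBU_16_18",))
    if scale == "full":
        return build_acinus(GeometryConfig(seed=seed))
    raise ValueError(f"unknown fixture scale {scale!r}")
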