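"""Named generator presets.

* ``binary-rare`` — the binary world at its calibrated rare-outcome
  defaults (unvaccinated prevalence 0.75 %).
* ``continuous-rare`` — the continuous world at its calibrated defaults
  (unvaccinated prevalence 0.34 %).
* ``binary-nonrare`` — the binary world with the outcome intercept raised
  so the unvaccinated prevalence is 10 %: the regime where the
  control-estimated bridge is only exact under the null of no vaccine
  effect.
"""

from __future__ import annotations

import numpy as np

from .simulate import BinaryDGPConfig, ContinuousDGPConfig, _E_UY

__all__ = ["binary_rare", "continuous_rare", "binary_nonrare", "get_preset",
           "PRESET_NAMES"]


def binary_rare(beta0: float = -0.693, n: int = 1_000_000,
                seed: int | None = None) -> BinaryDGPConfig:
    return BinaryDGPConfig(beta0=beta0, n=n, seed=seed)


def binary_nonrare(beta0: float = -0.693, n: int = 1_000_000,
                   seed: int | None = None) -> BinaryDGPConfig:
    # same confounding structure; only the baseline risk is raised to 10 %
    return BinaryDGPConfig(beta0=beta0, n=n, seed=seed,
                           eta_0y=float(np.log(0.10 / (0.85 + 0.15 * _E_UY))))


def continuous_rare(beta0: float = -0.693, n: int = 1_000_000,
                    seed: int | None = None) -> ContinuousDGPConfig:
    return ContinuousDGPConfig(beta0=beta0, n=n, seed=seed)


_PRESETS = {
    "binary-rare": binary_rare,
    "continuous-rare": continuous_rare,
    "binary-nonrare": binary_nonrare,
}
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str, **kw):
    try:
        return _PRESETS[name](**kw)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
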