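"""Pseudo-observed supply series with a known relationship to a prediction.

Field supply observations are daily megalopal counts: strongly overdispersed,
with long runs of zeros punctuated by multi-day pulses.  To exercise the
validation statistics end-to-end with a known truth, this module fabricates an
"observed" series from a predicted one by shifting it a known number of days,
scaling it, and applying overdispersed count noise (a gamma-Poisson mixture,
i.e. negative-binomial-type with variance mu + mu^2/dispersion) plus random
dropout days.  Feeding the pair through preprocessing and cross-correlation
should recover the injected lag (negated, by the lag-sign convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .recruitment import SupplySeries


@dataclass(frozen=True)
class PseudoObsConfig:
    """Known-truth generator settings.

    lag_days shifts the predicted series forward in time (positive: observed
    events happen ``lag_days`` after the predicted ones, so the recovered
    best lag is ``-lag_days``).
    """

    lag_days: int = 2
    scale: float = 1.0
    dispersion: float = 2.0      # NB dispersion k; variance = mu + mu^2/k
    dropout: float = 0.1         # probability a day records zero
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")


def generate_pseudo_observed(predicted: SupplySeries,
                             cfg: PseudoObsConfig | None = None) -> SupplySeries:
    """Fabricate an observed series from a predicted one; seeded, reproducible."""
    cfg = cfg or PseudoObsConfig()
    mu = np.asarray(predicted.counts, float)
    if mu.size == 0:
        raise ParameterError("predicted series is empty")
    if abs(cfg.lag_days) >= mu.size:
        raise ParameterError("lag_days exceeds the series length")
    shifted = np.zeros_like(mu)
    k = cfg.lag_days
    if k >= 0:
        shifted[k:] = mu[:mu.size - k]
    else:
        shifted[:k] = mu[-k:]
    lam = cfg.scale * shifted
    if not cfg.noise:
        return SupplySeries(predicted.dates, lam, predicted.estuary)
    rng = np.random.default_rng(cfg.seed)
    # gamma-Poisson mixture: overdispersed counts where the prediction is > 0
    gam = np.where(lam > 0,
                   rng.gamma(cfg.dispersion, 1.0 / cfg.dispersion, lam.size), 0.0)
    counts = rng.poisson(lam * gam).astype(float)
    if cfg.dropout > 0:
        counts[rng.uniform(size=lam.size) < cfg.dropout] = 0.0
    return SupplySeries(predicted.dates, counts, predicted.estuary)
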