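"""Distance featurization shared by all representation models.

Every edge enters the models through two quantities computed here: a smooth
cosine cutoff envelope phi(d) that takes every edge contribution continuously
to zero at the cutoff radius, and a radial basis expansion of the distance.
The basis family is the exponential-normal one,

    g_k(d) = exp(-beta_k * (exp(-d) - mu_k)^2) * phi(d),

with centers mu_k spaced evenly on [exp(-r_c), 1]; it resolves short
distances more finely than long ones, which matches the shape of interatomic
potentials.  Padded neighbor slots (sentinel -1) are masked to all-zero
feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Parameter

__all__ = ["RadialConfig", "cosine_cutoff", "ExpNormalBasis"]


@dataclass(frozen=True)
class RadialConfig:
    cutoff: float = 4.5
    num_rbf: int = 32
    trainable_rbf: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.num_rbf < 1:
            raise ValueError("num_rbf must be >= 1")


def cosine_cutoff(d: Tensor | np.ndarray, cutoff: float) -> Tensor:
    """phi(d) = (cos(pi d / r_c) + 1) / 2 for d <= r_c, 0 beyond.

    Continuous everywhere with phi(r_c) = 0; the inside/outside selection
    uses the numeric distance values, which is exact because phi and its
    derivative vanish at r_c.
    """
    d = ad.as_tensor(d)
    inside = d.data <= cutoff
    raw = ad.mul(ad.add(ad.tcos(ad.mul(d, np.pi / cutoff)), 1.0), 0.5)
    return ad.mul(raw, ad.constant(inside.astype(d.dtype)))


class ExpNormalBasis(Module):
    """Exponential-normal radial basis with the cutoff envelope built in."""

    def __init__(self, config: RadialConfig):
        self.config = config
        start = np.exp(-config.cutoff)
        means = np.linspace(start, 1.0, config.num_rbf)
        betas = np.full(
            config.num_rbf, (2.0 / config.num_rbf * (1.0 - start)) ** -2
        )
        self.means = Parameter(means, requires_grad=config.trainable_rbf)
        self.betas = Parameter(betas, requires_grad=config.trainable_rbf)

    def __call__(self, d: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        """Expand distances (M,) to features (M, num_rbf).

        ``pad_mask`` marks real slots with True; padded rows come out as
        exact zeros regardless of their stored distance.
        """
        d = ad.as_tensor(d)
        dcol = d.reshape(d.shape + (1,))
        diff = ad.texp(ad.mul(dcol, -1.0)) - self.means
        feats = ad.texp(ad.mul(ad.mul(self.betas, ad.mul(diff, diff)), -1.0))
        env = cosine_cutoff(dcol, self.config.cutoff)
        feats = ad.mul(feats, env)
        if pad_mask is not None:
            feats = ad.mul(
                feats, ad.constant(pad_mask.astype(d.dtype)[:, None])
            )
        return feats
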