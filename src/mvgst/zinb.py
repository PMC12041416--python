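"""Zero-inflated negative binomial (ZINB) decoder and likelihood.

The ZINB mixes a point mass at zero (weight π) with a negative binomial of
mean μ and dispersion θ:

    f(x | π, μ, θ) = π δ0(x) + (1 - π) NB(x | μ, θ)
    NB(x | μ, θ)  = Γ(x+θ) / (Γ(x+1) Γ(θ)) (θ/(θ+μ))^θ (μ/(θ+μ))^x

The decoder maps the fused embedding through one shared hidden layer to
three parallel heads with range-enforcing output transforms (exp for μ,
softplus for θ, logistic for π).  The reconstruction loss is the mean
negative ZINB log-likelihood of the raw highly-variable-gene counts plus a
penalty λ·mean(π²) discouraging the decoder from explaining everything as
structural zeros.

The likelihood functions operate on plain ndarrays or on autodiff tensors;
given ndarrays they return ndarrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ag
from ._autodiff import Tensor

THETA_FLOOR = 1e-4
THETA_CAP = 1e4


def _plain(out: Tensor, *inputs):
    return out if any(isinstance(i, Tensor) for i in inputs) else out.data


def nb_logpmf(x, mu, theta):
    """log NB(x | μ, θ) via log-gamma; stable for large x, μ and θ."""
    xt, mut, tht = map(ag.as_tensor, (x, mu, theta))
    log_t_tm = ag.add(ag.log(tht), ag.mul(ag.log(ag.add(tht, mut)), -1.0))
    log_m_tm = ag.add(ag.log(mut), ag.mul(ag.log(ag.add(tht, mut)), -1.0))
    out = ag.add(
        ag.add(
            ag.add(ag.gammaln(ag.add(xt, tht)), ag.mul(ag.gammaln(tht), -1.0)),
            ag.mul(ag.gammaln(ag.add(xt, 1.0)), -1.0),
        ),
        ag.add(ag.mul(tht, log_t_tm), ag.mul(xt, log_m_tm)),
    )
    return _plain(out, x, mu, theta)


def zinb_logpmf(x, pi, mu, theta):
    """log f_ZINB(x | π, μ, θ); the x = 0 mixture uses log-sum-exp."""
    x_arr = np.asarray(x if not isinstance(x, Tensor) else x.data, dtype=float)
    pit = ag.as_tensor(pi)
    nb = ag.as_tensor(nb_logpmf(x, mu, theta))
    with np.errstate(divide="ignore"):  # log(0) = -inf is the correct limit
        log_1mpi = ag.log(ag.add(1.0, ag.mul(pit, -1.0)))
        nonzero_case = ag.add(log_1mpi, nb)
        zero_case = ag.logaddexp(ag.log(pit), nonzero_case)
    out = ag.where(x_arr == 0, zero_case, nonzero_case)
    return _plain(out, x, pi, mu, theta)


@dataclass
class ZINBParams:
    """Per-entry decoder outputs; all N x M."""

    mu: object  # > 0
    theta: object  # > 0
    pi: object  # in (0, 1)


def zinb_loss(counts, params: ZINBParams, lambda_pi: float = 1.0,
              reduction: str = "mean"):
    """Negative ZINB log-likelihood of raw counts + λ·π² penalty.

    With ``reduction='mean'`` (default) both terms are means over the N x M
    entries, making the loss independent of slide size; 'sum' matches a
    summed likelihood.
    """
    ll = ag.as_tensor(zinb_logpmf(counts, params.pi, params.mu, params.theta))
    pi2 = ag.square(ag.as_tensor(params.pi))
    if reduction == "mean":
        out = ag.add(ag.mul(ag.tmean(ll), -1.0), ag.mul(ag.tmean(pi2), lambda_pi))
    elif reduction == "sum":
        out = ag.add(ag.mul(ag.tsum(ll), -1.0), ag.mul(ag.tsum(pi2), lambda_pi))
    else:
        raise ValueError("reduction must be 'mean' or 'sum'")
    return _plain(out, counts, params.pi, params.mu, params.theta)


class ZINBDecoder:
    """Shared hidden layer (ReLU) feeding three parallel output heads.

    At the zero-parameter origin the transforms give μ = exp(0) = 1,
    θ = softplus(0) + floor and π = σ(0) = 0.5.  θ is floored at 1e-4 and
    capped at 1e4 for numerical stability of the log-gamma terms.
    """

    def __init__(self, d: int, n_genes: int, rng: np.random.Generator,
                 hidden: int = 128):
        self.W_h = ag.glorot(rng, d, hidden)
        self.b_h = Tensor(np.zeros(hidden), requires_grad=True)
        self.W_mu = ag.glorot(rng, hidden, n_genes)
        self.b_mu = Tensor(np.zeros(n_genes), requires_grad=True)
        self.W_theta = ag.glorot(rng, hidden, n_genes)
        self.b_theta = Tensor(np.zeros(n_genes), requires_grad=True)
        self.W_pi = ag.glorot(rng, hidden, n_genes)
        self.b_pi = Tensor(np.zeros(n_genes), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W_h, self.b_h, self.W_mu, self.b_mu,
                self.W_theta, self.b_theta, self.W_pi, self.b_pi]

    def forward(self, H) -> ZINBParams:
        h = ag.relu(ag.add(ag.matmul(ag.as_tensor(H), self.W_h), self.b_h))
        mu = ag.exp(ag.add(ag.matmul(h, self.W_mu), self.b_mu))
        theta = ag.minimum(
            ag.add(ag.softplus(ag.add(ag.matmul(h, self.W_theta), self.b_theta)),
                   THETA_FLOOR),
            THETA_CAP,
        )
        pi = ag.sigmoid(ag.add(ag.matmul(h, self.W_pi), self.b_pi))
        for name, t in (("mu", mu), ("theta", theta), ("pi", pi)):
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite decoder output in {name}")
        return ZINBParams(mu=mu, theta=theta, pi=pi)
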