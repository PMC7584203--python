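"""Theta-neuron network simulator.

The theta neuron is the canonical Type I spiking model: a phase variable on
the circle obeying

    dtheta_i/dt = (1 - cos theta_i) + (1 + cos theta_i) (eta_i + I_i),

which undergoes a SNIC bifurcation as the excitability ``eta_i`` crosses 0 -
negative ``eta`` rests at the stable fixed point ``cos theta* = (1 + eta) /
(1 - eta)``, positive ``eta`` fires periodically at frequency
``sqrt(eta) / pi``.  A neuron is said to fire when its phase crosses pi.

Coupling enters as a pulsatile synaptic current summed over inbound
connections of the adjacency matrix ``A`` (``A[i, j]`` = multiplicity of the
j -> i connection):

    I_i = (kappa / <k>) sum_j A_ij P_n(theta_j),
    P_n(theta) = d_n (1 - cos theta)^n,

with ``d_n = 2^n / C(2n, n)`` normalising the pulse integral to 2 pi for
every sharpness ``n`` (the pulse tends to a delta function as n grows).
Self-loops contribute to a neuron's own input; the formula places no j != i
restriction.

Integration is fixed-step classical RK4 with phases wrapped to [0, 2 pi)
after each full step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError

__all__ = [
    "CauchyParams",
    "ThetaNetwork",
    "ThetaTrajectory",
    "pulse_normalisation",
    "synaptic_currents",
    "integrate_network",
    "sample_cauchy",
    "ring_adjacency",
    "rest_phase",
]


def pulse_normalisation(n_sharp: int) -> float:
    """Closed-form pulse normalisation ``d_n = 2^n / C(2n, n)``.

    Chosen so that ``integral_0^{2 pi} d_n (1 - cos t)^n dt = 2 pi`` for any
    integer sharpness ``n >= 1`` (the integral of ``(1 - cos t)^n`` is
    ``2 pi C(2n, n) / 2^n`` by the binomial expansion of the half-angle
    form ``2^n sin^{2n}(t/2)``).
    """
    if not isinstance(n_sharp, (int, np.integer)) or n_sharp < 1:
        raise ValidationError("pulse sharpness n must be an integer >= 1")
    return float(2**n_sharp / math.comb(2 * n_sharp, n_sharp))


@dataclass(frozen=True)
class CauchyParams:
    """Centre and half-width of the excitability distribution."""

    eta0: float = -2.0
    delta: float = 0.1

    def __post_init__(self):
        if self.delta <= 0:
            raise ValidationError("Cauchy width delta must be positive")


def sample_cauchy(
    params: CauchyParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` iid draws ``eta0 + delta * tan(pi (u - 1/2))``, ``u`` uniform."""
    if n < 1:
        raise ValidationError("need at least one draw")
    u = rng.random(n)
    return params.eta0 + params.delta * np.tan(np.pi * (u - 0.5))


def ring_adjacency(n: int, sparse: bool = True):
    """Neighbour-to-neighbour coupling: node j drives node (j + 1) mod n."""
    if sparse:
        rows = (np.arange(n) + 1) % n
        return sp.csr_matrix(
            (np.ones(n), (rows, np.arange(n))), shape=(n, n), dtype=np.float64
        )
    a = np.zeros((n, n))
    a[(np.arange(n) + 1) % n, np.arange(n)] = 1.0
    return a


@dataclass
class ThetaNetwork:
    """State and parameters of a coupled theta-neuron network."""

    theta: np.ndarray
    eta: np.ndarray
    adjacency: object  # dense ndarray or scipy sparse, A[i, j] = j -> i count
    kappa: float = 3.0
    n_sharp: int = 2

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        n = self.theta.size
        if self.eta.size != n:
            raise ValidationError("theta and eta must have equal length")
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape must match the number of neurons")
        if self.kappa < 0:
            raise ValidationError("coupling strength kappa must be >= 0")
        pulse_normalisation(self.n_sharp)  # validates n_sharp

    @property
    def n_neurons(self) -> int:
        return int(self.theta.size)

    @property
    def mean_degree(self) -> float:
        """<k> = (1/N) sum_ij A_ij."""
        return float(self.adjacency.sum() / self.n_neurons)


def _pulse(theta: np.ndarray, n_sharp: int, d_n: float) -> np.ndarray:
    return d_n * (1.0 - np.cos(theta)) ** n_sharp


def synaptic_currents(net: ThetaNetwork, theta: Optional[np.ndarray] = None) -> np.ndarray:
    """``I_i = (kappa / <k>) sum_j A_ij P_n(theta_j)``; non-negative.

    With ``kappa == 0`` the network is uncoupled and the currents are zero
    regardless of connectivity; otherwise a zero mean degree (no edges at
    all) is rejected.
    """
    if theta is None:
        theta = net.theta
    if net.kappa == 0:
        return np.zeros(theta.size)
    k_mean = net.mean_degree
    if k_mean == 0:
        raise ValidationError("mean degree is zero: no edges to couple through")
    p = _pulse(theta, net.n_sharp, pulse_normalisation(net.n_sharp))
    return (net.kappa / k_mean) * (net.adjacency @ p)


@dataclass
class ThetaTrajectory:
    """Recorded output of :func:`integrate_network`."""

    times: np.ndarray
    order: np.ndarray  # complex Kuramoto order parameter per record
    spike_counts: np.ndarray  # cumulative spikes per record
    spike_times: list = field(default_factory=list, repr=False)
    final_theta: Optional[np.ndarray] = None

    @property
    def coherence(self) -> np.ndarray:
        return np.abs(self.order)

    def steady_state_coherence(self, fraction: float = 0.2) -> float:
        """Mean |R(t)| over the final ``fraction`` of the run."""
        tail = max(1, int(round(self.coherence.size * fraction)))
        return float(self.coherence[-tail:].mean())


def integrate_network(
    net: ThetaNetwork,
    t_end: float = 200.0,
    dt: float = 0.01,
    record_every: int = 1,
    collect_spike_times: bool = False,
) -> ThetaTrajectory:
    """Fixed-step RK4 integration of the coupled phase equations.

    Phases are wrapped to [0, 2 pi) after each step; a spike is an upward
    crossing of pi between consecutive steps (the phase velocity at pi is
    exactly 2, so crossings are always upward), with the spike time linearly
    interpolated.  The complex order parameter and the cumulative spike
    count are recorded every ``record_every`` steps.
    """
    if dt <= 0 or t_end <= 0:
        raise ValidationError("dt and t_end must be positive")
    n_steps = int(round(t_end / dt))
    d_n = pulse_normalisation(net.n_sharp)
    kappa = net.kappa
    eta = net.eta
    adjacency = net.adjacency
    if kappa > 0:
        k_mean = net.mean_degree
        if k_mean == 0:
            raise ValidationError("mean degree is zero: no edges to couple through")
        gain = kappa / k_mean
    else:
        gain = 0.0

    def deriv(theta):
        c = np.cos(theta)
        drive = eta
        if gain:
            drive = eta + gain * (adjacency @ (d_n * (1.0 - c) ** net.n_sharp))
        return (1.0 - c) + (1.0 + c) * drive

    theta = np.mod(net.theta.astype(np.float64).copy(), 2 * np.pi)
    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    order = np.empty(n_rec, dtype=np.complex128)
    spikes = np.empty(n_rec, dtype=np.int64)
    spike_times: list = []
    total_spikes = 0
    rec = 0

    def record(step):
        nonlocal rec
        times[rec] = step * dt
        order[rec] = np.mean(np.exp(1j * theta))
        spikes[rec] = total_spikes
        rec += 1

    record(0)
    for step in range(1, n_steps + 1):
        k1 = deriv(theta)
        k2 = deriv(theta + 0.5 * dt * k1)
        k3 = deriv(theta + 0.5 * dt * k2)
        k4 = deriv(theta + dt * k3)
        new = theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(new)):
            raise ValidationError(
                f"non-finite phase encountered at t={step * dt:.4f}; "
                "reduce dt or check parameters"
            )
        crossed = (theta < np.pi) & (new >= np.pi)
        n_crossed = int(np.count_nonzero(crossed))
        if n_crossed:
            total_spikes += n_crossed
            if collect_spike_times:
                frac = (np.pi - theta[crossed]) / (new[crossed] - theta[crossed])
                for idx, f in zip(np.nonzero(crossed)[0], frac):
                    spike_times.append(((step - 1 + f) * dt, int(idx)))
        theta = np.mod(new, 2 * np.pi)
        if step % record_every == 0:
            record(step)
    return ThetaTrajectory(
        times=times[:rec],
        order=order[:rec],
        spike_counts=spikes[:rec],
        spike_times=spike_times,
        final_theta=theta,
    )


def rest_phase(eta: float) -> float:
    """Stable fixed point of an uncoupled neuron with ``eta < 0``.

    Setting the phase velocity to zero gives ``cos theta* = (1 + eta) /
    (1 - eta)``; the stable branch is the root with negative sine.
    """
    if eta >= 0:
        raise ValidationError("a resting state requires eta < 0")
    return 2 * np.pi - math.acos((1 + eta) / (1 - eta))
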