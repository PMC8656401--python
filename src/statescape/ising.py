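"""Pairwise maximum-entropy (Ising) model over binary brain states.

The model assigns each activation pattern sigma in {0,1}^n the energy

    E(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j

and the Boltzmann probability P(sigma) = exp(-E(sigma)) / Z.  ``h`` captures
per-region activity, the symmetric zero-diagonal matrix ``J`` captures pairwise
interaction.  Note the {0,1} state convention (not the +/-1 spin convention);
:func:`from_spin_parameters` / :func:`to_spin_parameters` convert exactly, up to
an additive energy constant, for cross-checking against spin-convention
references.

Fitting is exact maximum likelihood by full-batch gradient ascent with full
state enumeration, appropriate for the small networks (n <= ~10 regions) this
analysis targets.  The log-likelihood is concave in (h, J), so the optimum is
unique whenever the empirical moments are interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .preprocess import BinaryStateSeries

#: Refuse full 2^n enumeration beyond this many regions.
DEFAULT_ENUMERATION_GUARD = 20


class EnumerationGuardError(ValueError):
    """Raised when a computation would enumerate more than 2^guard states."""


class FitConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to reach the moment-matching tolerance.

    Carries ``last_gap``, the final maximum absolute moment mismatch, so the
    caller can distinguish slow convergence from a boundary pathology (for
    example a region that is never active, which drives h to -infinity).
    """

    def __init__(self, message: str, last_gap: float | None = None):
        super().__init__(message)
        self.last_gap = last_gap


def _check_guard(n: int, guard: int = DEFAULT_ENUMERATION_GUARD) -> None:
    if n > guard:
        raise EnumerationGuardError(
            f"n={n} regions would enumerate 2^{n} states; guard is n <= {guard}"
        )


def states_matrix(n: int, guard: int = DEFAULT_ENUMERATION_GUARD) -> np.ndarray:
    """All 2^n activation patterns as a (2^n, n) {0,1} array.

    Row ``code`` holds the bits of ``code`` with region ``i`` at weight ``2**i``,
    matching the state-encoding convention of :mod:`statescape.preprocess`.
    """
    _check_guard(n, guard)
    codes = np.arange(2**n, dtype=np.int64)
    return ((codes[:, None] >> np.arange(n)) & 1).astype(np.float64)


@dataclass
class IsingModel:
    """Activity terms ``h`` (length n) and symmetric interactions ``J`` (n x n)."""

    h: np.ndarray
    J: np.ndarray
    roi_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        n = self.h.shape[0]
        if self.h.ndim != 1 or self.J.shape != (n, n):
            raise ValueError("h must be length n and J n x n")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValueError("J must have zero diagonal")
        # enforce exactly after the tolerance check
        self.J = (self.J + self.J.T) / 2.0
        np.fill_diagonal(self.J, 0.0)
        if self.roi_names is not None and len(self.roi_names) != n:
            raise ValueError("roi_names length must equal n")

    @property
    def n(self) -> int:
        return self.h.shape[0]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "roi_names": self.roi_names,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsingModel":
        return cls(
            h=np.asarray(d["h"], dtype=float),
            J=np.asarray(d["J"], dtype=float),
            roi_names=d.get("roi_names"),
        )


@dataclass
class EnergyTable:
    """Energy (and optionally probability) of every one of the 2^n states.

    ``kind='model'`` tables come from an :class:`IsingModel` and are finite
    everywhere.  ``kind='empirical'`` tables hold -log p for observed states and
    NaN for unobserved states (their empirical energy is undefined, not
    infinite); the boolean ``observed`` mask flags which is which.
    """

    energies: np.ndarray
    kind: str
    n: int
    probabilities: Optional[np.ndarray] = None
    observed: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.kind not in ("model", "empirical"):
            raise ValueError("kind must be 'model' or 'empirical'")
        if self.energies.shape != (2**self.n,):
            raise ValueError("energies must have length 2^n")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=np.float64)
            if p.shape != (2**self.n,):
                raise ValueError("probabilities must have length 2^n")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("probabilities must be >= 0 and sum to 1 +/- 1e-12")
            self.probabilities = p


@dataclass
class FitReport:
    """Convergence diagnostics for a maximum-likelihood fit."""

    iterations: int
    max_moment_gap: float
    log_likelihood_per_sample: float
    kl_divergence: float


def model_energy(model: IsingModel, codes: Union[int, np.ndarray]) -> Union[float, np.ndarray]:
    """Energy of one state code or an array of codes under the quadratic model."""
    scalar = np.isscalar(codes)
    codes_arr = np.atleast_1d(np.asarray(codes, dtype=np.int64))
    if (codes_arr < 0).any() or (codes_arr >= 2**model.n).any():
        raise ValueError("state code out of range")
    bits = ((codes_arr[:, None] >> np.arange(model.n)) & 1).astype(np.float64)
    e = -bits @ model.h - 0.5 * np.einsum("ti,ij,tj->t", bits, model.J, bits)
    return float(e[0]) if scalar else e


def all_energies(model: IsingModel, guard: int = DEFAULT_ENUMERATION_GUARD) -> np.ndarray:
    """Energies of all 2^n states, ordered by state code."""
    S = states_matrix(model.n, guard)
    return -S @ model.h - 0.5 * np.einsum("ti,ij,tj->t", S, model.J, S)


def boltzmann_distribution(
    model: IsingModel, guard: int = DEFAULT_ENUMERATION_GUARD
) -> EnergyTable:
    """Exact Boltzmann distribution P(sigma) = exp(-E)/Z over all 2^n states.

    Normalization uses log-sum-exp, so arbitrarily shifted energies are safe.
    """
    e = all_energies(model, guard)
    logZ = logsumexp(-e)
    p = np.exp(-e - logZ)
    p = p / p.sum()  # kill residual rounding so sum() == 1 exactly
    return EnergyTable(energies=e, kind="model", n=model.n, probabilities=p)


def empirical_distribution(
    series: BinaryStateSeries, guard: int = DEFAULT_ENUMERATION_GUARD
) -> EnergyTable:
    """Empirical state distribution p(sigma) = n_sigma / T and -log p energies.

    Unobserved states get probability 0 and NaN energy (undefined rather than
    +infinity, to avoid NaN/inf contagion downstream; landscape construction
    always uses model energies).
    """
    _check_guard(series.n, guard)
    counts = np.bincount(series.states, minlength=2**series.n).astype(np.float64)
    T = counts.sum()
    if T < 1:
        raise ValueError("series must contain at least one timepoint")
    p = counts / T
    observed = counts > 0
    energies = np.full(2**series.n, np.nan)
    energies[observed] = -np.log(p[observed])
    return EnergyTable(
        energies=energies,
        kind="empirical",
        n=series.n,
        probabilities=p,
        observed=observed,
        counts=counts,
    )


def _moments(S: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First moments <sigma_i> and second moments <sigma_i sigma_j> under p."""
    m1 = p @ S
    m2 = S.T @ (S * p[:, None])
    return m1, m2


def _coerce_probabilities(data, n_hint: int | None = None) -> tuple[np.ndarray, int]:
    """Accept a BinaryStateSeries, empirical EnergyTable, or probability vector."""
    if isinstance(data, BinaryStateSeries):
        table = empirical_distribution(data)
        return table.probabilities, table.n
    if isinstance(data, EnergyTable):
        if data.probabilities is None:
            raise ValueError("EnergyTable must carry probabilities to be fit")
        return data.probabilities, data.n
    p = np.asarray(data, dtype=np.float64)
    n = int(np.log2(p.shape[0]))
    if 2**n != p.shape[0]:
        raise ValueError("probability vector length must be a power of 2")
    return p, n


def fit_pmem(
    data,
    tol: float = 1e-6,
    max_iter: int = 50_000,
    step: float = 0.2,
    roi_names: Optional[list[str]] = None,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> tuple[IsingModel, FitReport]:
    """Fit (h, J) by exact maximum likelihood (moment matching).

    Full-batch gradient ascent on the per-sample log-likelihood with exact
    gradients dL/dh_i = <sigma_i>_data - <sigma_i>_model and
    dL/dJ_ij = <sigma_i sigma_j>_data - <sigma_i sigma_j>_model, the model
    moments computed by full enumeration.  The step is halved whenever a
    proposed update lowers the likelihood (the objective is concave, so this
    cannot cycle), and gently re-grown afterwards.  Terminates when the largest
    absolute moment mismatch drops below ``tol``.

    Parameters
    ----------
    data
        A :class:`~statescape.preprocess.BinaryStateSeries`, an empirical
        :class:`EnergyTable`, or a length-2^n probability vector.
    tol
        Convergence threshold on the maximum absolute moment gap.
    max_iter
        Iteration budget; exceeding it raises :class:`FitConvergenceError`
        carrying the last gap.
    step
        Initial gradient-ascent step size.

    Returns
    -------
    (IsingModel, FitReport)
    """
    p_data, n = _coerce_probabilities(data)
    _check_guard(n, guard)
    S = states_matrix(n, guard)
    m1_data, m2_data = _moments(S, p_data)

    boundary = (m1_data <= 0.0) | (m1_data >= 1.0)
    if boundary.any():
        idx = np.flatnonzero(boundary)
        raise FitConvergenceError(
            "maximum-likelihood estimate does not exist: region(s) "
            f"{idx.tolist()} are never or always active, so h diverges; "
            "drop or merge the offending region(s)",
            last_gap=float("inf"),
        )

    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        h = np.log(m1_data) - np.log1p(-m1_data)  # logit of marginals
    J = np.zeros((n, n))

    def loglik_and_moments(h, J):
        e = -S @ h - 0.5 * np.einsum("ti,ij,tj->t", S, J, S)
        logZ = logsumexp(-e)
        logP = -e - logZ
        ll = float(p_data @ logP)
        p_model = np.exp(logP)
        m1, m2 = _moments(S, p_model)
        return ll, m1, m2

    ll, m1, m2 = loglik_and_moments(h, J)
    cur_step = step
    iterations = 0
    gap = max(np.abs(m1 - m1_data).max(), np.abs((m2 - m2_data)[off]).max())
    while gap >= tol:
        if iterations >= max_iter:
            raise FitConvergenceError(
                f"no convergence after {max_iter} iterations "
                f"(last moment gap {gap:.3e}); data may sit near the boundary "
                "of the exponential family",
                last_gap=float(gap),
            )
        g_h = m1_data - m1
        g_J = np.where(off, m2_data - m2, 0.0)
        while True:
            h_new = h + cur_step * g_h
            J_new = J + cur_step * g_J
            ll_new, m1_new, m2_new = loglik_and_moments(h_new, J_new)
            if ll_new >= ll or cur_step < 1e-12:
                break
            cur_step /= 2.0
        h, J, ll, m1, m2 = h_new, J_new, ll_new, m1_new, m2_new
        cur_step = min(cur_step * 1.05, 10.0)
        iterations += 1
        gap = max(np.abs(m1 - m1_data).max(), np.abs((m2 - m2_data)[off]).max())

    model = IsingModel(h=h, J=(J + J.T) / 2.0, roi_names=roi_names)
    report = fit_quality(model, p_data, iterations=iterations)
    return model, report


def fit_quality(
    model: IsingModel,
    data,
    iterations: int = 0,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> FitReport:
    """Diagnostics of a model against an empirical distribution.

    Reports KL(p_emp || P_model) with the 0*log 0 = 0 convention, the expected
    per-sample log-likelihood, and the largest absolute moment mismatch.
    """
    p_data, n = _coerce_probabilities(data)
    if n != model.n:
        raise ValueError("model and data have different n")
    S = states_matrix(n, guard)
    e = all_energies(model, guard)
    logZ = logsumexp(-e)
    logP = -e - logZ
    ll = float(p_data @ logP)
    nz = p_data > 0
    kl = float(np.sum(p_data[nz] * (np.log(p_data[nz]) - logP[nz])))
    m1_data, m2_data = _moments(S, p_data)
    m1, m2 = _moments(S, np.exp(logP))
    off = ~np.eye(n, dtype=bool)
    gap = float(max(np.abs(m1 - m1_data).max(), np.abs((m2 - m2_data)[off]).max()))
    return FitReport(
        iterations=iterations,
        max_moment_gap=gap,
        log_likelihood_per_sample=ll,
        kl_divergence=max(kl, 0.0),
    )


def from_spin_parameters(b: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert +/-1-convention parameters (b, K) to {0,1}-convention (h, J).

    With s = 2 sigma - 1, the spin Hamiltonian
    -sum b_i s_i - 1/2 sum_{i!=j} K_ij s_i s_j equals the {0,1} energy with
    J = 4K and h_i = 2 b_i - 2 sum_{j!=i} K_ij, up to a state-independent
    constant (irrelevant to the Boltzmann distribution).
    """
    b = np.asarray(b, dtype=float)
    K = np.asarray(K, dtype=float)
    J = 4.0 * K
    np.fill_diagonal(J, 0.0)
    h = 2.0 * b - 2.0 * (K.sum(axis=1) - np.diag(K))
    return h, J


def to_spin_parameters(h: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`from_spin_parameters` (again up to an energy constant)."""
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    K = J / 4.0
    np.fill_diagonal(K, 0.0)
    b = h / 2.0 + (K.sum(axis=1) - np.diag(K))
    return b, K
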