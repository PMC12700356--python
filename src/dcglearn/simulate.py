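"""Panel simulators for the linear cyclic longitudinal model.

Data-generating process for individual ``i`` at visit ``j``::

    Y_j = mu + sum_{l=0..Ly} B_l Y_{j-l} + sum_{l=0..Lx} A_l X_{j-l} + E_j

with ``B_0`` zero-diagonal and stable, and independent Laplace errors
``e_q ~ Laplace(0, 2*sigma_q)`` realized as a normal scale mixture
(``e | tau ~ N(0, sigma^2/tau)``, ``tau ~ Inverse-Gamma(1, 1/8)``), so
``Var(e_q) = 8*sigma_q^2``.

Two turnkey benchmark scenarios are provided: a four-outcome cyclic graph
with a single instrument (:func:`scenario_one`) and a three-outcome
graph with lag-1 dynamics and three covariates whose effect size is
controlled by a scale ``eta`` (:func:`scenario_two`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from dcglearn.equivalence import InstrumentSpec
from dcglearn.graphs import GraphError, WeightedDigraph, is_stable

__all__ = [
    "DCGParams",
    "PanelData",
    "ScenarioResult",
    "sample_laplace_mixture",
    "simulate_panel",
    "scenario_one",
    "scenario_two",
    "default_visit_counts",
]


@dataclass(frozen=True)
class DCGParams:
    """Parameters of the generative model.

    ``B[l]`` is the Q x Q coefficient matrix at outcome lag ``l`` (target-row
    convention), ``A[l]`` the Q x S covariate matrix at covariate lag ``l``.
    """

    mu: np.ndarray
    B: tuple[np.ndarray, ...]
    A: tuple[np.ndarray, ...] = ()
    sigma2: np.ndarray | None = None

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        B = tuple(np.asarray(b, dtype=float) for b in self.B)
        if not B:
            raise GraphError("at least B0 must be provided")
        Q = B[0].shape[0]
        for b in B:
            if b.shape != (Q, Q):
                raise GraphError("all B matrices must be Q x Q")
        if np.any(np.diagonal(B[0]) != 0.0):
            raise GraphError("B0 must have zero diagonal (no instantaneous self-loops)")
        if not is_stable(B[0]):
            raise GraphError("B0 violates the stability condition")
        A = tuple(np.asarray(a, dtype=float) for a in self.A)
        S = A[0].shape[1] if A else 0
        for a in A:
            if a.shape[0] != Q or a.shape[1] != S:
                raise GraphError("all A matrices must be Q x S")
        if mu.shape != (Q,):
            raise GraphError("mu must have length Q")
        sigma2 = (
            np.full(Q, 1.0) if self.sigma2 is None
            else np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        )
        if sigma2.shape != (Q,) or np.any(sigma2 <= 0):
            raise GraphError("sigma2 must be a strictly positive Q-vector")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "sigma2", sigma2)

    @property
    def Q(self) -> int:
        return self.B[0].shape[0]

    @property
    def S(self) -> int:
        return self.A[0].shape[1] if self.A else 0

    @property
    def Ly(self) -> int:
        return len(self.B) - 1

    @property
    def Lx(self) -> int:
        return len(self.A) - 1 if self.A else 0

    def instantaneous_graph(self, zero_tol: float = 1e-8) -> WeightedDigraph:
        return WeightedDigraph(self.B[0], zero_tol=zero_tol)


class PanelData:
    """Long-format longitudinal panel: one record per individual-visit.

    Visits within an individual are consecutive integers starting at 1 and
    every individual has at least two visits.  Optionally carries the
    latent errors of a simulation run (aligned with the rows).
    """

    def __init__(self, frame: pd.DataFrame, errors: np.ndarray | None = None):
        required = {"id", "visit"}
        if not required <= set(frame.columns):
            raise ValueError(f"panel frame must contain columns {sorted(required)}")
        frame = frame.sort_values(["id", "visit"], kind="mergesort").reset_index(drop=True)
        self.y_columns = sorted(
            (c for c in frame.columns if c.startswith("Y")),
            key=lambda c: int(c[1:]),
        )
        self.x_columns = sorted(
            (c for c in frame.columns if c.startswith("X")),
            key=lambda c: int(c[1:]),
        )
        if not self.y_columns:
            raise ValueError("panel frame must contain at least one Y column")
        for uid, grp in frame.groupby("id", sort=False):
            visits = grp["visit"].to_numpy()
            if len(visits) < 2:
                raise ValueError(f"individual {uid!r} has fewer than 2 visits")
            if not np.array_equal(visits, np.arange(1, len(visits) + 1)):
                raise ValueError(f"individual {uid!r} has non-consecutive visits")
        self.frame = frame
        if errors is not None:
            errors = np.asarray(errors, dtype=float)
            if errors.shape != (len(frame), len(self.y_columns)):
                raise ValueError("errors must align with panel rows")
        self.errors = errors

    @property
    def Q(self) -> int:
        return len(self.y_columns)

    @property
    def S(self) -> int:
        return len(self.x_columns)

    @property
    def n_individuals(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def visit_counts(self) -> dict:
        return self.frame.groupby("id", sort=False).size().to_dict()

    def individual_arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-individual ``(Y, X)`` arrays, shape ``(Ji, Q)`` / ``(Ji, S)``."""
        out = []
        for _, grp in self.frame.groupby("id", sort=False):
            y = grp[self.y_columns].to_numpy(dtype=float)
            x = grp[self.x_columns].to_numpy(dtype=float) if self.x_columns else np.zeros((len(grp), 0))
            out.append((y, x))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelData):
            return NotImplemented
        return self.frame.equals(other.frame)


def sample_laplace_mixture(
    sigma2: float,
    size: int,
    rng: np.random.Generator | int | None = None,
    return_tau: bool = False,
):
    """Draw Laplace errors via the normal scale mixture.

    ``tau ~ Inverse-Gamma(1, 1/8)`` then ``e | tau ~ N(0, sigma2/tau)``;
    marginally ``e ~ Laplace(0, 2*sqrt(sigma2))`` with variance
    ``8*sigma2``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # 1/tau ~ Gamma(1, scale=8) = Exponential(mean 8)
    tau = 1.0 / rng.exponential(8.0, size=size)
    e = rng.normal(0.0, np.sqrt(sigma2 / tau))
    return (e, tau) if return_tau else e


CovariateSampler = Callable[[np.random.Generator, int], np.ndarray]


def _covariate_samplers(spec, S: int) -> list[CovariateSampler]:
    if spec is None:
        spec = ["normal"] * S
    samplers = []
    for item in spec:
        if callable(item):
            samplers.append(item)
        elif item == "normal":
            samplers.append(lambda rng, n: rng.normal(0.0, 1.0, size=n))
        elif isinstance(item, str) and item.startswith("bernoulli"):
            p = float(item.split(":", 1)[1]) if ":" in item else 0.5
            samplers.append(lambda rng, n, p=p: rng.binomial(1, p, size=n).astype(float))
        else:
            raise ValueError(f"unknown covariate spec {item!r}")
    if len(samplers) != S:
        raise ValueError(f"{len(samplers)} covariate samplers for S={S}")
    return samplers


def _resolve_ji(ji_spec, n_individuals: int) -> np.ndarray:
    if np.isscalar(ji_spec):
        counts = np.full(n_individuals, int(ji_spec))
    else:
        counts = np.asarray(ji_spec, dtype=int)
        if counts.shape != (n_individuals,):
            raise ValueError("ji_spec must be a scalar or a length-n_individuals sequence")
    if np.any(counts < 2):
        raise ValueError("every individual needs at least 2 visits")
    return counts


def simulate_panel(
    params: DCGParams,
    n_individuals: int,
    ji_spec,
    seed=None,
    covariate_spec=None,
    burn_in: int = 50,
    init: str = "burnin",
    time_invariant_covariates: bool = False,
    noise_free: bool = False,
) -> PanelData:
    """Simulate a longitudinal panel from the generative model.

    ``init="burnin"`` simulates ``burn_in`` discarded visits per individual
    before the retained ones (approximately stationary start);
    ``init="zero"`` starts every lag buffer at zero with no burn-in.
    ``noise_free=True`` sets every error to exactly zero (deterministic
    dynamics, for exactness tests).
    """
    counts = _resolve_ji(ji_spec, n_individuals)
    if init == "zero":
        burn_in = 0
    elif init != "burnin":
        raise ValueError("init must be 'burnin' or 'zero'")
    Q, S, Ly, Lx = params.Q, params.S, params.Ly, params.Lx
    samplers = _covariate_samplers(covariate_spec, S)
    solve = np.linalg.inv(np.eye(Q) - params.B[0])
    sigma = np.sqrt(params.sigma2)

    child_seeds = np.random.SeedSequence(seed).spawn(n_individuals)
    rows_id, rows_visit = [], []
    ys, xs, errs = [], [], []
    for i in range(n_individuals):
        rng = np.random.default_rng(child_seeds[i])
        total = burn_in + int(counts[i])
        x = np.zeros((total, S))
        for s, sampler in enumerate(samplers):
            if time_invariant_covariates:
                x[:, s] = sampler(rng, 1)[0]
            else:
                x[:, s] = sampler(rng, total)
        if noise_free:
            e = np.zeros((total, Q))
        else:
            tau = 1.0 / rng.exponential(8.0, size=(total, Q))
            e = rng.normal(0.0, 1.0, size=(total, Q)) * sigma * np.sqrt(1.0 / tau)
        y = np.zeros((total, Q))
        for j in range(total):
            c = params.mu + e[j]
            for l in range(1, Ly + 1):
                c = c + params.B[l] @ (y[j - l] if j - l >= 0 else np.zeros(Q))
            for l in range(0, Lx + 1):
                if S:
                    c = c + params.A[l] @ (x[j - l] if j - l >= 0 else np.zeros(S))
            y[j] = solve @ c
        keep = slice(burn_in, total)
        rows_id.extend([i + 1] * int(counts[i]))
        rows_visit.extend(range(1, int(counts[i]) + 1))
        ys.append(y[keep])
        xs.append(x[keep])
        errs.append(e[keep])

    frame = pd.DataFrame({"id": rows_id, "visit": rows_visit})
    Y = np.vstack(ys)
    for q in range(Q):
        frame[f"Y{q + 1}"] = Y[:, q]
    if S:
        X = np.vstack(xs)
        for s in range(S):
            frame[f"X{s + 1}"] = X[:, s]
    return PanelData(frame, errors=np.vstack(errs))


class ScenarioResult(NamedTuple):
    panel: PanelData
    truth: WeightedDigraph
    instruments: InstrumentSpec
    params: DCGParams


def scenario_one_b0() -> np.ndarray:
    """Instantaneous coefficients of the four-outcome benchmark graph."""
    B0 = np.zeros((4, 4))
    B0[0, 2] = -0.95
    B0[1, 0] = 1.05
    B0[2, 1] = 1.0
    B0[2, 3] = 1.0
    B0[3, 0] = -0.1
    return B0


def scenario_one(
    n_individuals: int = 1000,
    instrument_type: str = "covariate",
    seed=None,
    ji: int = 5,
) -> ScenarioResult:
    """Four-outcome cyclic benchmark with a single instrument for Y1.

    ``instrument_type="covariate"`` uses an i.i.d. standard-normal covariate
    (model fitted with ``Ly = Lx = 0``); ``"lag1"`` uses the lag-1 copy of
    Y1 itself (fit with ``Ly = 1``).  Intercepts are zero and
    ``sigma_q^2 = 1/8`` (unit-variance Laplace errors).
    """
    B0 = scenario_one_b0()
    mu = np.zeros(4)
    sigma2 = np.full(4, 1.0 / 8.0)
    if instrument_type == "covariate":
        A0 = np.zeros((4, 1))
        A0[0, 0] = 0.5
        params = DCGParams(mu=mu, B=(B0,), A=(A0,), sigma2=sigma2)
        instruments = InstrumentSpec({0: "X1"})
        panel = simulate_panel(params, n_individuals, ji, seed=seed, init="zero")
    elif instrument_type == "lag1":
        B1 = np.zeros((4, 4))
        B1[0, 0] = 0.5
        params = DCGParams(mu=mu, B=(B0, B1), sigma2=sigma2)
        instruments = InstrumentSpec({0: "Y1[-1]"})
        panel = simulate_panel(params, n_individuals, ji, seed=seed, init="burnin")
    else:
        raise ValueError("instrument_type must be 'covariate' or 'lag1'")
    return ScenarioResult(panel, WeightedDigraph(B0), instruments, params)


def scenario_two_params(eta: float) -> DCGParams:
    if eta <= 0:
        raise ValueError("eta must be strictly positive")
    B0 = np.zeros((3, 3))
    B0[0, 1] = 0.5 * eta
    B0[1, 2] = 0.25 * eta
    B0[2, 0] = 0.1 * eta
    B1 = np.array(
        [
            [0.5 * eta, 0.25 * eta, 0.0],
            [0.0, 0.5 * eta, 0.125 * eta],
            [0.0, 0.0, 0.5 * eta],
        ]
    )
    A0 = np.diag([0.75 * eta, -0.5 * eta, 0.25 * eta])
    return DCGParams(
        mu=np.array([1.0, -1.0, 0.0]),
        B=(B0, B1),
        A=(A0,),
        sigma2=np.full(3, 1.0 / 8.0),
    )


def default_visit_counts(
    n_individuals: int = 200,
    total: int = 3684,
    lo: int = 3,
    hi: int = 46,
    seed: int = 20240901,
) -> np.ndarray:
    """Deterministic synthetic visit-count distribution on ``[lo, hi]``.

    Draws over-dispersed counts and then adjusts them within bounds so they
    sum exactly to ``total``.  Stands in for an empirical cohort visit-count
    distribution that is not publicly available.
    """
    if not n_individuals * lo <= total <= n_individuals * hi:
        raise ValueError(
            f"total {total} infeasible for {n_individuals} individuals in [{lo}, {hi}]"
        )
    rng = np.random.default_rng(seed)
    mean_excess = total / n_individuals - lo
    raw = lo + rng.negative_binomial(3, 3.0 / (3.0 + mean_excess), size=n_individuals)
    counts = np.clip(raw, lo, hi).astype(int)
    diff = total - int(counts.sum())
    step = 1 if diff > 0 else -1
    i = 0
    while diff != 0:
        c = counts[i % n_individuals] + step
        if lo <= c <= hi:
            counts[i % n_individuals] = c
            diff -= step
        i += 1
    return counts


def scenario_two(
    eta: float,
    n_individuals: int = 200,
    ji_spec=None,
    seed=None,
) -> ScenarioResult:
    """Three-outcome benchmark with lag-1 dynamics and three covariates.

    ``X1 ~ Bernoulli(0.6)``, ``X2, X3 ~ N(0, 1)``; intercepts ``(1, -1, 0)``;
    ``sigma_q^2 = 1/8``; true lag orders ``Ly = 1``, ``Lx = 0``.  ``eta``
    scales every causal coefficient.
    """
    params = scenario_two_params(eta)
    if ji_spec is None:
        # scale the benchmark total (3,684 visits for 200 individuals)
        ji_spec = default_visit_counts(
            n_individuals, total=round(3684 * n_individuals / 200)
        )
    panel = simulate_panel(
        params,
        n_individuals,
        ji_spec,
        seed=seed,
        covariate_spec=["bernoulli:0.6", "normal", "normal"],
        init="burnin",
    )
    instruments = InstrumentSpec({0: "X1", 1: "X2", 2: "X3"})
    return ScenarioResult(panel, params.instantaneous_graph(), instruments, params)
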