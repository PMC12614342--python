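"""First-order reaction networks: representation and exact simulation.

The schemes in scope are linear (first-order / pseudo-first-order) reaction
networks on a small number of species — substrates, intermediates, products
and iron-cluster states.  Under O2-saturated, reductant-excess single-turnover
conditions every step of interest is (pseudo-)first order, so the concentration
vector obeys ``dc/dt = K c`` with a constant rate matrix ``K`` and the solution
is a matrix exponential.  Networks are required to be acyclic, which covers
every branching and sequential scheme the analysis uses.

Canonical internal time unit is minutes (assay rate constants are min^-1);
stopped-flow data arrive in seconds and carry their unit explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError, InputError, UnsupportedSchemeError

SPECIES_ROLES = ("substrate", "intermediate", "product", "cluster-state")

#: seconds per minute, used for all unit conversions
_S_PER_MIN = 60.0


def _as_minutes(times: np.ndarray, unit: str) -> np.ndarray:
    if unit == "min":
        return times
    if unit == "s":
        return times / _S_PER_MIN
    raise InputError(f"unknown time unit {unit!r}; expected 's' or 'min'")


@dataclass(frozen=True)
class Species:
    """A chemical species of a kinetic scheme.

    Parameters
    ----------
    name : unique identifier within a scheme.
    role : one of ``substrate``, ``intermediate``, ``product``,
        ``cluster-state``.
    initial_amount : initial concentration (µM) or dimensionless fraction;
        must be non-negative.
    """

    name: str
    role: str = "intermediate"
    initial_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise InputError(f"unknown species role {self.role!r}")
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise InputError(
                f"initial amount of {self.name!r} must be finite and >= 0"
            )


@dataclass(frozen=True)
class FirstOrderReaction:
    """A first-order step ``source -> target`` with rate constant in min^-1."""

    source: str
    target: str
    rate_id: str
    rate_value: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InputError(f"reaction {self.rate_id!r}: source equals target")
        if not np.isfinite(self.rate_value) or self.rate_value <= 0:
            raise InputError(f"rate {self.rate_id!r} must be finite and > 0")


@dataclass
class KineticScheme:
    """An acyclic network of first-order reactions."""

    species: list[Species]
    reactions: list[FirstOrderReaction]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InputError("species names must be unique within a scheme")
        declared = set(names)
        for r in self.reactions:
            for endpoint in (r.source, r.target):
                if endpoint not in declared:
                    raise ConfigurationError(
                        f"reaction {r.rate_id!r} references undeclared "
                        f"species {endpoint!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on the reaction digraph
        succ: dict[str, list[str]] = {s.name: [] for s in self.species}
        indeg = {s.name: 0 for s in self.species}
        for r in self.reactions:
            succ[r.source].append(r.target)
            indeg[r.target] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for m in succ[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        if seen != len(self.species):
            raise UnsupportedSchemeError(
                "reaction graph contains a cycle; only acyclic first-order "
                "networks are supported"
            )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def initial_vector(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix K (min^-1) such that dc/dt = K c."""
        idx = {s.name: i for i, s in enumerate(self.species)}
        k = np.zeros((len(self.species),) * 2)
        for r in self.reactions:
            i, j = idx[r.source], idx[r.target]
            k[i, i] -= r.rate_value
            k[j, i] += r.rate_value
        return k

    def scaled(self, factors: Mapping[str, float]) -> "KineticScheme":
        """Return a copy with rate constants divided by per-``rate_id`` factors.

        Used to apply isotope effects: a factor of ``kie`` slows the step by
        that ratio.  Unlisted rate ids are kept unchanged.
        """
        reactions = [
            FirstOrderReaction(
                r.source, r.target, r.rate_id,
                r.rate_value / factors.get(r.rate_id, 1.0),
            )
            for r in self.reactions
        ]
        return KineticScheme(list(self.species), reactions)


@dataclass
class TimeCourse:
    """Sampled observables on a common time grid.

    ``times`` must be strictly increasing and carries an explicit unit
    ('s' or 'min').  ``observables`` maps a series name (a species, a product,
    or an absorbance channel) to its sampled values.
    """

    times: np.ndarray
    unit: str
    observables: dict[str, np.ndarray]
    replicate_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.unit not in ("s", "min"):
            raise InputError(f"unknown time unit {self.unit!r}")
        if self.times.ndim != 1 or len(self.times) == 0:
            raise InputError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        for name, vals in self.observables.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise InputError(
                    f"series {name!r} length does not match the time grid"
                )
            self.observables[name] = vals

    @property
    def times_min(self) -> np.ndarray:
        """Sample times in minutes regardless of the stored unit."""
        return _as_minutes(self.times, self.unit)

    def to_unit(self, unit: str) -> "TimeCourse":
        if unit == self.unit:
            return self
        if unit == "min":
            times = self.times / _S_PER_MIN if self.unit == "s" else self.times
        elif unit == "s":
            times = self.times * _S_PER_MIN if self.unit == "min" else self.times
        else:
            raise InputError(f"unknown time unit {unit!r}")
        meta = dict(self.meta)
        meta.setdefault("original_unit", self.unit)
        return TimeCourse(times, unit, dict(self.observables),
                          self.replicate_id, meta)


def simulate_scheme(
    scheme: KineticScheme,
    times: Sequence[float],
    unit: str = "min",
) -> TimeCourse:
    """Solve the linear ODE system of ``scheme`` exactly on a time grid.

    Uses eigendecomposition of the rate matrix when it is diagonalizable and
    well conditioned, falling back to a dense matrix exponential per time
    point otherwise (defective matrices arise e.g. for sequential steps with
    equal rate constants).  Total amount is conserved to machine precision.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise InputError("times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise InputError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    t_min = _as_minutes(t, unit)

    k = scheme.rate_matrix()
    c0 = scheme.initial_vector()
    conc = _propagate(k, c0, t_min)
    observables = {name: conc[:, i] for i, name in enumerate(scheme.names)}
    return TimeCourse(t, unit, observables, meta={"kind": "simulation"})


def _propagate(k: np.ndarray, c0: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Evaluate exp(K t) c0 on every t; rows are time points."""
    if len(c0) == 1 or not len(t_min):
        return np.tile(c0, (len(t_min), 1))
    try:
        lam, v = np.linalg.eig(k)
        cond = np.linalg.cond(v)
    except np.linalg.LinAlgError:  # pragma: no cover - eig rarely fails
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        w = np.linalg.solve(v, c0.astype(complex))
        # c(t) = V diag(exp(lam t)) V^-1 c0, evaluated for all times at once
        out = np.real((np.exp(np.outer(t_min, lam)) * w) @ v.T)
    else:
        out = np.vstack([expm(k * ti) @ c0 for ti in t_min])
    return out


def peroxo_fraction_at(
    scheme: KineticScheme,
    times: Sequence[float],
    intermediate: str,
    unit: str = "min",
) -> np.ndarray:
    """Fraction of all cluster states held by ``intermediate`` at each time.

    The scheme must declare ``intermediate`` with role ``cluster-state``; the
    denominator is the summed amount of every cluster-state species, so the
    result lies in [0, 1].
    """
    cluster = [s.name for s in scheme.species if s.role == "cluster-state"]
    if intermediate not in cluster:
        raise ConfigurationError(
            f"{intermediate!r} is not a declared cluster-state of the scheme"
        )
    tc = simulate_scheme(scheme, times, unit=unit)
    total = np.sum([tc.observables[n] for n in cluster], axis=0)
    if np.any(total <= 0):
        raise ConfigurationError("total cluster amount is zero; cannot form a fraction")
    return tc.observables[intermediate] / total
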