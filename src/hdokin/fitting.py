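"""Nonlinear least-squares fitting of the kinetic models to time courses.

Fits use bounded Levenberg-Marquardt / trust-region least squares (via
lmfit) with uniform weighting, heuristic initial guesses, and covariance
based standard errors.  Non-convergence and unidentifiable parameters are
flagged on the returned :class:`FitResult` rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import lmfit

from .errors import InputError
from .models import RiseDecayParams, SingleExpParams, eval_rise_decay, eval_single_exp
from .schemes import TimeCourse


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``params`` / ``param_sd`` are flat name -> value maps; ``param_sd`` holds
    NaN where the covariance was singular.  ``converged`` is False when the
    optimizer failed or the key rate constant was unidentifiable.
    """

    model_id: str
    params: dict[str, float]
    param_sd: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int
    units: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ReplicateSummary:
    """Per-parameter mean and sample SD (n-1 denominator) across replicates."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: int


def _series(tc: TimeCourse, observable: str) -> np.ndarray:
    if observable not in tc.observables:
        raise InputError(f"observable {observable!r} not present in time course")
    y = tc.observables[observable]
    if not np.all(np.isfinite(y)):
        raise InputError(f"observable {observable!r} contains non-finite values")
    return y


def _result_from_lmfit(model_id, out, n_points, units, warnings, key_rates):
    params = {name: float(p.value) for name, p in out.params.items()}
    sds = {
        name: float(p.stderr) if p.stderr is not None else float("nan")
        for name, p in out.params.items()
    }
    converged = bool(out.success)
    for key in key_rates:
        if not np.isfinite(sds.get(key, float("nan"))):
            converged = False
            warnings = warnings + [f"{key} unidentifiable (no standard error)"]
    return FitResult(
        model_id=model_id,
        params=params,
        param_sd=sds,
        residual_norm=float(np.sum(out.residual**2)),
        converged=converged,
        n_points=n_points,
        units=units,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# single-exponential product formation
# ---------------------------------------------------------------------------

def _single_exp_guess(t: np.ndarray, y: np.ndarray) -> SingleExpParams:
    a0 = y[-1]
    a = a0 - y[0]
    # time to half-approach gives k ~ ln2 / t_half; fall back to mid-grid
    target = y[0] + 0.5 * (y[-1] - y[0])
    rising = y >= target if a >= 0 else y <= target
    idx = np.argmax(rising) if np.any(rising) else len(t) // 2
    t_half = t[idx] if t[idx] > 0 else t[max(1, len(t) // 2)]
    k = np.log(2.0) / t_half
    return SingleExpParams(a0=float(a0), a=float(a) if a != 0 else 1e-12,
                           k=float(k) if k > 0 else 1.0)


def fit_single_exponential(
    tc: TimeCourse,
    observable: str,
    init: SingleExpParams | None = None,
) -> FitResult:
    """Fit ``P(t) = A0 - A exp(-k t)`` to one observable of a time course.

    Requires at least four points.  ``k`` is constrained positive.  A flat
    series leaves ``k`` unidentifiable and is returned flagged, not raised.
    """
    t = tc.times_min
    y = _series(tc, observable)
    if len(t) < 4:
        raise InputError("at least 4 time points are required")
    guess = init or _single_exp_guess(t, y)

    model = lmfit.Model(lambda t, a0, a, k: a0 - a * np.exp(-k * t))
    p = model.make_params(a0=guess.a0, a=guess.a, k=max(guess.k, 1e-9))
    p["k"].set(min=1e-12)
    out = model.fit(y, p, t=t)
    units = {"a0": "uM", "a": "uM", "k": "1/min"}
    res = _result_from_lmfit("single_exp", out, len(t), units, [], ["k"])
    res.params.setdefault("k", float("nan"))
    return res


def fit_total_products(
    tc: TimeCourse,
    product_names: Sequence[str],
    init: SingleExpParams | None = None,
) -> FitResult:
    """Sum the product series pointwise and fit the exponential-approach model.

    For parallel first-order branches the total rises with the summed branch
    rate constant, which is what this fit estimates.
    """
    if not product_names:
        raise InputError("product_names must be non-empty")
    total = np.sum([_series(tc, name) for name in product_names], axis=0)
    summed = TimeCourse(tc.times, tc.unit, {"total": total},
                        tc.replicate_id, dict(tc.meta))
    res = fit_single_exponential(summed, "total", init=init)
    res.model_id = "single_exp_total"
    return res


def partition_branch_rates(
    total_fit: "FitResult | float",
    product_amplitudes: Mapping[str, float],
) -> dict[str, float]:
    """Split a total first-order rate constant over parallel product channels.

    Each product's share is its plateau amplitude over the summed amplitudes:
    ``k_i = f_i * k_total``, so the branch constants always sum back to the
    total.
    """
    if isinstance(total_fit, FitResult):
        k_total = total_fit.params["k"]
    else:
        k_total = float(total_fit)
    amps = {name: float(a) for name, a in product_amplitudes.items()}
    if any(a < 0 for a in amps.values()):
        raise InputError("product amplitudes must be >= 0")
    total_amp = sum(amps.values())
    if total_amp <= 0:
        raise InputError("at least one product amplitude must be > 0")
    return {name: (a / total_amp) * k_total for name, a in amps.items()}


# ---------------------------------------------------------------------------
# stopped-flow transient
# ---------------------------------------------------------------------------

def _rise_decay_guess(t: np.ndarray, y: np.ndarray) -> RiseDecayParams:
    ipk = int(np.argmax(y))
    t_pk = t[ipk] if t[ipk] > 0 else t[max(1, len(t) // 4)]
    a0 = y[0]
    amp = y[ipk] - a0
    # decay from the log-linear tail after the peak, if there is one
    k2 = 0.5 / t_pk
    tail = slice(ipk + max(2, (len(t) - ipk) // 4), len(t))
    yt = y[tail] - min(0.0, np.min(y[tail])) if ipk < len(t) - 4 else np.array([])
    if yt.size >= 4 and np.all(yt > 0):
        slope = np.polyfit(t[tail], np.log(yt), 1)[0]
        if slope < 0:
            k2 = -slope
    return RiseDecayParams(a0=float(a0), da=float(0.7 * amp), da2=float(0.3 * amp),
                           k1=5.0 / t_pk, k1p=0.5 / t_pk, k2=float(k2))


def fit_stopped_flow(
    trace: TimeCourse,
    observable: str = "absorbance",
    init: RiseDecayParams | None = None,
) -> FitResult:
    """Fit the two-channel rise / common-decay model to a stopped-flow trace.

    Rate constants are constrained positive and reported with the convention
    ``k1 >= k1p``.  When the second channel amplitude is smaller than twice
    its standard error, the single-channel nested model is refitted and
    returned instead (flagged in ``warnings``).  A monotone trace is flagged
    as decay-unidentifiable.  Rate constants are in the unit of the stored
    time axis (s^-1 for traces recorded in seconds).
    """
    t = np.asarray(trace.times, dtype=float)
    y = _series(trace, observable)
    if len(t) < 20:
        raise InputError("at least 20 points spanning rise and decay are required")
    warnings: list[str] = []
    if int(np.argmax(y)) >= len(y) - 1:
        warnings.append("trace is monotone: decay rate is unidentifiable")
    guess = init or _rise_decay_guess(t, y)

    def run(fix_da2: bool) -> lmfit.model.ModelResult:
        def f(t, a0, da, da2, k1, k1p, k2):
            return eval_rise_decay(
                RiseDecayParams(a0, da, da2, k1, k1p, k2), t
            )

        model = lmfit.Model(f)
        p = model.make_params(
            a0=guess.a0, da=guess.da, da2=0.0 if fix_da2 else guess.da2,
            k1=guess.k1, k1p=guess.k1p, k2=guess.k2,
        )
        for name in ("k1", "k1p", "k2"):
            p[name].set(min=1e-12)
        if fix_da2:
            p["da2"].set(vary=False)
            p["k1p"].set(vary=False)
        return model.fit(y, p, t=t)

    out = run(fix_da2=False)
    unit = "1/s" if trace.unit == "s" else "1/min"
    units = {"a0": "AU", "da": "AU", "da2": "AU",
             "k1": unit, "k1p": unit, "k2": unit}
    res = _result_from_lmfit("rise_decay", out, len(t), units, warnings,
                             ["k1", "k2"])
    # reporting convention: channel 1 is the faster riser
    if res.params["k1p"] > res.params["k1"]:
        for a, b in (("k1", "k1p"), ("da", "da2")):
            res.params[a], res.params[b] = res.params[b], res.params[a]
            res.param_sd[a], res.param_sd[b] = res.param_sd[b], res.param_sd[a]
    da2_sd = res.param_sd.get("da2", float("nan"))
    if (res.converged and np.isfinite(da2_sd)
            and abs(res.params["da2"]) < 2.0 * da2_sd):
        reduced = run(fix_da2=True)
        res = _result_from_lmfit(
            "rise_decay_single", reduced, len(t), units,
            warnings + ["second channel insignificant: single-channel model preferred"],
            ["k1", "k2"],
        )
        res.param_sd["da2"] = 0.0
        res.param_sd["k1p"] = float("nan")
    return res


def normalize_trace(trace: TimeCourse, observable: str = "absorbance") -> TimeCourse:
    """Divide a trace by its maximum so the normalized maximum equals 1."""
    y = _series(trace, observable)
    peak = float(np.max(y))
    if peak <= 0:
        raise InputError("trace maximum must be positive for normalization")
    obs = dict(trace.observables)
    obs[observable] = y / peak
    meta = dict(trace.meta)
    meta["normalized_by"] = peak
    return TimeCourse(trace.times, trace.unit, obs, trace.replicate_id, meta)


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

def replicate_stats(fits: Iterable[FitResult]) -> ReplicateSummary:
    """Per-parameter mean and sample standard deviation over replicate fits.

    All fits must share a model and have converged; at least two are needed
    for an SD (the replicate-triplicate design of the assays).
    """
    fits = [f for f in fits]
    if len({f.model_id for f in fits}) > 1:
        raise InputError("replicate fits mix different models")
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise InputError("at least 2 converged fits are required")
    names = fits[0].params.keys()
    mean = {n: float(np.mean([f.params[n] for f in fits])) for n in names}
    sd = {n: float(np.std([f.params[n] for f in fits], ddof=1)) for n in names}
    return ReplicateSummary(mean=mean, sd=sd, n=len(fits))
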