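"""Simulation and decomposition of Moessbauer quadrupole doublets.

A high-spin iron site in zero/weak applied field shows a symmetric quadrupole
doublet: two equal-area Lorentzian absorption lines centred at
``delta +/- delta_eq / 2``, where ``delta`` is the isomer shift and
``delta_eq`` the quadrupole splitting (both in mm/s).  Spectra of reaction
freeze-quench samples are mixtures of such doublets — here typically the
high-spin Fe(II)2 reactant and the mu-peroxo-Fe(III)2 intermediate — and the
species fractions are the doublet area fractions.

The thin-absorber approximation is used throughout (absorption is a plain
sum of Lorentzians, no transmission-integral saturation), matching how area
fractions are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import InputError

#: default full width at half maximum, mm/s (typical 57Fe linewidth)
DEFAULT_GAMMA = 0.30


def default_grid(vmax: float = 6.0, step: float = 0.01) -> np.ndarray:
    """Symmetric velocity grid, mm/s."""
    n = int(round(2 * vmax / step))
    return np.linspace(-vmax, vmax, n + 1)


@dataclass(frozen=True)
class DoubletParams:
    """A symmetric quadrupole doublet.

    delta : isomer shift (centroid), mm/s
    delta_eq : quadrupole splitting (line separation), mm/s, >= 0
    gamma : FWHM of each Lorentzian line, mm/s, > 0
    area : integrated absorption (fraction of total iron for mixtures);
        may be negative in difference spectra
    """

    delta: float
    delta_eq: float
    gamma: float = DEFAULT_GAMMA
    area: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_eq < 0:
            raise InputError("quadrupole splitting must be >= 0")
        if self.gamma <= 0:
            raise InputError("linewidth must be > 0")


@dataclass
class Spectrum:
    """A velocity spectrum with optional per-point standard deviations."""

    velocities: np.ndarray
    absorption: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if np.any(np.diff(self.velocities) <= 0):
            raise InputError("velocity grid must be strictly increasing")
        if self.absorption.shape != self.velocities.shape:
            raise InputError("absorption length does not match the grid")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.velocities.shape:
                raise InputError("sd length does not match the grid")
            if np.any(self.sd < 0):
                raise InputError("sd must be >= 0")


def _lorentzian(v: np.ndarray, center: float, gamma: float, area: float) -> np.ndarray:
    # unit-area Lorentzian with FWHM gamma, scaled by area
    half = gamma / 2.0
    return area * (half / np.pi) / ((v - center) ** 2 + half**2)


def _doublet_profile(p: DoubletParams, v: np.ndarray) -> np.ndarray:
    lo = p.delta - p.delta_eq / 2.0
    hi = p.delta + p.delta_eq / 2.0
    return _lorentzian(v, lo, p.gamma, p.area / 2.0) + _lorentzian(
        v, hi, p.gamma, p.area / 2.0
    )


def simulate_doublet(p: DoubletParams, grid: np.ndarray | None = None) -> Spectrum:
    """Two equal-area Lorentzian lines at ``delta +/- delta_eq/2``."""
    v = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(v, _doublet_profile(p, v))


def simulate_mixture(
    components: list[DoubletParams], grid: np.ndarray | None = None
) -> Spectrum:
    """Pointwise sum of component doublets; areas must sum to <= 1."""
    if not components:
        raise InputError("at least one component is required")
    total_area = sum(c.area for c in components)
    if total_area > 1.0 + 1e-9:
        raise InputError(f"component areas sum to {total_area:g} > 1")
    v = default_grid() if grid is None else np.asarray(grid, dtype=float)
    absorption = np.sum([_doublet_profile(c, v) for c in components], axis=0)
    return Spectrum(v, absorption)


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a - b; standard deviations combine in quadrature."""
    if a.velocities.shape != b.velocities.shape or not np.allclose(
        a.velocities, b.velocities
    ):
        raise InputError("spectra are on different velocity grids")
    sd = None
    if a.sd is not None or b.sd is not None:
        sa = a.sd if a.sd is not None else np.zeros_like(a.absorption)
        sb = b.sd if b.sd is not None else np.zeros_like(b.absorption)
        sd = np.sqrt(sa**2 + sb**2)
    return Spectrum(a.velocities, a.absorption - b.absorption, sd)


@dataclass
class DoubletFit:
    """Result of a doublet decomposition.

    ``fractions`` are signed component areas normalized by the summed
    absolute area (percent of total iron when all areas are positive).
    ``correlations`` flags near-degenerate parameter pairs (|r| > 0.95).
    """

    components: list[DoubletParams]
    fractions: np.ndarray
    converged: bool
    residual_norm: float
    param_sd: dict[str, float] = field(default_factory=dict)
    correlations: list[tuple[str, str, float]] = field(default_factory=list)


def _init_guess(s: Spectrum, n: int) -> list[DoubletParams]:
    """Heuristic initialization from the line positions of the spectrum.

    Finds the 2n most prominent absorption lines and pairs them nested
    (outermost pair = widest-split doublet), which matches how overlapping
    doublets of distinct species typically interleave.  Falls back to
    moment-based guesses when fewer lines resolve.
    """
    return _candidate_inits(s, n)[0]


def _nested_pairs(lines: np.ndarray, n: int, total: float) -> list[DoubletParams]:
    guesses = []
    for i in range(n):  # nested pairing: i-th with (2n-1-i)-th
        lo, hi = lines[i], lines[2 * n - 1 - i]
        guesses.append(
            DoubletParams(
                delta=(lo + hi) / 2.0,
                delta_eq=max(hi - lo, 0.05),
                gamma=DEFAULT_GAMMA,
                area=total / n,
            )
        )
    return guesses


def _candidate_inits(s: Spectrum, n: int) -> list[list[DoubletParams]]:
    """Candidate initializations: resolved-line pairings, then moment-based."""
    from scipy.signal import find_peaks

    v, y = s.velocities, s.absorption
    ay = np.abs(y)
    peaks, props = find_peaks(ay, prominence=0.05 * float(np.max(ay)))
    total = float(np.trapezoid(ay, v))
    candidates = []
    if len(peaks) >= 2:
        order = peaks[np.argsort(props["prominences"])]
        # pad with duplicates of the most prominent line when doublets overlap
        top = list(order[-min(len(order), 2 * n):])
        while len(top) < 2 * n:
            top.append(order[-1])
        candidates.append(_nested_pairs(np.sort(v[np.array(top)]), n, total))
    weight = ay + 1e-30
    centroid = float(np.sum(v * weight) / np.sum(weight))
    spread = float(np.sqrt(np.sum((v - centroid) ** 2 * weight) / np.sum(weight)))
    spread = max(spread, 0.2)
    candidates.append(
        [
            DoubletParams(delta=centroid + float(off), delta_eq=spread,
                          gamma=DEFAULT_GAMMA, area=total / n)
            for off in (np.linspace(-0.5, 0.5, n) * spread if n > 1 else [0.0])
        ]
    )
    candidates.append(
        [
            DoubletParams(delta=centroid, delta_eq=float(ds) * spread,
                          gamma=DEFAULT_GAMMA, area=total / n)
            for ds in np.linspace(0.5, 2.0, n)
        ]
    )
    return candidates


def fit_doublets(
    s: Spectrum,
    n_components: int,
    init: list[DoubletParams] | None = None,
) -> DoubletFit:
    """Least-squares decomposition into ``n_components`` symmetric doublets.

    Per-point SDs weight the residuals when present.  Areas are left
    unbounded so difference spectra (negative components) fit naturally.
    """
    if n_components not in (1, 2, 3):
        raise InputError("n_components must be 1, 2 or 3")
    if init is not None and len(init) != n_components:
        raise InputError("init must provide one guess per component")
    candidates = [init] if init is not None else _candidate_inits(s, n_components)

    v, y = s.velocities, s.absorption
    weights = None
    if s.sd is not None and np.all(s.sd > 0):
        weights = 1.0 / s.sd
    span = float(v[-1] - v[0])

    def residual(p):
        model = np.sum(
            [
                _doublet_profile(
                    DoubletParams(
                        p[f"delta{i}"].value, p[f"deq{i}"].value,
                        p[f"gamma{i}"].value, p[f"area{i}"].value,
                    ),
                    v,
                )
                for i in range(n_components)
            ],
            axis=0,
        )
        r = model - y
        return r * weights if weights is not None else r

    out = None
    for guesses in candidates:
        params = lmfit.Parameters()
        for i, g in enumerate(guesses):
            params.add(f"delta{i}", value=g.delta, min=v[0], max=v[-1])
            params.add(f"deq{i}", value=min(g.delta_eq, span), min=0.0, max=span)
            params.add(f"gamma{i}", value=g.gamma, min=1e-3, max=span / 2)
            params.add(f"area{i}", value=g.area)
        trial = lmfit.minimize(residual, params, method="leastsq")
        if out is None or np.sum(trial.residual**2) < np.sum(out.residual**2):
            out = trial
    comps = [
        DoubletParams(
            out.params[f"delta{i}"].value,
            out.params[f"deq{i}"].value,
            out.params[f"gamma{i}"].value,
            out.params[f"area{i}"].value,
        )
        for i in range(n_components)
    ]
    # stable reporting order: by isomer shift
    order = np.argsort([c.delta for c in comps])
    comps = [comps[i] for i in order]
    areas = np.array([c.area for c in comps])
    total = np.sum(np.abs(areas))
    fractions = areas / total if total > 0 else np.full_like(areas, np.nan)
    sds = {
        name: float(p.stderr) if p.stderr is not None else float("nan")
        for name, p in out.params.items()
    }
    correlations = []
    for name, p in out.params.items():
        if p.correl:
            for other, r in p.correl.items():
                if name < other and abs(r) > 0.95:
                    correlations.append((name, other, float(r)))
    return DoubletFit(
        components=comps,
        fractions=fractions,
        converged=bool(out.success),
        residual_norm=float(np.sum(np.asarray(out.residual) ** 2)),
        param_sd=sds,
        correlations=correlations,
    )
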