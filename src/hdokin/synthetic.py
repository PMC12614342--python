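"""Synthetic data generators emulating the study's experimental designs.

Every consumer module has an exact inverse-test partner here: noiseless
output round-trips through the corresponding fitter back to the generating
truth.  All randomness flows from the single seed in
:class:`GeneratorConfig`; there is no hidden global state.

The shipped presets encode the study conditions: the four-way branching of
the valine single-turnover reaction, the serial physical-step + abstraction
model with site-specific intrinsic isotope effects for the isotopologue
experiments, log-sampled stopped-flow transients, and two-doublet
freeze-quench spectra driven by a cluster-state kinetic scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .kie import AZI, DH, OH3, OH4, ProductProfile
from .models import RiseDecayParams, eval_rise_decay
from .mossbauer import DoubletParams, Spectrum, default_grid, simulate_mixture
from .schemes import (
    FirstOrderReaction,
    KineticScheme,
    Species,
    TimeCourse,
    simulate_scheme,
)

#: single-turnover quench grid: 5 s, 10 s, 20 s, 30 s, 1, 2, 4 and 10 min
SINGLE_TURNOVER_TIMES_MIN = np.array(
    [5 / 60, 10 / 60, 20 / 60, 0.5, 1.0, 2.0, 4.0, 10.0]
)

ISOTOPOLOGUE_LABELS = ("H", "3-D", "4-D6", "U-D8")


@dataclass
class GeneratorConfig:
    """Noise model and design shared by the generators.

    noise_sd is relative: per observable, the additive Gaussian SD is
    ``noise_sd`` times the dynamic range of the noiseless series (time
    courses), the peak (traces) or the peak absorption (spectra).
    """

    seed: int = 0
    noise_sd: float = 0.05
    replicates: int = 3
    times: np.ndarray | None = None
    unit: str = "min"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# presets — the study conditions
# ---------------------------------------------------------------------------

#: printed branch rate constants of the valine single-turnover reaction, min^-1
LVAL_BRANCH_RATES = {DH: 0.23, AZI: 0.15, OH4: 0.14, OH3: 0.036}

#: initial reactive-complex concentration for synthetic assays, µM
DEFAULT_S0_UM = 100.0


def branching_scheme_lval(s0: float = DEFAULT_S0_UM) -> KineticScheme:
    """Four-way parallel branching of the valine single-turnover reaction."""
    species = [Species("Val", "substrate", s0)] + [
        Species(p, "product", 0.0) for p in LVAL_BRANCH_RATES
    ]
    reactions = [
        FirstOrderReaction("Val", p, f"k_{p}", k)
        for p, k in LVAL_BRANCH_RATES.items()
    ]
    return KineticScheme(species, reactions)


@dataclass(frozen=True)
class IsotopologueTruth:
    """Ground truth of the serial two-step isotopologue model.

    The physical step (isotope-insensitive, rate ``k_phys``) precedes the
    branch between C3-H abstraction (``k3h``) and C4-H abstraction
    (``k4h``).  The C3 radical then partitions between desaturation,
    aziridine closure and C3 hydroxylation with the relative rates in
    ``c3_partition``; only the desaturation channel carries the 4-H+
    transfer and is slowed by ``kie_pcet`` when C4 is deuterated.
    """

    k_phys: float = 1.0 / (1.0 / 0.556 - 1.0 / (3.5 + 1.1))  # min^-1
    k3h: float = 3.5     # min^-1
    k4h: float = 1.1     # min^-1
    kie3: float = 25.0
    kie4: float = 36.0
    kie_pcet: float = 1.3
    #: relative desaturation : aziridine : 3-OH rates of the C3 radical
    c3_partition: tuple[float, float, float] = (0.23, 0.15, 0.036)
    #: overall radical consumption rate (min^-1); fast vs the serial steps
    radical_rate: float = 100.0
    s0: float = DEFAULT_S0_UM

    def site_scalings(self, label: str) -> tuple[float, float, float]:
        """(KIE on k3h, KIE on k4h, KIE on the desaturation channel)."""
        if label == "H":
            return 1.0, 1.0, 1.0
        if label == "3-D":
            return self.kie3, 1.0, 1.0
        if label == "4-D6":
            return 1.0, self.kie4, self.kie_pcet
        if label == "U-D8":
            return self.kie3, self.kie4, self.kie_pcet
        raise InputError(f"unknown isotopologue {label!r}")


def isotopologue_scheme(truth: IsotopologueTruth, label: str) -> KineticScheme:
    """Full first-order scheme for one substrate isotopologue."""
    f3, f4, fp = truth.site_scalings(label)
    r_des, r_azi, r_oh3 = truth.c3_partition
    scale = truth.radical_rate / (r_des + r_azi + r_oh3)
    species = [
        Species("complex", "substrate", truth.s0),
        Species("activated", "intermediate", 0.0),
        Species("C3-radical", "intermediate", 0.0),
        Species(DH, "product", 0.0),
        Species(AZI, "product", 0.0),
        Species(OH3, "product", 0.0),
        Species(OH4, "product", 0.0),
    ]
    reactions = [
        FirstOrderReaction("complex", "activated", "k_phys", truth.k_phys),
        FirstOrderReaction("activated", "C3-radical", "k3H", truth.k3h / f3),
        FirstOrderReaction("activated", OH4, "k4H", truth.k4h / f4),
        FirstOrderReaction("C3-radical", DH, "k_des", scale * r_des / fp),
        FirstOrderReaction("C3-radical", AZI, "k_azi", scale * r_azi),
        FirstOrderReaction("C3-radical", OH3, "k_oh3", scale * r_oh3),
    ]
    return KineticScheme(species, reactions)


def profile_from_truth(truth: IsotopologueTruth, label: str) -> ProductProfile:
    """Exact long-time product pool fractions implied by the truth."""
    f3, f4, fp = truth.site_scalings(label)
    k3, k4 = truth.k3h / f3, truth.k4h / f4
    s3 = k3 / (k3 + k4)
    r_des, r_azi, r_oh3 = truth.c3_partition
    r_des = r_des / fp
    r_tot = r_des + r_azi + r_oh3
    fractions = {
        DH: s3 * r_des / r_tot,
        AZI: s3 * r_azi / r_tot,
        OH3: s3 * r_oh3 / r_tot,
        OH4: 1.0 - s3,
    }
    return ProductProfile(label, fractions, basis="fractions")


def stopped_flow_truth(decay_per_min: float = 0.556) -> RiseDecayParams:
    """Biphasic-rise / monophasic-decay truth for a stopped-flow transient.

    The decay constant is an apparent turnover rate converted to s^-1; the
    rise constants put the peak near 10 s, as in the optical transients of
    the peroxo intermediate.
    """
    return RiseDecayParams(
        a0=0.01, da=0.28, da2=0.12, k1=0.5, k1p=0.08, k2=decay_per_min / 60.0
    )


#: doublet parameters of the two freeze-quench species (areas set per mixture)
PEROXO_DOUBLET = DoubletParams(delta=0.58, delta_eq=1.26)
FE2_DOUBLET = DoubletParams(delta=1.23, delta_eq=2.65)


def peroxo_accumulation_scheme(
    k_form: float = 2.0,
    k_decay: float | None = None,
    active_fraction: float = 0.6,
) -> KineticScheme:
    """Cluster-state scheme for peroxo-intermediate accumulation.

    A fraction of the iron sits in reactive complexes that form the peroxo
    intermediate (``k_form``) which then decays through the slow serial
    turnover (``k_decay``, defaulting to the deuterated apparent rate of the
    isotopologue truth); the remainder stays as unreactive Fe(II).  Amounts
    are dimensionless fractions of total iron.
    """
    if k_decay is None:
        t = IsotopologueTruth()
        k_chem_d = t.k3h / t.kie3 + t.k4h / t.kie4
        k_decay = 1.0 / (1.0 / t.k_phys + 1.0 / k_chem_d)
    if not 0 < active_fraction <= 1:
        raise InputError("active_fraction must be in (0, 1]")
    species = [
        Species("Fe(II)2-active", "cluster-state", active_fraction),
        Species("Fe(II)2-inactive", "cluster-state", 1.0 - active_fraction),
        Species("peroxo", "cluster-state", 0.0),
        Species("decayed", "cluster-state", 0.0),
    ]
    reactions = [
        FirstOrderReaction("Fe(II)2-active", "peroxo", "k_form", k_form),
        FirstOrderReaction("peroxo", "decayed", "k_decay", k_decay),
    ]
    return KineticScheme(species, reactions)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _noisy(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return values + rng.normal(0.0, sd, size=values.shape) if sd > 0 else values.copy()


def gen_single_turnover(
    scheme: KineticScheme, cfg: GeneratorConfig
) -> list[TimeCourse]:
    """Simulate a branching scheme on the quench grid with replicate noise.

    The additive Gaussian SD per observable is ``cfg.noise_sd`` times that
    observable's noiseless dynamic range.
    """
    times = cfg.times if cfg.times is not None else SINGLE_TURNOVER_TIMES_MIN
    clean = simulate_scheme(scheme, times, unit=cfg.unit)
    rng = cfg.rng()
    out = []
    for rep in range(cfg.replicates):
        obs = {}
        for name, vals in clean.observables.items():
            span = float(np.ptp(vals))
            obs[name] = _noisy(vals, cfg.noise_sd * span, rng)
        out.append(
            TimeCourse(clean.times.copy(), cfg.unit, obs, replicate_id=rep,
                       meta={"seed": cfg.seed, "noise_sd": cfg.noise_sd})
        )
    return out


def gen_isotopologue_set(
    truth: IsotopologueTruth, cfg: GeneratorConfig
) -> dict[str, list[TimeCourse]]:
    """Single-turnover time-course sets for the four substrate isotopologues.

    Site-deuterated schemes have the corresponding abstraction (and, for
    4-deuteration, the desaturation PCET channel) slowed by the intrinsic
    isotope effects; the serial physical step applies to all of them.
    """
    out = {}
    for i, label in enumerate(ISOTOPOLOGUE_LABELS):
        sub_cfg = replace(cfg, seed=cfg.seed + 7919 * i)
        scheme = isotopologue_scheme(truth, label)
        tcs = gen_single_turnover(scheme, sub_cfg)
        for tc in tcs:
            tc.meta["isotopologue"] = label
        out[label] = tcs
    return out


def gen_stopped_flow(
    truth: RiseDecayParams,
    cfg: GeneratorConfig,
    n_points: int = 1000,
    t_max_s: float = 1000.0,
    t_min_s: float = 1e-3,
    normalize: bool = False,
) -> TimeCourse:
    """A log-sampled stopped-flow absorbance trace (seconds).

    Defaults follow the acquisition design: 1000 points on a logarithmic
    grid over 1000 s.  Noise SD is ``cfg.noise_sd`` times the peak.
    """
    t = np.geomspace(t_min_s, t_max_s, n_points)
    y = eval_rise_decay(truth, t)
    rng = cfg.rng()
    noisy = _noisy(y, cfg.noise_sd * float(np.max(y)), rng)
    if normalize:
        noisy = noisy / np.max(noisy)
    return TimeCourse(
        t, "s", {"absorbance": noisy},
        meta={"seed": cfg.seed, "noise_sd": cfg.noise_sd, "truth": truth},
    )


def gen_mossbauer(
    components: list[DoubletParams],
    cfg: GeneratorConfig,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """One mixture spectrum with per-point Gaussian noise and recorded SDs."""
    clean = simulate_mixture(components, grid)
    sd = cfg.noise_sd * float(np.max(np.abs(clean.absorption)))
    rng = cfg.rng()
    noisy = _noisy(clean.absorption, sd, rng)
    return Spectrum(clean.velocities, noisy, np.full_like(noisy, sd))


def gen_mossbauer_series(
    scheme: KineticScheme,
    doublet_map: dict[str, DoubletParams],
    times_min: np.ndarray,
    cfg: GeneratorConfig,
    grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """Freeze-quench spectra whose species fractions follow a kinetic scheme.

    ``doublet_map`` assigns a doublet to each spectroscopically visible
    species; unmapped species contribute no absorption.  Species amounts are
    normalized by the total initial amount so doublet areas are iron
    fractions.
    """
    tc = simulate_scheme(scheme, times_min, unit="min")
    total = float(np.sum(scheme.initial_vector()))
    grid = default_grid() if grid is None else grid
    spectra = []
    for i in range(len(times_min)):
        comps = [
            replace(p, area=float(tc.observables[name][i]) / total)
            for name, p in doublet_map.items()
        ]
        sub_cfg = replace(cfg, seed=cfg.seed + 104729 * i)
        spectra.append(gen_mossbauer(comps, sub_cfg, grid))
    return spectra
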