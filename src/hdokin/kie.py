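"""Kinetic isotope effect inference from isotopologue product profiles.

The substrate offers two abstractable sites, C3 and C4.  Desaturation,
aziridine formation and C3-hydroxylation all descend from C3-H abstraction,
while C4-hydroxylation descends from C4-H abstraction, so the product profile
partitions the total flux between the two sites.  Deuterating one site slows
only that site's abstraction, shifting the branching ratio; because every
step preceding the branch point is common to both channels, the ratio shift
measures the *intrinsic* isotope effect directly (intramolecular
competition), unattenuated by slow physical steps.

The apparent isotope effect of the whole turnover is, in contrast, damped by
any isotope-insensitive step in series with the chemistry.  This module
commits to the steady-state harmonic composition of a physical step and the
abstraction step, ``1/k_app = 1/k_phys + 1/k_chem``, and solves it for the
site-resolved abstraction rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InfeasibleError, InputError

ISOTOPOLOGUES = ("H", "3-D", "4-D6", "U-D8")

#: canonical product names for the branching chemistry
DH = "3,4-dh-Val"     # desaturation product
AZI = "Azi"           # aziridine product
OH3 = "3-OH-Val"      # C3 hydroxylation
OH4 = "4-OH-Val"      # C4 hydroxylation


@dataclass
class ProductProfile:
    """Per-product branch rates (min^-1) or pool fractions for one isotopologue."""

    isotopologue: str
    per_product: dict[str, float]
    basis: str = "rates"  # "rates" or "fractions"

    def __post_init__(self) -> None:
        if self.isotopologue not in ISOTOPOLOGUES:
            raise InputError(f"unknown isotopologue {self.isotopologue!r}")
        if self.basis not in ("rates", "fractions"):
            raise InputError("basis must be 'rates' or 'fractions'")
        vals = np.array(list(self.per_product.values()), dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InputError("profile values must be finite and >= 0")
        if self.basis == "fractions" and abs(vals.sum() - 1.0) > 1e-9:
            raise InputError("fractions must sum to 1")


@dataclass
class SiteMap:
    """Maps each product to its abstraction site (C3 or C4)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if any(site not in ("C3", "C4") for site in self.mapping.values()):
            raise InputError("sites must be 'C3' or 'C4'")

    def site_of(self, product: str) -> str:
        if product not in self.mapping:
            raise InputError(f"product {product!r} has no site assignment")
        return self.mapping[product]


def default_site_map() -> SiteMap:
    """Site assignment for the valine chemistry: C3 feeds desaturation,
    aziridine and 3-OH; C4 feeds 4-OH (overoxidation products fold into
    their precursor channel)."""
    return SiteMap({DH: "C3", AZI: "C3", OH3: "C3", OH4: "C4"})


@dataclass
class KIEResult:
    """A single kinetic isotope effect with its provenance."""

    site: str                # "C3", "C4", "PCET-4H" or "apparent"
    value: float
    method: str              # "intramolecular", "decay-rate" or "product-rate"
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise InputError("KIE value must be finite and > 0")


@dataclass
class TwoStepSolution:
    """Resolved rate constants of the serial physical + abstraction model."""

    k_phys: float  # min^-1, isotope-insensitive physical step
    k3h: float     # min^-1, C3-H abstraction
    k4h: float     # min^-1, C4-H abstraction

    def __post_init__(self) -> None:
        for name in ("k_phys", "k3h", "k4h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"{name} must be finite and > 0")

    @property
    def k_chem(self) -> float:
        return self.k3h + self.k4h

    def apparent_rate(self, kie3: float = 1.0, kie4: float = 1.0) -> float:
        """Forward model: apparent rate with the chemistry optionally slowed
        by site-specific isotope effects."""
        k_chem = self.k3h / kie3 + self.k4h / kie4
        return 1.0 / (1.0 / self.k_phys + 1.0 / k_chem)


@dataclass
class CouplingEfficiency:
    """Product yield per intermediate decayed, protiated vs deuterated."""

    ce_h: float
    ce_d: float
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ce_h <= 0 or self.ce_d <= 0:
            raise InputError("coupling efficiencies must be > 0")
        self.ratio = self.ce_h / self.ce_d


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def site_flux_ratio(profile: ProductProfile, sitemap: SiteMap | None = None) -> float:
    """Ratio of C3-channel to C4-channel flux, r = flux(C3)/flux(C4).

    Basis-independent: rates and the fractions they imply give the same r.
    """
    sitemap = sitemap or default_site_map()
    c3 = sum(v for p, v in profile.per_product.items() if sitemap.site_of(p) == "C3")
    c4 = sum(v for p, v in profile.per_product.items() if sitemap.site_of(p) == "C4")
    if c3 == 0 and c4 == 0:
        raise InputError("profile carries no flux at either site")
    if c4 == 0:
        raise InputError("C4 flux is zero: site ratio is infinite")
    return c3 / c4


def intrinsic_kie(r_unlabeled: float, r_site_labeled: float, site: str) -> KIEResult:
    """Intrinsic abstraction KIE from the shift in the site flux ratio.

    Deuterating C3 divides only the C3 flux by the KIE, so
    ``KIE_C3 = r_H / r_[3-D]``; deuterating C4 divides the C4 flux, so
    ``KIE_C4 = r_[4-D6] / r_H``.  Exact under the branching model because the
    competition cancels every common preceding step.
    """
    if r_unlabeled <= 0 or r_site_labeled <= 0:
        raise InputError("flux ratios must be > 0")
    if site == "C3":
        value = r_unlabeled / r_site_labeled
    elif site == "C4":
        value = r_site_labeled / r_unlabeled
    else:
        raise InputError("site must be 'C3' or 'C4'")
    return KIEResult(site=site, value=value, method="intramolecular")


def apparent_kie(k_h: float, k_d: float, method: str = "product-rate") -> KIEResult:
    """Apparent KIE as the ratio of observed rate constants, k_H / k_D."""
    if k_h <= 0 or k_d <= 0:
        raise InputError("rate constants must be > 0")
    if method not in ("decay-rate", "product-rate"):
        raise InputError("method must be 'decay-rate' or 'product-rate'")
    return KIEResult(site="apparent", value=k_h / k_d, method=method)


def pcet_kie(dh_over_azi_h: float, dh_over_azi_4d6: float) -> KIEResult:
    """KIE of the proton(4-H+)-coupled electron transfer of desaturation.

    After C3-H abstraction the carbon radical partitions between desaturation
    (which removes a 4-H+) and aziridine closure (which does not).  Both
    descend from the same radical, so the desaturation/aziridine ratio shift
    on 4-deuteration isolates the 4-H+ transfer KIE:
    ``KIE = (dh/Azi)_H / (dh/Azi)_[4-D6]``.  The C3-hydroxylation channel is
    excluded (common-factor cancellation makes the ratio insensitive to it).
    """
    if dh_over_azi_h <= 0 or dh_over_azi_4d6 <= 0:
        raise InputError("partition ratios must be > 0")
    return KIEResult(site="PCET-4H", value=dh_over_azi_h / dh_over_azi_4d6,
                     method="intramolecular")


def coupling_ratio(
    products_h: float, decayed_h: float,
    products_d: float, decayed_d: float,
) -> CouplingEfficiency:
    """Coupling efficiency (product formed per intermediate decayed) for the
    protiated and deuterated reactions, and their ratio CE_H/CE_D."""
    for name, v in (("products_h", products_h), ("decayed_h", decayed_h),
                    ("products_d", products_d), ("decayed_d", decayed_d)):
        if v <= 0:
            raise InputError(f"{name} must be > 0")
    return CouplingEfficiency(ce_h=products_h / decayed_h,
                              ce_d=products_d / decayed_d)


def solve_serial_two_step(
    k_app_h: float,
    k_app_d: float,
    r_h: float,
    kie3: float,
    kie4: float,
) -> TwoStepSolution:
    """Resolve (k_phys, k3H, k4H) from apparent rates, flux ratio and KIEs.

    Solves the three-equation system

    * ``1/k_app_H = 1/k_phys + 1/(k3H + k4H)``
    * ``1/k_app_D = 1/k_phys + 1/(k3H/KIE3 + k4H/KIE4)``
    * ``k3H / k4H = r_H``

    in closed form.  The isotope-insensitive physical step drops out of the
    difference of the first two equations, which fixes the chemistry; the
    remainder fixes k_phys.  Raises :class:`InfeasibleError` with a
    diagnostic when no positive solution exists (degenerate KIEs, or an
    implied non-positive k_phys).
    """
    if k_app_h <= 0 or k_app_d <= 0:
        raise InputError("apparent rate constants must be > 0")
    if r_h <= 0:
        raise InputError("flux ratio r_H must be > 0")
    if kie3 <= 0 or kie4 <= 0:
        raise InputError("KIEs must be > 0")
    if k_app_h <= k_app_d:
        raise InfeasibleError(
            "k_app_H must exceed k_app_D for a normal isotope effect; "
            f"got {k_app_h} <= {k_app_d}"
        )
    # chemistry slow-down factor implied by the KIEs at the observed branching
    rho = (1.0 + r_h) / (r_h / kie3 + 1.0 / kie4)
    if abs(rho - 1.0) < 1e-12:
        raise InfeasibleError(
            "degenerate system: KIEs imply no isotopic slow-down of the "
            "chemistry (rho = 1), so the equations are underdetermined"
        )
    inv_chem_h = (1.0 / k_app_h - 1.0 / k_app_d) / (1.0 - rho)
    if inv_chem_h <= 0:
        raise InfeasibleError(
            f"implied chemistry rate is non-positive (1/k_chem = {inv_chem_h:g})"
        )
    k_chem_h = 1.0 / inv_chem_h
    inv_phys = 1.0 / k_app_h - inv_chem_h
    if inv_phys <= 0:
        raise InfeasibleError(
            "implied physical step rate is non-positive "
            f"(1/k_phys = {inv_phys:g}); the apparent rates are inconsistent "
            "with the serial model at these KIEs"
        )
    k_phys = 1.0 / inv_phys
    k4h = k_chem_h / (1.0 + r_h)
    k3h = k_chem_h - k4h
    return TwoStepSolution(k_phys=k_phys, k3h=k3h, k4h=k4h)


def bootstrap_kie_sd(
    estimator,
    observed: Mapping[str, float],
    sds: Mapping[str, float],
    n_resamples: int = 200,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SD of a KIE estimator.

    ``estimator`` maps a dict of observables to a KIE value; each observable
    is resampled from a normal with its replicate SD.  Non-positive draws and
    estimator failures are discarded.
    """
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_resamples):
        draw = {k: rng.normal(v, sds.get(k, 0.0)) for k, v in observed.items()}
        if any(v <= 0 for v in draw.values()):
            continue
        try:
            values.append(estimator(draw))
        except (InputError, InfeasibleError):
            continue
    if len(values) < 2:
        raise InputError("too few successful bootstrap resamples")
    return float(np.std(values, ddof=1))
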