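# hdokin

Kinetic and spectroscopic analysis for diiron enzymes of the
haem-oxygenase-like dimetal oxidase/oxygenase (HDO) superfamily — the class
of O₂-activating enzymes that accumulate a μ-peroxo-Fe(III)₂ intermediate
and abstract hydrogen from unactivated C–H bonds, as in the enzymatic
construction of azetidine amino acids from L-valine and L-isoleucine.

The package is for mechanistic enzymologists who need to turn
single-turnover product time courses, stopped-flow transients and
freeze-quench Mössbauer spectra into rate constants, kinetic isotope
effects (KIEs) and intermediate fractions — reproducibly, with a seeded
synthetic-data generator standing in for instrument output so every
analysis step is testable end to end.

## What it computes

**Branching single-turnover kinetics.** Product formation follows the
exponential approach

```
P(t) = A0 − A·exp(−k·t)                                   (single product)
```

For parallel first-order channels every product rises with the *total*
rate constant k_tot = Σkᵢ; the individual branch constants follow from the
amplitude fractions, kᵢ = (Aᵢ/ΣAⱼ)·k_tot.

**Stopped-flow transients.** The optically detected intermediate shows a
biphasic rise and a monophasic decay,

```
A(t) = A0 + ΔA·k1/(k2−k1)·(e^(−k1·t) − e^(−k2·t))
          + ΔA′·k1′/(k2−k1′)·(e^(−k1′·t) − e^(−k2·t))
```

with the analytic degenerate limit ΔA·k·t·e^(−k·t) used when k2 ≈ kᵢ.

**Kinetic isotope effects.** Intrinsic KIEs come from intramolecular
competition: deuterating one of the two abstractable sites (C3 or C4)
shifts the product branching ratio r = flux(C3)/flux(C4) by exactly the
site KIE, independent of any slow preceding step. Apparent KIEs are ratios
of observed rate constants and are damped by the isotope-insensitive
physical step; the serial model

```
1/k_app = 1/k_phys + 1/(k_3H + k_4H)
```

is solved in closed form for (k_phys, k_3H, k_4H) from the protiated and
perdeuterated apparent rates, the branching ratio and the intrinsic KIEs.
The PCET (proton-coupled electron transfer) KIE of the desaturation step is
extracted from the desaturation/aziridine partition shift on C4
deuteration.

**Mössbauer doublets.** Spectra are simulated and decomposed as mixtures
of symmetric quadrupole doublets — two equal-area Lorentzian lines at
δ ± ΔE_Q/2 with FWHM Γ — with per-point SD weighting; species fractions
are doublet area fractions.

## Worked example

```python
import numpy as np
from hdokin import (fit_total_products, fit_single_exponential,
                    partition_branch_rates, replicate_stats)
from hdokin.synthetic import (GeneratorConfig, branching_scheme_lval,
                              gen_single_turnover)
from hdokin.kie import DH, AZI, OH3, OH4

products = [DH, AZI, OH3, OH4]
cfg = GeneratorConfig(seed=1, noise_sd=0.05, replicates=3)
tcs = gen_single_turnover(branching_scheme_lval(), cfg)

total = replicate_stats([fit_total_products(tc, products) for tc in tcs])
print(f"k_total = {total.mean['k']:.3f} +/- {total.sd['k']:.3f} 1/min")

amps = {p: np.mean([fit_single_exponential(tc, p).params["a0"] for tc in tcs])
        for p in products}
for p, k in partition_branch_rates(total.mean["k"], amps).items():
    print(f"  k[{p}] = {k:.3f} 1/min")
```

prints

```
k_total = 0.567 +/- 0.015 1/min
  k[3,4-dh-Val] = 0.231 1/min
  k[Azi] = 0.156 1/min
  k[3-OH-Val] = 0.037 1/min
  k[4-OH-Val] = 0.143 1/min
```

Three replicates of an eight-point quench series (5 s–10 min) with 5%
noise were generated from the branching scheme whose true constants are
0.230, 0.150, 0.036 and 0.140 min⁻¹; the total rate is the sum of the
branches and the partition recovers each branch constant from its
amplitude share.

A command-line front end exposes the same operations
(`hdokin simulate | fit-timecourse | fit-stoppedflow | kie | solve-twostep |
mossbauer | make-synthetic | run`); `hdokin run` executes the whole
pipeline and writes traceable CSV reports.

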