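# nmshield

Broad-beam radiation-shielding calculations for nuclear medicine, covering
the radionuclides that dominate current diagnostic and theranostic practice:
**Tc-99m, F-18, I-131 and Lu-177**, against lead, gypsum wallboard, light-
and normal-weight concrete, A514 steel and glass.

Hospital nuclear medicine departments must now design and verify shielding
the way x-ray facilities long have, and the growth of Lu-177 therapies
(DOTATATE, PSMA) makes wall-by-wall barrier calculations routine work for
medical physicists.  Unlike a collimated x-ray beam, a patient is an
uncollimated photon source: the dose behind a wall includes radiation
scattered back toward the point of concern, so transmission follows a
*broad-beam* law `T = B·exp(-μx)` with buildup factor `B ≥ 1` rather than
the narrow-beam exponential.

## What the package provides

* **Archer transmission model** (`nmshield.archer`) — the three-parameter
  broad-beam form

  `T(x) = [(1 + β/α)·e^{αγx} − β/α]^{−1/γ}`,

  its closed-form inverse `x(T)`, and fractional value layers
  (HVL/QVL/TVL/CVL/MVL = thicknesses transmitting 1/2, 1/4, 1/10, 1/100,
  1/1000), driven by a shipped table of fitted (α, β, γ) per
  nuclide/material pair (thicknesses in mm).
* **Barrier solver** (`nmshield.dose`) — weekly workload W (mCi·h/week) →
  unshielded dose `D = W·Γ·f/d²` → required transmission `T = P/(O·D)`
  under a weekly limit P and occupancy factor O → required thickness.
  Ships the nuclide constants (Γ, f-factor, half-lives, photon lines) and
  an NCRP-147-style occupancy table.
* **Curve fitting** (`nmshield.fitting`) — least squares on ln T with
  multi-start initialization, synthetic noisy-curve generation, and
  curve-space fit comparison.
* **Monte Carlo simulator** (`nmshield.mc`) — analog photon transport
  (Klein-Nishina scattering, photoelectric absorption, kerma approximation)
  in the source–barrier–tissue slab geometry, with a narrow-beam oracle
  mode, buildup-factor extraction, and a ceiling/floor scatter variant.
  Its cross sections are a synthetic parametric library (see
  `docs/methods.md`); it supports consistency and trend studies, not
  reference dosimetry.
* **CLI** (`nmshield`) — verbs `solve`, `dose`, `transmission`, `vlayers`,
  `fit`, `simulate`, `dump-tables`.

## Worked example

A Lu-177 DOTATATE room: five patients a week, 200 mCi (7.4 GBq) each,
4 hours in the room, so `W = 4000 mCi·h/week` ignoring decay.  An office
sits behind a wall; the total source-to-person distance is 2.40 m, and the
design goal is the US public limit of 20 µGy/week.  The packaged scenario
reproduces this:

```sh
nmshield solve src/nmshield/examples/lu177_office.yaml
```

prints (abridged):

```
Calculation chain:
  W (weekly workload) = 4000 mCi*h/week
  Gamma (exposure-rate constant at 1 cm) = 0.181 R*cm^2/(mCi*h)
  f (exposure-to-dose factor) = 0.957 cGy/R
  d (source to point of concern) = 240 cm
  D (unshielded weekly dose) = 120.29 uGy/week
  P (weekly design limit) = 20 uGy/week
  O (occupancy factor) = 1
Required transmission T = 0.1663
Required lead thickness x = 1.48 mm
```

Reading: 4000 mCi·h/week at 2.4 m deposits 120.3 µGy/week unshielded;
meeting 20 µGy/week needs a transmission of 20/120.3 = 0.166, which the
inverse Archer model for Lu-177/lead converts to **1.48 mm of lead**.
Had the protected area been a corridor (occupancy 1/5), the required
transmission would quintuple and the wall would thin accordingly.

Value layers for any pair:

```sh
$ nmshield vlayers --nuclide Lu-177 --material lead
nuclide,material,HVL,QVL,TVL,CVL,MVL
Lu-177,Lead,0.511,1.1,1.99,4.91,8.76
```

i.e. 0.511 mm of lead halves the Lu-177 dose rate and 1.99 mm cuts it
tenfold.  The solver warns when the required transmission drops below 0.01:
past that point scatter over the barrier off ceilings and floors dominates,
and a thicker primary barrier alone no longer helps.

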