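# flashkin

Reaction-kinetics simulation of radical production in water and biological
media under pulsed versus continuous irradiation, for researchers studying
the FLASH effect in ultra-high-dose-rate (UHDR) radiotherapy.

At conventional dose rates (~0.1 Gy/s) and at FLASH rates (≥ 40 Gy/s) the
same physical dose produces very different transient radical populations.
`flashkin` models this with a mass-action kinetic network for water
radiolysis extended with biomolecule chemistry (an organic hydrogen-donor
pool RH, glutathione, lipids, Fenton iron, catalase), driven by an
arbitrary beam time microstructure, and maps the resulting peroxyl-radical
exposure onto a normal-tissue complication probability (NTCP).

## Model

**Beam.** A fraction of dose *D* delivered at mean dose rate *Ḋ* lasts
*t*<sub>irr</sub> = *D*/*Ḋ*. A pulsed delivery with *N*<sub>p</sub> pulses of
width *t*<sub>pulse</sub> reaches an intra-pulse dose rate

> *Ḋ*<sub>pulse</sub> = *D* / (*N*<sub>p</sub> · *t*<sub>pulse</sub>),

which can exceed the mean rate by many orders of magnitude. Dose rate maps
to molar production of each chemical species *s* through its radiolytic
yield *G<sub>s</sub>* (molecules per 100 eV):

> *P<sub>s</sub>* [M/s] = *Ḋ* · ρ · *G<sub>s</sub>* / (*f*<sub>c</sub> · *N*<sub>av</sub>),
> ρ = 1 kg/L, *f*<sub>c</sub> = 1.602×10⁻¹⁷ J/100 eV.

**Chemistry.** Species concentrations obey d**c**/dt = S **r**(**c**) +
**P**(t), a stiff coupled nonlinear ODE system over ~53 first- and
second-order reactions (water radiolysis plus the biological extension).
Dissolved O₂ is set by Henry's law (c = p·H, H = 1.71×10⁻⁶ mol/mmHg).
Carbon-centred radicals R• form by direct ionisation and by •OH abstraction
from RH; R• + O₂ → ROO• creates the peroxyl radical whose time-integrated
concentration,

> AUC-ROO = ∫ [ROO•](t) dt  (µM·s),

is the biological-damage surrogate. An optional heterogeneous stage evolves
the first microsecond of track chemistry on a 50×50×50 lattice of 100 nm
cells (periodic diffusion, per-cell reactions, border-fed oxygen), seeded
from a species n-tuple produced by the built-in synthetic track generator.

**Damage model.** AUC-ROO is min–max normalised between a high-exposure
anchor (30 Gy at 0.03 Gy/s) and a minimal two-pulse anchor (1 Gy at
100 Gy/s) and fed to a logistic response NTCP = 1/(1+e^(−γ(AUC_norm −
AUC₅₀))) with default γ = 1000, AUC₅₀ = 0.1682. D₅₀ is the dose at
NTCP = 0.5; the FLASH modifying factor (FMF) is D₅₀(UHDR)/D₅₀(CONV).

## Worked example

```python
import flashkin as fk

system = fk.biological_system()          # shipped reaction tables
for label, sched in [
    ("CONV  0.1 Gy/s continuous", fk.BeamSchedule.continuous(10, 0.1)),
    ("FLASH 100 Gy/s, 11 x 1.8 us pulses", fk.pulses_for(100, 10, 100, 1.8e-6)),
]:
    tr = fk.simulate(system, sched, t_end=sched.duration + 300.0)
    print(f"{label}: AUC-ROO = {fk.auc_roo(tr):5.1f} uM s, "
          f"[ROO]max = {tr.max_concentration('ROO')*1e6:4.2f} uM")
```

prints

```
CONV  0.1 Gy/s continuous: AUC-ROO =  87.5 uM s, [ROO]max = 0.83 uM
FLASH 100 Gy/s, 11 x 1.8 us pulses: AUC-ROO =  60.1 uM s, [ROO]max = 4.70 uM
```

Both runs deliver the same 10 Gy at 3.8 % oxygen. At the conventional rate
the peroxyl population stays below a micromolar while dose trickles in over
100 s, giving the larger integrated exposure; at the FLASH rate the whole
radical load is present at once (4.7 µM peak), second-order peroxyl
recombination bites, and the integrated exposure drops by ~30 % — the
radical-level signature of normal-tissue sparing.

The same runs are available from the shell:

```sh
flashkin make-fixtures            # writes fixtures/run.yaml
flashkin simulate fixtures/run.yaml
flashkin sweep fixtures/run.yaml --kind pulses --values 2,11,101,semi
flashkin dose-response fixtures/run.yaml
```

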