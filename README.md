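# clockwave

A delay-differential-equation model of **somitogenesis clock-wave initiation**
in the zebrafish presomitic mesoderm (PSM), together with the parameter
screening, sensitivity, robustness, and in-silico experiment pipeline used to
discriminate between genetic control mechanisms of the segmentation clock.

## The science

Vertebrate somites form in the wake of travelling waves of oscillatory
clock-gene expression that originate in the tailbud and sweep anteriorly,
narrowing as they go. `clockwave` implements a minimal multicellular circuit
for this process, modelled on zebrafish *her7*:

- **Clock.** In each cell *i*, total clock protein `P_i` and clock mRNA `M_i`
  obey delay equations: protein is translated from mRNA after delay `τ_p`;
  mRNA is produced at rate `κ_m · f(R, A)` after delay `τ_m`, where the
  thermodynamic (Shea–Ackers) promoter probability

  `f(R, A) = q(1 + c_a k_a A) / [q(1 + c_a k_a A) + (1 + k_a A)·F_R(R)]`

  is repressed by the clock homodimer `R = hh` through one binding site
  (`F_R = 1 + k_r R`) or two cooperative sites
  (`F_R = 1 + 2 k_r R + c_r (k_r R)²`), and weakly activated by the
  neighbour Notch signal `A`.

- **Competitive dimerization.** The clock protein exists as monomer `p`,
  homodimer `hh = p²/K_hh`, or heterodimer `pg = p·g/K_pg` with a prescribed
  control protein (the Her13.2 role, total `G`, with its own homodimer
  `gg = g²/K_gg`). Dimerization is fast, so at every instant the monomers
  solve the conservation system
  `P = p + 2p²/K_hh + pg`, `G = g + 2g²/K_gg + pg`.

- **Differential decay (cooperative stability).** Either only monomers decay
  (`δ_hh = δ_pg = 0`) or all forms decay at the monomer rate `δ_p`. Four
  scenarios result: I = 1 site/monomer-only, II = 1 site/equal,
  III = 2 sites/monomer-only, IV = 2 sites/equal.

- **Tissue.** Cells on a 1-D line or a 50×5 Moore-coupled array leave the
  tailbud every `1/(σω)` minutes; afterwards their control protein relaxes
  from `G_max` to `G_min` with half-life `t_half`. Falling `G` releases clock
  protein from heterodimer buffering and slows the oscillator — the period
  gradient that lays down the wave. A clock-repressed signal gene (the DeltaC
  role) couples nearest neighbours.

The model-selection question: which scenario can both oscillate at the
tailbud period (30 min ± 10%) and slow down enough across the PSM
(`ΔT = max − min period over the swept G range ≥ 10 min`) to produce a
realistic wave? The screen over 8 estimated parameters answers: only
scenario III — two binding sites *and* differential decay.

## Worked example

```python
from clockwave.fixtures import WAVE_DEMO_III
from clockwave.analysis import sweep_control_protein, classify_collections

sweep = sweep_control_protein(WAVE_DEMO_III, "III", G_step=25, G_max_sweep=500)
per = sweep.periods[sweep.periodic_mask]
print(f"period range {per.min():.2f}-{per.max():.2f} min, delta_T = {sweep.delta_T:.2f}")
print(classify_collections(sweep))
```

prints

```
period range 32.53-45.45 min, delta_T = 12.93
{'A': True, 'B': True, 'C': True, 'D': True}
```

i.e. this scenario-III parameter set oscillates at a tailbud-compatible
period at high control-protein levels, slows to 45.4 min as the control
protein falls, and its period change of 12.9 min marks it as a
collection-D (realistic clock-wave) set. A 50-cell run shows the wave:

```python
from clockwave.tissue import LatticeSpec
from clockwave.experiments import simulate_tissue, band_spacing

run = simulate_tissue(LatticeSpec(50, 1), WAVE_DEMO_III, "III", t_end=400)
print(band_spacing(run.snapshot("M", 380.0), prominence_frac=0.05))
```

```
[18. 16.]
```

— three mRNA expression bands whose spacing narrows from 18 to 16 cells
toward the anterior end (posterior-most spacing first).

The same pipeline is scriptable from the shell:

```bash
clockwave screen --n 500 --seed 42 --g-step 100 --out results/
clockwave simulate-line --out results/wave
clockwave experiment her7kd --out results/kd
```

(The full-scale screen of the study is `--n 40000 --g-step 10`; it takes
hours on one CPU.)

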