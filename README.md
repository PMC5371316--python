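# helixscan

Helix propensity of intrinsically disordered protein segments, at desk
scale.

Transiently helical segments inside disordered regions — populated maybe
15–40% of the time — are where many disordered proteins do their work, and
estimating those populations is notoriously method-dependent. `helixscan`
implements the full analysis stack used to map per-segment helical
propensity along a disordered region and to cross-check it against NMR
chemical shifts, for computational structural biologists who want the
estimators (not a molecular-dynamics engine) as tested, reusable,
seed-reproducible components:

- a **dRMSD helicity coordinate**
  `R = sqrt((1/N) Σᵢ (dᵢ − dᵢ₀)²)` over Cα(j)–Cα(j+3) distances with
  dᵢ₀ = 0.5 nm (R = 0 ⇔ fully helical), its analytic gradient, and the
  umbrella restraint V(R) = ½k₀(R − R₀)²;
- **umbrella sampling with Hamiltonian replica exchange**: 12 windows over
  R₀ = 0…0.5 nm, Metropolis Monte Carlo on a coarse-grained Cα peptide
  model, neighbour swaps accepted with
  min(1, e^(−β[Vₐ(x_b)+V_b(xₐ)−Vₐ(xₐ)−V_b(x_b)]));
- **WHAM** free-energy profiles F(R) with block-bootstrap uncertainty, the
  helical-state population p = Σ_{R<0.15} e^(−F/kT) / Σ e^(−F/kT), and a
  quarter-wise convergence check;
- **ensemble metrics**: geometric helicity assignment, radius of gyration,
  an H-bond surrogate (Cα contacts at sequence separation ≥ 4 within
  0.62 nm), Daura-style greedy RMSD clustering, and per-variant cluster
  dominance analysis (>80% dominated, <1% neglected, clusters >100
  structures);
- **NMR secondary-structure propensity**: SSP = ΔδCα − ΔδCβ from Cα/Cβ
  secondary chemical shifts, neighbour-corrected, normalised to fractional
  helicity, and region helicities against a helix-stabilised (TFE-like)
  reference.

Because microsecond all-atom trajectories are out of reach on a desk, the
sampling engine is a calibrated Cα-trace helix–coil model with four named
parameter presets (`V-TIP3P`, `V-TIP4P-s`, `V-TIP4P-ws`, `V-TIP4P-D`)
standing in for water force fields of varying helix stabilisation and
compaction; a synthetic shift generator plays the same role for the NMR
stage. `docs/methods.md` spells out the model, its calibration, and what
the surrogates do and do not emulate.

## Worked example

Estimate the helical population of one 10-residue segment under the
compact, helix-friendly preset:

```python
import helixscan as hx
from helixscan.cg_model import variant_parameters

params = variant_parameters("V-TIP3P", sequence="ARLREALKAQ")
windows = hx.build_windows()          # 12 windows, R0 = 0.0 ... 0.5 nm
samples = hx.run_hremd(params, windows, n_steps=4000,
                       exchange_interval=100, seed=1)
production = samples.discard_equilibration(0.1)
profile = hx.wham(production, windows, temperature=300.0, n_boot=50)
p, lo, hi = hx.helical_population_ci(profile)
print(f"helical population (R < 0.15 nm): {p:.3f}  [95% CI {lo:.3f}-{hi:.3f}]")
report = hx.convergence_quarters(production, windows)
print(f"quarter-wise max |dF| = {report.max_deviation_kt:.2f} kBT, "
      f"converged: {report.converged}")
```

prints

```
helical population (R < 0.15 nm): 0.699  [95% CI 0.660-0.732]
quarter-wise max |dF| = 0.64 kBT, converged: False
```

Read: this Arg/Glu-rich segment spends ~70% of its time in the helical
basin (R below the 0.15 nm boundary where geometric helicity crosses 50%),
with a bootstrap interval of about ±0.04. The convergence check compares
free-energy profiles from the 2nd–4th quarters of the run and here still
flags ~0.6 kBT of drift in the sparsely visited unfolded tail — the
population itself is stable, but a longer run would be needed before
trusting the full profile shape. Under the most expanded preset
(`V-TIP4P-D`) the same segment's population collapses below 0.03.

The same workflow scales to a whole region via `run_scan` /
`write_report`, or from the shell:

```bash
helixscan segment seq.fasta --first-residue 380 --last-residue 490
helixscan sample --sequence ARLREALKAQ --seed 1 --out run/
helixscan pmf --samples-dir run/ --out pmf.tsv
helixscan report --config scan.json --out report/
```

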