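# elevatorfep

A desk-scale, fully tested implementation of the enhanced-sampling
free-energy workflow used to characterize conformational transitions of
elevator-type membrane transporters — the alternating-access switch in
which a transport domain (TD) translates and rotates against a static
scaffold domain (SD), carrying its substrate across the membrane.

Microsecond all-atom MD is replaced by synthetic Langevin systems with
analytic ground truth, so every stage of the workflow can be validated
against a closed form or a brute-force oracle:

* **Collective variables** — the elevator CVs *z* (signed projection of the
  TD center of mass onto the OF→IF displacement axis, Å) and *θ* (angle of
  the TD's first principal axis relative to the inward-facing reference,
  degrees), measured after least-squares scaffold superposition.
* **Driven transitions** — moving harmonic restraints drag the system from
  the outward-facing (OF) to the inward-facing (IF) basin under three
  protocols (rotation→translation, translation→rotation, simultaneous),
  with nonequilibrium work accounting
  W = ∫ k (c(t) − x(t)) ċ(t) dt and a release stage.
* **String method with swarms of trajectories (SMwST)** — 32 images × 24
  replicas per image; each cycle anchors the swarms, lets them drift, moves
  each image by the mean drift, then smooths and reparametrizes the string
  to equal arc length until it converges onto the minimum free-energy path.
* **Bias-exchange umbrella sampling (BEUS)** — 64 windows at equal arc
  length along the refined path (k = 36 kcal/mol/Å² in span-normalized
  units), with Metropolis swaps of neighboring restraint centers,
  Δ = β[U_i(x_j) + U_j(x_i) − U_i(x_i) − U_j(x_j)].
* **WHAM** — self-consistent solution of
  p_b ∝ Σ_i n_ib / Σ_i N_i e^{β(f_i − U_ib)},
  f_i = −kT ln Σ_b p_b e^{−βU_ib},
  giving the potential of mean force F(s) = −kT ln p(s) with bootstrap
  errors resampled across windows.
* **Binding analytics** — heavy-atom contact detection (3.5 Å cutoff),
  residence-time segmentation, the dissociation constant
  K_d = (t_unbound/t_bound)·[C] (equivalently k_off/k_on), per-residue
  interaction ranking, and 3D occupancy density maps written as OpenDX.

The synthetic systems plant the phenomena the workflow must detect: a
two-basin landscape whose saddle is lowered by exactly 3 kcal/mol by a
"substrate" coupling and raised by 2 kcal/mol by an anionic-lipid-like
confinement term, and two-state telegraph binding with known on/off rates.

## Worked example

Umbrella sampling with center exchange on a 5 kcal/mol double well, then
WHAM with window-bootstrap errors:

```python
import numpy as np
from elevatorfep.toy_systems import make_double_well, analytic_pmf
from elevatorfep.beus import seed_windows, run_beus
from elevatorfep.wham import bootstrap_pmf

model = make_double_well(barrier=5.0, separation=4.0)          # kcal/mol, Å
windows = seed_windows(np.linspace(-2.6, 2.6, 16)[:, None], 16, k=10.0)
run = run_beus(model, windows, exchange_interval=100, n_sweeps=800,
               dt=0.002, seed=1)
pmf = bootstrap_pmf(run, bins=80, n_boot=40, seed=2, min_count=200)

ref = analytic_pmf(model, pmf.bins)
ok = np.isfinite(pmf.values)
err = (pmf.values - ref.values)[ok]
err -= err.mean()
print(f"swap acceptance   : {run.exchange_log.acceptance_rate():.3f}")
print(f"recovered barrier : {pmf.barrier():.3f} kcal/mol (true 5.000)")
print(f"max |PMF error|   : {np.abs(err).max():.3f} kcal/mol")
print(f"mean bootstrap SD : {np.nanmean(pmf.sd[ok]):.3f} kcal/mol")
```

prints

```
swap acceptance   : 0.380
recovered barrier : 5.018 kcal/mol (true 5.000)
max |PMF error|   : 0.116 kcal/mol
mean bootstrap SD : 0.131 kcal/mol
```

i.e. the exchanged umbrella windows mix well (38% swap acceptance), and the
reconstructed free-energy profile reproduces the analytic barrier to ~0.1
kcal/mol, consistent with its own bootstrap error bars.

The full multi-condition pipeline (drive → SMwST → BEUS → WHAM → barrier
comparison) runs from the command line:

```bash
elevatorfep pipeline --seed 42 --outdir out/
```

which writes per-condition PMFs (`pmf_apo.tsv`, …), string histories,
exchange logs, a barrier table with bootstrap SDs, and a JSON run record
with every stage seed. `elevatorfep bind`, `drive`, `refine`, `beus`,
`wham`, `simulate` and `compare` expose the individual stages.

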