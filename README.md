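# recolorpoly

**Recolourable-polymer Brownian dynamics of Polycomb read–write chromatin,
with the matching condensate imaging statistics.**

Polycomb group proteins (PRC1: CBX, PCGF/BMI1, PHC, RING/RNF2) read the
H3K27me3 histone mark and write H2AK119Ub, and their condensation can
compact chromatin into facultative heterochromatin.  A central puzzle is
*memory*: compaction persists after the protein condensates are gone.
`recolorpoly` implements a minimal physical model of this behaviour and
the quantitative image analysis used to study it in cells:

* a coarse-grained chromatin fibre (bead–spring polymer, 30 nm / 3 kbp
  beads) whose beads carry dynamic epigenetic "colours";
* diffusing protein bridges that bind K27me3-marked beads
  (bridging-induced compaction) and ubiquitinate beads within a 60 nm
  writing radius via a Monte-Carlo recoloring rule;
* Ub–Ub self-attraction, so the written mark sustains compaction after
  binding is switched off;
* imaging statistics for two-channel micrographs — masked Pearson
  colocalization, pixel-variance traces (normalization + history
  integral), inactive-X partition coefficients, FRAP-style region traces,
  concentration/valence phase diagrams — plus synthetic-image generators
  with known ground truth for all of them.

## The model in brief

Chromatin is `N` beads with WCA excluded volume, FENE bonds
(`k = 30 ε/σ²`, `R0 = 1.5 σ`) and bending energy `k_θ (1 − cos α)` with
`k_θ = 3 kBT` (persistence length ≈ 90 nm).  Binding and Ub–Ub
attraction are truncated Lennard-Jones wells (4 and 3 `kBT`, cutoff
`1.8 σ`).  Langevin dynamics (BAOAB, `γ = m = 1`, `Δt = 0.01 τ`) runs a
three-phase protocol — equilibrate → binding window with recoloring
every `10 τ` → binding off — and records the squared radius of gyration,
the local density within 60 nm of each bead,
its square (the simulation analogue of the imaging variance), and the Ub
count.  See `docs/methods.md` for the full model description, numerical
choices and limitations.

## Worked example

```python
import numpy as np
import recolorpoly as rp
from recolorpoly.workflows import compaction_experiment, scaled_compaction_params

params = scaled_compaction_params()        # 300 beads, 25 marked, 6 binders
schedule = rp.ProtocolSchedule(t_equil=3e3, t_bind=1e4, t_post=6e3,
                               recolor_enabled=True, sample_interval=50.0)
result = compaction_experiment(params, schedule, n_replicas=2, base_seed=100)
print(f"baseline density^2    {result.baseline:.4f}")
print(f"at binding termination {result.termination:.4f}")
print(f"end of post window     {result.end:.4f}")
print(f"retention              {result.retention:.3f}")
```

Output from this exact invocation:

```
baseline density^2    0.0250
at binding termination 0.1332
end of post window     0.1334
retention              1.001
```

The mean local density squared (in `σ⁻⁶`) rises roughly five-fold during
the binding window and is fully retained after the binders are
decoupled — the written Ub marks keep the domain compact.  Running the
same schedule with `recolor_enabled=False` returns the fibre to within
~1% of its baseline, the no-memory control.

The same machinery is scriptable from the shell:

```bash
recolorpoly simulate --config run.toml --replicas 8 --seed 1 --out out/
recolorpoly analyze-traj out/trajectory_rep000.xyz --out obs.csv
recolorpoly synth --kind pair --pcc 0.7 --out synth/
recolorpoly img-metrics --channel-a synth/channel_a.tif --channel-b synth/channel_b.tif \
    --nucleus synth/mask_nucleus.tif --mode colocalization --out metrics.csv
recolorpoly phase-diagram --records cells.csv --out diagram.csv
```

An empty `run.toml` reproduces the full-scale study parameters
(`N = 1000`, 20 binders, 85 marked beads in `[400, 600)`, 36 replicas);
every key can be overridden per section (`[simulation]`, `[schedule]`,
`[output]`, `[imaging]`).

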