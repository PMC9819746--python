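# ly6orient

Positional and orientational analysis of GPI-anchored three-finger
(Ly6/uPAR-family) proteins in planar lipid bilayers, from molecular-dynamics
trajectories.

Proteins such as Lynx1, Lynx2, Ly6H, Lypd6, Lypd6B and CD59 consist of a
compact β-structural "head" with three protruding loops, tethered to the
outer membrane leaflet by a glycosylphosphatidylinositol (GPI) anchor.
Whether the anchor pre-orients the receptor-binding loops toward or away
from the membrane is a quantitative question about the protein's pose above
the bilayer. `ly6orient` reduces each trajectory frame to three parameters:

* **Z** — height of the amino-acid centre of mass above the mean z of the
  upper-leaflet phosphorus atoms (nm, the "rise");
* **α = 90° − ∠(A, Z⃗)** — tilt of the head → central-loop vector A against
  the membrane normal (deg, the "pitch"; α > 0 head down, α < 0 loops down);
* **β** — rotation built from the loop III → loop I vector B and a
  disambiguation vector F via a three-branch formula (deg, the "roll";
  −90° loop I down, +90° loop III down, 0° ventral, ±180° dorsal).

On top of the per-frame series the package provides probability histograms
(1D and joint α/β), uni-/bi-/trimodal Gaussian mode fits selected by BIC and
reported as median ± SD per mode, principal component analysis of the
backbone after xy-only superposition, and typed protein–lipid contact
analysis (ionic/ion–dipole, hydrogen bond, π–cation, hydrophobic via atomic
lipophilicity constants) accumulated into relative lifetimes and rendered as
a four-column residue report with 10 %/5 %/200 % inclusion thresholds and
bold (≥ 50 %) / bold-underline (≥ 75 %) emphasis tiers.

A synthetic-data module generates membrane + rigid mock-protein trajectories
whose per-frame (Z, α, β) and planted residue–lipid contacts are known
exactly, so the entire pipeline is testable without external data. See
`docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from ly6orient import (
    SyntheticSpec, generate_trajectory, default_groups_config,
    orientation_series, fit_modes,
)

spec = SyntheticSpec(n_frames=200, seed=4)       # Lynx1-like defaults
traj, truth = generate_trajectory(spec)
series = orientation_series(traj, default_groups_config())
print(series.summary())
fit = fit_modes(series.alpha, seed=4)
print(f"k={fit.k}, tilt mode = {fit.modes[0].median:.1f} "
      f"+/- {fit.modes[0].sd:.1f} deg")
```

Output:

```
{'label': 'mock', 'n_frames': 200,
 'Z_nm': {'min': 1.676..., 'max': 2.257..., 'mean': 2.004...},
 'alpha_deg': {'min': -54.18..., 'max': -3.87..., 'mean': -30.51...},
 'beta_deg': {'min': -67.57..., 'max': -29.78...}}
k=1, tilt mode = -30.5 +/- 8.3 deg
```

The generator was asked for a unimodal tilt of −31.5 ± 8.7°; the measured
series recovers the ground truth frame by frame (to ~1e-13), and the mode
fit recovers the configured well within sampling error. The same functions
run on real data loaded with `load_topology` (PDB/GRO) and
`load_trajectory` (XTC/DCD), given a YAML residue-groups config naming the
head and loop-tip residues for the protein at hand.

The same pipeline is available from the shell:

```sh
ly6orient simulate --seed 4 --out demo/
ly6orient orient   --top demo/synthetic.pdb --traj demo/synthetic.xtc \
                   --groups groups.yaml --out series.tsv
ly6orient report   --series series.tsv --out stats/ --plots
ly6orient pca      --top demo/synthetic.pdb --traj demo/synthetic.xtc --out pca/
ly6orient contacts --top demo/synthetic.pdb --traj demo/synthetic.xtc --out contacts/
```

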