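# helixcharge

Tools for studying how duplicated protein families escape the constraints of
the multiprotein complexes they belong to, through electrostatic change in
the N-terminal helix that tethers them to the complex. The motivating system
is the plant exocyst: the Exo70 subunit radiated into three paralogue
families (I, II, III), and the diverged family II carries an N-terminal helix
that is markedly more acidic than its siblings — enough to break the
interaction with Exo84 and free the protein from the complex. `helixcharge`
implements the sequence-level side of that analysis so the same questions can
be asked of any paralogue family on a rooted phylogeny:

* **Per-site variability.** Shannon entropy of alignment columns,
  H = −Σₐ pₐ log₂ pₐ (bits, 20-residue alphabet, gaps excluded), compared
  across (family × region) groups with two-sided pairwise Tukey HSD tests and
  a compact letter display.
* **Composition classification.** A from-scratch linear discriminant
  analysis on 20-dimensional amino-acid frequency vectors of N-terminal
  segments, written as a scikit-learn estimator (`CompositionLDA`), with a
  stratified 30% training split and per-residue contribution scores.
* **Net charge at fixed pH.** Henderson–Hasselbalch partial charges per
  ionizable group (q⁺ = 1/(1+10^(pH−pKa)), q⁻ = −1/(1+10^(pKa−pH))), summed
  over a segment and normalized by length: q̃ = q/L, the per-residue charge
  that serves as the evolving trait.
* **Ancestral reconstruction.** Maximum-likelihood ancestral states of q̃
  under Brownian motion on a rooted tree — a two-pass O(n) pruning algorithm
  equivalent to re-rooting at every node, validated against a full GLS oracle
  (V[i,j] = shared root-to-MRCA path length; â₀ = (1ᵀV⁻¹y)/(1ᵀV⁻¹1)).
* **Interface confidence scoring.** The PEAK score of a predicted multimer:
  the mean predicted aligned error over interchain residue pairs (both
  off-diagonal PAE blocks), plus mean/max aggregation across models together
  with ipTM.
* **Synthetic data.** A seeded generator producing three paralogue families
  on one rooted tree, a charge trait evolving by Brownian motion with a
  negative jump on the family-II stem, and sequences whose N-terminal
  composition realizes each tip's charge — so the entire pipeline runs and is
  validated without any external download.

## Worked example

```python
import numpy as np
from helixcharge import (
    SyntheticConfig, generate, composition_matrix, split_fit_evaluate,
    net_charge, ancestral_states_fast, shift_summary,
)

ds = generate(SyntheticConfig(seed=1))          # 3 families x 120 taxa

# classify families from N-terminal composition (30% training split)
ids, X = composition_matrix({t: s[0] for t, s in ds.segments.items()})
y = np.array([ds.families[t] for t in ids])
res = split_fit_evaluate(X, y, train_frac=0.3)
print(f"held-out accuracy: {res['accuracy_heldout']:.3f}")

# the charge trait and its history
q = {t: net_charge(s[0], 7.0).q_norm for t, s in ds.segments.items()}
recon = ancestral_states_fast(ds.tree, q)
print(f"root q_norm: {recon.fit.root_state:+.3f}")
print(f"family-II stem shift: {shift_summary(recon, 'stemII')['delta']:+.3f}")
```

prints

```
held-out accuracy: 1.000
root q_norm: -0.059
family-II stem shift: -0.156
```

The classifier separates the three families from composition alone; the
reconstructed root sits near the uncharged ancestral state while the
family-II stem shows the negative electrostatic shift (attenuated from the
simulated −0.25 jump by Brownian-motion smoothing; see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
helixcharge simulate --seed 1 --out data/
helixcharge pipeline --config run.toml --out results/
helixcharge anc --tree data/tree.nwk --traits data/traits_true.tsv \
    --clade stemII --out states.tsv
```

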