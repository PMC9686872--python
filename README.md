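# windtree

**Functional–structural tree growth under wind: source–sink allocation,
beam biomechanics, stem breakage, and growth-strategy optimization.**

Trees visibly acclimate to wind — shorter stature, smaller leaf area,
thicker stems ("thigmomorphogenesis").  `windtree` tests the hypothesis
that this plasticity is not a hard-wired reflex but the *optimal growth
strategy* under a mechanical survival constraint.  It couples:

* a growth-cycle plant model (GreenLab family): each cycle the tree
  produces biomass `Q(n) = E_pot·S_p·(1 − e^{−k·A/S_p})` from its leaf
  area and divides it between primary growth (new internodes and leaves,
  per-PA sink strengths) and secondary growth (a new wood ring on every
  internode).  The ring demand follows the pipe model,
  `D_sec = S_layer · N_leaves(n−1)`, and the per-internode split
  `q = [(1−λ)/D1 + λ·spa/D2]·l·P_r·Q_sec` conserves the ring pool for any
  λ ∈ [0, 1];
* an incremental transfer-matrix beam solver: internodes are multilayer
  beam elements; gravity increments deform the tree permanently, wind
  drag (logarithmic profile `u(z) = u(h0)·ln(z/z0)/ln(h0/z0)`, stem and
  leaf drag) deforms it elastically, and the equilibrium loop lets the
  tree sway to rest, shifting gravity centres as it bends;
* a safety model: an internode breaks when its peripheral stress
  `σ = 32M/(πd³)` exceeds the modulus of rupture; breakage severs the
  distal substructure.  The critical wind speed (CWS) is the smallest
  steady wind that breaks the trunk;
* a hand-written NSGA-II that maximizes `(H_tree, Q_stem)` over the ring
  sink strength `S_layer`, subject to the trunk surviving the whole
  horizon.

With these pieces, "stronger wind, smaller tree" *emerges*: under calm the
Pareto-optimal `S_layer` is small (tall, slender trees); under wind the
slender end of the front breaks and the optimum shifts toward thicker,
shorter, heavier-ringed trees.

## Worked example

Grow the poplar preset for 8 cycles without wind:

```bash
windtree simulate --preset poplar_preset --cycles 8
```

```
 cycle          Q_n     Q_stem    H_tree  leaf_area    dbh_cm  top_deflection  broken_count  trunk_broken
     1   100.000000   0.046667  0.727385   0.231884       NaN             0.0             0         False
     2  1012.444038   0.652323  2.024961   1.768643  2.519787             0.0             0         False
     3  7340.754707   5.197547  4.285047  12.154480  6.604376             0.0             0         False
     4 36648.136270  28.790162  7.735953  56.763134 11.886009             0.0             0         False
     5 64500.028932  72.017572 11.366789  92.489648 15.693943             0.0             0         False
     6 65861.421982 117.774428 14.528881  87.411159 18.019010             0.0             0         False
     7 65805.584148 164.874207 17.287206  81.329585 19.707640             0.0             0         False
     8 65708.384052 213.041285 19.717410  76.266551 21.031604             0.0             0         False
```

Reading the output: the seedling runs on a 100 g seed reserve, production
saturates near `E_pot·S_p ≈ 66 kg`/cycle once the crown closes, and after
8 cycles the tree stands 19.7 m tall with 213 kg of stem wood and a 21 cm
diameter at breast height.  Under wind the same tree sways (a 10 m/s wind
deflects the top ~19°, settling within 8 equilibrium iterations), and at
the critical wind speed the trunk snaps:

```bash
windtree cws --preset poplar_preset --u-max 30
# CWS = 13.4 m/s (ok)
windtree sweep --slayer-grid 0.5,1,2,4,8   # stem biomass peaks at interior S_layer
windtree optimize --wind 12 --pop 20 --gen 15 --horizon 6 --seed 42
```

The optimizer writes the Pareto front (`pareto_front.csv`), the three
strategies — I heaviest, III tallest, II the compromise nearest the front
mean — and a box summary of optimal `S_layer` percentiles.  At wind
12 m/s the median optimal `S_layer` rises to ≈0.9 versus ≈0.6 in calm
conditions: the digital tree reinforces its stem exactly as real trees
do.

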