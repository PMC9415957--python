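# pnde — Poincaré plot nonextensive distribution entropy

`pnde` quantifies the complexity of a single-channel physiological time
series (EEG, HRV, and similar signals) from the geometry of its Poincaré
plot. It implements the **nonextensive distribution entropy (NDE)** — a
distance-weighted generalization of Poincaré plot distribution entropy —
together with the validation apparatus needed to use it with confidence: an
exact fractional Brownian motion simulator, sliding-window parameter sweeps,
and a sleep-EEG staging pipeline with ordered-alternative trend testing.

## The measure

For a series `s_1 … s_N`, subtract the minimum so `x_i = s_i − min(s) ≥ 0`
and form the Poincaré scatter `{(x_i, x_{i+τ})}` (standard form `τ = 1`).
Partition the first quadrant into `W` concentric sector rings of equal
radial width `dl = L_max / W`, where `L_max` is the largest Euclidean
distance of any point from the origin, and let `p_k` be the fraction of
points in ring `k`.

* **Distribution entropy (DE)** is the Shannon entropy
  `E_D = −Σ_k p_k ln p_k`. It sees only the occupancy histogram: any
  permutation of the rings leaves it unchanged, so scatters concentrated
  near the origin and scatters concentrated far from it can score
  identically.
* **NDE** restores the radial information through a per-ring Tsallis
  (nonextensive) parameter derived from the reverse-subtracted ring-center
  distance,

  ```
  q_k = 1 + L_max − (k − 1)·dl − dl/2 ,        q_1 > q_2 > … > q_W > 1
  ```

  so distal, high-amplitude rings get small `q` (large weight) and proximal
  rings large `q` (small weight), and sums the generalized-entropy terms

  ```
  S = Σ_k (p_k − p_k^{q_k}) / (q_k − 1) ,
  ```

  which is nonnegative and reduces to Shannon entropy as every `q_k → 1`.
  Because `q_k` carries `L_max`, NDE is amplitude-aware: it is invariant to
  adding a constant to the signal but deliberately not to rescaling it.

The canonical illustration: two five-ring scatters with mirrored occupancy
`{1/15, 2/15, 1/5, 4/15, 1/3}` (inner→outer vs outer→inner) share
`DE = 1.4898` nats, but with `q = {10, 8, 6, 4, 2}` their NDE values are
`0.3759` and `0.2217` — the radial layout is no longer invisible.

## Worked example

Fractional Brownian motion is the standard synthetic benchmark: its Hurst
index `H` dials the complexity, and entropy should fall as `H` rises.

```python
import numpy as np
from pnde import nde, de, FbmSpec, generate_fbm

rough  = generate_fbm(FbmSpec(H=0.2, n=2500, seed=42))  # anti-persistent
smooth = generate_fbm(FbmSpec(H=0.8, n=2500, seed=42))  # persistent
for name, s in [("H=0.2", rough), ("H=0.8", smooth)]:
    print(name, "DE =", round(de(s, W=50).value, 4),
          " NDE =", round(nde(s, W=50).value, 4))
```

prints

```
H=0.2 DE = 3.5264  NDE = 0.1592
H=0.8 DE = 3.6334  NDE = 0.0141
```

DE barely separates the two regimes (and moves the wrong way); NDE drops by
an order of magnitude from the rough to the smooth path, tracking the loss
of complexity. The `sweep` subcommand runs this over a whole Hurst grid with
replicate averaging; on the default grid the mean NDE decreases strictly
monotonically in `H`.

## Command-line interface

```bash
pnde nde series.csv --rings 50            # score one series
pnde fbm --hurst 0.7 --length 20000 --seed 1 --out fbm.csv
pnde sweep --hurst-grid 0.1,0.3,0.5,0.7,0.9 --replicates 10 \
     --seed 1 --out sweep.csv
pnde sleep --synthetic --epochs-per-stage 30 --seed 1 --out scores.csv
pnde selftest                             # built-in oracle checks
```

`pnde sleep` runs the full staging pipeline — singular-spectrum detrending,
zero-phase 1–32 Hz band-pass, per-30-s-epoch NDE scoring (201 sliding
windows of 1000 samples, step 10), stage grouping and the
Jonckheere–Terpstra ordered trend test with Bonferroni-adjusted pairwise
comparisons. With `--synthetic` it uses the bundled stage-labelled EEG
generator, so no recording needs to be downloaded; with `--input record.edf
--hypnogram stages.csv` it reads a real EDF channel.

Every command accepts `--config run.yaml` and `--seed`; a fixed config and
seed reproduce a run bit for bit.

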