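# sitmotif

Dynamic sitting behaviour from a sensor-equipped office chair, and what it
says about within-day low-back-pain (LBP) change.

Office chairs fitted with four corner load cells record how a sitter's
centre of pressure (COP) moves through the working day. `sitmotif`
implements the full analysis chain for such recordings:

1. **COP reduction** — corner loads A1..A4 (kg) become a 1 Hz 2-D COP
   series, `x = (−A1 − A2 + A3 + A4)/4`, `y = (A1 − A2 + A3 − A4)/4`, with
   presence detection (chair empty below 5 kg total load).
2. **State segmentation (TICC)** — Toeplitz inverse-covariance-based
   clustering: each sitting state (stable sit, slight sway, big sway, off
   chair) is a Gaussian Markov random field over a 5-sample window whose
   `nw × nw` precision Θ is block Toeplitz (sub-block *(i, j)* depends only
   on *j − i*).  Fitting alternates an exact switching-penalised dynamic
   program (penalty β) with a block-Toeplitz graphical lasso (ℓ1 weight λ)
   solved by ADMM; the number of states K is chosen by
   BIC = −2 ln L + k ln n.
3. **Motif discovery (MASA)** — motif-aware state assignment: recurring
   ordered state sequences (|m| > 2, adjacent states distinct, > L
   non-overlapping recurrences) are scored, and the state sequence is
   re-decoded over an expanded graph that charges log γ (0 ≤ γ ≤ 1) for
   every measurement left outside a motif instance.  The headline feature
   is the occurrence rate of the top ("common") motif per 30 sitting
   minutes.
4. **Prediction (SSA-PNN)** — a weighted Parzen-window probabilistic neural
   network classifies each participant-day's LBP change (morning minus
   evening score: exacerbated / no change / improved) from sex, sitting
   hours, motif rate, sleepiness and fullness:

   p_g(x) = (2π)^(−n/2) σ^(−n) l_g^(−1) Σᵢ exp(−Σⱼ (ω_j x_j − ω_j x_ij^(g))² / 2σ²)

   The smoothing σ and feature weights ω are tuned by the social spider
   algorithm (SSA) on a 5-fold inner cross-entropy objective inside each of
   6 stratified outer folds; a label-permuted surrogate estimates chance
   level.
5. **Attribution and statistics** — exact Shapley values (full 2⁵ coalition
   enumeration with interventional expectations) rank the features;
   Kruskal–Wallis and Dunn tests compare motif rates across the three
   LBP-change groups.

Because chair recordings of this kind are not generally shareable, the
package ships a first-class synthetic-data module (`sitmotif.synthetic_data`)
that simulates cohorts with known states, planted motifs and a planted
motif-rate/LBP-change association, so every stage is testable end to end.
It is aimed at movement-scientists and biostatisticians who want to
reanalyse their own smart-chair data or study the method's behaviour under
controlled conditions.

## Worked example

Simulate one two-hour sitting bout with a stable-sit/slight-sway
alternation planted at 2 instances per 30 minutes, then recover it:

```python
from sitmotif import synthetic_data as syn, ticc, masa

specs = syn.demo_state_specs(3)                      # stable sit / slight sway / big sway
seq, planted = syn.simulate_state_sequence(
    specs, 7200, dwell=60, planted_motif=masa.Motif((1, 2, 1)),
    motif_rate=2.0, seed=21)
cop = syn.emit_cop(seq, specs, seed=22)              # 1 Hz COP samples
X, idx = ticc.stack_windows(cop, 5)                  # 5 s windows
model = ticc.fit_ticc(X, ticc.TICCConfig(K=3, seed=21))
fitted = masa.fit_masa(X, model, masa.MASAConfig())

top = fitted.motifs[0]
print("planted instances :", len(planted))
print("top motif (ids)   :", top["motif"].states, " decoded instances:", top["count"])
print("occurrence rate   : %.2f / 30 min" % masa.motif_occurrence_rate(
    top["instances"][0], len(X) / 3600))
```

prints

```
planted instances : 6
top motif (ids)   : (0, 2, 0)  decoded instances: 19
occurrence rate   : 4.75 / 30 min
```

Cluster ids are arbitrary: here cluster 0 is the stable-sit state and
cluster 2 the slight sway, so `(0, 2, 0)` *is* the planted alternation.
The decoder finds 19 instances — the 6 planted ones plus the alternations
the background sitting dynamics produce on their own; the occurrence rate
counts both, exactly as it would on real data.

The same stages are exposed on the command line (`sitmotif simulate`,
`preprocess`, `segment`, `motifs`, `train`, `pipeline`); run any of them
with `--help`.

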