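# synid

Muscle-synergy-based intention decoding for center-out reaching.

## The problem

People with severe upper-limb motor impairment can be assisted by a
powered shoulder–elbow exoskeleton, but the device must know *where* the
user wants to reach — and know it early, before the limb has moved.
Surface EMG precedes measurable movement by the electromechanical delay,
so a decoder built on muscle activity can commit to a direction while a
purely kinematic classifier still sees a stationary hand.

`synid` implements such a decoder and everything needed to study it on
synthetic sessions: subjects reach from a home position toward eight
targets on a 25 cm-radius circle (E, NE, N, NW, W, SW, S, SE), six
muscles are recorded at 1 kHz, and the control loop runs at 100 Hz.

## The method

1. **Linear envelopes** — causal chain: Butterworth band-pass 20–400 Hz,
   50 Hz notch, rectification, 4 Hz low-pass; decimation to 100 Hz.
2. **Onset detection** — the summed envelope must exceed
   `μ + h·σ` of a trailing 150 ms window (default `h = 9`).
3. **Muscle synergies** — non-negative matrix factorization
   `E ≈ W H` with `W ∈ R₊^{6×4}` (multiplicative updates, restarts,
   per-iteration monotone RMSE); online activation coefficients by
   non-negative least squares `c_k = argmin_{c≥0} ‖e_k − W c‖₂`.
4. **Direction classification** — one 3-component Gaussian mixture per
   direction on the activation vectors; per-sample direction
   probabilities `p(d | c_k) ∝ f_d(c_k)`; evidence accumulation
   `P_k ∝ P_{k−1} ⊙ p(· | c_k)` (renormalized each step); running
   estimate `argmax_d P_k(d)`, frozen after the 0.6 s accumulation time.
5. **Assistance** — virtual stiffness `F = K ∘ R(x_target − x_hand)`
   mapped to joint torques by `τ = Jᵀ F` on a simplified 4-DOF arm, plus
   point-mass gravity compensation; manipulability
   `w(q) = √(λ_min/λ_max)` of `J Jᵀ`.
6. **Evaluation** — confusion matrix; error types 1–4 by circular target
   distance; modified accuracy (correct + adjacent); Δρ/Δθ polar
   repeatability; MVC-normalized iEMG; adjusted chance level (binomial
   upper bound, 18.1% for 160 trials over 8 classes); time-resolved
   modified-accuracy curves against a nearest-target-angle kinematics
   benchmark.

Model details, parameter rationale and the limits of the synthetic data
are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from synid.synthetic_data import GeneratorConfig, generate_session
from synid.pipeline import PipelineConfig, run_synthetic_study

session = generate_session(GeneratorConfig(seed=1))   # 80 train + 160 test trials
study = run_synthetic_study(session, PipelineConfig())
m = study["metrics"]
print(f"accuracy          {m.accuracy_pct:5.1f} %")
print(f"modified accuracy {m.modified_accuracy_pct:5.1f} %")
print(f"type-1 errors     {m.type1_pct:5.1f} %")
print(f"chance level      {m.chance_level_pct:5.1f} %  (n={m.n_trials})")
curve = m.accuracy_vs_time
bench = study["benchmark_curve"]
for t in (0.05, 0.20, 0.60):
    i = list(curve["time_s"]).index(t)
    print(f"t={t:.2f}s  synergy {curve['accuracy_pct'][i]:5.1f} %"
          f"   kinematics {bench['accuracy_pct'][i]:5.1f} %")
```

prints

```
accuracy           86.4 %
modified accuracy  93.2 %
type-1 errors       6.8 %
chance level       18.4 %  (n=147)
t=0.05s  synergy  92.5 %   kinematics  37.4 %
t=0.20s  synergy  93.2 %   kinematics  37.4 %
t=0.60s  synergy  93.2 %   kinematics 100.0 %
```

Reading: the decoder identifies the intended direction (or its immediate
neighbor) in over 90% of test reaches within 50 ms of EMG onset, far
above the 18% adjusted chance level, while the kinematics-only
classifier is still near its chance floor because the hand has not yet
moved a centimeter; once the reach unfolds, kinematics win. Thirteen of
the 160 test trials were excluded because no onset was detected —
mirroring how real sessions handle undetected onsets.

The same chain is scriptable from a shell:

```bash
synid generate --out session/            # seeded synthetic session (CSV + JSON)
synid train    --manifest session/manifest.json --out model.json
synid decode   --manifest session/manifest.json --model model.json --out decodes.json
synid evaluate --decodes decodes.json --out metrics.json
```

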