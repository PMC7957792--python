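# wheezefactor

Monophonic/polyphonic wheeze classification for auscultation audio, based
on a constrained low-rank non-negative matrix factorization (CL-RNMF) of
the respiratory-sound spectrogram.

## The problem

Wheezes are continuous adventitious respiratory sounds: narrowband tones
between 100 and 1000 Hz lasting more than 100 ms that ride on top of the
wideband normal breath sound. Clinicians distinguish **monophonic (MP)**
wheezes — a single narrowband peak (Type 1) or a basal peak plus its
integer harmonics (Type 2), associated with single-airway narrowing and
asthma — from **polyphonic (PP)** wheezes — several non-harmonically
related peaks, a marker of multi-airway compression and COPD. Telling
them apart by ear is hard because both are sinusoidal in character and
both are masked by normal respiratory noise.

## The method

Stage I separates the wheeze spectrum from the breath-noise interference.
The band-limited (100–1000 Hz), grand-mean-normalised magnitude
spectrogram `X` (F×T) is decomposed as

    X ≈ B_R A_R + B_W A_W

with a *low-rank* wheeze part (`K_w = 4` components versus `K_r = 32`
respiratory components) and opposing structural penalties, minimising

    D = D_KL(X | B_R A_R + B_W A_W) + α·ψ(B_W) + λ·φ(A_W) + β·φ(B_R)

where `D_KL` is the generalised Kullback–Leibler divergence, `ψ` an L1
sparseness penalty (wheeze bases: few active frequency bins), and `φ` an
RMS-normalised squared-difference smoothness penalty (wheeze activations
smooth in time; respiratory bases smooth in frequency, i.e. wideband).
All four matrices are learned by multiplicative updates (50 iterations,
`α = λ = β = 0.5`), which keep them non-negative and monotonically
decrease `D`. The wheeze bases are collapsed into a spectral energy
distribution `ξ(f) = Σ_k B_W[f, k]`.

Stage II classifies the harmonic structure of `ξ(f)`: narrowband peaks
are detected by topographic prominence (threshold 5% of max `ξ`), the
basal (lowest-frequency) peak at `f_p(1)` with half-prominence main-lobe
width `Δ` defines tolerance intervals `Λ_z = [z·f_p(1) ± Δ/2]`, and the
segment is labelled MP if every detected peak `z = 2..η` falls inside its
interval `Λ_z`, PP otherwise. A single peak (`η = 1`) is MP Type 1. The
method is fully unsupervised — no training data.

Because no public MP/PP-labelled corpus exists, the package ships a
synthetic generator (`wheezefactor.simulate`) that emulates the target
recordings: MP1/MP2/PP tone complexes (0.1–0.7 s at 4096 Hz, slow
frequency drift) mixed at a controlled SNR with wideband breath noise
concentrated in 60–1000 Hz.

## Worked example

```python
from wheezefactor import SyntheticSegmentSpec, generate_wheeze, classify_segment

seg = generate_wheeze(SyntheticSegmentSpec(
    "MP2", f0=250.0, n_harmonics=2, duration=0.5, seed=1))
result = classify_segment(seg, seed=0)
print(result.label, result.mp_subtype)
print("eta =", result.detail["eta"])
print("peaks (Hz):", [round(f, 1) for f in result.detail["fp"]])
print("delta (Hz):", round(result.detail["delta"], 1))
```

prints

```
MP Type2
eta = 3
peaks (Hz): [248.9, 500.7, 750.8]
delta (Hz): 35.0
```

The decomposition found three narrowband peaks in `ξ(f)`; the second and
third lie inside the tolerance intervals around twice and three times the
basal 248.9 Hz, so the segment is monophonic Type 2 — the planted ground
truth.

The same pipeline is scriptable from the shell:

```bash
wheezefactor simulate --n-mp1 2 --n-mp2 2 --n-pp 2 --snr-db inf --seed 0 --out-dir corpus/
wheezefactor classify corpus/segment_0000.wav --seed 0
wheezefactor evaluate --manifest corpus/manifest.csv --runs 5 --out report.json
```

The estimators compose with scikit-learn: `CLRNMF` is a decomposition
(`fit` on an F×T spectrogram matrix, fitted factors in `wheeze_basis_`,
`resp_basis_`, …) and `WheezeClassifier` a stateless classifier
(`predict` over a list of `AudioSegment`s), both with the usual
`get_params`/`set_params`/`clone` behaviour.

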