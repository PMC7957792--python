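# Methods

## Signal model and front end

An auscultation segment is modelled as an additive mixture
`x(t) = x_w(t) + x_r(t)` of a wheeze (one or more slowly varying
narrowband tones, 100–1000 Hz, > 100 ms) and normal respiratory sound
(wideband noise with most of its energy in 60–1000 Hz). All audio is
canonicalised to mono at 4096 Hz (channel mean, polyphase resampling)
before any spectral analysis, so every downstream constant — in
particular the 8 Hz bin→Hz map — can be fixed once.

The time-frequency representation is a Hamming-windowed STFT with
`N = 256` samples (62.5 ms), 10% inter-window overlap and a `2N = 512`
point DFT. The nominal 10% overlap is 25.6 samples; it is rounded to 26,
giving a hop of 230 samples, the nearest integer realisation of the
stated overlap. Frames are full windows only — trailing samples shorter
than `N` are dropped — so `T = 1 + floor((L − N)/230)`. The magnitude
(not power) spectrogram is band-limited to 100–1000 Hz (bins 13–125 of
the one-sided spectrum, `F = 113`) and then divided by its grand mean so
that `mean(X) = 1`. Normalising *after* band-limiting makes the
penalty weights act on the statistics of the analysed band only; since
the normalisation is a pure rescaling, the order affects nothing except
the effective weight scale, and the chosen order keeps that scale
independent of out-of-band energy. The whole front end is invariant to
the recording level.

## Stage I: constrained low-rank NMF

`X` is factorised as `X ≈ B_R A_R + B_W A_W` with `K_w = 4` wheeze
components and `K_r = 32` respiratory components, minimising

    D = D_KL(X | X̂) + α ψ(B_W) + λ φ(A_W) + β φ(B_R),

* `D_KL(X|X̂) = Σ [X log(X/X̂) − X + X̂]`, the generalised
  Kullback–Leibler divergence (scale-relevant, with the `0·log 0 = 0`
  convention);
* `ψ(B) = Σ_{f,k} B[f,k]`, the L1 sparseness penalty pushing wheeze
  bases toward few active bins;
* `φ(A) = Σ_k σ_k^{-2} Σ_t (A[k,t] − A[k,t−1])²` with
  `σ_k² = (1/T) Σ_t A[k,t]²`, the RMS-normalised smoothness penalty,
  applied along time to `A_W` and along frequency to `B_R`. The σ
  normalisation makes φ invariant to the numeric scale of each
  component; all-zero components contribute zero.

Defaults `α = λ = β = 0.5` and `M = 50` iterations. The component counts
follow the recommended operating range (2 ≤ K_w ≤ 6, K_r ≥ 32): few
wheeze bases compact the narrowband peaks for later analysis, while the
many respiratory bases — individually forced smooth in frequency — model
the wideband interference.

### Multiplicative updates

Each iteration updates `B_W`, `B_R`, `A_W`, `A_R` in that order, each
step using the freshest matrices, with the usual
`θ ← θ ⊙ (∂D/∂θ)⁻ / (∂D/∂θ)⁺` construction from the negative/positive
parts of the gradient. The KL parts are the standard Lee–Seung terms.
For the penalties:

* `∂ψ/∂B_W = 1` enters the denominator of the `B_W` rule.
* The smoothness gradient is derived from φ by the quotient rule,
  treating `σ_k` as part of the differentiated expression. Writing
  `E_k = Σ_t A[k,t]²` and `D_k = Σ_t (A[k,t] − A[k,t−1])²`, the positive
  part is `(T/E_k)·{4A interior, 2A at the two ends}` and the negative
  part `(T/E_k)·2·(neighbour sums) + (2T D_k/E_k²)·A` (transposed
  analogue for `B_R` along frequency).

This split is validated numerically rather than symbolically: on seeded
random 113×17 problems at the defaults the recorded objective is
non-increasing at every one of the 50 iterations (relative tolerance
1e−9, 20/20 problems) — the acceptance suite re-runs this check. With
`α = λ = β = 0` every rule reduces exactly (to machine precision) to the
standard KL-NMF multiplicative update applied blockwise.

Numerical choices: all denominators and the reconstruction inside logs
are floored at `ε = 1e−12`; the four factors are initialised uniform on
(0, 1] from a seeded generator — strictly positive draws avoid
multiplicative lock-in at zero; the objective is recorded at
initialisation and after each full iteration; `tol = 0` by default (all
`M` iterations run, matching the observation that the reconstruction
error has converged by then), `tol > 0` enables an early stop on
relative objective change. Matrices with `T = 1` (a 100 ms segment
yields a single full frame) are supported: the temporal penalty has no
adjacent-frame terms there and contributes zero.

A property worth knowing: the objective is invariant under
`B_W → B_W/c`, `A_W → c·A_W` except for the L1 term, so the updates
slowly deflate the scale of `B_W` rather than sparsifying its shape; the
penalty's practical effect is transient. This is inherent to the printed
objective. A per-iteration unit-norm basis renormalisation was evaluated
and rejected: it neither reduced the relative noise residue in ξ nor
preserved the monotone descent of the objective.

### Spectral energy distribution

`ξ(f) = Σ_k B_W[f,k]` collapses all wheeze bases into one spectrum.
Summing over components makes the classifier insensitive to whether the
decomposition compacted the peaks into one basis or split them across
several.

## Stage II: harmonic-structure classification

Peaks of `ξ(f)` are local maxima with topographic prominence at least
`prominence_fraction · max(ξ)` (default 0.05 — the classifier's main
free parameter; it suppresses numerical ripple without hiding genuine
secondary components). ξ is zero-padded by one bin on each side so
band-edge maxima are detectable. The basal peak is the lowest-frequency
detection; its main-lobe width Δ is measured at the half-prominence
reference height with linearly interpolated crossings. Peak frequencies
are refined to sub-bin precision by quadratic interpolation through the
three bins around each maximum: the harmonic test below multiplies the
basal localisation error by the harmonic index `z`, and at 8 Hz
resolution a half-bin error alone would consume the whole Δ/2 tolerance
by `z = 4`, misclassifying exactly-harmonic inputs.

With `η` detected peaks: `η = 1` is MP Type 1. Otherwise the tolerance
intervals `Λ_z = [z·f_p(1) − Δ/2, z·f_p(1) + Δ/2]` are built for
`z = 1..η` — the width is Δ for every `z`; it does not grow with the
index — and the segment is MP (Type 2) iff each non-basal peak `z` lies
inside its own `Λ_z`, PP otherwise. Consequences of this strict indexed
pairing: a pattern with a missing harmonic (f₀ and 3f₀ but no 2f₀)
classifies PP, and any spurious extra peak breaks the pairing for all
later peaks. The decision is invariant to rescaling ξ.

With `n_runs > 1` the pipeline classifies under consecutive seeds and
reports the majority label, ties broken toward PP (the clinically
distinct COPD alarm); experiment-level accuracy averaging (below) is
independent of this.

## Synthetic data

The generator emulates the kind of corpus the method targets — no
public MP/PP-labelled database exists — with three planted classes:
MP1 (single tone), MP2 (basal tone plus 1–3 exact integer harmonics,
amplitudes rolling off as 1/h), PP (2–5 tones, mutually non-harmonic).
Basal frequencies are uniform in [150, 450] Hz so harmonics stay below
1000 Hz; durations uniform in [0.1, 0.7] s; all at 4096 Hz.

Tones carry a shared slow sinusoidal frequency drift (depth 10 Hz, rate
2 Hz, random phase) applied as a **common additive offset, mean-centred
over the segment**, plus a raised-cosine on/off envelope. Two deliberate
emulator simplifications: (i) real harmonics drift proportionally to
their index, but a proportional drift moves the 3rd harmonic by ±30 Hz —
far outside the fixed-width Λ_z tolerance — so the shared additive
offset keeps every component within one to two analysis bins of nominal,
matching the "slowly varying" character the classifier assumes; (ii)
mean-centring makes each partial's time-averaged frequency equal its
declared ground-truth frequency, so labels describe the signal exactly.
PP tones are rejection-sampled so no component lies within 32 Hz (four
bins) of an integer multiple of the lowest — the guard must exceed the
worst-case half main-lobe width of a drifting basal peak (≈ 18 Hz) plus
localisation error, otherwise a nominally non-harmonic peak could land
inside a tolerance interval and the PP label would be wrong by
construction.

Respiratory noise is Gaussian noise band-passed to 60–1000 Hz with a
−6 dB/octave tilt above 200 Hz and a slow breath amplitude modulation
(0.2–0.4 Hz); ≥ 90% of its power lies in band. Mixtures are scaled so
the wheeze-to-noise power ratio over the 60–1000 Hz band matches the
requested SNR exactly; the repository's reference study condition is
5 dB.

What the generator does **not** emulate: airway acoustics (formant-like
coloration, transmission through the chest wall), crackles and other
discontinuous sounds, recording-chain artefacts, heart sounds, and the
correlation between wheeze loudness and noise that clinician-curated
corpora exhibit. Passing the synthetic study therefore demonstrates the
pipeline's mechanics, not clinical performance.

## Evaluation

Confusion counts treat PP as the positive class: TP/FP count PP segments
classified PP/MP, TM/FM count MP segments classified MP/PP, with
TM1/TM2/FM1/FM2 the restriction to MP subtypes. Accuracy rates are
ACCG = (TP+TM)/(all), ACCP = TP/(TP+FP), ACCM = TM/(TM+FM), and the two
subtype rates; arithmetic is exact (rationals), and zero-denominator
rates are reported as undefined rather than zero. An experiment
classifies every segment once per run (run `r` reseeds the factorisation
with `base_seed + r`), computes per-run rates and averages the *rates*
across runs (pooled-count rates are attached as a secondary view, since
the per-segment aggregation of the multi-run protocol is otherwise
underdetermined); undefined rates are excluded from averages with a
warning.

## Operating envelope and limitations

Measured on the 60-segment reference study (20/20/20): all rates are
100% noise-free and at 25 dB, ≈ 98% at 20 dB, ≈ 89% at 15 dB, ≈ 66% at
10 dB, ≈ 40% at 5 dB (ACCP stays at 100%; errors are MP→PP). The
mechanism is irreducible within this method: the time-averaged
within-band roughness of the noise periodogram scales as `T^(−1/2)` and,
for segments of at most 12 frames at 5 dB in-band SNR, produces spurious
ξ peaks of 5–15% of the wheeze maximum — above the 5% prominence
threshold. The roughness can neither be absorbed by the
smooth-in-frequency respiratory bases nor rejected by the (scale-soluble)
sparse wheeze bases; the same spurious structure appears in the raw
time-averaged spectrum. The classifier is therefore reliable on
prominent wheezes (roughly ≥ 15–20 dB in-band) and degrades on faint
ones, always erring toward PP.

Other known limitations: recordings longer than one wheeze episode must
be segmented upstream; wheeze *detection* (is there a wheeze at all?) is
out of scope — an all-noise input will still be forced into an MP/PP
label; the strict indexed harmonic pairing mislabels harmonic patterns
with missing low harmonics; and Δ is a single fixed tolerance for all
harmonic indices although physical jitter grows with the index.
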