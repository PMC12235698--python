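# Methods

## Problem and model

De novo peptide sequencing reads an MS2 fragment spectrum — a list of
(m/z, intensity) peaks from a fragmented precursor peptide — directly into a
residue sequence, without a protein database. The informative structure is
the fragment ladder: consecutive b-ions (and, mirrored, y-ions) differ by
exactly one monoisotopic residue mass, so the *differences* between peaks,
not their absolute positions, carry the sequence.

`pairnovo` implements an encoder–decoder transformer in which the encoder's
self-attention is explicitly told about those differences. For a spectrum of
N peaks:

1. **Peak features.** Each peak's m/z and intensity are expanded into fixed
   sinusoidal (Fourier) features of dimension r_m and r_I, concatenated and
   linearly projected to the model width d. No positional encoding is added,
   so the encoder is permutation-equivariant over peaks.
2. **Pairwise features.** The full difference matrix Δm[i,j] = m_i − m_j is
   Fourier-encoded into Φ ∈ R^(N×N×r_pw′). The sin channels are odd and the
   cos channels even under i↔j, mirroring Δm's antisymmetry.
3. **Pairwise attention bias.** A two-layer MLP with SiLU activation,
   f_pw : r_pw′ → 2·r_pw → r_pw, shared across all encoder layers and heads,
   maps Φ to a latent pair tensor z (computed once per spectrum). Each
   encoder layer l applies its own affine head g_l : r_pw → h and adds the
   result inside the softmax:

       A_pw = softmax(Q Kᵀ / √d_h + g_l(f_pw(Φ)))

   Padded peaks are masked to −∞ after the bias is added, so a padded key
   never receives attention regardless of bias values.
4. **Decoder.** A standard autoregressive transformer decoder (causal
   self-attention + cross-attention to the encoder latents) emits residue
   tokens. Its start-of-sequence input conditions on the precursor: the
   adjusted precursor mass, Fourier-encoded with the m/z configuration,
   concatenated with a learned charge embedding and projected to d.

The matched **base** model is identical with the bias pathway removed; with
the pairwise parameters zeroed and remaining weights shared, the two
variants produce identical outputs (a tested reduction).

### Parameter budget

The bias pathway adds (r_pw′ + r_pw)(2·r_pw + 1) parameters for the shared
MLP plus D·h·(r_pw + 1) for the per-layer heads. At the shipped defaults
(r_pw′ = 128, r_pw = 64, D = 9, h = 8) that is 29,448 parameters — about
0.1% of the model. The closed form coincides with the structural count of
the instantiated tensors exactly when r_pw′ = 2·r_pw, the relation the
default configuration satisfies; the acceptance script verifies the budget
by enumerating the instantiated tensors, not by trusting the formula. The
base encoder at full size (r_m = 1024, r_I = 256, d = 512, 8 heads, 9
post-norm blocks, MLP hidden width 1024, including the 1280→512 peak
projection) counts 19.6 M trainable parameters; the decoder's nine blocks
alone count 28.4 M because of the extra cross-attention.

The MLP hidden width of 1024 (2×d) is reverse-derived: it is the standard
width that reproduces the 19.6 M encoder count (4×d would give ≈28 M).

## Numerical and design choices

* **Fourier ladder.** A scalar is encoded at r/2 geometrically spaced
  wavelengths; the first half of the vector is sin, the second cos of the
  same arguments (the source formulation prints sin for both halves; the
  cos half is the conventional reading, and `FourierConfig(strict_sin=True)`
  reproduces the literal variant). The wavelength ladder is
  λ(p) = λ_min (λ_max/λ_min)^(p/r) with endpoints λ(0)=λ_min, λ(r)=λ_max;
  features sample its even indices so each half sweeps the full
  λ_min…λ_max range. The full sweep matters in practice: restricting the
  features to the lower half of the ladder caps every wavelength near
  √(λ_min·λ_max) (≈3 Da for the m/z configuration), which leaves only
  fast, jitter-sensitive phase channels and measurably slows learning for
  both model variants. Defaults: r_m = 1024 over 0.001–10,000 Da,
  r_I = 256 over 10⁻⁶–1, r_pw′ = 128 sharing the m/z wavelengths.
* **Precursor mass convention.** MGF PEPMASS fields are inconsistent across
  community files, so the model input mass is always re-derived as
  precursor m/z × charge, deliberately *without* subtracting the charge's
  proton masses — a constant offset the model absorbs. The evaluation-side
  50 ppm filter, by contrast, compares the predicted peptide mass against
  the proton-corrected neutral mass (m/z·z − z·1.00727647 Da), the only
  chemically coherent reading at ppm scale; `ppm_reference="adjusted"`
  exposes the uncorrected alternative.
* **Attention masking.** Masking uses a finite −10⁹ logit; after the
  softmax's max-shift, masked entries underflow to exactly zero weight, and
  fully padded query rows come out uniform instead of NaN.
* **Optimization.** Adam (β = 0.9/0.999, ε = 10⁻⁸), cross entropy under
  teacher forcing (gold prefixes, EOS position included, PAD masked),
  learning rate warmed up linearly and then held constant. Full-scale
  defaults: batch 100, peak 2·10⁻⁴ after 20,000 steps. Per-epoch validation
  is scored by peptide precision under greedy decoding, and the
  best-validation checkpoint is returned.
* **Beam search** scores hypotheses by mean token log-probability with the
  EOS step included; hypotheses reaching the length cap are force-terminated
  with their EOS log-probability so finished and capped hypotheses compete
  on the same footing. Width 1 reduces exactly to greedy decoding.
* **Initialization** is fan-in uniform U(±1/√fan_in) for all linear maps,
  driven by an explicit seed; fixed seeds reproduce loss trajectories
  bit-exactly on one machine.
* The tensor core is a compact reverse-mode autodiff engine on numpy
  (float64 throughout), verified against central finite differences.

## Evaluation

Residue matching follows the DeepNovo convention: a matched pair must agree
in residue mass within 0.1 Da and in prefix *or* suffix mass within 0.5 Da.
The implementation is the field's two-pointer walk — a forward pass in
prefix-mass coordinates, then a backward pass in suffix-mass coordinates
down to the last forward match. Against an exhaustive monotone-pairing
dynamic program it agrees on >99.9% of random peptide pairs; the rare
exceptions are configurations where prefix- and suffix-consistent pairs
interleave, which no single two-pass walk can pair.

Peptide confidence is the mean softmax probability of the emitted residues,
overridden to −1 when the 50 ppm precursor filter fires (strictly more than
50 ppm). Precision at coverage c sorts by confidence (stable, descending),
keeps the top ⌈c·N⌉ spectra and reports the matched fraction; at c = 1 every
spectrum counts in the denominator.

## Synthetic data: what it does and does not emulate

The generator samples peptides i.i.d. from a 10-residue alphabet
(G, A, S, P, V, T, L, N, D, K — pairwise mass-distinct far beyond the
jitter scale), lengths uniform on 5–8, and builds the singly protonated
b/y ladder with unit intensities and a charge-2 precursor. Corruption:
each peak dropped with probability 0.1, surviving m/z jittered with
σ = 0.001 Da, and 5 uniform noise peaks added in 50–1500 m/z. These
defaults are the package's standard desk-scale task: hard enough that a
tiny base model cannot solve it instantly, easy enough that training is
observable in minutes on one CPU.

Not modeled: realistic fragment intensities, isotope envelopes, a/c/x/z
ions, neutral losses, higher precursor charges, co-fragmentation chimeras.
Consequently, passing desk-scale tests demonstrates that the architecture,
training loop and metrics are correct and that the pairwise bias helps on
ladder-structured data — it does not certify real-spectrum accuracy.

The `ladder_oracle` is an independent non-neural solver used as a test
oracle: a dynamic program over peaks that reads the b-ion ladder from the
proton mass to the precursor-derived total, restricted to maximal-length
paths and disambiguated by how many observed peaks a candidate's full b/y
theory explains. Residual failures are genuine chemical ambiguities: G+G
vs N residue-sum coincidences and block swaps whose alternative reading is
fully supported by complementary ions (~1–2% of random peptides, depending
on the draw).

## Desk-scale ablation

The headline comparison trains matched tiny models (d = 64, 8 heads, 2
encoder and 2 decoder blocks, r_m = 128, r_I = 32, r_pw′ = 32, r_pw = 16,
dropout 0.1) on 5,000 synthetic spectra (4,800 train / 200 validation) for
a fixed budget of 1,500 Adam steps at batch 32 (peak LR 10⁻³, 100-step
warmup), then scores peptide precision at 100% coverage on 500 held-out
spectra, repeated for seeds 0, 10 and 20. The budget deliberately stops
mid-convergence: the pairwise bias hands the encoder every m/z difference
up front, so its advantage is largest while the base model is still
learning to recover differences from absolute encodings; with unbounded
training on this easy task the gap narrows. The packaged test asserts the
mean precision ordering (pair-biased > base), not absolute values, which
vary a few points across seeds.

## Known limitations

* Pure-numpy training is single-threaded BLAS-bound; the full-size
  configuration is instantiable (parameter counts are tested) but not
  practically trainable here — the library targets desk-scale studies of
  the mechanism.
* No KV caching in decoding; greedy decoding re-runs the decoder per step.
* The MGF dialect is the annotated-benchmark subset (TITLE/PEPMASS/CHARGE/
  SEQ + peak lines); mzML/mzXML are out of scope.
* Modified residues are supported in the token grammar (`X[+delta]`) and
  mass bookkeeping, but the synthetic generator emits unmodified peptides
  only.
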