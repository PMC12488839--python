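# hdemg-hypoxia

Motor-unit analysis of high-density surface EMG (HD-sEMG) during maximal
isometric contractions under graded normobaric hypoxia — as a tested,
reusable Python pipeline, from the multichannel signal to per-motor-unit
discharge rate and conduction velocity, through hypoxic cardiorespiratory
response metrics, to the repeated-measures statistics.

## Who this is for

Neuromuscular physiologists who record HD-sEMG grids (here: 13 rows × 5
columns, 8 mm inter-electrode distance, 2048 Hz, monopolar μV) over the
knee extensors while participants perform repeated 5-s maximal
contractions in three inspired-oxygen conditions — normoxia (CON), light
hypoxia (H1, FiO₂ ≈ 15%) and mild hypoxia (H2, FiO₂ ≈ 13.5%) — and want a
fully scripted, operator-independent version of the standard analysis
chain. Because no raw recordings of this kind are publicly deposited, the
package includes a synthetic-data generator that provides ground truth for
every stage, so each step is validated by parameter recovery rather than
by eye.

## The pipeline

1. **`simulate`** — motor-unit (MU) pools with condition- and
   sex-dependent discharge rates (~10–25 pps) and conduction velocities
   (~3–6 m/s); biphasic action potentials propagating bidirectionally
   from an innervation zone along the grid columns (inter-row delay
   = IED / CV, sub-sample shifts via frequency-domain phase); 9 × (5 s
   on / 15 s off) contraction bouts; breath-by-breath HR, V̇e, V̇O₂ with
   outlier contamination; endpoint SpO₂ per condition
   (97.1 / 91.3 / 86.9 % means).
2. **`preprocess`** — 20–500 Hz zero-phase Butterworth band-pass (2nd
   order), resting-noise QC (RMS < 20 μV), contraction segmentation
   (protocol or envelope detection), selection of the 2 highest-RMS
   contractions among the first 5, and the double-differential montage
   along columns: `DD(r,c) = x(r−1,c) − 2x(r,c) + x(r+1,c)`.
3. **`decompose`** — blind source separation of the band-passed monopolar
   observations (convolution-kernel-compensation / fixed-point ICA family:
   channel extension, whitening, skewness contrast with deflation,
   spike-triggered refinement), quality-gated by the pulse-to-noise ratio

   PNR = 10·log₁₀( mean ŝ² at spikes / mean ŝ² off spikes ) ≥ 28 dB,

   then deduplicated. The gate + dedup replace manual editing.
4. **`muprops`** — instantaneous discharge rate IDRᵢ = 1/(tᵢ₊₁ − tᵢ),
   smoothed with a unit-sum 4-discharge Hanning kernel → mean smoothed
   discharge rate; spike-triggered MUAP averaging (50 ms window, DD
   montage); channel selection per column (adjacent cross-correlation
   ≥ 0.8, consistent delay sign, no innervation-zone or end-of-fiber
   channels); maximum-likelihood delay estimation →
   CV = IED·fs/θ with θ the inter-channel delay in samples.
5. **`cardioresp`** — breath-by-breath cleaning (rolling median/MAD,
   interpolation), exercise-phase medians, and the response metrics

   HVR = (V̇e_H − V̇e_N)/(SpO₂_N − SpO₂_H),  HCR = (HR_H − HR_N)/(SpO₂_N − SpO₂_H),

   plus simple differences ΔIDR, ΔCV, ΔV̇O₂ (hypoxia − normoxia).
6. **`stats`** — z-score (±2.5) outlier filter and log transform of IDR;
   REML linear mixed models `response ~ condition * sex + (1 | participant)`
   with Satterthwaite degrees of freedom, η²p and Cohen's
   f = √(η²p/(1−η²p)), Nakagawa marginal/conditional R², Holm-corrected
   pairwise contrasts; Pearson correlation tables.

## Worked example

```python
from hdemg_hypoxia.simulate import decomposition_fixture
from hdemg_hypoxia.preprocess import bandpass, double_differential
from hdemg_hypoxia.decompose import decompose, rate_of_agreement
from hdemg_hypoxia.muprops import compute_idr, smooth_idr, mu_cv

specs, trains, rec = decomposition_fixture(n_mus=5, seed=42)
filtered = bandpass(rec)
res = decompose(filtered, seed=42)
dd = double_differential(filtered)
by_id = {s.mu_id: s for s in specs}
for tr in res.trains:
    truth = max(trains, key=lambda t: rate_of_agreement(tr, t))
    spec = by_id[truth.mu_id]
    dr = smooth_idr(compute_idr(tr)).mean_smoothed_dr
    cv = mu_cv(dd, tr)
    print(f"{tr.mu_id}: PNR {tr.pnr:.1f} dB, agreement "
          f"{rate_of_agreement(tr, truth):.3f}, "
          f"DR {dr:.1f} pps (truth {spec.mean_dr:.1f}), "
          f"CV {cv.cv:.2f} m/s (truth {spec.cv_true:.2f})")
```

prints:

```
mu0: PNR 29.5 dB, agreement 1.000, DR 11.5 pps (truth 11.4), CV 5.32 m/s (truth 5.36)
mu1: PNR 28.4 dB, agreement 1.000, DR 14.9 pps (truth 14.7), CV 3.66 m/s (truth 3.63)
mu2: PNR 28.2 dB, agreement 1.000, DR 13.0 pps (truth 12.7), CV 4.02 m/s (truth 4.04)
mu3: PNR 28.2 dB, agreement 1.000, DR 14.8 pps (truth 14.9), CV 4.97 m/s (truth 4.97)
```

Four of the five simulated motor units are recovered with perfect
discharge-time agreement, pass the 28 dB quality gate, and their mean
smoothed discharge rates and conduction velocities match the generating
parameters to within a few percent.

## The full analysis

Numbered drivers under `analysis/` run the study end to end on synthetic
data and write tables under `results/sim/` (bulky raw EMG goes to
`scratch/`):

```bash
python analysis/01_simulate.py --seed 1   # demo EMG sessions + 18-participant cohort
python analysis/02_preprocess.py          # band-pass, QC, contraction selection
python analysis/03_decompose.py --seed 1  # spike trains + decomposition log
python analysis/04_mu_properties.py       # per-MU DR and CV vs ground truth
python analysis/05_responses.py           # HVR, HCR, ΔIDR, ΔCV, ΔVO2
python analysis/06_stats.py               # mixed models, post-hocs, correlations
```

On the default cohort this detects the injected condition effect on both
discharge rate and conduction velocity (mixed-model condition term
p < 0.001 for CV, Holm-corrected H2 − CON contrast +0.20 m/s), the large
sex effect on CV (η²p ≈ 0.5), and positive HVR/HCR in all participants.

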