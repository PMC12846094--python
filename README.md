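# semgfatigue

Surface-EMG muscle fatigue classification pipeline: a tested, reusable
library + CLI covering synthetic cohort generation, signal conditioning,
compound fatigue labeling, time/frequency feature extraction, continuous
wavelet transform (CWT) scalogram imaging, and leakage-safe
leave-one-subject-out (LOSO) classification.

## What it does

1. **`semgfatigue.synth`** — seeded synthetic sEMG cohorts (4 channels: BB,
   BRA, TRI, DEL at 1000 Hz) whose signals carry the two signatures of a
   fatiguing contraction: rising amplitude and a power spectrum compressing
   toward low frequencies. Includes per-channel MVC calibration trials and a
   0–10 Borg self-report stream.
2. **`semgfatigue.preprocessing`** — 4th-order Butterworth band-pass
   (20–450 Hz), linear envelope (rectification + 10 Hz low-pass), and MVC
   normalization (mean of three maximal-contraction trial values).
3. **`semgfatigue.segmentation`** — 2500 ms sliding windows with a 250 ms
   hop; compound labels from the task-progress third and the binned Borg
   score, disagreements conservatively resolved to the higher class;
   consensus filtering; LOSO splits with hard anti-leakage assertions.
4. **`semgfatigue.features`** — 8 features per channel window (RMS, MAV, ZC,
   MNF, MPF, WL, MDF, WAMP) assembled into the 32-dimensional vector used by
   the classical baselines.
5. **`semgfatigue.scalogram`** — complex-Morlet CWT (256 scales), rendered
   as 224 × 224 RGB images; Haralick + Hu texture descriptors for the
   classical-classifier ablation route.
6. **`semgfatigue.classification`** — five sklearn baselines with the
   published per-task hyperparameters, plus an image classifier: a pluggable
   convolutional backbone and a dense head
   (GAP → 256 → dropout 0.4 → 128 → dropout 0.4 → softmax). The default
   backbone is a small scratch CNN implemented in NumPy, so the whole
   pipeline trains on one CPU; ImageNet backbones can be registered as
   plugins.
7. **`semgfatigue.evaluation`** — LOSO experiment runner (split before any
   windowing; per-fold segment-provenance checks), confusion matrices,
   accuracy/precision/recall/F1 (macro), one-vs-rest ROC and
   precision–recall curves with AUCs, and full-vs-consensus comparisons.

## CLI

```bash
semgfatigue simulate  --subjects 5 --seed 1 --out data/ --duration-s 60
semgfatigue preprocess --in data/ --out processed/
semgfatigue segment   --in data/ --out segments.tsv --task three
semgfatigue features  --in data/ --out features.tsv
semgfatigue scalogram --in data/ --out scalograms/ --size 224
semgfatigue evaluate  --in data/ --task binary --model rf --out run.json
semgfatigue evaluate  --in data/ --task binary --model cnn --epochs 10
semgfatigue report    --in run.json
```

## Notes

- Everything is seeded; identical (profile, seed) pairs give bit-identical
  recordings, and training runs are reproducible.
- The end-to-end acceptance tests use a scaled-down 5-subject synthetic
  cohort (30 s sessions) so the suite runs in minutes on one CPU; the
  library defaults correspond to the full-scale protocol (~4–5 min
  sessions, 20 subjects).
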