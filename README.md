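# tseeg

Tsallis-entropy features and KNN classification for binary emotion
recognition from multichannel EEG.

## The problem

EEG-based emotion recognition pipelines commonly summarise each channel and
rhythm of a trial with a nonlinear complexity statistic and feed those
features to a simple classifier. `tseeg` implements one such pipeline end to
end for two emotional states (positive vs negative film-clip responses, as in
the 62-channel, 200 Hz SEED recordings): rhythm decomposition into theta
(4–7 Hz), alpha (8–15 Hz), beta (16–31 Hz), gamma (32–55 Hz) and the full
0–75 Hz range; sliding-window Tsallis entropy features; k-nearest-neighbour
classification under repeated stratified holdout; and per-channel, per-rhythm
and per-scalp-region performance analysis.

The statistic at the core is the nonextensive (Tsallis) entropy of the
window-local amplitude distribution,

    E_ts(q) = (1 − Σᵢ Pᵢ^q) / (q − 1),      q > 0, q ≠ 1,

where the Pᵢ are equal-width amplitude-histogram probabilities inside one
sliding window. E_ts reduces to Shannon's −Σ Pᵢ ln Pᵢ as q → 1 and obeys the
pseudo-additivity rule E(X∪Y) = E(X) + E(Y) + (1−q)E(X)E(Y) for independent
subsystems; q > 1 (the regime used here, q ∈ {2, 3, 4}) weights the statistic
toward subextensive, long-range-correlated dynamics. The mean and sample
variance of the per-window entropy series form each channel-rhythm feature
pair.

Because the SEED recordings themselves are access-gated, the package ships a
first-class synthetic generator (`tseeg.synthetic`) that emulates their shape
— 62 channels, 200 Hz, one-minute trials, two classes — with a *plantable*
class difference in band-limited complexity (orderly gamma oscillation vs
gamma-band noise on chosen electrodes), so every pipeline stage is testable
without a download.

## Worked example

Plant a subtle complexity difference (gap 0.05) in the gamma band of four
temporal electrodes, extract q = 3 entropy features, and classify:

```python
import tseeg as T
from tseeg.entropy import EntropyConfig, build_feature_table
from tseeg.classify import SplitSpec, repeated_holdout

profiles = T.gamma_discriminative_profiles(gap=0.05)
dataset = T.generate_dataset(profiles, n_subjects=5, trials_per_class=4, seed=42)
print(f"{len(dataset.trials)} trials, {dataset.trials[0].n_channels} channels, "
      f"{dataset.trials[0].duration_s:.0f} s at {dataset.trials[0].rate:.0f} Hz")

banded = [T.extract_bands(tr, target_rate=None, crop_seconds=None,
                          bands=(T.BandSpec("gamma", 32, 55),))
          for tr in dataset.trials]
table = build_feature_table(banded, EntropyConfig(q=3))
print(f"feature table: {table.shape[0]} rows x {table.shape[1] - 4} features")

summary = repeated_holdout(table, SplitSpec(seed=42), k=10)
print(f"mean accuracy {summary.mean_accuracy:.3f}  max accuracy {summary.max_accuracy:.3f}")
print(f"mean F-score  {summary.mean_f_score:.3f}  mean sensitivity {summary.mean_sensitivity:.3f}")
```

prints

```
40 trials, 62 channels, 60 s at 200 Hz
feature table: 40 rows x 124 features
mean accuracy 0.810  max accuracy 1.000
mean F-score  0.802  mean sensitivity 0.800
```

Forty one-minute trials yield a 40 × 124 feature table (62 channels × {mean,
variance} in the gamma band). Ten stratified 80/20 holdout repetitions with a
k = 10 Euclidean KNN average 81% accuracy — the subtle planted structure is
recovered well above the 50% chance level, with the best single split
separating the classes perfectly.

The same pipeline is available from the shell:

```
tseeg synth data/ --subjects 5 --trials-per-class 4 --seed 42
tseeg features data/ features.csv --q 3
tseeg classify features.csv summary.json --k 10
tseeg evaluate data/ results/ --axes channel,band,region --q-values 2,3,4
tseeg topology results/results_channel.csv topo.json --band gamma
```

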