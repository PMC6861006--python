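# vesipool

Quantification pipeline for synaptic-vesicle (SV) **super-pool** dynamics:
the exchange of vesicles between presynaptic boutons and the mobile axonal
pool. The package implements the three measurement channels such studies
rely on — FRAP recovery kinetics at boutons, kymograph-based axonal
transport statistics, and miniature postsynaptic current (mEPSC/mIPSC)
analysis — together with a synthetic-data generator with known ground
truth, so every stage can be validated end to end without microscope or
patch-clamp data.

Intended users: neurobiology labs quantifying presynaptic vesicle mobility
from spinning-disk time-lapse imaging and voltage-clamp recordings, and
anyone who needs a tested, scriptable replacement for the usual
ImageJ-macro + spreadsheet workflow.

## The model at the core

A bleached bouton refills from the unbleached axonal super-pool. The
normalized fluorescence recovery is modelled as a two-component saturating
exponential parameterized by half-lives:

```
R(t) = P · [ f · (1 − 2^(−t/h_f)) + (1 − f) · (1 − 2^(−t/h_s)) ]
```

* `P` — plateau / mobile fraction: the fraction of the bleached signal that
  is replenished as t → ∞ (the immobile fraction is `1 − P`);
* `f` — share of the plateau recovered by the fast component;
* `h_f`, `h_s` — fast and slow half-lives in seconds (`h = τ·ln 2`).

Raw bouton traces are background-subtracted, corrected for acquisition
photobleaching by the ratio to a whole-cell reference, and scaled so the
pre-bleach mean is 1 and the immediately-post-bleach frame is 0.
Experiments with more than 60% reference photobleaching are discarded.
Group differences in kinetics are tested with the **extra sum-of-squares F
test**: one biexponential fitted to all groups jointly versus one per
group,

```
F = ((SS_shared − SS_separate) / (df_shared − df_separate)) / (SS_separate / df_separate)
```

with `df_shared = N − 4` and `df_separate = N − 4k` for `k` groups.
Transport is quantified from kymographs (track slopes in µm/s) and from
the cumulative cross-section traffic: per-frame integrated density across
a line normal to the axon, background-subtracted, divided by the mean of
the 10 lowest frames, summed over the sequence. Minis are detected by
sliding scaled-template matching (Clements–Bekkers criterion: fitted
template scale over the standard error of the fit).

## Worked example

Simulate one FRAP field (five boutons, true plateau 0.7, fast fraction
0.4, half-lives 60 s / 1200 s, 3% noise) and fit the pooled recovery:

```sh
$ vesipool sim --out demo_traces.csv --seed 2 --noise-sd 0.03
wrote 5 traces (true plateau 0.7) to demo_traces.csv

$ vesipool frap --traces demo_traces.csv
{
  "plateau": 0.7516691739646391,
  "fast_fraction": 0.37107892914241064,
  "half_fast_s": 79.3719552126511,
  "half_slow_s": 1674.9981094297143,
  "residual_ss": 0.36644227621399994,
  "n_points": 105,
  "n_traces_pass": 5
}
```

The fitted plateau says ~75% of the bouton's vesicle cluster is mobile
(exchanged with the super-pool within the 73-min recording); ~37% of that
exchange happens with a ~79 s half-life, the rest over ~28 min. With only
5 noisy traces the estimates scatter around the generating truth (0.7,
0.4, 60 s, 1200 s); pooling 20+ traces tightens them to a few percent (see
`tests/test_acceptance.py`). Multi-group comparisons, the F test, the
68-min timepoint comparison and report figures are driven from one YAML
config via `vesipool run --config run.yaml`; see
`vesipool.pipeline.RunConfig` for the stage list.

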