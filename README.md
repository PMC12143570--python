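# burstfusion

A seeded simulator and model zoo for a burst-structured multisensory
detection task, for computational neuroscientists studying how observers
should combine evidence **across sensory channels and across time**.

## The problem

A hidden target moves in direction *M* ∈ {−1, +1}.  Over *n* = 200 time
steps, each of *N<sub>c</sub>* = 2 sensory channels reports a trinary
observation *X<sub>it</sub>* ∈ {−1, 0, +1}.  The target emits signal in
*bursts*: starts occur with per-step probability *p<sub>g</sub>* and last
*L* steps, where *L* is fixed at *k*, uniform, or follows a truncated
inverse-square ("Lévy") law.  While emitting, channels show the true
direction with probability *p<sub>c</sub>* = 0.45 and the wrong one with
*p<sub>i</sub>* = 0.01; while silent they show direction-free noise
(*p<sub>n</sub>* = 0.33 neutral).  The start rate is solved per variant from
the closed-form emission fraction

    p_e = P(E_t = 1 | trial contains signal) = 0.04

so every burst-length law delivers the same expected amount of signal and
differs only in how it is packaged in time.

The models are the classical fusion family plus temporal extensions, all
with a uniform `predict` contract:

| model | features | parameters (N_c = 2) | temporal structure |
|---|---|---|---|
| LF   | per-channel value counts | 6 | none |
| NLF  | joint per-step patterns | 9 | none |
| NLF_w | joint patterns over sliding w-step windows | 81 (w=2), 729 (w=3) | w-step window |
| RNN  | ReLU recurrence, summed outputs | 10,502 (100 hidden units) | unbounded |

plus an exact Bayes oracle for tiny trials (exhaustive marginalisation over
every hidden burst configuration), which upper-bounds all of them.

## Worked example

```python
import numpy as np
from burstfusion import fit_classifier, make_task_config
from burstfusion.task import batch_arrays, sample_batch

config = make_task_config(kind="fixed", k=3)        # p_g solved from p_e = 0.04
print(f"solved p_g = {config.p_g:.5f}")

m, x, e = batch_arrays(sample_batch(config, 20_000, seed=3))
m_test, x_test, _ = batch_arrays(sample_batch(config, 5_000, seed=99))
for name, kind, w in [("LF", "lf", 1), ("NLF", "nlf", 1), ("NLF_2", "nlf_w", 2)]:
    clf = fit_classifier(x, m, kind, w=w)
    acc = (clf.predict(x_test) == m_test).mean()
    print(f"{name}: {clf.n_parameters} parameters, accuracy {acc:.3f}")
```

prints

```
solved p_g = 0.01242
LF: 6 parameters, accuracy 0.671
NLF: 9 parameters, accuracy 0.694
NLF_2: 81 parameters, accuracy 0.713
```

With bursts of length 3, the 81-parameter two-step window model already
beats both order-free models: consecutive same-direction observations are
much less likely under noise than under an emission burst, and only the
windowed model can see them.  The same comparison at *k* = 1 shows no gain —
there is no temporal structure to exploit, and all three collapse to the
same accuracy (a calibration check in the test suite).

A command-line interface mirrors the library:

```bash
burstfusion normalize --task fixed --k 3 --n 200 --pe 0.04
burstfusion simulate --task levy --lmax 8 --n 200 --pe 0.04 --trials 1000 --seed 1 --out trials.csv
burstfusion grid --model nlf2 --train k1,k4,k8 --test k1,k4,k8 --seed 1 --out grids/
```

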