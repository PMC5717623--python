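# gestnet

Analysis pipeline for studying how overlap in gestural repertoires relates
to social bonding in fission–fusion primate groups, built around
focal-animal sampling data: scan records of party composition and
proximity, and continuously recorded intentional gestures.

Animal communication researchers ask whether pairs of animals that share
more of their gesture repertoire (repertoire *homogeneity*) also maintain
stronger social bonds, and whether unshared (*heterogeneous*) gestures play
a distinct role. `gestnet` provides the full chain for that question:
repertoire construction, dyadic overlap statistics, bonding-rate
construction, weighted social networks, and the permutation and
mixed-model inference those data require — plus a synthetic-data generator
that emulates the whole observational design so every stage is testable
without field data.

## The statistics at the core

**Dyadic repertoire overlap.** For two individuals with repertoires *A*
and *B* over a common gesture-type catalog:

- Cohen's κ = (p_o − p_e)/(1 − p_e) from the 2×2 presence/absence
  contingency table; κ = 1 for identical non-constant repertoires, −1 for
  exact complements, undefined (missing) when chance agreement p_e = 1.
- homogeneous repertoire size = |A ∩ B|; heterogeneous repertoire size =
  |A \ B| + |B \ A| (symmetric in the dyad ordering).

**Bonding rates.** Each instantaneous scan stands for a 2-minute interval,
so a dyad's rate of a behaviour in minutes per hour co-present in a party
is 60 · n_behaviour / n_party, bounded by [0, 60], directed (computed from
follows where the first member was focal), and missing for dyads never
co-present.

**Inference.** Dyadic observations are not independent, so associations
between networks are tested with MRQAP double semi-partialling (residualize
each predictor matrix on the others, permute the residual matrix's node
labels jointly over rows and columns, refit; add-one two-tailed p), and
node-level associations with outcome-permutation regression. Observation-
level hypotheses (e.g. homogeneous gestures eliciting emotional responses)
use binomial-logit random-intercept GLMMs with focal identity as the
grouping factor, fitted by Gauss–Hermite maximum likelihood.

## Worked example

```python
from gestnet import (Repertoire, SyntheticConfig, dyad_repertoire_summary,
                     generate_dataset, kappa_matrix, mrqap_dsp, rate_matrix)
from gestnet.network import DyadMatrix

catalog = {"visual": tuple(f"v{k}" for k in range(20)),
           "tactile": (), "auditory_short": (), "auditory_long": ()}
shared = {"v0", "v1", "v2"}
bb = Repertoire.build("BB", catalog, shared | {"v3", "v4", "v5", "v6", "v7"})
hw = Repertoire.build("HW", catalog, shared | {"v8", "v9"})
s = dyad_repertoire_summary(bb, hw)
print(s.homog_size, s.heterog_size, round(s.kappa, 3))
```

prints `3 7 0.222`: the dyad shares 3 gesture types; BB has 5 types HW
lacks and HW has 2 types BB lacks, so the heterogeneous repertoire size is
7 for both orderings; chance-corrected agreement over the 20-type catalog
is κ = 0.222.

Running the inference end to end on a generated study
(`python examples/05_mrqap_inference.py`):

```
outcome: proximity rate, 130 dyads, r^2 = 0.276
  kappa_visual           beta = +0.439, p = 0.0005
  kappa_tactile          beta = +0.222, p = 0.0095
  kappa_auditory_short   beta = +0.141, p = 0.1039
  kappa_auditory_long    beta = +0.162, p = 0.0575
```

Each standardized β is the expected change (in s.d. units) of the dyadic
proximity rate per s.d. of that modality's κ overlap, with the other
modalities partialled out; p-values come from 2000 QAP permutations. The
generator plants a positive overlap→proximity coupling, which the visual
and tactile networks recover clearly here.

The `examples/` directory has one short script per capability (simulation,
overlap, rates, networks, MRQAP, GLMM, full pipeline), and the same
pipeline is scriptable from the shell:

```sh
gestnet run --seed 42 --out-dir run1          # all stages
gestnet simulate --seed 42 --out-dir run2     # data only
```

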