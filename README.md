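# a3som

Abstained, explainable, semi-supervised classification built on a
self-organizing map (SOM) coupled to dense layers.

## The problem

In many tabular-data settings — the flagship case here is bulk-transcriptomics
cancer subtyping — labels are scarce, and some samples may belong to classes
that are absent from the label set altogether. `a3som` addresses both at
once:

* **semi-supervised classification** that uses every sample, labeled or not;
* **abstained (reject-option) classification** that withholds low-confidence
  predictions, distinguishing *distance* abstention (the sample resembles no
  known class — a candidate member of a new class) from *ambiguity*
  abstention (the sample sits in an overlap between known classes);
* **prototype-based explanation**: every sample is anchored to a unit of a
  2-D map whose prototype vector, neighborhood and label make-up explain the
  prediction visually.

## The model

A sample $x \in \mathbb{R}^m$ passes through a SOM layer — a fixed
$h \times w$ grid of units $u$, each holding a prototype $w_u \in
\mathbb{R}^m$ — whose output is the vector of Euclidean distances
$a_u = d(x, w_u)$. A block of $B$ fully-connected ReLU layers maps this
activation vector to one output per class, finished by either a softmax
(standard classification) or a sigmoid head (independent per-class
probabilities, used for abstention). Training minimizes

$$L = \mathrm{CE}(Y_L, \hat Y_L) \;+\; \gamma\, D(X, U) \;+\; \eta\, \lVert w \rVert^2$$

where CE is the cross-entropy summed over the **labeled** samples only, and

$$D(X,U) = \frac{1}{N} \sum_i \sum_u H_\sigma\!\big(\mathrm{BMU}(x_i), u\big)\, d(x_i, w_u)^2$$

is the SOM distortion over **all** samples
($H_\sigma(u,v) = \exp(-\lVert r_u - r_v \rVert^2 / 2\sigma^2)$ is the
Gaussian grid neighborhood and the BMU is the unit nearest to $x_i$). The
unlabeled data thus shapes the prototypes — and through them the decision
function — while the labels shape the dense head and pull the map toward
class structure.

After training, per-class abstention thresholds are calibrated from the
training predictions (the mean top-probability and mean top-two margin of
each predicted class); a prediction is withheld when its top probability
falls below the distance threshold of its class, or its margin below the
ambiguity threshold. The quality of an abstained classifier is summarized by
the **accepted accuracy** AA = |G∩A|/|A| and the **rejected error**
RE = |E∩R|/|E|.

## Worked example: discovering a hidden class

```python
import numpy as np
from a3som import (A3SOM, generate_artificial, hide_class, mask_labels,
                   train_test_split_dataset, reference_abstained_config,
                   bmu_region_connected)

data = generate_artificial()                      # 3000 x 2, 6 classes
train, test = train_test_split_dataset(data, 0.25, seed=3)
train = hide_class(train, 1)                      # class 1 becomes unknown
train = mask_labels(train, 0.9, seed=4)           # keep 10% of the rest

model = A3SOM(train, map_shape=(8, 8), head="sigmoid")
results = model.fit(reference_abstained_config(seed=1))
print(results.summary())

thresholds = results.calibrate_thresholds()
preds = results.abstain(test.X, thresholds)

hidden = test.y_full == 1
dist = np.array([p.abstained and p.reason == "distance" for p in preds])
print(f"hidden-class samples distance-abstained: {100*dist[hidden].mean():.1f}%")
_, _, bmus = results.predict(test.X)
units = set(bmus[hidden & dist])
print("their BMUs:", sorted(int(u) for u in units),
      "connected:", bmu_region_connected(results.params.grid, units))
```

prints

```
A3SOM Results
==========================================================
Map size:                   8 x 8 (64 units)
Dense layers:               [32]
Classes:                    5
Output head:                sigmoid
...
Samples (labeled):          2250 (187)
Final total loss:           197.229
Training accuracy:          0.8610
==========================================================
hidden-class samples distance-abstained: 99.2%
their BMUs: [6, 7, 15] connected: True
```

Only 187 of 2250 training samples carry labels, and none of them belong to
class 1 — yet 99% of the held-out class-1 samples are flagged by the
distance rule, and their best-matching units form a single connected corner
of the map: the model has *discovered* a coherent unknown class rather than
silently mislabeling it. The same workflow on the synthetic PAM50-like
expression table (with the Basal-like subtype hidden) flags the Basal
samples and shows their tell-tale low ESR1/PGR/ERBB2 signature on the
abstained map units.

A command-line interface mirrors the library:

```
a3som generate --kind artificial --out data.csv
a3som train --data data.csv --head sigmoid --out model.a3som
a3som calibrate --model model.a3som --data data.csv --out thresholds.json
a3som abstain --model model.a3som --data data.csv --thresholds thresholds.json --out decisions.csv
a3som plot-map --model model.a3som --data data.csv --out map.png
```

## Documentation

`docs/methods.md` describes the model, the synthetic generators, the
numerical choices and the known limitations in detail.
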