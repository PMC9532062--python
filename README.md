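# mvkmeans

Weighted multi-view K-means for categorical survey data, built for screening
mental-health state from student surveys. Respondents are described by
several aligned feature blocks ("views") — here a basic-information table
(gender, grade, character, household income, origin, only-child status, GPA,
attendance) and a questionnaire (stress level and source, coping style,
seminar attendance, stress relief, perceived manageability). Views differ in
quality: a noisy questionnaire should count for less than clean records. The
package clusters respondents into latent state levels while *learning* how
much to trust each view, and ships everything needed to run the full
protocol without access to real student records: single-view baselines
(K-means, fuzzy C-means), NMI / Rand index validity metrics, a synthetic
two-view survey generator, and a CLI.

## The model

Given `V` views with `x_i^(v)` the view-`v` features of respondent `i`,
MvK-means minimizes

```
J_H = Σ_v w_v^p Σ_j Σ_i φ_ij ‖x_i^(v) − z_j^(v)‖² + η Σ_v w_v^p
s.t.  Σ_v w_v = 1,  0 ≤ w_v ≤ 1
```

over the hard partition `φ_ij`, per-view cluster centers `z_j^(v)`, and view
weights `w`. The fit alternates three exact block minimizations, so `J_H`
never increases:

* **assignment** — respondent `i` joins `argmin_j Σ_v w_v^p ‖x_i^(v) − z_j^(v)‖²`;
* **centers** — `z_j^(v)` is the per-view mean of cluster `j`'s members;
* **weights** — the simplex-constrained Lagrangian solution
  `w_v ∝ (D_v + η)^(−1/(p−1))`, where `D_v` is view `v`'s within-cluster
  dispersion: high-dispersion (low-quality) views get less weight.

`p > 1` smooths the weight distribution (default 2); `η ≥ 0` softens weight
contrast (default 0). With one view, or with `weight_mode="fixed_uniform"`,
the procedure reduces exactly to classical K-means. Categorical survey
values enter as integer codes from a packaged code book (Gender Male→11,
…, Attendance Excellent→85; questionnaire options A→1, B→2, …).

## Worked example

```bash
# 800 synthetic respondents, 5 latent states, two views of 8 attributes
mvkmeans simulate --out-dir data --n 800 --seed 7
# weighted multi-view fit: C=5 clusters, 100-iteration cap, 10 restarts
mvkmeans fit --view data/view1.csv --view data/view2.csv \
    --codebook data/codebook.yaml --algo mvk --clusters 5 --seed 7 \
    --out model.json
# score the partition against the generating labels
mvkmeans evaluate --view data/view1.csv --view data/view2.csv \
    --codebook data/codebook.yaml --labels data/labels.csv --model model.json
```

The fit prints `final objective 968.854318 after 13 iteration(s)` and the
evaluation reports `"nmi": 0.9858..., "rand_index": 0.9969...` — the learned
partition recovers the five generating mental-state classes almost exactly.
The model file shows the learned view weights `[0.2913, 0.7087]`: the
questionnaire view separates the classes far better than the demographic
view, so it earns most of the weight.

The four-model comparison (with the questionnaire view corrupted at noise
0.5, 10 seeds, 600/200 train/test split):

```bash
mvkmeans benchmark --out-json report.json --out-csv report.csv
```

prints a table of NMI / Rand index means and standard deviations for
`kmeans`, `fcm`, `mvk_fixed_uniform` and `mvk_weighted` on both splits; at
these settings the weighted model leads (e.g. test NMI ≈ 0.62 vs 0.53 for
the uniform-weight model), because it shifts weight onto the clean view.

The same operations are available as a library:

```python
import mvkmeans as mk

ds = mk.generate(mk.default_class_profiles("high", n=800, seed=7)).dataset
model = mk.mvk_fit(ds, n_clusters=5, seed=7, n_restarts=10)
print(model.weights.w, mk.nmi(ds.labels, model.assignment))
```

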