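# pitmorph

Observer-error assessment and landmark-model revision for 3D carnivore
tooth-pit geometric morphometrics.

Tooth pits — the roughly circular depressions a carnivore's tooth cusp
leaves on bone — are routinely digitised as 3D landmark configurations and
compared across carnivore species. Those comparisons are only as good as
the landmarks: observer experience, landmark type (well-defined Type II
points vs constructed Type III points) and the superimposition procedure
itself all inject error. `pitmorph` is a library for taphonomists and
morphometricians that quantifies each of those error sources on a
specimen × analyst panel of configurations, and evaluates a revised
landmark scheme that replaces the ambiguous Type III points with computed
sliding semilandmarks. Because raw coordinate panels of this kind are
rarely published, the package ships a synthetic study generator that
reproduces the study design (30 wolf + 30 dog pits × 3 analysts of
differing experience, 17 landmarks) so every analysis is runnable and
testable at desk scale.

## What it computes

**Robust error statistics.** Landmark errors are strongly right-skewed, so
dispersion is reported as the median, the normalised median absolute
deviation

&nbsp;&nbsp;&nbsp;&nbsp;NMAD = 1.4826 · median(|xᵢ − median(x)|),&nbsp;&nbsp;
1.4826 ≈ 1/Φ⁻¹(3/4),

and the square root of the Tukey biweight midvariance (BWMV), which
zero-weights observations beyond 9 MADs of the median. Group contrasts use
the rank-based Kruskal–Wallis H.

**Four error assessments.** (1) Raw inter-analyst Euclidean distances per
landmark, before any superimposition; (2) distances from each analyst's
point to the cross-analyst centroid; (3) Procrustes distances from each
configuration to the mean reference after full GPA (*shape space*, with
scaling) and partial GPA (*form space*, without scaling — immune to the
"Pinocchio effect" by which least-squares scaling smears a localised error
across all landmarks); (4) the repeatability measure

&nbsp;&nbsp;&nbsp;&nbsp;RMⱼ = Σᵢ d²ᵢⱼ / Σᵢⱼ d²ᵢⱼ ∈ [0, 1],&nbsp;&nbsp;Σⱼ RMⱼ = 1,

each analyst's share of the total squared Procrustes distance to the mean.

**Landmark identifiability.** All analysts' placements of every landmark
are pooled in shape space and clustered with DBSCAN (MinPts = 30, ε from
the k-distance elbow) and flat-kernel mean shift (0.05-quantile
bandwidth); noise points and cluster/landmark disagreements measure how
observer-independent each landmark is.

**Model revision.** PCA (dimensionality, PC1–2 and PC1–10 cumulative
variance), MANOVA (Hotelling–Lawley or Wilks' Λ chosen by a Shapiro–Wilk
normality rule), and two-group CVA with Mahalanobis/Procrustes distances
and 999-permutation p-values compare the 17-landmark scheme, the 5 fixed
Type II landmarks, and the hybrid 30-point model (LM1–5 plus a 5×5
semilandmark patch slid to minimise thin-plate-spline bending energy),
plus a patch-size sweep (5×5 … 10×10). UPGMA trees from Procrustes
distance matrices export to newick.

## Worked example

```python
from pitmorph.synthetic import ObserverStudyConfig, generate_observer_study
from pitmorph.superimposition import full_gpa
from pitmorph.error_analysis import (
    procrustes_distances_to_reference, repeatability_measures)

dataset = generate_observer_study(ObserverStudyConfig(n_pits_per_carnivore=30, seed=1))
ensemble = full_gpa(dataset.configurations)
rm = repeatability_measures(procrustes_distances_to_reference(ensemble))
print({analyst: round(share, 3) for analyst, share in rm.items()})
```

prints

```
{'A1': 0.405, 'A2': 0.343, 'A3': 0.252}
```

the analysts' shares of measurement variance in shape space: the least
experienced analyst (A1, noise scale ×1.3) contributes the most, the most
experienced (A3) the least, and the three shares sum to one exactly. The
`examples/` directory holds one narrative script per capability
(simulation + raw errors, superimposition + repeatability,
identifiability, model revision); each prints the numbers it computes with
a line on what they mean. A thin CLI wraps the same pipeline:

```sh
pitmorph observer-error --seed 1 --out results/
pitmorph model-revision --seed 1 --out results/
```

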