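# dichroma

**Sex-specific color evolution on phylogenies: did dichromatism evolve by
male elaboration (Darwin) or female dulling (Wallace)?**

Observing that males are colorful and females drab cannot, by itself, tell
you *which sex moved*: directional sexual selection on males and directional
natural selection on females produce the same present-day pattern. Telling
them apart requires reconstructing the history of color change in each sex
separately. `dichroma` implements that reconstruction for comparative
datasets (one color phenotype per species per sex, e.g. European
butterflies) and is aimed at researchers in phylogenetic comparative
methods and color evolution.

## The model

Each species/sex phenotype is a centroid in CIELAB color space, `c_m` and
`c_f`, computed as the mean of a large pixel sample from an image. The
dichromatism of a species is the vector

    D = c_m − c_f,    ‖D‖ = ΔE (perceptual color distance)

Both sexes' centroids are modelled along a time-calibrated phylogeny with
**phylogenetic ridge regression**: tip traits are regressed on root-to-tip
branch-length paths,

    y = μ·1 + Xβ + ε,    β̂ = argmin ‖y − μ1 − Xβ‖² + λ‖β‖²,

yielding a rate vector per branch (m⃗ and f⃗ for the two sexes, in Lab units
per Myr) and ancestral states per node, with λ chosen by exact leave-one-out
cross-validation, shared between the sexes. Projecting the rate vectors on
the ancestral dichromatism direction D̂ gives per-branch *effective rates of
dichromatism change*:

    s_m = m⃗·D̂,    s_f = −f⃗·D̂,    s = s_m + s_f = (m⃗ − f⃗)·D̂

`s` is the first-order rate of change of ‖D‖: positive where the sexes
diverge. The regressions of `s_m ~ s` and `s_f ~ s` split every change in
dichromatism into male and female shares (slopes sum to 1; 0.5/0.5 means
equal contribution — a male slope well above 0.5 is the Darwinian
signature). Additional statistics: the rate ratio mean‖m⃗‖/mean‖f⃗‖, the
regression of log(‖m⃗‖/‖f⃗‖) on ancestral ‖D‖, Pagel's λ for phylogenetic
signal of dichromatism, and a sex-swap permutation test (labels swapped
within species with probability ½, full pipeline re-run per replicate) for
significance.

A synthetic-data module generates all of the above with known ground truth
(Yule trees; strongly correlated male/female Brownian color evolution;
clade-localized directional drive of one sex; exactly monochromatic
species) under `darwinian`, `wallacean`, `shared_null`, and `mixed`
scenarios.

## Worked example

```python
import dichroma as dc

# a male-driven (Darwinian) dataset: 150 species, known ground truth
ds = dc.simulate_dataset("darwinian", seed=1)

table, summary, (fit_m, fit_f) = dc.analyze_dataset(ds.index, ds.centroids)
print(summary["rate_ratio"], summary["male_slope"], summary["female_slope"])
# 1.271 0.853 0.147

perm = dc.run_permutation_study(ds.index, ds.centroids, R=199, seed=2)
print(perm["rate_ratio"].p_two_tailed)   # 0.005

dichro = dc.dichromatism_table(ds.centroids)
lam = dc.pagel_lambda(ds.index, dichro.set_index("species_id")["D_mag"],
                      R_boot=200, seed=3)
print(lam.lambda_hat)                    # 0.836
```

Reading: male color evolved 1.27× faster than female color; changes in
dichromatism are 85% attributable to male color change (permutation
p = 0.005, the smallest attainable at R = 199); dichromatism carries strong
phylogenetic signal (λ ≈ 0.84). That is the expected signature for a
male-driven simulation. `table` holds the per-branch quantities
(`m_mag`, `f_mag`, `anc_D_mag`, `s_m`, `s_f`, `s`, ...).

The same pipeline runs from the shell:

```sh
dichroma simulate --scenario darwinian --n-tips 150 --seed 1 --out sim/
dichroma decompose --tree sim/tree.nwk --centroids sim/centroids.csv --out results/
dichroma permtest --tree sim/tree.nwk --centroids sim/centroids.csv -R 1000 --seed 2 --out perm.json
dichroma signal --tree sim/tree.nwk --centroids sim/centroids.csv -R 1000 --seed 3
dichroma run --config run.yaml     # full pipeline incl. report.json
dichroma colors --images drawings/ --n-pixels 50000 --seed 4 --out centroids.csv
```

Real data enter as a Newick tree plus a centroid CSV with columns
`species_id, sex, L, a, b` (or as a directory of
`<species>_<sex>.png` images from which centroids are computed).

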