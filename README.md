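# wellcount

Counting viable cells in nanoliter-well microscopy images with a
convolutional neural network, plus confidence triage of the wells the
network is unsure about.

## The problem

Single-cell experiments distribute cells into plates of thousands of
nanoliter wells (3984 per plate in the system this package models) and need
to know, for every well, whether it holds 0, 1, 2 or more than 2 cells.
The cells are unstained and unlabeled, so the gold standard is visual
inspection of each 8-bit grayscale frame (natively 511×511 pixels) by
trained technicians — accurate but hopelessly slow at scale. `wellcount`
implements an automated counter for this setting:

* a CNN that maps the raw well frame to a posterior
  `(p₀, p₁, p₂, p_{>2})` over the four occupancy categories — 18 layers
  between input and output (8 convolutions, 4 max-pools, 4 local response
  normalizations, 2 fully connected layers), 468,768 weight elements at
  native resolution, trained by plain SGD on stratified mini-batches
  (77/21/10/11 samples per category, 119 per batch) with early stopping on
  validation loss;
* an "enhanced system": wells whose highest output `h(s) = max_c p_c(s)`
  falls below a threshold `t` form the ambiguous set `{s : h(s) < t}` and
  are routed to human review (or excluded). Errors concentrate at low
  `h`, so reviewing a few percent of wells buys a large accuracy gain;
* a synthetic plate generator (Poisson occupancy with an adhesion excess,
  square or round walls, debris/defocus/illumination artifacts) so the
  whole pipeline is testable end to end without microscope data;
* the evaluation statistics of a counting experiment: confusion matrix,
  per-category sensitivities and positive predictive values, discordance
  table, rater-comparison chi-square, Mann-Whitney confidence separation,
  and maximum-likelihood estimation of the Poisson occupancy rate λ from
  categorized (right-censored at >2) counts.

The classifier is a scikit-learn estimator (`CellCountCNN`), so it clones,
`get_params`/`set_params`, and composes with sklearn tooling; the network
itself runs on a small numpy engine inside the package (no deep-learning
framework required).

## Worked example

```python
import numpy as np
import wellcount as wc

# 1. synthesize plates: square wells, 64 px, lambda = 0.2 cells/well
geom = wc.WellGeometry(shape="square", image_side=64)
occ = wc.OccupancyModel(lam=0.2, cluster_excess=0.05)
plates = {
    pid: wc.plates_from_manifest(
        wc.generate_plate(geom, occ, n_wells=n, seed=s, plate_id=pid))
    for pid, n, s in [("train1", 2000, 111), ("train2", 2000, 112),
                      ("val", 400, 113), ("test", 800, 114)]
}

# 2. train the counting CNN at desk scale
est = wc.CellCountCNN(minibatch_composition=(26, 7, 3, 4),
                      stage_schedule=((400, 2),), rotation_stage=None,
                      n_iterations=400, learning_rate=0.01,
                      eval_every=50, patience=6, random_state=1)
est = wc.train_on_plates(plates, wc.SubsetPartition(("train1", "train2"),
                                                    ("val",), ("test",)),
                         estimator=est)

# 3. evaluate and triage
X = np.stack([w.pixels for w in plates["test"]])
y = np.array([w.category for w in plates["test"]])
pred, h = est.predict(X), est.highest_outputs(X)
print("held-out accuracy:", (pred == y).mean())
t, realized = wc.threshold_for_proportion(h, 0.05)
res = wc.concordance_with_triage((pred, h), y, t, "resolve_by_human")
print(f"resolve {realized:.1%} least-confident wells -> concordance {res.concordance:.4f}")
```

Output (exact values depend on the seed):

```
held-out accuracy: 0.95
resolve 5.0% least-confident wells -> concordance 0.9613
```

The accuracy beats the 82% majority-class baseline of a λ=0.2 plate by a
wide margin, and sending the 5% least-confident wells to human review
raises concordance further — the same qualitative gain the triage system
delivers at full scale. `docs/methods.md` describes the model, the
training protocol, the generator and the desk-scale study conditions in
detail.

A command-line interface mirrors the library:

```bash
wellcount generate --shape round --wells 500 --side 64 --lambda 0.2 --seed 1 --out data/
wellcount train --config train.yaml --data data/ --partition partition.yaml --out model.npz
wellcount predict --model model.npz --data data/ --out predictions.tsv
wellcount triage --predictions predictions.tsv --target-proportion 0.05 \
                 --policy resolve_by_human --out triage.tsv
wellcount evaluate --predictions predictions.tsv --truth data/test.tsv --out report.json
```

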