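"""Train a reduced LGN-CNN on synthetic oriented images (a few minutes).

Generates a two-class dataset of oriented contours (classes differ in
contour curvature) over 1/f background noise, then runs the two-phase
protocol: feedforward pre-training without lateral connections, followed
by joint training with the lateral kernel enabled.  Afterwards the
prefilter is compared against a Laplacian of Gaussian: training on
1/f-dominated images pushes the single prefilter toward a center-surround
(LoG-like) shape, so its fit correlation should rise above the value at
random initialization.
"""

import numpy as np

import lgncnn as L

spec = L.SyntheticImageDatasetSpec(
    n_images=1200, size=24, background_amplitude=0.3, seed=5
)
ds = L.make_oriented_image_dataset(spec)
print(f"dataset: {ds.images.shape[0]} images {ds.images.shape[1:]}, "
      f"class balance {np.bincount(ds.labels)}")

cfg = L.ArchitectureConfig(unit_fraction=0.25, depth=2, lateral_size=9)
net = L.build_network(cfg, image_size=24, seed=0)
init_fit = L.fit_log(net.psi0)
print(f"prefilter at init: LoG correlation {100 * init_fit.correlation:.1f}%")

tc = L.TrainingConfig(max_epochs=8, patience=16, lr=0.015, batch_size=64, seed=0)
hist = L.train(net, (ds.images, ds.labels), tc)

for i, (ph, tr, va) in enumerate(zip(hist["phase"], hist["train_acc"], hist["val_acc"])):
    print(f"epoch {i:2d} [{ph:>20s}] train {tr:.3f}  val {va:.3f}")

final_fit = L.fit_log(net.psi0)
print(f"\nprefilter LoG correlation: {100 * init_fit.correlation:.1f}% at init "
      f"-> {100 * final_fit.correlation:.1f}% after training "
      f"(sigma = {final_fit.params.sigma:.3f})")
print(f"best validation accuracy: {max(hist['val_acc']):.3f} (chance = 0.5)")
print("a rising LoG correlation indicates the prefilter is moving toward a")
print("center-surround, LGN-like receptive profile; at this desk scale the")
print("trend is visible though far from the structure full training yields.")
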