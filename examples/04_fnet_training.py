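"""Train the F-Net CNN at smoke scale on separable phantom recipes.

Run:  python examples/04_fnet_training.py   (~1 min)
"""

from folliscan import default_normal_spec, default_pcos_spec, generate_dataset
from folliscan.fnet import FNetConfig, TrainConfig, build_fnet, fnet_predict, train_fnet

# disjoint background intensities: the pooled-statistics signal F-Net learns
pcos = default_pcos_spec(background_intensity=120.0)
norm = default_normal_spec(background_intensity=190.0)
data = generate_dataset(20, pcos, norm, seed=11)

model = build_fnet(FNetConfig(input_size=112), seed=0)
print("layer census:", model.layer_census())
print("trainable parameters:", model.n_parameters())

history = train_fnet(model, data, TrainConfig(epochs=10, seed=0))
for e, (tl, ta, va) in enumerate(
    zip(history.train_loss, history.train_accuracy, history.val_accuracy), 1
):
    print(f"epoch {e:2d}  loss={tl:.4f}  train_acc={ta:.3f}  val_acc={va:.3f}")

labels, probs = fnet_predict(model, [d.image for d in data[:4]])
print("\nfirst four predictions:", labels)
print("softmax rows sum to:", probs.sum(axis=1))
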