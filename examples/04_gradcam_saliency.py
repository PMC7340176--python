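"""Localise the waveform regions a trained network relies on (Grad-CAM).

Trains a small regressor on a planted-feature task — the label is the
amplitude of a bump hidden at samples 50-80 of the brachial channel — and
shows that the saliency map concentrates on exactly that window.
"""

import numpy as np

from padpulse import gradcam, nn

rng = np.random.default_rng(7)

def planted(n):
    X = np.zeros((n, 2, 256))
    y = rng.uniform(0.1, 0.8, n)
    for i in range(n):
        X[i, 0] = y[i] * np.exp(-0.5 * ((np.arange(256) - 65) / 6.0) ** 2)
    return X, y

X, y = planted(400)
Xv, yv = planted(80)
model = nn.build_model(nn.NetworkConfig(batch_norm=False), seed=0)
nn.train(model, (X, y), (Xv, yv),
         nn.TrainingConfig(epochs=60, learning_rate=1e-3, seed=0, patience=30))

Xt, yt = planted(5)
print(f"{'label':>6} {'mass in window 50-80':>21} {'mass on silent channel':>23}")
for i in range(5):
    sal = gradcam(model, Xt[i, 0], Xt[i, 1])
    total = sal.total_mass()
    print(f"{yt[i]:6.2f} {sal.brachial[50:81].sum() / total:21.2%} "
          f"{sal.ankle.sum() / total:23.2%}")

print("\nMost saliency mass falls inside the only informative window, and"
      "\nalmost none on the channel that carries no signal: the network's"
      "\nattribution matches the data-generating mechanism.")
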