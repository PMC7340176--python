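"""Model introspection: latent-space embedding and Grad-CAM saliency.

Two questions about a trained severity regressor are answered here: does
the latent space organise samples along disease severity (checked with a
t-SNE embedding and a nearest-neighbour label-coherence statistic), and
which waveform regions drive the prediction (localised with Grad-CAM
adapted to regression — the "class score" is the scalar severity output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .nn import SeverityRegressor

__all__ = [
    "SaliencyMap",
    "extract_latents",
    "tsne_embed",
    "gradcam",
    "neighbor_label_coherence",
]


@dataclass
class SaliencyMap:
    """Per-channel, non-negative, input-length importance profile.

    ``brachial`` and ``ankle`` each have length L; unless identically zero
    a map is normalised to max 1 (jointly, preserving the channels'
    relative magnitudes).
    """

    brachial: np.ndarray
    ankle: np.ndarray

    def total_mass(self) -> float:
        return float(self.brachial.sum() + self.ankle.sum())


def extract_latents(
    model: SeverityRegressor, x: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Flattened last-conv-layer activations, paired with severity labels.

    The forward pass runs in evaluation mode, so latents are deterministic
    and independent of batch composition.
    """
    feats = model.latent_features(np.asarray(x, dtype=float))
    return feats, (None if labels is None else np.asarray(labels))


def tsne_embed(
    features: np.ndarray, perplexity: float = 30.0, seed: int = 0, n_iter: int = 1000
) -> np.ndarray:
    """2-D t-SNE embedding (delegates to scikit-learn; seed-reproducible)."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} samples for perplexity "
            f"{perplexity}, got {features.shape[0]}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    )
    return tsne.fit_transform(features)


def neighbor_label_coherence(
    features: np.ndarray, labels: np.ndarray, k: int = 5
) -> float:
    """Mean |label difference| between each sample and its k nearest
    neighbours in feature space (smaller = labels vary more smoothly).

    Used to compare the input space against the learned latent space: a
    well-trained model shows a smaller value in latent space, the
    quantitative counterpart of a severity-ordered manifold.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    _, idx = nn.kneighbors(features)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    return float(np.mean(np.abs(neighbor_labels - labels[:, None])))


def _upsample_linear(x: np.ndarray, length: int) -> np.ndarray:
    if x.size == length:
        return x.copy()
    old = np.linspace(0.0, 1.0, x.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, x)


def gradcam(model: SeverityRegressor, brachial_bp: np.ndarray, ankle_bp: np.ndarray) -> SaliencyMap:
    """Grad-CAM saliency of the severity output for one input sample.

    Channel weights are the spatially averaged gradients of the severity
    output with respect to the last convolution layer's activation maps;
    the weighted activation sum is rectified (negative contributions
    zeroed), linearly upsampled to the input length and jointly normalised
    to a maximum of 1 (all-zero maps are left at zero).
    """
    from .nn import preprocess_waveform

    L = model.config.input_len
    x = np.stack(
        [preprocess_waveform(brachial_bp, L), preprocess_waveform(ankle_bp, L)]
    )[None, ...]
    xs = model.standardize(x)
    model._forward(xs, train=False)
    acts = model._conv_maps.copy()  # (2, C, L5): one map per input row
    # gradient of the scalar output w.r.t. the conv maps
    grads = model._backward(np.ones(1), to_conv_maps_only=True)  # (2, C, L5)
    weights = grads.mean(axis=2)  # (2, C)
    cams = np.maximum((weights[:, :, None] * acts).sum(axis=1), 0.0)  # (2, L5)
    up = np.stack([_upsample_linear(c, L) for c in cams])
    peak = up.max()
    if peak > 0:
        up = up / peak
    return SaliencyMap(brachial=up[0], ankle=up[1])
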