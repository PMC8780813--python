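"""Arrange a per-sample SND vector into a square "expression image".

A vector of n genes is written row-major into the smallest square that
holds it (side = ceil(sqrt(n))); trailing pixels are padding (default 0,
the N(0,1) median). The layout is fixed by the reference gene list, so the
same pixel means the same gene in every image — the property convolutional
models rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .snd import SNDMatrix

__all__ = ["SampleImage", "embed_2d", "unembed", "embed_matrix"]


@dataclass(frozen=True)
class SampleImage:
    """A side × side pixel array holding one sample's first n_genes values."""

    pixels: np.ndarray
    n_genes: int
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ArgumentError(f"pixels must be square, got shape {px.shape}")
        side = px.shape[0]
        if self.n_genes < 1 or side**2 < self.n_genes or (side - 1) ** 2 >= self.n_genes:
            raise ArgumentError(
                f"side {side} is not ceil(sqrt({self.n_genes}))"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_padding(self) -> int:
        return self.side**2 - self.n_genes


def embed_2d(vector: np.ndarray, fill_value: float = 0.0) -> SampleImage:
    """Reshape a 1-D vector into its square image, padding the tail."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.size == 0:
        raise ArgumentError("cannot embed an empty vector")
    if not np.all(np.isfinite(v)):
        raise ArgumentError("vector contains non-finite values")
    side = math.ceil(math.sqrt(v.size))
    flat = np.full(side * side, float(fill_value))
    flat[: v.size] = v
    return SampleImage(pixels=flat.reshape(side, side), n_genes=v.size,
                       fill_value=float(fill_value))


def unembed(image: SampleImage) -> np.ndarray:
    """Invert :func:`embed_2d`: the first n_genes pixels, row-major."""
    return image.pixels.ravel()[: image.n_genes].copy()


def embed_matrix(snd: SNDMatrix, fill_value: float = 0.0) -> np.ndarray:
    """Embed every SND column; returns an (n_samples, side, side) array."""
    side = math.ceil(math.sqrt(snd.n_genes))
    out = np.full((len(snd.sample_ids), side, side), float(fill_value))
    for j in range(len(snd.sample_ids)):
        out[j] = embed_2d(snd.values[:, j], fill_value).pixels
    return out
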