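"""Per-residue sequence embeddings behind a pluggable contract.

The models consume a matrix of ``(n_residues, dim)`` per-residue embedding
vectors, by default 1280-dimensional as produced by large protein language
models.  Any object with a ``dim`` attribute and an
``embed(sequence) -> ndarray`` method satisfies the contract.

Shipped implementations:

* :class:`StubEmbedder` — deterministic pseudo-random unit-variance vectors
  keyed by (residue letter, position, seed), with an optional planted signal
  on channel 0 for labeled residues.  This is the test-time stand-in and the
  workhorse of the synthetic suite.
* :class:`ESM2Adapter` — thin optional adapter over the ``esm`` package if it
  is installed; raises a clear ImportError otherwise.  Never used in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EMBED_DIM", "StubEmbedder", "ESM2Adapter", "get_embedder"]

EMBED_DIM = 1280

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXUO"


class StubEmbedder:
    """Deterministic stand-in embedder with a controllable label signal.

    Each residue's vector is drawn from a standard normal generator seeded by
    ``(seed, position, letter index)``, so the same sequence and seed always
    produce the same matrix, and a given letter at a given position is stable
    across proteins.  When ``signal_labels`` is supplied to :meth:`embed`,
    channel 0 of every labeled residue is shifted by ``+signal_strength`` —
    a clean, tunable correlate of binding used to test learnability.
    """

    def __init__(self, dim: int = EMBED_DIM, seed: int = 0, signal_strength: float = 0.0):
        self.dim = int(dim)
        self.seed = int(seed)
        self.signal_strength = float(signal_strength)

    def embed(self, sequence: str, signal_labels: np.ndarray | None = None) -> np.ndarray:
        if signal_labels is not None and len(signal_labels) != len(sequence):
            raise ValueError("signal_labels length must equal sequence length")
        out = np.empty((len(sequence), self.dim), dtype=float)
        for i, letter in enumerate(sequence):
            li = _ALPHABET.find(letter)
            rng = np.random.default_rng([self.seed, i, max(li, 0)])
            out[i] = rng.standard_normal(self.dim)
        if signal_labels is not None and self.signal_strength != 0.0:
            out[np.asarray(signal_labels, dtype=bool), 0] += self.signal_strength
        return out


class ESM2Adapter:
    """Optional adapter over the ``esm`` package (ESM2 650M, 1280-dim)."""

    def __init__(self):
        try:
            import esm  # noqa: F401
        except ImportError as exc:  # pragma: no cover - esm not installed in CI
            raise ImportError(
                "the 'esm' package is not installed; use StubEmbedder or install fair-esm"
            ) from exc
        import esm

        self.dim = EMBED_DIM
        self._model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
        self._converter = alphabet.get_batch_converter()
        self._model.eval()

    def embed(self, sequence: str, signal_labels=None) -> np.ndarray:  # pragma: no cover
        import torch

        _, _, toks = self._converter([("q", sequence)])
        with torch.no_grad():
            rep = self._model(toks, repr_layers=[33])["representations"][33]
        return rep[0, 1 : len(sequence) + 1].numpy().astype(float)


def get_embedder(name: str = "stub", **kwargs):
    """Factory: ``stub`` or ``esm2``."""
    if name == "stub":
        return StubEmbedder(**kwargs)
    if name == "esm2":
        return ESM2Adapter()
    raise ValueError(f"unknown embedder {name!r}")
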