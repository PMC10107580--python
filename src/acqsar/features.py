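"""Molecular representations: circular fingerprints, descriptor vectors and
graph-encoder embeddings, as sklearn-style transformers.

All three featurisers map an iterable of SMILES strings to a fixed-width
``(n, d)`` array and are pure functions of the molecular structure (given a
frozen encoder for the graph representation). ``fit`` is a no-op except for
the descriptor scaler, which learns training-set standardisation statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .curation import InvalidStructureError
from .descriptors import DESCRIPTOR_NAMES
from .gin import GINEncoder, mol_graph


@dataclass(frozen=True)
class FingerprintConfig:
    """Binary circular-substructure fingerprint settings."""

    radius: int = 2
    n_bits: int = 2048
    use_chirality: bool = True


@dataclass(frozen=True)
class DescriptorConfig:
    """Ordered physicochemical-descriptor vector settings."""

    descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES

    @property
    def dimensionality(self) -> int:
        return len(self.descriptor_names)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    return mol


class ECFPFeaturizer(BaseEstimator, TransformerMixin):
    """Extended-connectivity fingerprints: radius 2, 2048 bits, chirality on."""

    def __init__(self, radius: int = 2, n_bits: int = 2048, use_chirality: bool = True):
        self.radius = radius
        self.n_bits = n_bits
        self.use_chirality = use_chirality

    def fit(self, X, y=None):
        self.n_features_out_ = self.n_bits
        return self

    def transform(self, X) -> np.ndarray:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius,
            fpSize=self.n_bits,
            includeChirality=self.use_chirality,
        )
        out = np.zeros((len(X), self.n_bits), dtype=np.float64)
        for i, smi in enumerate(X):
            fp = gen.GetFingerprint(_mol(smi))
            out[i, list(fp.GetOnBits())] = 1.0
        return out


class PDVFeaturizer(BaseEstimator, TransformerMixin):
    """Physicochemical-descriptor vectors (200-dim by default), standardised
    with training-set statistics; non-finite descriptor values are imputed as
    0 with a warning."""

    def __init__(self, descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES, scale: bool = True):
        self.descriptor_names = descriptor_names
        self.scale = scale

    def _raw(self, X) -> np.ndarray:
        funcs = [getattr(Descriptors, name) for name in self.descriptor_names]
        out = np.zeros((len(X), len(funcs)))
        n_imputed = 0
        for i, smi in enumerate(X):
            mol = _mol(smi)
            for j, fn in enumerate(funcs):
                try:
                    v = float(fn(mol))
                except Exception:
                    v = float("nan")
                if not np.isfinite(v):
                    v = 0.0
                    n_imputed += 1
                out[i, j] = v
        if n_imputed:
            warnings.warn(f"imputed {n_imputed} non-finite descriptor values as 0", stacklevel=2)
        return out

    def fit(self, X, y=None):
        raw = self._raw(X)
        self.mean_ = raw.mean(axis=0)
        std = raw.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        self.n_features_out_ = len(self.descriptor_names)
        return self

    def transform(self, X) -> np.ndarray:
        raw = self._raw(X)
        if not self.scale:
            return raw
        return (raw - self.mean_) / self.scale_


class GINFeaturizer(BaseEstimator, TransformerMixin):
    """Embeddings from a trained, frozen graph encoder (static extractor)."""

    def __init__(self, encoder: GINEncoder):
        self.encoder = encoder

    def fit(self, X, y=None):
        if not self.encoder.frozen:
            raise ValueError("encoder must be trained and frozen before feature extraction")
        self.n_features_out_ = self.encoder.hidden_dim
        return self

    def transform(self, X) -> np.ndarray:
        return self.encoder.embed([mol_graph(smi) for smi in X])


def ecfp_features(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Fingerprint of one compound (functional convenience wrapper)."""
    f = ECFPFeaturizer(config.radius, config.n_bits, config.use_chirality).fit([smiles])
    return f.transform([smiles])[0]


def pdv_features(smiles: str, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Unscaled descriptor vector of one compound."""
    return PDVFeaturizer(config.descriptor_names, scale=False)._raw([smiles])[0]


def gin_embed(smiles: str, encoder: GINEncoder) -> np.ndarray:
    """Embedding of one compound under a frozen encoder."""
    if not encoder.frozen:
        raise ValueError("encoder must be frozen")
    return encoder.embed([mol_graph(smiles)])[0]
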