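"""The four numeric representations of an ion pair.

Each ion pair can be featurized as

- **B-MF** — binary circular-substructure fingerprint (presence/absence),
- **C-MF** — count circular-substructure fingerprint (occurrence counts),
- **MD**   — a fixed list of 2D physicochemical/topological descriptors,
- **MI**   — a grayscale raster of the pair's 2D depiction,
- **MG**   — a molecular graph with atom/bond feature vectors.

Cation and anion are featurized separately and concatenated for the vector
schemes, so ion identity is preserved; the image draws both ions on one
canvas; the graph keeps the two components disconnected and tags each node
with its component.  All featurizers are pure functions of (pair, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Draw, Descriptors
from rdkit.Chem import rdFingerprintGenerator

from .chem import Conditions, IonPair, PROPERTY_CONDITIONS

# Condition coordinates are centred on standard ambient conditions and scaled
# by a typical lab range so they are O(1) next to standardized features.
_COND_CENTER = {"temperature_K": 298.15, "pressure_kPa": 101.325}
_COND_SCALE = {"temperature_K": 30.0, "pressure_kPa": 100.0}


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length real vector plus a tag identifying the scheme that made it."""

    values: np.ndarray
    scheme_tag: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MoleculeImage:
    """An H×W×C raster of the pair's 2D depiction, pixel values in [0, 1]."""

    pixels: np.ndarray

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class MoleculeGraph:
    """A featurized molecular graph of the pair.

    Nodes are heavy atoms of cation then anion; ``component_tag`` is 0 for
    cation nodes and 1 for anion nodes.  Edges are undirected bonds, stored
    once; no edge crosses the component boundary.
    """

    node_features: np.ndarray          # (n_nodes, ATOM_DIM)
    edges: np.ndarray                  # (n_edges, 2) int
    edge_features: np.ndarray          # (n_edges, BOND_DIM)
    component_tag: np.ndarray          # (n_nodes,) int in {0, 1}

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


class RenderError(RuntimeError):
    """The drawing canvas is too small to depict the pair."""


# --------------------------------------------------------------------------
# fingerprints

_FP_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_CACHE:
        _FP_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_CACHE[key]


class BaseFeaturizer:
    """Minimal transformer interface: stateless, ``fit`` is a no-op."""

    scheme_tag: str = "base"

    def fit(self, pairs=None, y=None):
        return self

    def transform(self, pairs: list[IonPair]):
        raise NotImplementedError

    def fit_transform(self, pairs, y=None):
        return self.fit(pairs).transform(pairs)


class CountFingerprintFeaturizer(BaseFeaturizer):
    """Count circular-substructure (Morgan) fingerprint, per-ion then concatenated.

    Radius-``radius`` environments hashed into ``n_bits`` slots per ion;
    entries are non-negative occurrence counts.
    """

    def __init__(self, radius: int = 2, n_bits: int = 1024):
        self.radius = radius
        self.n_bits = n_bits

    @property
    def scheme_tag(self) -> str:
        return f"cmf-r{self.radius}-{self.n_bits}x2"

    def _one(self, mol: Chem.Mol) -> np.ndarray:
        gen = _morgan_generator(self.radius, self.n_bits)
        return np.asarray(gen.GetCountFingerprintAsNumPy(mol), dtype=float)

    def transform(self, pairs: list[IonPair]) -> np.ndarray:
        out = np.empty((len(pairs), 2 * self.n_bits), dtype=float)
        for i, p in enumerate(pairs):
            cat, ani = p.to_mols()
            out[i, : self.n_bits] = self._one(cat)
            out[i, self.n_bits :] = self._one(ani)
        return out


class BinaryFingerprintFeaturizer(CountFingerprintFeaturizer):
    """Binary variant of the circular fingerprint: presence/absence bits."""

    @property
    def scheme_tag(self) -> str:
        return f"bmf-r{self.radius}-{self.n_bits}x2"

    def _one(self, mol: Chem.Mol) -> np.ndarray:
        gen = _morgan_generator(self.radius, self.n_bits)
        return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=float)


# --------------------------------------------------------------------------
# descriptors

#: Fixed, versioned 2D descriptor list computed per ion (v1).  Chosen to span
#: size, composition, topology, flexibility and electronic character while
#: staying cheap (no conformers).
DESCRIPTOR_NAMES_V1: tuple[str, ...] = (
    "MolWt", "HeavyAtomCount", "NumValenceElectrons", "NumHAcceptors",
    "NumHDonors", "NumRotatableBonds", "RingCount", "NumAromaticRings",
    "NumAliphaticRings", "NumSaturatedRings", "FractionCSP3", "TPSA",
    "MolLogP", "MolMR", "BalabanJ", "BertzCT", "Chi0", "Chi1", "Chi0n",
    "Chi1n", "Chi2n", "Chi0v", "Chi1v", "Chi2v", "Kappa1", "Kappa2",
    "Kappa3", "HallKierAlpha", "LabuteASA", "NumHeteroatoms", "NOCount",
    "NHOHCount", "MaxPartialCharge", "MinPartialCharge",
    "MaxAbsPartialCharge", "MinAbsPartialCharge", "FpDensityMorgan1",
    "FpDensityMorgan2", "NumSaturatedCarbocycles", "NumAromaticHeterocycles",
)

_DESC_FUNCS = {name: getattr(Descriptors, name) for name in DESCRIPTOR_NAMES_V1}


class DescriptorFeaturizer(BaseFeaturizer):
    """Fixed 2D descriptor vector per ion, concatenated (cation then anion).

    A descriptor that is undefined for a molecule (e.g. partial charges on
    exotic atoms) is imputed as 0.0; imputation is rare and logged by RDKit.
    """

    scheme_tag = f"md-v1-{len(DESCRIPTOR_NAMES_V1)}x2"

    @property
    def feature_names(self) -> list[str]:
        return [f"cation:{n}" for n in DESCRIPTOR_NAMES_V1] + [
            f"anion:{n}" for n in DESCRIPTOR_NAMES_V1
        ]

    @staticmethod
    def _one(mol: Chem.Mol) -> np.ndarray:
        vals = np.empty(len(DESCRIPTOR_NAMES_V1))
        for j, name in enumerate(DESCRIPTOR_NAMES_V1):
            try:
                v = float(_DESC_FUNCS[name](mol))
            except (ValueError, ZeroDivisionError, RuntimeError):
                v = np.nan
            vals[j] = v
        # undefined descriptors imputed to 0 (documented rule)
        return np.nan_to_num(vals, nan=0.0, posinf=0.0, neginf=0.0)

    def transform(self, pairs: list[IonPair]) -> np.ndarray:
        d = len(DESCRIPTOR_NAMES_V1)
        out = np.empty((len(pairs), 2 * d))
        for i, p in enumerate(pairs):
            cat, ani = p.to_mols()
            out[i, :d] = self._one(cat)
            out[i, d:] = self._one(ani)
        return out


# --------------------------------------------------------------------------
# images

class ImageFeaturizer(BaseFeaturizer):
    """Grayscale 2D depiction of the pair, both ions on one canvas.

    Pixels are "ink" intensities in [0, 1] (0 = blank).  Deterministic:
    2D coordinates are recomputed with the default coordinate generator
    for every call.
    """

    def __init__(self, height: int = 64, width: int = 64, channels: int = 1):
        if channels not in (1, 3):
            raise ValueError("channels must be 1 (grayscale) or 3 (RGB)")
        self.height = height
        self.width = width
        self.channels = channels

    @property
    def scheme_tag(self) -> str:
        return f"mi-{self.height}x{self.width}x{self.channels}-v1"

    def render(self, pair: IonPair) -> MoleculeImage:
        if self.height < 16 or self.width < 16:
            raise RenderError(
                f"canvas {self.height}x{self.width} too small to place atoms"
            )
        mol = pair.combined_mol()
        AllChem.Compute2DCoords(mol)
        img = Draw.MolToImage(mol, size=(self.width, self.height))
        arr = np.asarray(img, dtype=float)[:, :, :3] / 255.0
        ink = 1.0 - arr  # white background -> 0
        if self.channels == 1:
            pixels = ink.mean(axis=2, keepdims=True)
        else:
            pixels = ink
        return MoleculeImage(pixels=pixels)

    def transform(self, pairs: list[IonPair]) -> np.ndarray:
        out = np.empty((len(pairs), self.height, self.width, self.channels))
        for i, p in enumerate(pairs):
            out[i] = self.render(p).pixels
        return out


def rotations(image: MoleculeImage) -> list[MoleculeImage]:
    """4-fold rotation augmentation (0/90/180/270 degrees), training-time only."""
    return [MoleculeImage(np.ascontiguousarray(np.rot90(image.pixels, k))) for k in range(4)]


# --------------------------------------------------------------------------
# graphs

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + 5  # one-hot(+other), then scalars
BOND_FEATURE_DIM = 4


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    idx = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
    v[idx] = 1.0
    base = len(_ELEMENTS) + 1
    v[base + 0] = atom.GetDegree()
    v[base + 1] = atom.GetFormalCharge()
    v[base + 2] = 1.0 if atom.GetIsAromatic() else 0.0
    v[base + 3] = 1.0 if atom.IsInRing() else 0.0
    v[base + 4] = atom.GetTotalNumHs()
    return v


_BOND_ORDER = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class GraphFeaturizer(BaseFeaturizer):
    """Featurized molecular graph: heavy-atom nodes, bond edges, component tags."""

    scheme_tag = "mg-v1"

    def build(self, pair: IonPair) -> MoleculeGraph:
        mol = pair.combined_mol()
        frags = Chem.GetMolFrags(mol)  # tuples of atom indices; cation first
        comp = np.zeros(mol.GetNumAtoms(), dtype=int)
        for fi, frag in enumerate(frags):
            for a in frag:
                comp[a] = 0 if fi == 0 else 1
        nodes = np.stack([_atom_features(a) for a in mol.GetAtoms()])
        edges, efeats = [], []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            edges.append((i, j))
            e = np.zeros(BOND_FEATURE_DIM)
            e[_BOND_ORDER.get(b.GetBondType(), 0)] = 1.0
            efeats.append(e)
        edges_arr = np.asarray(edges, dtype=int).reshape(-1, 2)
        efeats_arr = (
            np.stack(efeats) if efeats else np.zeros((0, BOND_FEATURE_DIM))
        )
        return MoleculeGraph(
            node_features=nodes,
            edges=edges_arr,
            edge_features=efeats_arr,
            component_tag=comp,
        )

    def transform(self, pairs: list[IonPair]) -> list[MoleculeGraph]:
        return [self.build(p) for p in pairs]


# --------------------------------------------------------------------------
# single-pair convenience operations

def binary_fingerprint(pair: IonPair, radius: int = 2, n_bits: int = 1024) -> FeatureVector:
    f = BinaryFingerprintFeaturizer(radius=radius, n_bits=n_bits)
    return FeatureVector(f.transform([pair])[0], f.scheme_tag)


def count_fingerprint(pair: IonPair, radius: int = 2, n_bits: int = 1024) -> FeatureVector:
    f = CountFingerprintFeaturizer(radius=radius, n_bits=n_bits)
    return FeatureVector(f.transform([pair])[0], f.scheme_tag)


def descriptor_vector(pair: IonPair) -> FeatureVector:
    f = DescriptorFeaturizer()
    return FeatureVector(f.transform([pair])[0], f.scheme_tag)


def render_image(pair: IonPair, height: int = 64, width: int = 64, channels: int = 1,
                 augment: str = "off") -> MoleculeImage | list[MoleculeImage]:
    img = ImageFeaturizer(height=height, width=width, channels=channels).render(pair)
    if augment == "off":
        return img
    if augment == "rotations":
        return rotations(img)
    raise ValueError(f"unknown augment mode {augment!r}")


def build_graph(pair: IonPair) -> MoleculeGraph:
    return GraphFeaturizer().build(pair)


# --------------------------------------------------------------------------
# conditions

def condition_columns(conditions: list[Conditions], property_name: str) -> np.ndarray:
    """Standardized condition coordinates required by ``property_name``.

    Returns an (n, k) array where k is the number of conditions the property
    depends on (possibly 0).
    """
    needed = PROPERTY_CONDITIONS[property_name]
    cols = np.empty((len(conditions), len(needed)))
    for j, name in enumerate(needed):
        raw = np.asarray([getattr(c, name) for c in conditions])
        cols[:, j] = (raw - _COND_CENTER[name]) / _COND_SCALE[name]
    return cols


def attach_conditions(
    features: FeatureVector, conditions: Conditions, property_name: str
) -> FeatureVector:
    """Extend a feature vector by the standardized condition coordinates the
    property depends on.  Image and graph representations never pass through
    here — their models take conditions as a parallel scalar channel — so a
    non-vector input is a contract error.
    """
    if not isinstance(features, FeatureVector):
        raise TypeError(
            "attach_conditions applies to FeatureVector only; image/graph "
            "models receive conditions through a side channel"
        )
    extra = condition_columns([conditions], property_name)[0]
    if extra.size == 0:
        return features
    return FeatureVector(
        np.concatenate([features.values, extra]),
        f"{features.scheme_tag}+cond:{property_name}",
    )
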