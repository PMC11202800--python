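"""Feature schema: ordered, named feature columns with block provenance.

The default schema describes the 218-dimensional feature vector used for
hot-spot classification at protein-DNA interfaces:

* 43 conventional structural descriptors — solvent-accessible surface
  area (ASA/RSA over four atom classes, in the bound state, the unbound
  state and their difference: 3 x 8), six secondary-structure descriptors,
  twelve depth/protrusion (DPX/CX) descriptors, and one hydrogen-bond
  count;
* 132 wavelet features — 33 per signal group (bound ASA, unbound ASA,
  delta ASA, secondary structure) from a Haar DWT cascade and a level-3
  wavelet-packet transform;
* 43 EMD features — statistics of the first intrinsic mode functions of
  the same four signal groups.

The canonical column order ships as a JSON registry file
(``schemas/default_schema.json``); :func:`build_default_schema`
regenerates it and is the single source of the naming convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .errors import SchemaError

BLOCKS = ("conventional", "wavelet", "emd")

# Atom classes over which ASA/RSA are measured.
ASA_CLASSES = ("all_atoms", "nonpolar_side", "polar_side", "side_chain")

# Signal-group prefixes: bound-state ASA, unbound ASA, bound-unbound
# difference, and the secondary-structure block.
SIGNAL_GROUPS = ("ASA", "u_ASA", "d_ASA", "dssp")
EMD_GROUP_TAGS = {"ASA": "ASA", "u_ASA": "uASA", "d_ASA": "dASA", "dssp": "dssp"}

ENTROPY_KINDS = ("shannon", "sure", "threshold", "norm", "log_energy")

EMD_STATS = ("meanValue", "variance", "energy", "autocorr")

#: lengths of the four raw per-residue signal blocks
SIGNAL_LENGTHS = {"ASA": 8, "u_ASA": 8, "d_ASA": 8, "dssp": 6}


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    block: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise SchemaError(f"unknown block {self.block!r} for {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of named feature columns with block provenance."""

    entries: tuple[SchemaEntry, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def block_names(self, block: str) -> list[str]:
        return [e.name for e in self.entries if e.block == block]

    def block_count(self, block: str) -> int:
        return sum(1 for e in self.entries if e.block == block)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SchemaError(f"unknown feature name {name!r}") from None

    def subset(self, names: Iterable[str]) -> "FeatureSchema":
        keep = set(names)
        return FeatureSchema(tuple(e for e in self.entries if e.name in keep))

    @classmethod
    def from_names(cls, names: Sequence[str], block: str = "conventional") -> "FeatureSchema":
        return cls(tuple(SchemaEntry(n, block) for n in names))

    def to_json(self) -> str:
        payload = {
            "version": 1,
            "entries": [{"name": e.name, "block": e.block} for e in self.entries],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        payload = json.loads(text)
        return cls(tuple(SchemaEntry(d["name"], d["block"]) for d in payload["entries"]))


def conventional_names() -> list[str]:
    """The 43 conventional descriptor names, in raw-block order:
    bound ASA (8), unbound ASA (8), delta ASA (8), secondary structure (6),
    DPX/CX (12), hydrogen-bond count (1)."""
    names: list[str] = []
    for prefix in ("ASA", "u_ASA", "d_ASA"):
        for cls in ASA_CLASSES:
            names.append(f"{prefix}_abs_{cls}")
            names.append(f"{prefix}_rel_{cls}")
    names += [
        "dssp_carbonyl_angle",
        "dssp_phi",
        "dssp_psi",
        "dssp_alpha",
        "dssp_kappa",
        "dssp_water_num",
    ]
    for measure in ("DPX", "CX"):
        for state in ("bound", "unbound"):
            names.append(f"{measure}_mean_{state}")
            names.append(f"{measure}_sd_{state}")
    for measure in ("DPX", "CX"):
        names.append(f"d_{measure}_mean")
        names.append(f"d_{measure}_sd")
    names.append("donor_num")
    return names


def wavelet_names() -> list[str]:
    """The 132 wavelet feature names: 33 per signal group, groups in
    fixed order. Within a group: approximation-band energies Ea at DWT
    levels 1-3, their std and mean, the level-3 detail energy Ed, five
    entropies of the DWT coefficients, the total leaf energy, eight
    absolute leaf energies (natural order), five entropies of the WPT
    leaves, and eight relative leaf energies."""
    names: list[str] = []
    for g in SIGNAL_GROUPS:
        names += [f"{g}_Ea_{lvl}" for lvl in (1, 2, 3)]
        names += [f"{g}_Ea_std", f"{g}_Ea_mean", f"{g}_Ed"]
        names += [f"{g}_dwt_{k}" for k in ENTROPY_KINDS]
        names.append(f"{g}_wpt_energy_total")
        names += [f"{g}_node_{i}" for i in range(1, 9)]
        names += [f"{g}_wpt_{k}" for k in ENTROPY_KINDS]
        names += [f"{g}_relnode_{i}" for i in range(1, 9)]
    return names


def emd_names() -> list[str]:
    """The 43 EMD feature names: for each ASA group, four statistics of
    the first three IMFs (36); for the secondary-structure group, all
    four statistics of IMF 1 plus mean/variance/energy of IMF 2 (7)."""
    names: list[str] = []
    for g in ("ASA", "u_ASA", "d_ASA"):
        tag = EMD_GROUP_TAGS[g]
        for k in (1, 2, 3):
            names += [f"imf_{k}_{tag}_{stat}" for stat in EMD_STATS]
    names += [f"imf_1_dssp_{stat}" for stat in EMD_STATS]
    names += [f"imf_2_dssp_{stat}" for stat in ("meanValue", "variance", "energy")]
    return names


def build_default_schema() -> FeatureSchema:
    """Construct the canonical 218-column schema (43 + 132 + 43)."""
    entries = [SchemaEntry(n, "conventional") for n in conventional_names()]
    entries += [SchemaEntry(n, "wavelet") for n in wavelet_names()]
    entries += [SchemaEntry(n, "emd") for n in emd_names()]
    return FeatureSchema(tuple(entries))


def load_default_schema() -> FeatureSchema:
    """Load the shipped JSON schema registry."""
    text = resources.files("ecpdh").joinpath("schemas/default_schema.json").read_text()
    return FeatureSchema.from_json(text)
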