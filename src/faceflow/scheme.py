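"""Landmark scheme registry and the DogFACS variable vocabulary.

A :class:`LandmarkScheme` ties together the landmark identifiers, the
face-region grouping used for region-restricted analysis (eyes / ears /
nose-mouth), the inter-ocular-distance (IOD) endpoints used for scale
normalization, and the mapping from DogFACS variable categories to face
regions.

The shipped default is a *synthetic* 46-point scheme: the authoritative
landmark placement manual for real dog faces is not reproduced here, so the
default names are positional and the region sizes are eyes(10), ears(12),
nose_mouth(16), contour(8).  Schemes for real annotation conventions can be
loaded from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import SchemaError, VocabularyError

#: DogFACS variable categories used for facial coding.
CATEGORIES = (
    "UpperFaceAU",
    "LowerFaceAU",
    "ActionDescriptor",
    "EarActionDescriptor",
)

#: DogFACS variables by category (the facial subset used for event detection).
VARIABLES_BY_CATEGORY: dict[str, tuple[str, ...]] = {
    "UpperFaceAU": (
        "Inner Brow Raiser (AU101)",
        "Blink (AU145)",
    ),
    "LowerFaceAU": (
        "Jaw Drop (AU26)",
        "Nose Wrinkler & Upper Lip Raiser (AU109+110)",
        "Lip Corner Puller (AU12)",
        "Lower Lip Depressor (AU116)",
        "Upper Lip Raiser (AU110)",
    ),
    "ActionDescriptor": (
        "Tongue Show (AD19)",
        "Nose Lick (AD137)",
    ),
    "EarActionDescriptor": (
        "Ears Flattener (EAD103)",
        "Ears Forward (EAD101)",
        "Ears Adductor (EAD102)",
    ),
}

#: Flat variable -> category lookup.
VARIABLE_CATEGORY: dict[str, str] = {
    v: cat for cat, vs in VARIABLES_BY_CATEGORY.items() for v in vs
}

#: Each category concentrates on one face region: upper-face AUs move the
#: eye region, lower-face AUs and action descriptors the nose/mouth region,
#: and ear action descriptors the ears.
DEFAULT_CATEGORY_TO_REGION: dict[str, str] = {
    "UpperFaceAU": "eyes",
    "LowerFaceAU": "nose_mouth",
    "ActionDescriptor": "nose_mouth",
    "EarActionDescriptor": "ears",
}

REQUIRED_REGIONS = ("eyes", "ears", "nose_mouth")


@dataclass(frozen=True)
class LandmarkScheme:
    """Immutable description of a facial landmark convention.

    Parameters
    ----------
    n_landmarks : int
        Number of landmarks per face (46 for the dog scheme).
    names : tuple of str
        One identifier per landmark, index-aligned with coordinate arrays.
    regions : dict
        Region name -> tuple of landmark indices.  Must contain the regions
        ``eyes``, ``ears`` and ``nose_mouth``; index sets are disjoint.
    iod_pair : (int, int)
        Indices of the outer corners of the two eyes; the distance between
        them is the inter-ocular distance (IOD).
    category_to_region : dict
        DogFACS category -> region name, covering all four categories.
    """

    n_landmarks: int = 46
    names: tuple[str, ...] = ()
    regions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    iod_pair: tuple[int, int] = (0, 5)
    category_to_region: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_TO_REGION)
    )

    def __post_init__(self) -> None:
        if len(self.names) != self.n_landmarks:
            raise SchemaError(
                f"scheme has {len(self.names)} names for {self.n_landmarks} landmarks"
            )
        seen: set[int] = set()
        for region, idx in self.regions.items():
            s = set(idx)
            if len(s) != len(idx):
                raise SchemaError(f"region {region!r} has duplicate indices")
            if s & seen:
                raise SchemaError(f"region {region!r} overlaps another region")
            if not s <= set(range(self.n_landmarks)):
                raise SchemaError(f"region {region!r} has out-of-range indices")
            seen |= s
        for required in REQUIRED_REGIONS:
            if required not in self.regions:
                raise SchemaError(f"scheme is missing required region {required!r}")
        eyes = set(self.regions["eyes"])
        if not set(self.iod_pair) <= eyes:
            raise SchemaError("iod_pair indices must belong to the 'eyes' region")
        if set(self.category_to_region) != set(CATEGORIES):
            raise SchemaError(
                "category_to_region must cover exactly the four DogFACS categories"
            )
        for cat, region in self.category_to_region.items():
            if region not in self.regions:
                raise SchemaError(f"category {cat!r} maps to unknown region {region!r}")

    def region_indices(self, region: str) -> tuple[int, ...]:
        """Landmark indices of ``region``, in scheme order."""
        try:
            return tuple(sorted(self.regions[region]))
        except KeyError:
            raise VocabularyError(
                f"unknown region {region!r}; known: {sorted(self.regions)}"
            ) from None

    def region_for_variable(self, variable: str) -> str:
        """Face region moved by a DogFACS variable."""
        try:
            category = VARIABLE_CATEGORY[variable]
        except KeyError:
            raise VocabularyError(f"unknown DogFACS variable {variable!r}") from None
        return self.category_to_region[category]

    def region_columns(self, region: str) -> tuple[int, ...]:
        """Flat (x,y)-interleaved column indices of ``region`` in a window row."""
        cols: list[int] = []
        for j in self.region_indices(region):
            cols.extend((2 * j, 2 * j + 1))
        return tuple(cols)


def default_scheme() -> LandmarkScheme:
    """The shipped synthetic 46-point scheme.

    Layout: indices 0-9 eyes (0 and 5 are the outer corners, left then
    right), 10-21 ears (six per ear), 22-37 nose and mouth, 38-45 face
    contour and brows.
    """
    eyes = tuple(range(0, 10))
    ears = tuple(range(10, 22))
    nose_mouth = tuple(range(22, 38))
    contour = tuple(range(38, 46))
    names = (
        tuple(f"eye_{i}" for i in range(10))
        + tuple(f"ear_{i}" for i in range(12))
        + tuple(f"nose_mouth_{i}" for i in range(16))
        + tuple(f"contour_{i}" for i in range(8))
    )
    return LandmarkScheme(
        n_landmarks=46,
        names=names,
        regions={
            "eyes": eyes,
            "ears": ears,
            "nose_mouth": nose_mouth,
            "contour": contour,
        },
        iod_pair=(0, 5),
        category_to_region=dict(DEFAULT_CATEGORY_TO_REGION),
    )


def load_scheme(path) -> LandmarkScheme:
    """Load a scheme from YAML (keys: names, regions, iod_pair, category_to_region)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return LandmarkScheme(
            n_landmarks=len(raw["names"]),
            names=tuple(raw["names"]),
            regions={k: tuple(v) for k, v in raw["regions"].items()},
            iod_pair=tuple(raw["iod_pair"]),
            category_to_region=dict(raw["category_to_region"]),
        )
    except KeyError as exc:
        raise SchemaError(f"scheme file {path} is missing key {exc}") from None


def save_scheme(scheme: LandmarkScheme, path) -> None:
    """Write a scheme as YAML, re-loadable by :func:`load_scheme`."""
    doc = {
        "names": list(scheme.names),
        "regions": {k: list(v) for k, v in scheme.regions.items()},
        "iod_pair": list(scheme.iod_pair),
        "category_to_region": dict(scheme.category_to_region),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
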