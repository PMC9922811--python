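"""Tissue-class scheme: integer label codes, class names and role groupings.

A segmentation model upstream of this package assigns each pixel one of 13
classes (12 tissue types plus background).  Different scoring modes group
these classes differently:

* ``stroma_semi`` — the stromal classes counted by the semi-automated score
  (tumor-associated stroma, lymphocytes, erythrocytes, muscle, healthy
  stroma, nerve, stroma lamina propria).
* ``denominator_excluded_semi`` — classes removed from the semi-automated
  denominator (mucus, necrosis, background).
* ``tumor_full`` / ``stroma_full`` — the tumor set (tumor glands + healthy
  glands) and stroma set (tumor-associated stroma, lymphocytes, nerve,
  erythrocytes) used by the fully automated heatmap ratio.
* ``fat`` / ``erythrocytes`` / ``necrosis`` — nuisance classes checked by
  the field-of-view validity rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import FormatError

CLASS_NAMES = (
    "background",
    "tumor glands",
    "tumor-associated stroma",
    "necrosis",
    "lymphocytes",
    "erythrocytes",
    "muscle",
    "healthy stroma",
    "fatty tissue",
    "mucus",
    "nerve",
    "stroma lamina propria",
    "healthy glands",
)

#: default code assignment: 0 = background, then the 12 tissue classes
DEFAULT_ENTRIES = {code: name for code, name in enumerate(CLASS_NAMES)}

_DEFAULT_GROUPINGS_BY_NAME = {
    "tumor_full": ["tumor glands", "healthy glands"],
    "stroma_full": ["tumor-associated stroma", "lymphocytes", "nerve", "erythrocytes"],
    "stroma_semi": [
        "tumor-associated stroma",
        "lymphocytes",
        "erythrocytes",
        "muscle",
        "healthy stroma",
        "nerve",
        "stroma lamina propria",
    ],
    "denominator_excluded_semi": ["mucus", "necrosis", "background"],
    "fat": ["fatty tissue"],
    "erythrocytes": ["erythrocytes"],
    "necrosis": ["necrosis"],
}


@dataclass(frozen=True)
class TissueClassScheme:
    """Mapping of integer raster codes to tissue-class names plus groupings.

    Parameters
    ----------
    entries
        ``{code: class name}``; codes are small non-negative integers and
        must include a ``background`` entry.
    groupings
        ``{grouping name: frozenset of codes}``; every grouping must be a
        subset of the declared codes.
    """

    entries: dict[int, str]
    groupings: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.entries)
        if len(codes) != len(set(codes)):
            raise FormatError("duplicate class codes in scheme")
        if any((not isinstance(c, int)) or c < 0 for c in codes):
            raise FormatError("class codes must be non-negative integers")
        for name in self.entries.values():
            if name not in CLASS_NAMES:
                raise FormatError(f"unknown tissue class name: {name!r}")
        if "background" not in self.entries.values():
            raise FormatError("scheme must declare a background class")
        declared = set(codes)
        for gname, members in self.groupings.items():
            extra = set(members) - declared
            if extra:
                raise FormatError(
                    f"grouping {gname!r} references undeclared codes {sorted(extra)}"
                )
        tf = self.groupings.get("tumor_full", frozenset())
        sf = self.groupings.get("stroma_full", frozenset())
        if tf & sf:
            raise FormatError("tumor_full and stroma_full groupings must be disjoint")

    # -- lookups -----------------------------------------------------------

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(self.entries)

    @property
    def background_code(self) -> int:
        for code, name in self.entries.items():
            if name == "background":
                return code
        raise AssertionError("unreachable: background enforced in __post_init__")

    def codes_for(self, grouping: str) -> frozenset[int]:
        """Codes belonging to a named grouping (empty set if absent)."""
        return self.groupings.get(grouping, frozenset())

    def code_of(self, class_name: str) -> int:
        for code, name in self.entries.items():
            if name == class_name:
                return code
        raise KeyError(class_name)


def default_scheme() -> TissueClassScheme:
    """The 13-class scheme with all default groupings."""
    return TissueClassScheme(
        entries=dict(DEFAULT_ENTRIES),
        groupings=_default_groupings(DEFAULT_ENTRIES),
    )


def _default_groupings(entries: dict[int, str]) -> dict[str, frozenset[int]]:
    """Build every default grouping expressible with the declared classes."""
    name_to_code = {name: code for code, name in entries.items()}
    out: dict[str, frozenset[int]] = {}
    for gname, members in _DEFAULT_GROUPINGS_BY_NAME.items():
        codes = [name_to_code[m] for m in members if m in name_to_code]
        out[gname] = frozenset(codes)
    return out


def read_scheme(path) -> TissueClassScheme:
    """Read a class-palette config (YAML).

    The file maps ``classes: {code: name}`` and optionally
    ``groupings: {name: [codes or class names]}``.  Groupings not given are
    filled with the defaults restricted to the declared classes.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse scheme config: {exc}") from exc
    if not isinstance(raw, dict) or "classes" not in raw:
        raise FormatError("scheme config must contain a 'classes' mapping")
    classes = raw["classes"]
    if not isinstance(classes, dict):
        raise FormatError("'classes' must map codes to class names")
    entries: dict[int, str] = {}
    for code, name in classes.items():
        try:
            icode = int(code)
        except (TypeError, ValueError):
            raise FormatError(f"non-integer class code: {code!r}") from None
        if icode in entries:
            raise FormatError(f"duplicate class code {icode}")
        entries[icode] = str(name)

    groupings = _default_groupings(entries)
    name_to_code = {name: code for code, name in entries.items()}
    for gname, members in (raw.get("groupings") or {}).items():
        codes = []
        for m in members:
            if isinstance(m, int):
                if m not in entries:
                    raise FormatError(
                        f"grouping {gname!r} references unknown code {m}"
                    )
                codes.append(m)
            elif m in name_to_code:
                codes.append(name_to_code[m])
            else:
                raise FormatError(
                    f"grouping {gname!r} references unknown class {m!r}"
                )
        groupings[gname] = frozenset(codes)
    return TissueClassScheme(entries=entries, groupings=groupings)


def write_scheme(scheme: TissueClassScheme, path) -> None:
    """Write a scheme as a YAML palette config (round-trips with read_scheme)."""
    payload = {
        "classes": {int(c): n for c, n in sorted(scheme.entries.items())},
        "groupings": {g: sorted(m) for g, m in sorted(scheme.groupings.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
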