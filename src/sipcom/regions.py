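"""The 18-bilateral-region cortical label scheme.

Detections and the resection zone are localized to one of 18 canonical
cortical regions per hemisphere.  Short codes follow the field's
abbreviations (AML = anterior medial temporal, ...); a region-with-hemisphere
is written e.g. ``AML_R``.
"""

from __future__ import annotations

import re

__all__ = [
    "REGION_CODES",
    "REGION_NAMES",
    "RegionCode",
    "parse_region_set",
    "format_region_set",
]

#: code -> full region name
REGION_NAMES: dict[str, str] = {
    "VMPF": "ventral medial prefrontal",
    "MDPF": "medial dorsal prefrontal",
    "VLPF": "lateral ventral prefrontal",
    "DLPF": "lateral dorsal prefrontal",
    "MP": "medial premotor",
    "LPr": "lateral premotor",
    "MC": "medial central",
    "LC": "lateral central",
    "AML": "anterior medial temporal",
    "ATL": "anterior lateral temporal",
    "PMT": "posterior medial temporal",
    "PLT": "posterior lateral temporal",
    "MPa": "medial parietal",
    "LP": "lateral parietal",
    "MO": "medial occipital",
    "LO": "lateral occipital",
    "OI": "operculo-insular",
    "TPO": "temporo-parieto-occipital junction",
}

#: the 18 canonical short codes, fixed order
REGION_CODES: tuple[str, ...] = tuple(REGION_NAMES)

_HEMIS = ("L", "R")
_CODE_LOOKUP = {c.upper(): c for c in REGION_CODES}


class RegionCode(str):
    """A region-with-hemisphere code such as ``AML_R``.

    Subclasses ``str`` so sets of codes behave like sets of strings; the
    constructor validates the region and hemisphere parts.
    """

    def __new__(cls, value: str) -> "RegionCode":
        value = str(value)
        try:
            region, hemi = value.rsplit("_", 1)
        except ValueError as exc:
            raise ValueError(f"malformed region code: {value!r}") from exc
        if region.upper() not in _CODE_LOOKUP:
            raise ValueError(f"unknown region code: {region!r}")
        if hemi not in _HEMIS:
            raise ValueError(f"hemisphere must be L or R, got {hemi!r}")
        return super().__new__(cls, f"{_CODE_LOOKUP[region.upper()]}_{hemi}")

    @property
    def region(self) -> str:
        return self.rsplit("_", 1)[0]

    @property
    def hemisphere(self) -> str:
        return self.rsplit("_", 1)[1]


def parse_region_set(text: str) -> frozenset[RegionCode]:
    """Parse a region-set string in the cohort-table dialect.

    The dialect lists codes joined by ``+`` with a hemisphere letter that
    distributes leftward over every code since the previous hemisphere
    letter: ``"AML + ATL R"`` means {AML_R, ATL_R}; ``"AML L + ATL L + ATL
    R"`` keeps per-code hemispheres.  ``"N"`` (none) is the empty set.

    Raises
    ------
    ValueError
        On an unknown code or a trailing code with no hemisphere.
    """
    text = text.strip()
    if text in ("N", "", "-"):
        return frozenset()
    out: set[RegionCode] = set()
    pending: list[str] = []
    for token in (t.strip() for t in text.split("+")):
        if not token:
            raise ValueError(f"empty element in region set: {text!r}")
        m = re.fullmatch(r"(?P<code>\S+)(?:\s+(?P<hemi>[LR]))?", token)
        if m is None:
            raise ValueError(f"cannot parse region token: {token!r}")
        code = m.group("code")
        if code.upper() not in _CODE_LOOKUP:
            raise ValueError(f"unknown region code: {code!r} in {text!r}")
        pending.append(code)
        hemi = m.group("hemi")
        if hemi is not None:
            out.update(RegionCode(f"{c}_{hemi}") for c in pending)
            pending = []
    if pending:
        raise ValueError(f"region(s) {pending} lack a hemisphere in {text!r}")
    return frozenset(out)


def format_region_set(codes: frozenset[RegionCode] | set[RegionCode]) -> str:
    """Render a set of codes back into the table dialect.

    Codes are grouped by hemisphere (left first), each group written as
    ``"A + B H"``; the empty set renders as ``"N"``.  ``parse_region_set``
    round-trips the output.
    """
    if not codes:
        return "N"
    codes = {RegionCode(c) for c in codes}
    parts = []
    for hemi in _HEMIS:
        group = sorted(
            (c for c in codes if c.hemisphere == hemi),
            key=lambda c: REGION_CODES.index(c.region),
        )
        if group:
            parts.append(" + ".join(c.region for c in group) + f" {hemi}")
    return " + ".join(parts)
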