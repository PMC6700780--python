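"""ICD-9/ICD-10 topography lexicon for colorectal cancer.

Normalizes raw diagnosis-code strings, maps them to colorectal anatomic
sites, and groups sites into the left / right / transverse sidedness
scheme used in clinical sidedness research:

* left side   — splenic flexure, descending colon, sigmoid colon,
  rectosigmoid junction;
* right side  — cecum, ascending colon, hepatic flexure;
* transverse  — transverse colon.

Codes that carry no side information (unspecified colon, appendix,
overlapping sites) map to ``UNSPECIFIED``; rectal and anal codes map to
``RECTUM``, which is kept as its own discordant category rather than
being folded into the left colon.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class CodeSystem(str, Enum):
    """Diagnosis-code revision."""

    ICD9 = "ICD9"
    ICD10 = "ICD10"


class AnatomicSite(str, Enum):
    """Topographic site of a colorectal tumor, as coded in ICD."""

    CECUM = "cecum"
    APPENDIX = "appendix"
    ASCENDING_COLON = "ascending_colon"
    HEPATIC_FLEXURE = "hepatic_flexure"
    TRANSVERSE_COLON = "transverse_colon"
    SPLENIC_FLEXURE = "splenic_flexure"
    DESCENDING_COLON = "descending_colon"
    SIGMOID_COLON = "sigmoid_colon"
    OVERLAPPING_COLON = "overlapping_colon"
    UNSPECIFIED_COLON = "unspecified_colon"
    RECTOSIGMOID_JUNCTION = "rectosigmoid_junction"
    RECTUM = "rectum"
    ANUS = "anus"


class SideCategory(str, Enum):
    """Sidedness grouping of anatomic sites."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    TRANSVERSE = "TRANSVERSE"
    UNSPECIFIED = "UNSPECIFIED"
    RECTUM = "RECTUM"


class LexiconError(ValueError):
    """Base class for lexicon failures."""


class MalformedCodeError(LexiconError):
    """Raised when a code string cannot be normalized."""


class NotInLexiconError(LexiconError):
    """Raised when a normalized code has no entry in the site mapping."""


@dataclass(frozen=True)
class NormalizedCode:
    """A diagnosis code in canonical form.

    ``canonical`` is uppercase with dots and whitespace stripped; the
    system is ICD-10 exactly when the canonical form starts with a
    letter.
    """

    raw: str
    system: CodeSystem
    canonical: str

    def format(self) -> str:
        """Render the code with its conventional dot (``C184`` -> ``C18.4``)."""
        c = self.canonical
        head = 3
        if len(c) <= head:
            return c
        return f"{c[:head]}.{c[head:]}"


#: Code families that select colorectal-cancer patients.
INCLUSION_FAMILIES: tuple[str, ...] = ("153", "154", "C18", "C19", "C20", "C21")

# ICD-9-CM 153.x (colon) and 154.x (rectum/rectosigmoid/anus).
_ICD9_SITES: dict[str, AnatomicSite] = {
    "1530": AnatomicSite.HEPATIC_FLEXURE,
    "1531": AnatomicSite.TRANSVERSE_COLON,
    "1532": AnatomicSite.DESCENDING_COLON,
    "1533": AnatomicSite.SIGMOID_COLON,
    "1534": AnatomicSite.CECUM,
    "1535": AnatomicSite.APPENDIX,
    "1536": AnatomicSite.ASCENDING_COLON,
    "1537": AnatomicSite.SPLENIC_FLEXURE,
    "1538": AnatomicSite.OVERLAPPING_COLON,
    "1539": AnatomicSite.UNSPECIFIED_COLON,
    "1540": AnatomicSite.RECTOSIGMOID_JUNCTION,
    "1541": AnatomicSite.RECTUM,
    "1542": AnatomicSite.ANUS,
    "1543": AnatomicSite.ANUS,
    "1548": AnatomicSite.RECTUM,
}

# ICD-10-CM C18 (colon), C19 (rectosigmoid), C20 (rectum), C21 (anus).
_ICD10_SITES: dict[str, AnatomicSite] = {
    "C180": AnatomicSite.CECUM,
    "C181": AnatomicSite.APPENDIX,
    "C182": AnatomicSite.ASCENDING_COLON,
    "C183": AnatomicSite.HEPATIC_FLEXURE,
    "C184": AnatomicSite.TRANSVERSE_COLON,
    "C185": AnatomicSite.SPLENIC_FLEXURE,
    "C186": AnatomicSite.DESCENDING_COLON,
    "C187": AnatomicSite.SIGMOID_COLON,
    "C188": AnatomicSite.OVERLAPPING_COLON,
    "C189": AnatomicSite.UNSPECIFIED_COLON,
    "C19": AnatomicSite.RECTOSIGMOID_JUNCTION,
    "C20": AnatomicSite.RECTUM,
    "C210": AnatomicSite.ANUS,
    "C211": AnatomicSite.ANUS,
    "C212": AnatomicSite.ANUS,
    "C218": AnatomicSite.ANUS,
}

_SITE_TO_SIDE: dict[AnatomicSite, SideCategory] = {
    AnatomicSite.SPLENIC_FLEXURE: SideCategory.LEFT,
    AnatomicSite.DESCENDING_COLON: SideCategory.LEFT,
    AnatomicSite.SIGMOID_COLON: SideCategory.LEFT,
    AnatomicSite.RECTOSIGMOID_JUNCTION: SideCategory.LEFT,
    AnatomicSite.CECUM: SideCategory.RIGHT,
    AnatomicSite.ASCENDING_COLON: SideCategory.RIGHT,
    AnatomicSite.HEPATIC_FLEXURE: SideCategory.RIGHT,
    AnatomicSite.TRANSVERSE_COLON: SideCategory.TRANSVERSE,
    # No slot in the three-side scheme: treated as side-unspecified.
    AnatomicSite.UNSPECIFIED_COLON: SideCategory.UNSPECIFIED,
    AnatomicSite.APPENDIX: SideCategory.UNSPECIFIED,
    AnatomicSite.OVERLAPPING_COLON: SideCategory.UNSPECIFIED,
    AnatomicSite.RECTUM: SideCategory.RECTUM,
    AnatomicSite.ANUS: SideCategory.RECTUM,
}


def normalize_code(code: str, system_hint: CodeSystem | None = None) -> NormalizedCode:
    """Normalize a raw diagnosis-code string.

    Strips dots and whitespace, uppercases, and infers the code system
    from the leading character (letter -> ICD-10) when no hint is given.

    Raises
    ------
    MalformedCodeError
        If the code is empty, non-alphanumeric after stripping, or the
        hint contradicts the code's leading character.
    """
    if not isinstance(code, str):
        raise MalformedCodeError(f"code must be a string, got {type(code).__name__}")
    canonical = "".join(code.split()).replace(".", "").upper()
    if not canonical or not canonical.isalnum():
        raise MalformedCodeError(f"malformed diagnosis code: {code!r}")
    inferred = CodeSystem.ICD10 if canonical[0].isalpha() else CodeSystem.ICD9
    if system_hint is not None and system_hint != inferred:
        raise MalformedCodeError(
            f"system hint {system_hint.value} contradicts code {code!r} "
            f"(leading character implies {inferred.value})"
        )
    return NormalizedCode(raw=code, system=inferred, canonical=canonical)


def is_inclusion_code(code: NormalizedCode) -> bool:
    """True iff the code belongs to a colorectal-cancer inclusion family
    (153.x, 154.x, C18x, C19x, C20x, C21x)."""
    return code.canonical.startswith(INCLUSION_FAMILIES)


def site_of(code: NormalizedCode) -> AnatomicSite:
    """Anatomic site of a colorectal diagnosis code.

    Unknown child codes inside an inclusion family raise
    :class:`NotInLexiconError` rather than silently mapping to
    unspecified, so data-quality problems surface.
    """
    table = _ICD10_SITES if code.system is CodeSystem.ICD10 else _ICD9_SITES
    site = table.get(code.canonical)
    if site is None:
        raise NotInLexiconError(f"code {code.raw!r} is not in the colorectal lexicon")
    return site


def side_of(site: AnatomicSite) -> SideCategory:
    """Sidedness category of an anatomic site."""
    return _SITE_TO_SIDE[site]


def side_of_code(code: NormalizedCode) -> SideCategory:
    """Convenience composition ``side_of(site_of(code))``."""
    return side_of(site_of(code))


def lexicon_codes() -> dict[str, AnatomicSite]:
    """All canonical codes in the shipped lexicon and their sites."""
    out: dict[str, AnatomicSite] = {}
    out.update(_ICD9_SITES)
    out.update(_ICD10_SITES)
    return out


#: ICD-9 <-> ICD-10 site-equivalent pairs (used by the generator and by
#: revision-parity checks).
ICD9_ICD10_PAIRS: tuple[tuple[str, str], ...] = (
    ("1530", "C183"),
    ("1531", "C184"),
    ("1532", "C186"),
    ("1533", "C187"),
    ("1534", "C180"),
    ("1535", "C181"),
    ("1536", "C182"),
    ("1537", "C185"),
    ("1538", "C188"),
    ("1539", "C189"),
    ("1540", "C19"),
    ("1541", "C20"),
    ("1542", "C211"),
    ("1543", "C210"),
)
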